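import numpy as np
import pandas as pd
import pytest

from dysbioscan.synthetic import SyntheticConfig, gen_metagenome_cohort
from dysbioscan.tables import GenomeHitTable, LipidTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_lipid_table(rng):
    """6 HC + 5 CD samples, 8 species, no planted effect."""
    samples = [f"HC{i}" for i in range(6)] + [f"CD{i}" for i in range(5)]
    conc = pd.DataFrame(
        np.exp(rng.normal(2.0, 0.5, size=(11, 8))),
        index=samples,
        columns=[f"sp{j}" for j in range(8)],
    )
    labels = pd.Series(["HC"] * 6 + ["CD"] * 5, index=conc.index)
    return LipidTable(concentrations=conc, group_labels=labels)


@pytest.fixture
def toy_hits():
    """Three genomes in two phyla over two samples; hand-checkable."""
    counts = pd.DataFrame(
        {"s1": [100, 100, 50], "s2": [10, 0, 40]},
        index=pd.Index(["g1", "g2", "g3"], name="genome_id"),
    )
    lengths = pd.Series([1_000_000, 2_000_000, 500_000], index=counts.index)
    lineages = pd.Series(
        [
            "k__B;p__P1;c__C1;o__O1;f__F1;g__G1;s__S1",
            "k__B;p__P1;c__C1;o__O1;f__F1;g__G1;s__S2",
            "k__B;p__P2;c__C2;o__O2;f__F2;g__G2;s__S3",
        ],
        index=counts.index,
    )
    return GenomeHitTable(best_hit_counts=counts, genome_lengths=lengths,
                          lineages=lineages)


@pytest.fixture(scope="session")
def metagenome_cohort():
    """One modest seeded cohort shared across read-only tests."""
    cfg = SyntheticConfig.metagenome_default(seed=3, n_features=60)
    return cfg, gen_metagenome_cohort(cfg)
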