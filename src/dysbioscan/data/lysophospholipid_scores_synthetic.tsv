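sample_id	group	total_score
HC01	HC	20
HC02	HC	25
HC03	HC	30
HC04	HC	35
HC05	HC	40
HC06	HC	45
HC07	HC	50
HC08	HC	55
HC09	HC	60
HC10	HC	65
HC11	HC	70
HC12	HC	74
CD01	CD	15
CD02	CD	45
CD03	CD	52
CD04	CD	66
CD05	CD	72
CD06	CD	78
CD07	CD	82
CD08	CD	88
CD09	CD	95
CD10	CD	103
CD11	CD	115
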