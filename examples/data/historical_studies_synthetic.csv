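study_id,publication_year,sample_size,sparing_proportion
aspo_2014_synthetic,2014,277,0.22
cso_2019_synthetic,2019,77,0.578
global_2024_synthetic,2024,132,0.712
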