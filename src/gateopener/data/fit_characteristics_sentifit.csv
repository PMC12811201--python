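cutoff,positivity,sens_any_neoplasm,sens_advanced_neoplasm,sens_preclinical_crc,spec_no_advanced
17,0.10,0.196,0.394,0.907,0.933
10,0.15,0.274,0.485,0.963,0.889
8,0.19,0.321,0.534,0.981,0.851
6,0.29,0.408,0.595,0.981,0.747
4,0.44,0.545,0.683,0.981,0.582
3,0.51,0.604,0.727,0.981,0.511
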