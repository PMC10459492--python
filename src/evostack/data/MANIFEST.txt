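ddb43dc1ac0eba8a32defc861459a9871d6938dabbde7ade031b3e8162617f2e  one_step_results.csv
01008c629d6eb06e7d2b5daf2b139ba91ced13a537f9f0839f725bdc1abb76c4  three_step_results.csv
2eba1e050e1b437c530b04466dcc10b620a04f49b8a3d316ecb4cc57452e8342  studentized_range_qinf.csv
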