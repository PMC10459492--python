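alpha,k,q
0.05,2,2.771808
0.05,3,3.314493
0.05,4,3.633160
0.05,5,3.857656
0.05,6,4.030092
0.05,7,4.169554
0.05,8,4.286309
0.05,9,4.386509
0.05,10,4.474124
0.05,11,4.551864
0.05,12,4.621655
0.05,13,4.684920
0.05,14,4.742732
0.05,15,4.795924
0.05,16,4.845154
0.05,17,4.890951
0.05,18,4.933745
0.05,19,4.973892
0.05,20,5.011689
0.1,2,2.326174
0.1,3,2.902380
0.1,4,3.240446
0.1,5,3.478281
0.1,6,3.660721
0.1,7,3.808098
0.1,8,3.931349
0.1,9,4.037023
0.1,10,4.129346
0.1,11,4.211200
0.1,12,4.284635
0.1,13,4.351158
0.1,14,4.411913
0.1,15,4.467782
0.1,16,4.519464
0.1,17,4.567519
0.1,18,4.612403
0.1,19,4.654494
0.1,20,4.694104
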