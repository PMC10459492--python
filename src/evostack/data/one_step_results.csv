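participant,model,vaf,rmse
1,LASSO,94.75,0.2225
1,MLP,94.12,0.2392
1,GP,88.52,0.3298
1,SVR,90.96,0.2919
1,XGBoost,91.77,0.2791
1,JADE-STACK,96.12,0.2076
1,DE-STACK,95.01,0.2122
1,GA-STACK,95.28,0.2063
1,PSO-STACK,95.34,0.2051
1,NARMAX-HNN,94.37,
1,NARMAX-P,95.52,
1,Volterra_1,38.37,
1,Volterra_2,45.00,
2,LASSO,94.06,0.2667
2,MLP,93.58,0.2792
2,GP,85.74,0.4136
2,SVR,88.10,0.3781
2,XGBoost,87.26,0.3909
2,JADE-STACK,94.48,0.2616
2,DE-STACK,94.21,0.2631
2,GA-STACK,94.22,0.2629
2,PSO-STACK,94.25,0.2625
2,NARMAX-HNN,92.83,
2,NARMAX-P,94.74,
2,Volterra_1,29.12,
2,Volterra_2,34.00,
3,LASSO,93.21,0.2650
3,MLP,91.48,0.2975
3,GP,88.40,0.3466
3,SVR,90.86,0.3073
3,XGBoost,89.81,0.3251
3,JADE-STACK,95.04,0.2545
3,DE-STACK,93.47,0.2616
3,GA-STACK,94.01,0.2505
3,PSO-STACK,93.90,0.2525
3,NARMAX-HNN,90.95,
3,NARMAX-P,92.95,
3,Volterra_1,32.18,
3,Volterra_2,40.00,
4,LASSO,86.70,0.3299
4,MLP,84.59,0.3565
4,GP,79.72,0.4073
4,SVR,83.04,0.3724
4,XGBoost,79.45,0.4103
4,JADE-STACK,91.59,0.3336
4,DE-STACK,85.56,0.3433
4,GA-STACK,86.61,0.3309
4,PSO-STACK,85.18,0.3480
4,NARMAX-HNN,91.02,
4,NARMAX-P,91.94,
4,Volterra_1,28.10,
4,Volterra_2,50.00,
5,LASSO,93.12,0.2529
5,MLP,91.86,0.2767
5,GP,89.39,0.3144
5,SVR,91.86,0.2752
5,XGBoost,89.11,0.3183
5,JADE-STACK,94.96,0.2348
5,DE-STACK,93.24,0.2504
5,GA-STACK,94.06,0.2347
5,PSO-STACK,94.09,0.2340
5,NARMAX-HNN,92.58,
5,NARMAX-P,94.04,
5,Volterra_1,53.74,
5,Volterra_2,56.00,
6,LASSO,94.59,0.2068
6,MLP,93.91,0.2223
6,GP,88.89,0.2963
6,SVR,91.31,0.2620
6,XGBoost,90.60,0.2739
6,JADE-STACK,95.99,0.2031
6,DE-STACK,94.54,0.2047
6,GA-STACK,94.55,0.2043
6,PSO-STACK,94.58,0.2035
6,NARMAX-HNN,93.76,
6,NARMAX-P,93.72,
6,Volterra_1,61.07,
6,Volterra_2,46.00,
7,LASSO,95.25,0.2226
7,MLP,94.43,0.2672
7,GP,91.38,0.3000
7,SVR,92.97,0.2713
7,XGBoost,91.75,0.2933
7,JADE-STACK,95.39,0.2167
7,DE-STACK,95.13,0.2215
7,GA-STACK,95.34,0.2169
7,PSO-STACK,95.04,0.2247
7,NARMAX-HNN,93.08,
7,NARMAX-P,95.73,
7,Volterra_1,54.30,
7,Volterra_2,60.00,
8,LASSO,91.01,0.2924
8,MLP,88.51,0.3454
8,GP,84.57,0.3836
8,SVR,87.02,0.3514
8,XGBoost,82.55,0.4083
8,JADE-STACK,93.10,0.2950
8,DE-STACK,90.19,0.3061
8,GA-STACK,90.95,0.2939
8,PSO-STACK,88.64,0.3293
8,NARMAX-HNN,90.23,
8,NARMAX-P,91.90,
8,Volterra_1,39.95,
8,Volterra_2,51.00,
9,LASSO,92.48,0.2831
9,MLP,91.33,0.3071
9,GP,83.97,0.4144
9,SVR,86.67,0.3792
9,XGBoost,85.37,0.3953
9,JADE-STACK,92.37,0.2834
9,DE-STACK,91.90,0.2949
9,GA-STACK,92.33,0.2864
9,PSO-STACK,92.44,0.2841
9,NARMAX-HNN,90.36,
9,NARMAX-P,92.24,
9,Volterra_1,26.35,
9,Volterra_2,36.00,
10,LASSO,95.83,0.2137
10,MLP,95.09,0.2485
10,GP,90.57,0.3216
10,SVR,92.94,0.2787
10,XGBoost,93.69,0.2627
10,JADE-STACK,95.99,0.2186
10,DE-STACK,95.94,0.2128
10,GA-STACK,95.95,0.2129
10,PSO-STACK,95.93,0.2126
10,NARMAX-HNN,94.15,
10,NARMAX-P,96.28,
10,Volterra_1,65.19,
10,Volterra_2,44.00,
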