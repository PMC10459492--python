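participant,model,vaf,rmse
1,LASSO,77.62,0.4605
1,MLP,70.97,0.5460
1,GP,66.39,0.5626
1,SVR,67.95,0.5514
1,XGBoost,66.12,0.5654
1,JADE-STACK,77.59,0.4655
1,DE-STACK,73.81,0.3618
1,GA-STACK,77.81,0.4610
1,PSO-STACK,78.28,0.4577
1,NARMAX-HNN,63.44,
1,NARMAX-P,57.08,
2,LASSO,61.16,0.6822
2,MLP,65.57,0.6467
2,GP,52.82,0.7530
2,SVR,52.85,0.7531
2,XGBoost,50.13,0.7760
2,JADE-STACK,63.77,0.6589
2,DE-STACK,63.82,0.6584
2,GA-STACK,62.98,0.6662
2,PSO-STACK,63.35,0.6638
2,NARMAX-HNN,56.85,
2,NARMAX-P,39.53,
3,LASSO,61.39,0.6319
3,MLP,47.20,0.7430
3,GP,66.02,0.5953
3,SVR,66.43,0.5908
3,XGBoost,70.08,0.5578
3,JADE-STACK,64.92,0.6023
3,DE-STACK,61.14,0.6342
3,GA-STACK,65.78,0.5949
3,PSO-STACK,65.63,0.5961
3,NARMAX-HNN,67.16,
3,NARMAX-P,31.17,
4,LASSO,53.62,0.6173
4,MLP,46.84,0.6698
4,GP,48.00,0.6528
4,SVR,49.96,0.6415
4,XGBoost,37.54,0.7169
4,JADE-STACK,52.37,0.6252
4,DE-STACK,47.47,0.6571
4,GA-STACK,53.68,0.6194
4,PSO-STACK,48.71,0.6479
4,NARMAX-HNN,74.89,
4,NARMAX-P,32.26,
5,LASSO,67.66,0.5485
5,MLP,60.96,0.6118
5,GP,65.26,0.5699
5,SVR,67.05,0.5538
5,XGBoost,55.64,0.6426
5,JADE-STACK,69.51,0.5327
5,DE-STACK,66.80,0.5564
5,GA-STACK,69.34,0.5340
5,PSO-STACK,69.48,0.5333
5,NARMAX-HNN,82.31,
5,NARMAX-P,61.57,
6,LASSO,72.10,0.4700
6,MLP,68.02,0.5190
6,GP,63.12,0.5411
6,SVR,65.50,0.5223
6,XGBoost,59.68,0.5706
6,JADE-STACK,72.55,0.4656
6,DE-STACK,72.85,0.4633
6,GA-STACK,72.98,0.4620
6,PSO-STACK,73.81,0.4555
6,NARMAX-HNN,75.55,
6,NARMAX-P,49.18,
7,LASSO,76.20,0.4985
7,MLP,67.53,0.6660
7,GP,70.85,0.5515
7,SVR,72.10,0.5402
7,XGBoost,71.49,0.5454
7,JADE-STACK,76.74,0.4930
7,DE-STACK,75.07,0.5106
7,GA-STACK,67.53,0.4843
7,PSO-STACK,73.54,0.5274
7,NARMAX-HNN,74.32,
7,NARMAX-P,65.35,
8,LASSO,59.55,0.6207
8,MLP,43.11,0.7953
8,GP,52.03,0.6779
8,SVR,53.03,0.6685
8,XGBoost,46.70,0.7168
8,JADE-STACK,61.08,0.6085
8,DE-STACK,55.87,0.6486
8,GA-STACK,58.56,0.6283
8,PSO-STACK,55.45,0.6510
8,NARMAX-HNN,43.40,
8,NARMAX-P,32.57,
9,LASSO,63.69,0.6232
9,MLP,57.40,0.6775
9,GP,53.12,0.7086
9,SVR,54.30,0.7034
9,XGBoost,55.09,0.6932
9,JADE-STACK,63.47,0.6290
9,DE-STACK,65.61,0.6108
9,GA-STACK,62.90,0.6334
9,PSO-STACK,63.33,0.6289
9,NARMAX-HNN,77.16,
9,NARMAX-P,37.98,
10,LASSO,73.92,0.5348
10,MLP,66.34,0.6664
10,GP,67.07,0.6008
10,SVR,67.69,0.5955
10,XGBoost,74.32,0.5304
10,JADE-STACK,73.03,0.5445
10,DE-STACK,73.84,0.5353
10,GA-STACK,73.65,0.5379
10,PSO-STACK,73.71,0.5363
10,NARMAX-HNN,78.44,
10,NARMAX-P,64.21,
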