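pattern,kappa
XOOOO,-0.555297
XOOOX,-1.288087
XOOXO,0.305483
XOOXX,-0.305483
XOXOO,-0.083538
XOXOX,-0.700532
XOXXO,0.878427
XOXXX,0.157059
XXOOO,-0.448809
XXOOX,-1.121573
XXOXO,0.438980
XXOXX,-0.314374
XXXOO,-0.025999
XXXOX,-0.893873
XXXXO,-0.202071
XXXXX,-2.000000
OXOOOO,-0.547046
OXOOOX,-1.250123
OXOOXO,0.372007
OXOOXX,-0.168652
OXOXOO,0.021541
OXOXOX,-0.500000
OXOXXO,1.168652
OXOXXX,0.610788
OXXOOO,-0.295915
OXXOOX,-0.831348
OXXOXO,0.831348
OXXOXX,0.295915
OXXXOO,0.500000
OXXXOX,-0.043148
OXXXXO,1.603423
OXXXXX,0.893064
OOXOOOO,-0.546627
OOXOOOX,-1.246549
OOXOOXO,0.380443
OOXOOXX,-0.144333
OOXOXOO,0.038540
OOXOXOX,-0.458002
OOXOXXO,1.237323
OOXOXXX,0.732282
OOXXOOO,-0.266118
OOXXOOX,-0.762677
OOXXOXO,0.934564
OOXXOXX,0.462898
OOXXXOO,0.648075
OOXXXOX,0.187174
OOXXXXO,1.916882
OOXXXXX,1.329121
OOOXOOOO,0.182522
OOOXOOOX,-0.400015
OOOXOOXO,0.380903
OOOXOOXX,-0.142208
OOOXOXOO,0.039809
OOOXOXOX,-0.453253
OOOXOXXO,1.247042
OOOXOXXX,0.755935
OOOXXOOO,-0.263221
OOOXXOOX,-0.752958
OOOXXOXO,0.952404
OOOXXOXX,0.500000
OOOXXXOO,0.678077
OOOXXXOX,0.244065
OOOXXXXO,2.000000
OOOXXXXX,1.464904
OOOOXOOOO,0.761674
OOOOXOOOX,0.190349
OOOOXOOXO,1.039846
OOOOXOOXX,0.541554
OOOOXOXOO,0.039846
OOOOXOXOX,-0.453032
OOOOXOXXO,1.247644
OOOOXOXXX,0.758206
OOOOXXOOO,-0.263109
OOOOXXOOX,-0.752356
OOOOXXOXO,0.953846
OOOOXXOXX,0.504390
OOOOXXXOO,0.681143
OOOOXXXOX,0.252209
OOOOXXXXO,2.000000
OOOOXXXXX,1.496240
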