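config_id,n_radars,densenet121,resnet50,efficientnet_b0,phresnet50
1,8,0.804,0.721,0.775,0.723
2,7,0.703,0.774,0.688,0.738
3,7,0.794,0.787,0.758,0.729
4,7,0.771,0.771,0.662,0.728
5,6,0.809,0.781,0.702,0.750
6,6,0.785,0.760,0.684,0.735
7,6,0.803,0.760,0.641,0.722
8,5,0.675,0.758,0.652,0.698
9,5,0.674,0.755,0.662,0.707
10,5,0.779,0.720,0.735,0.698
11,5,0.750,0.728,0.715,0.708
12,5,0.770,0.744,0.725,0.691
13,5,0.661,0.708,0.736,0.707
14,4,0.592,0.721,0.698,0.662
15,4,0.612,0.712,0.709,0.687
16,4,0.728,0.676,0.684,0.653
17,4,0.735,0.724,0.696,0.669
18,4,0.753,0.722,0.725,0.690
19,4,0.702,0.668,0.678,0.625
20,4,0.748,0.707,0.709,0.691
21,3,0.550,0.672,0.678,0.656
22,2,0.594,0.649,0.633,0.613
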