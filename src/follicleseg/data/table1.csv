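image,accuracy_classical,accuracy_hybrid,dice_classical,dice_hybrid,jaccard_classical,jaccard_hybrid,sensitivity_classical,sensitivity_hybrid
Image 1,0.7900,0.8303,0.5869,0.7275,0.4154,0.5717,0.4268,0.6481
Image 2,0.8891,0.9231,0.7583,0.8568,0.6107,0.7495,0.6116,0.8099
Image 3,0.7064,0.8313,0.5152,0.7690,0.3470,0.6247,0.3472,0.6249
Image 4,0.8442,0.9007,0.7051,0.8132,0.5445,0.7111,0.5445,0.7149
Image 5,0.7951,0.8500,0.6082,0.7498,0.4370,0.5598,0.4421,0.6247
Image 6,0.8446,0.9068,0.7242,0.8561,0.5677,0.7484,0.5727,0.7775
Image 7,0.8778,0.9112,0.7570,0.8385,0.6090,0.7219,0.6150,0.7445
Image 8,0.9756,0.8935,0.8788,0.6357,0.7838,0.4660,0.9492,0.9986
Image 9,0.8482,0.9477,0.6366,0.9013,0.4669,0.8203,0.4685,0.8406
Image 10,0.9139,0.9607,0.8121,0.9244,0.6837,0.8595,0.6855,0.8865
Image 11,0.8932,0.9621,0.7023,0.9190,0.5412,0.8502,0.5448,0.9299
Image 12,0.8444,0.8563,0.5811,0.7237,0.4095,0.5670,0.4426,0.7713
Image 13,0.9215,0.8827,0.7904,0.7721,0.6535,0.6288,0.6858,0.9208
Image 14,0.8913,0.9261,0.7077,0.8175,0.5476,0.6913,0.5557,0.6992
Image 15,0.8697,0.9030,0.6321,0.7503,0.4621,0.6004,0.4626,0.6024
Image 16,0.8370,0.8993,0.4995,0.7437,0.3329,0.5920,0.3339,0.6001
Image 17,0.7730,0.7915,0.3663,0.5284,0.2242,0.3590,0.2910,0.5181
Image 18,0.9403,0.9488,0.7989,0.8357,0.6652,0.7178,0.6683,0.7332
Image 19,0.9488,0.9598,0.8240,0.8680,0.7007,0.7667,0.7026,0.7752
Image 20,0.9322,0.9014,0.5231,0.4930,0.3542,0.3271,0.5373,0.6740
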