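description: Synthetic six-class Bernoulli item profiles for 50 dichotomized AQ items. Calibrated so class
  expected total scores match the target class means; an emulation, not published item-level data.
weights: [0.1466, 0.1387, 0.2458, 0.2107, 0.1045, 0.1537]
male_prob: [0.52, 0.4, 0.42, 0.3, 0.47, 0.6]
item_probs:
  class_1: [0.2585, 0.3399, 0.4447, 0.8066, 0.6094, 0.7969, 0.7116, 0.3563, 0.7079, 0.4532, 0.2614, 0.7743,
    0.3412, 0.5059, 0.3513, 0.6968, 0.284, 0.4634, 0.5965, 0.6608, 0.4542, 0.3051, 0.7669, 0.25, 0.485,
    0.3232, 0.752, 0.3253, 0.2587, 0.7243, 0.8091, 0.4795, 0.6022, 0.5215, 0.6351, 0.7443, 0.4974, 0.3104,
    0.4778, 0.4531, 0.6577, 0.6956, 0.5078, 0.2912, 0.2707, 0.2962, 0.2904, 0.4797, 0.3043, 0.5008]
  class_2: [0.559, 0.6528, 0.2727, 0.6438, 0.2147, 0.6323, 0.2581, 0.5594, 0.2676, 0.3553, 0.5889, 0.5881,
    0.6414, 0.357, 0.665, 0.5791, 0.5855, 0.3358, 0.2209, 0.2304, 0.4103, 0.6854, 0.6288, 0.5704, 0.3183,
    0.6682, 0.6478, 0.5537, 0.622, 0.5566, 0.621, 0.276, 0.2397, 0.4052, 0.1993, 0.6272, 0.3022, 0.636,
    0.2649, 0.3677, 0.2743, 0.2667, 0.3112, 0.5889, 0.6476, 0.6712, 0.5902, 0.3286, 0.5729, 0.3301]
  class_3: [0.1901, 0.2397, 0.2226, 0.251, 0.7193, 0.2465, 0.7093, 0.1836, 0.676, 0.2704, 0.1897, 0.2358,
    0.2374, 0.3435, 0.211, 0.2899, 0.139, 0.1917, 0.6931, 0.7043, 0.255, 0.1446, 0.2818, 0.14, 0.2554,
    0.2264, 0.228, 0.2149, 0.246, 0.2092, 0.2474, 0.2852, 0.7078, 0.2689, 0.6392, 0.2016, 0.1943, 0.1712,
    0.2583, 0.292, 0.718, 0.6394, 0.3352, 0.1846, 0.2262, 0.1713, 0.1407, 0.2867, 0.1899, 0.347]
  class_4: [0.1475, 0.6049, 0.2394, 0.2429, 0.2112, 0.2156, 0.1612, 0.1286, 0.1664, 0.2608, 0.1967, 0.1261,
    0.1451, 0.6049, 0.1985, 0.1385, 0.1871, 0.202, 0.2199, 0.1581, 0.302, 0.1596, 0.2319, 0.1899, 0.2048,
    0.23, 0.148, 0.1499, 0.1422, 0.6049, 0.1652, 0.271, 0.241, 0.2158, 0.243, 0.167, 0.2245, 0.1556, 0.2054,
    0.206, 0.2145, 0.2377, 0.2145, 0.1907, 0.2163, 0.6049, 0.2285, 0.1939, 0.1753, 0.221]
  class_5: [0.7052, 0.6406, 0.4602, 0.4488, 0.2077, 0.4479, 0.2742, 0.7016, 0.2793, 0.504, 0.6973, 0.4578,
    0.6893, 0.4035, 0.6306, 0.4197, 0.6326, 0.3451, 0.2421, 0.215, 0.4124, 0.6993, 0.3986, 0.6789, 0.4841,
    0.7116, 0.4897, 0.6367, 0.6018, 0.4667, 0.427, 0.4549, 0.2501, 0.4437, 0.2085, 0.4549, 0.4242, 0.6373,
    0.45, 0.4073, 0.2674, 0.3051, 0.5029, 0.6428, 0.6309, 0.6921, 0.6503, 0.4074, 0.6231, 0.5079]
  class_6: [0.743, 0.7939, 0.162, 0.933, 0.7693, 0.7278, 0.7257, 0.8286, 0.162, 0.8373, 0.9829, 0.933,
    0.7611, 0.6918, 0.7428, 0.8067, 0.933, 0.7491, 0.7311, 0.8155, 0.162, 0.933, 0.7494, 0.7283, 0.6932,
    0.933, 0.7429, 0.8173, 0.7124, 0.736, 0.7759, 0.8126, 0.7302, 0.7047, 0.8498, 0.7018, 0.767, 0.933,
    0.7744, 0.8407, 0.7244, 0.8103, 0.8271, 0.7096, 0.7611, 0.933, 0.747, 0.817, 0.8106, 0.813]
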