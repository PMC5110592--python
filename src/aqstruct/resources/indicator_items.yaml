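description: Best-effort item-to-composite map for the four taxometric indicators
  (43 of 50 items; negative entries are subtracted, e.g. item 30). The published table's
  typography is ambiguous, so this map is editable data, not code.
indicators:
  ind_1: [1, 2, 8, 11, 13, 15, 17, 22, 24, 26, 28, 29, 38, 44, 45, 46, 47, 49]
  ind_2: [4, 6, 12, 16, 23, 27, -30, 31, 36]
  ind_3: [5, 7, 9, 19, 20, 33, 35, 41, 42]
  ind_4: [10, 14, 21, 25, 34, 43, 50]
excluded: [3, 18, 32, 37, 39, 40, 48]
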