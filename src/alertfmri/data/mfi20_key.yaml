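# Scoring key for the 20-item multidimensional fatigue inventory.
# Responses are on a 1..5 agreement scale anchored so that, after applying
# the reversal map r -> 6 - r to the items listed under `reversed`, higher
# scored values always mean more fatigue.  Each domain sums exactly 4 items
# (domain range 4..20; total range 20..100).
domains:
  general_fatigue: [1, 5, 12, 16]
  physical_fatigue: [2, 8, 14, 20]
  reduced_activity: [3, 6, 10, 17]
  reduced_motivation: [4, 9, 15, 18]
  mental_fatigue: [7, 11, 13, 19]
reversed: [2, 5, 9, 10, 13, 14, 16, 17, 18, 19]
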