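# Derived-trait memberships over the 39 UHPLC glycan peaks.
# Each trait is a weighted sum of %Area peak shares; GP12 contains
# co-eluting structures and contributes half its area to each of two
# families (weight 0.5). Three families partition the glycome:
#   branching  {LB, HB} + HM
#   galactosylation {G0..G4} + HM
#   sialylation {S0..S4} + HM
# each summing to 100% per sample.
LB:
  "0.5": [12]
  "1": [1, 2, 3, 4, 5, 6, 8, 9, 10, 11, 13, 14, 15, 16, 17, 18, 20, 21, 22, 23]
HB:
  "1": [24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39]
G0:
  "1": [1, 2]
G1:
  "1": [3, 4, 5, 6, 13]
G2:
  "0.5": [12]
  "1": [8, 9, 10, 11, 14, 15, 16, 17, 18, 20, 21, 22, 23]
G3:
  "1": [24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34, 35]
G4:
  "1": [36, 37, 38, 39]
S0:
  "1": [1, 2, 3, 4, 5, 6, 8, 9, 10, 11]
S1:
  "0.5": [12]
  "1": [13, 14, 15, 16, 17]
S2:
  "1": [18, 20, 21, 22, 23, 24, 25, 26, 27]
S3:
  "1": [28, 29, 30, 31, 32, 33, 34, 35, 36]
S4:
  "1": [37, 38, 39]
B:
  "1": [2, 3, 6, 9, 11, 15, 17, 23]
AF:
  "1": [27, 33, 35, 39]
CF:
  "1": [1, 2, 4, 5, 6, 10, 11, 13, 16, 17, 22, 23, 31, 34, 35]
HM:
  "0.5": [12]
  "1": [7, 19]
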