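# Packaged simulation-truth scenarios: true probabilities of each pooled
# toxicity-grade category (rows: 0-1, 2, 3, 4) at each of six dose levels
# (columns), for eight scenarios A-H.  Values are stored verbatim as printed;
# two columns (B dose 6, D dose 6) sum to 1.06 and 1.14 respectively — see
# docs/methods.md.  Sampling renormalises proportionally.
A:
  "0-1": [0.83, 0.75, 0.62, 0.51, 0.34, 0.19]
  "2":   [0.12, 0.15, 0.18, 0.19, 0.16, 0.11]
  "3":   [0.04, 0.07, 0.11, 0.14, 0.15, 0.11]
  "4":   [0.01, 0.03, 0.09, 0.16, 0.35, 0.59]
B:
  "0-1": [0.92, 0.85, 0.70, 0.55, 0.24, 0.00]
  "2":   [0.03, 0.05, 0.10, 0.15, 0.26, 0.36]
  "3":   [0.03, 0.07, 0.14, 0.21, 0.35, 0.49]
  "4":   [0.02, 0.03, 0.06, 0.09, 0.15, 0.21]
C:
  "0-1": [0.78, 0.56, 0.50, 0.40, 0.30, 0.16]
  "2":   [0.14, 0.19, 0.18, 0.17, 0.15, 0.09]
  "3":   [0.06, 0.12, 0.14, 0.15, 0.14, 0.10]
  "4":   [0.02, 0.12, 0.18, 0.28, 0.41, 0.65]
D:
  "0-1": [0.88, 0.64, 0.52, 0.35, 0.17, 0.00]
  "2":   [0.04, 0.12, 0.16, 0.22, 0.28, 0.39]
  "3":   [0.06, 0.17, 0.22, 0.30, 0.38, 0.52]
  "4":   [0.02, 0.07, 0.10, 0.13, 0.17, 0.23]
E:
  "0-1": [1.00, 0.91, 0.88, 0.86, 0.80, 0.65]
  "2":   [0.00, 0.06, 0.07, 0.08, 0.10, 0.13]
  "3":   [0.00, 0.03, 0.04, 0.05, 0.08, 0.14]
  "4":   [0.00, 0.00, 0.01, 0.01, 0.02, 0.08]
F:
  "0-1": [0.50, 0.38, 0.29, 0.19, 0.13, 0.08]
  "2":   [0.25, 0.24, 0.21, 0.16, 0.11, 0.07]
  "3":   [0.11, 0.12, 0.12, 0.10, 0.08, 0.05]
  "4":   [0.14, 0.26, 0.38, 0.55, 0.68, 0.80]
G:
  "0-1": [0.78, 0.58, 0.50, 0.40, 0.30, 0.16]
  "2":   [0.14, 0.18, 0.18, 0.17, 0.15, 0.09]
  "3":   [0.00, 0.00, 0.00, 0.00, 0.00, 0.00]
  "4":   [0.08, 0.24, 0.32, 0.43, 0.55, 0.75]
H:
  "0-1": [0.92, 0.76, 0.68, 0.57, 0.45, 0.25]
  "2":   [0.00, 0.00, 0.00, 0.00, 0.00, 0.00]
  "3":   [0.08, 0.24, 0.32, 0.43, 0.55, 0.75]
  "4":   [0.00, 0.00, 0.00, 0.00, 0.00, 0.00]
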