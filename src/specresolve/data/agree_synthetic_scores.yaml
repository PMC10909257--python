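# SYNTHETIC per-principle AGREE scores for the spectrophotometric-chemometric
# procedure. The source study reports only the aggregated pictogram value
# (0.77); it never itemizes the twelve principle scores. The breakdown below
# is an editorial reconstruction chosen to be plausible for a direct UV-Vis
# method using methanol (no derivatization, low energy, modest solvent
# toxicity) and to average to the reported overall under equal weights. It is
# a regression fixture, not measured data.
principles:
  - {id: 1, name: sample treatment, score: 0.70}
  - {id: 2, name: sample amount, score: 0.85}
  - {id: 3, name: device positioning, score: 0.66}
  - {id: 4, name: procedure steps, score: 0.80}
  - {id: 5, name: automation / miniaturization, score: 0.75}
  - {id: 6, name: derivatization, score: 1.00}
  - {id: 7, name: waste, score: 0.55}
  - {id: 8, name: sample throughput, score: 0.75}
  - {id: 9, name: energy consumption, score: 0.95}
  - {id: 10, name: reagent source, score: 0.60}
  - {id: 11, name: reagent toxicity, score: 0.63}
  - {id: 12, name: operator safety, score: 1.00}
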