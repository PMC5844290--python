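# Full study on the built-in simulated panel.
# Run:  fluctassay run --config examples/study.yaml --out-dir results/
seed: 42
estimator: auto
alpha: 0.05
n_boot: 2000
simulate:
  preset: paper_panel
reference: WT
exo_null: pol2-exo-null
dominance:
  - wt: WT/WT
    het: pol2-strong/WT
    hom: pol2-strong/pol2-strong
synergy:
  - wt: WT
    a: pol2-syn
    b: mlh1
    ab: pol2-syn mlh1
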