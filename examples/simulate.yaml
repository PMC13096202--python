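# Full-pipeline run on a simulated cohort under the default study conditions:
# 90 HC / 113 FEP subjects, 48 inflammation-panel proteins, hubs C4A/C4B/C1QA.
# Permutation and bootstrap counts are reduced from the 10,000 defaults to
# keep the example quick; raise them for production-grade empirical p-values.
simulate:
  n_hc: 90
  n_fep: 113
  n_panel: 48
  missing_rate: 0.02
hubs: [C4A, C4B, C1QA]
panel: auto
covariate_cols: [age, sex, bmi, medication]
method_policy: spearman
n_perm: 2000
n_boot: 2000
q_fdr: 0.10
seed: 7
outdir: results/example_run
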