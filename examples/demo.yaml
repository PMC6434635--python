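# End-to-end demo: synthetic connectome cohort, nested LOOCV + permutation.
# Run:  dticlass run-all --config examples/demo.yaml --seed 7
mode: connectome
n_patients: 10
n_controls: 14
n_regions: 16
n_informative: 10
effect: 1.5
D: 15
k: 8
d: 4
kernel: rbf
C: 1.0
n_perm: 99
seed: 7
out_dir: dticlass-report
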