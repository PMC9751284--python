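# Demo screen: five compound archetypes at 1 uM, 4 replicate wells each,
# 24/72 hr timepoints, 10^4 calibration beads per sample.
seed: 7
replicates: 4
depth: 2000
dup_factor: 3
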