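# Full-scale demo run: simulate the reference cohort (277 samples, 27
# carriers, 20,000 background probes), scan, threshold by permutation,
# train, evaluate across platforms and apply to a hidden-label cohort.
# Runs end to end in a few minutes on one CPU:
#   repeatmeth run --config examples/demo.yaml
out_dir: repeatmeth_demo
seed: 1

# For a quick look, shrink the heavy knobs, e.g.:
#   simulate: {n_background_probes: 2000}
#   dma: {n_permutations: 20}
#   evaluate: {n_iterations: 10}
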