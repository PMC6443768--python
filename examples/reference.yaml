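# Reference experiment: 4-neighbor torus, 1% random cooperators,
# normal reciprocity, horizon 2, return sweep over [1, 6].
r: 3.0
delta: 0.05
d: 0.0
h: 2
network: square4
n: 1024
seed: 1
scheme: random
initial_fraction: 0.01
max_rounds: 10000
replicates: 20
r_grid: [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0]
out_dir: results
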