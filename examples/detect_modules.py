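"""Detect subnetwork modules in a synthetic multilayer network.

Simulates a planted-partition network (8 modules of 25 genes), aggregates
its relation layers with uniform convex weights, selects the module count
by scanning modularity over a k range, and compares the detected partition
with the planted truth via the adjusted Rand index (1 = exact recovery).
"""

import deathnet as dn

cfg = dn.SynthConfig(n_genes=200, k_true=8, p_in=0.35, p_out=0.01, seed=7)
net, truth = dn.simulate_multilayer(cfg)
print(f"simulated: {net.n_genes()} genes, layers {dn.census(net)[1]}")

W = dn.aggregate_layers(net, dn.uniform_weights(net))
config = dn.ClusteringConfig(k_min=4, k_max=12, seed=0)
part = dn.spectral_partition(W, config)

truth_vs = dn.ModulePartition(
    {g: m for g, m in truth.assignment.items() if g in part.assignment}, k=truth.k
)
ari = dn.adjusted_rand(part, truth_vs)
print(f"selected k = {part.k} (true k = {cfg.k_true})")
print(f"modularity = {part.quality:.4f}")
print(f"adjusted Rand index vs planted truth = {ari:.4f}")

# k is chosen as the modularity argmax over [4, 12]; ARI near 1 means the
# planted communities were recovered almost gene-for-gene.
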