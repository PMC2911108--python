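"""Quality control and clustering of GI profiles.

Computes the three QC statistics on simulated data — technical-replicate
correlation, uptag/dntag log-ratio agreement, spike-in linearity — and
clusters a small gene x condition GI matrix with average linkage on
1 - uncentered correlation, exporting the gene tree as Newick.
"""

import numpy as np

from barseq import (
    CountTable,
    FitnessProfile,
    SimConfig,
    cluster_profiles,
    random_catalog,
    replicate_correlation,
    spikein_fit,
    tag_agreement,
)
from barseq.simulate import inject_spikeins, simulate_pool_counts

# --- technical replicates: two sequencing samples of the same pool
rng = np.random.default_rng(3)
p = rng.lognormal(sigma=1.0, size=2500)
p /= p.sum()
a = rng.multinomial(1_000_000, p)
b = rng.multinomial(1_000_000, p)
r = replicate_correlation(
    {i: float(v) for i, v in enumerate(a)},
    {i: float(v) for i, v in enumerate(b)},
)
print(f"technical replicate Pearson r (log10 counts): {r:.4f}")

# --- tag agreement: uptag vs dntag log ratios in a rich-vs-minimal pool
cfg = SimConfig(n_strains=500, depth=1_000_000, generations=(5,), seed=4)
catalog = random_catalog(cfg.n_strains, cfg.rng(stream=99))
strains = [rec.gene_id for rec in catalog.records]
fitness = FitnessProfile.uniform(strains, ["rich", "minimal"])
fitness.fitness["minimal"] = cfg.rng(stream=50).uniform(0.3, 1.2, size=500)
counts = simulate_pool_counts(cfg, fitness, ["rich", "minimal"])
n, r_tags = tag_agreement(counts, "rich_g5", "minimal_g5")
print(f"tag agreement: {n} strains pass the >=12-read filter, r = {r_tags:.4f}")

# --- spike-in linearity at the six benchmark cell ratios
ratios = [1 / 200, 1 / 1000, 1 / 2500, 1 / 5000, 1 / 10000, 1 / 20000]
reads = {}
for i, ratio in enumerate(ratios):
    table = CountTable()
    table.add("S", "library", "up", 1_000_000)
    table.add("S", "library", "dn", 1_000_000)
    inject_spikeins(table, [("A" * 20, "C" * 20, ratio)], cfg.rng(stream=60 + i))
    reads[ratio] = float(table.get("S", "spikein_1", "up"))
fit = spikein_fit(reads)
print(f"spike-in fit: slope {fit.slope:.3f}, R^2 {fit.r_squared:.4f} "
      f"over {fit.n} levels")

# --- clustering: two co-functional gene groups across four conditions
matrix = np.array([
    [1.0, 0.9, 0.1, 0.0],   # damage-response-like profile
    [0.9, 1.1, 0.0, 0.1],
    [0.0, 0.1, 1.0, 0.8],   # microtubule-like profile
    [0.1, 0.0, 0.9, 1.0],
])
gene_tree, cond_tree = cluster_profiles(
    matrix, ["rad1", "rad2", "tub1", "tub2"], ["UV", "HU", "TBZ_A", "TBZ_B"]
)
print("gene tree:", gene_tree.to_newick())
print("condition tree:", cond_tree.to_newick())
# replicates correlate near 1, the slope is ~1 over two orders of magnitude,
# and the two gene groups (and the two TBZ conditions) pair up in the trees
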