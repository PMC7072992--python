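"""Build a neighbor-joining tree with bootstrap supports from an alignment.

Simulates a small aligned character matrix with a clear split, builds the
NJ tree from p-distances and attaches bootstrap percentages (fraction of
column-resampled replicates reproducing each internal edge).
"""

import numpy as np

from riboprot.phylogeny import bootstrap_support

rng = np.random.default_rng(42)

# two four-taxon groups separated by 30 diagnostic columns plus noise
group1, group2 = ["tilapia_a", "medaka_a"], ["tilapia_b", "medaka_b"]
n_noise = 40
cols = []
for _ in range(30):  # diagnostic columns
    cols.append({t: "A" for t in group1} | {t: "T" for t in group2})
for _ in range(n_noise):  # noise columns
    cols.append({t: rng.choice(list("ACGT")) for t in group1 + group2})
alignment = {t: "".join(c[t] for c in cols) for t in group1 + group2}

tree = bootstrap_support(alignment, n_replicates=1000, seed=1)
print(tree.ascii_art())
for node in tree.non_tips(include_self=False):
    tips = sorted(t.name for t in node.tips())
    print(f"edge separating {tips}: bootstrap {node.support:.0f}%")
print("\nA support near 100% means nearly every resampled alignment "
      "reproduces that grouping.")
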