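"""Identify network hubs by z-scored nodal strength.

Nodal strength (functional connectivity strength) sums each node's
connection weights; strengths are z-normalized and nodes with z strictly
above 1 are flagged as hubs.
"""

import bnv
from bnv.fixtures import make_toy_network

nodes, matrix = make_toy_network(n_nodes=12, density=0.4, seed=1)
strength, z, hubs = bnv.nodal_strength(matrix)

print(f"{'node':<6} {'strength':>9} {'z':>7}  hub")
for lab, s, zz, h in zip(nodes.labels, strength, z, hubs):
    print(f"{lab:<6} {s:9.3f} {zz:7.3f}  {'*' if h else ''}")
print(f"\nhubs: {int(hubs.sum())} of {matrix.n} nodes (strict z > {bnv.HUB_Z_CUTOFF})")
print("a hub is a node whose summed connection weight is more than one")
print("standard deviation above the network mean")
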