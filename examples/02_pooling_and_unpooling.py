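"""Learnable top-k pooling: score, select, gate, and restore.

Pools a 10-node graph at ratio 0.6 and scatters the subgraph back to the
original size.
"""

import numpy as np

import eqppis as eq
from eqppis.pooling import PoolingParams, pool, unpool

rng = np.random.default_rng(3)
chain = eq.generate_chain(eq.SyntheticSpec(n_residues=10, seed=3))
g = chain.graph

params = PoolingParams(p=rng.normal(size=62), ratio=0.6)
res = pool(g.features, g.adjacency, g.coords, params)

print(f"node scores (sigmoid of the learned projection): {np.round(res.scores, 3)}")
print(f"kept nodes (top 60% by score):                   {res.idx}")
print(f"subgraph: {res.sub_features.shape[0]} nodes, "
      f"{res.sub_adjacency.sum() // 2} edges (from the squared adjacency)")

restored = unpool(res.sub_features, res.idx, g.n_residues)
zero_rows = np.where(~restored.data.any(axis=1))[0]
print(f"after unpooling: shape {restored.data.shape}, zero rows at {zero_rows}")
print()
print("Kept rows are gated by their scores, which keeps node selection")
print("differentiable; dropped rows return as exact zeros, ready for the")
print("elementwise-max fusion with the original-graph channel.")
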