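"""Structural deep network embedding of a planted-block association network.

Generates a small five-node-type molecular association network whose
miRNA-disease edges concentrate within matched blocks, embeds every node
with the graph autoencoder, and shows that nodes of the same block end up
closer than nodes of different blocks.
"""

import numpy as np

from mdlink import FixtureSpec, SdneConfig, fit_sdne, generate_network
from mdlink.simulate import block_assignment

spec = FixtureSpec(
    n_mirna=30, n_disease=20, n_protein=20, n_lncrna=10, n_drug=10,
    n_blocks=2, p_in=0.4, p_out=0.03, seed=3,
)
fix = generate_network(spec)
net = fix.network
print(f"network: {len(net.nodes)} nodes, {net.n_edges()} edges, "
      f"{len(fix.positives)} known miRNA-disease pairs")

res = fit_sdne(net, SdneConfig(seed=3, epochs=60, layer_dims=(64, 128)))
print(f"training loss: {res.loss_history[0]:.0f} -> {res.loss_history[-1]:.0f} "
      f"over {len(res.loss_history)} epochs")

blocks = block_assignment(spec)
keys = [k for k in res.embeddings if k[0] in ("miRNA", "disease")]
E = np.array([res.embeddings[k] for k in keys])
lab = np.array([blocks[k] for k in keys])
d = np.sqrt(((E[:, None, :] - E[None, :, :]) ** 2).sum(-1))
same = lab[:, None] == lab[None, :]
off = ~np.eye(len(keys), dtype=bool)
print(f"mean embedding distance within blocks:  {d[same & off].mean():.3f}")
print(f"mean embedding distance between blocks: {d[~same].mean():.3f}")
print("nodes sharing a block (and hence neighbourhoods) embed closer — the "
      "second-order proximity the reconstruction objective preserves.")
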