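"""Structural analytics: ensemble RMSD, backbone PCA, LJ interface rescoring.

Generates a jittered two-chain complex ensemble, summarizes its backbone
deviation from the reference, projects it into backbone principal
components, finds the 5 A interface contact shell, and scores it with the
12-6 Lennard-Jones potential.
"""

import numpy as np

from designscreen import structscore, synthetic

models = synthetic.simulate_structures(n_models=50, n_residues=18, displacement_sd=0.5, seed=1)
ref = models[0]

rmsds, median = structscore.ensemble_rmsd_summary(models[1:], ref)
print(f"ensemble of {len(models)} models: median C-alpha RMSD to reference "
      f"{median:.2f} A (range {min(rmsds):.2f}-{max(rmsds):.2f})")

pca = structscore.backbone_pca(models, [], n_components=2)
print(f"backbone PCA: first two components capture "
      f"{100 * pca.variance_fractions.sum():.0f}% of coordinate variance")

contacts = structscore.interface_contacts(
    ref, designed_positions=list(range(1, 19)), partner_chain="B", cutoff=5.0
)
oriented = structscore.interface_contacts(
    ref, designed_positions=list(range(1, 19)), partner_chain="B",
    cutoff=5.0, mode="side-chain-oriented",
)
print(f"interface shell at 5 A: residues {contacts}")
print(f"side-chain-oriented subset: {oriented}")

score = structscore.lj_interface_score(ref, contacts, partner_chain="B")
print(f"LJ interface score: attractive {score.attractive:.2f}, "
      f"repulsive {score.repulsive:.2f}, total {score.total:.2f} "
      f"(lower total = more favorable packing)")

# closed loop: when binding is governed by the same LJ terms, read counts
# anti-correlate with the interface energy
totals = [
    structscore.lj_interface_score(
        m,
        structscore.interface_contacts(m, list(range(1, 19)), "B", 5.0) or [1],
        "B",
    ).total
    for m in models
]
totals = np.array(totals)
scaled = (totals - totals.mean()) / totals.std()
counts = np.random.default_rng(2).poisson(1e4 * 10 ** (-0.5 * scaled))
rho, p = structscore.rank_correlation(totals, counts)
print(f"Spearman(LJ total, simulated counts) = {rho:.2f} (P = {p:.2e}) — "
      f"tighter interfaces accumulate more reads")
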