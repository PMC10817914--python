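"""Identify dominant nodes and contrast gene expression between categories.

Dominant nodes are those whose diffusion profiles resemble the maturation
map more than spin-test chance; the rank-based method cross-checks them.
A synthetic developmental gene panel then contrasts set-level expression
(PC1 scores) between dominant and non-dominant regions against a
gene-resampling null.
"""

import numpy as np
from scipy.stats import spearmanr

import connectoshape as cs

parc = cs.gen_parcellation(100, 7, seed=1)
conn = cs.gen_connectome(parc, seed=2)
profiles = cs.diffusion_profiles(conn)
hubs = np.argsort(-conn.degrees)[:2].tolist()
effect = cs.gen_effect_map(
    profiles, parc, dominant_nodes=hubs, weights=[2.0, 2.0], noise_sd=0.01, seed=3
)

dom = cs.dominant_nodes(profiles, effect.beta, parc, spin_n=199, seed=4)
conj = dom.conjunction
print(f"planted hubs {hubs}; nodes dominant at >= half the scales: "
      f"{np.flatnonzero(conj >= 0.5).tolist()}")

ranked = cs.rank_based_dominance(effect.beta, conn, parc, spin_n=199, seed=5)
rho = spearmanr(dom.likelihood[0], ranked.likelihood[0]).statistic
print(f"cross-method Spearman rho = {rho:.2f}")
# The two dominance definitions agree strongly on planted data.

categories = {f"region-{i}": ("dominant" if i < 4 else "non_dominant")
              for i in range(11)}
panel = cs.gen_gene_panel(divergence=2.0, noise_sd=0.5,
                          region_categories=categories, seed=6)
contrast = cs.dominant_contrast(panel, "set_a", n_resamples=999, seed=7)
print(f"gene-set contrast: difference = {contrast.difference:+.2f}, "
      f"p = {contrast.p:.3f} against {len(contrast.null_differences)} resampled sets")
# A planted category divergence in the target set is detected while region
# categories stay fixed throughout the resampling null.
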