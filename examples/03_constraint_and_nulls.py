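"""Test whether a maturation map is constrained by the connectome.

Correlates each node's planted maturation value with the mean over its
directly connected neighbors, then compares the observed correlation with
spin-map and rewired-network surrogate ensembles and with the two
spatial-confound variants.
"""

import numpy as np

import connectoshape as cs

parc = cs.gen_parcellation(100, 7, seed=1)
conn = cs.gen_connectome(parc, seed=2)
profiles = cs.diffusion_profiles(conn)
hubs = np.argsort(-conn.degrees)[:2].tolist()
effect = cs.gen_effect_map(
    profiles, parc, dominant_nodes=hubs, weights=[2.0, 2.0], noise_sd=0.01, seed=3
)

for variant in ("plain", "excluded", "regressed"):
    res = cs.constraint_correlation(
        effect.beta, conn, variant=variant, parcellation=parc, n_nulls=99, seed=5
    )
    print(f"{variant:9s}: r = {res.r:.2f}  p_spin = {res.p_spin:.3f}  "
          f"p_rewired = {res.p_rewired:.3f}  (n_used = {int(res.used.sum())})")
# r near 0.9 with both p-values at the 1/(n+1) floor: the map follows the
# network's wiring, not merely its spatial embedding ("excluded" removes
# border-sharing neighbors; "regressed" partials out neighbor distance).
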