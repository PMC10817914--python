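"""Multiscale random-walk diffusion on the binary connectome.

An unbiased random walker on the white-matter graph has one-step transition
matrix P = D^-1 A (D the degree diagonal).  Starting every walker at its own
node (p0 = I), the m-step distribution is P^m; its rows are the *diffusion
profiles* at neighboring scale m.  Averaging the outgoing and incoming
distributions, S_m = (P^m + P^m^T) / 2, gives the symmetric bidirectional
diffusion matrix used as the per-scale feature set downstream.  The maximum
scale M defaults to the network diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, _require_connected, graph_diameter


@dataclass
class DiffusionProfiles:
    """One-step matrix P plus per-scale m-step and symmetrized matrices.

    ``P_m[m]`` and ``S_m[m]`` are keyed by scale m = 1..M.
    """

    P: np.ndarray
    P_m: dict[int, np.ndarray]
    S_m: dict[int, np.ndarray]
    M: int

    @property
    def scales(self) -> list[int]:
        return list(range(1, self.M + 1))

    def profile(self, m: int, symmetrized: bool = True) -> np.ndarray:
        return self.S_m[m] if symmetrized else self.P_m[m]


def transition_matrix(connectome: Connectome) -> np.ndarray:
    """P = D^-1 A: probability of stepping from i to each neighbor is 1/d_i."""
    deg = connectome.degrees
    if (deg == 0).any():
        bad = np.flatnonzero(deg == 0)
        raise ValueError(f"degree-0 node(s) {bad.tolist()} have no transition row")
    return connectome.adjacency.astype(float) / deg[:, None].astype(float)


def diffusion_profiles(connectome: Connectome, max_scale: int | None = None) -> DiffusionProfiles:
    """m-step diffusion matrices for m = 1..M (M = diameter by default)."""
    _require_connected(connectome, "diffusion_profiles")
    p = transition_matrix(connectome)
    m_max = graph_diameter(connectome) if max_scale is None else int(max_scale)
    p_m: dict[int, np.ndarray] = {}
    s_m: dict[int, np.ndarray] = {}
    current = np.eye(connectome.n_nodes)
    for m in range(1, m_max + 1):
        current = current @ p
        p_m[m] = current
        s_m[m] = (current + current.T) / 2.0
    return DiffusionProfiles(P=p, P_m=p_m, S_m=s_m, M=m_max)


def system_diffusion_summary(
    profiles: DiffusionProfiles, system_labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Mean within- and between-system diffusive probability per scale.

    For each node the within-probability is the mass its symmetrized scale-m
    profile places on same-system nodes (self included); between is the
    remaining row mass.  Returns across-node means per scale plus the full
    per-system-pair mean matrix.
    """
    labels = np.asarray(system_labels)
    systems = np.unique(labels)
    n_scales = profiles.M
    within = np.zeros(n_scales)
    between = np.zeros(n_scales)
    pair_means = np.zeros((n_scales, systems.size, systems.size))
    for k, m in enumerate(profiles.scales):
        s = profiles.S_m[m]
        same = labels[:, None] == labels[None, :]
        row_sum = s.sum(axis=1)
        w = (s * same).sum(axis=1)
        within[k] = w.mean()
        between[k] = (row_sum - w).mean()
        for a, sa in enumerate(systems):
            rows = labels == sa
            for b, sb in enumerate(systems):
                pair_means[k, a, b] = s[np.ix_(rows, labels == sb)].sum(axis=1).mean()
    return {
        "scales": np.asarray(profiles.scales),
        "within": within,
        "between": between,
        "systems": systems,
        "pair_means": pair_means,
    }
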