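import numpy as np
import pytest

import connectoshape as cs


@pytest.fixture(scope="session")
def parc100():
    return cs.gen_parcellation(100, 7, seed=3)


@pytest.fixture(scope="session")
def conn100(parc100):
    return cs.gen_connectome(parc100, seed=1)


@pytest.fixture(scope="session")
def profiles100(conn100):
    return cs.diffusion_profiles(conn100)


@pytest.fixture(scope="session")
def small_study(parc100, conn100, profiles100):
    """A compact planted study: hub-planted effect map plus scan roster."""
    hubs = np.argsort(-conn100.degrees)[:2].tolist()
    effect = cs.gen_effect_map(
        profiles100, parc100, dominant_nodes=hubs, weights=[2.0, 2.0],
        noise_sd=0.01, seed=11,
    )
    scans = cs.gen_longitudinal_ct(
        parc100, effect, n_single=30, n_double=20, n_triple=10, seed=13
    )
    return {"effect": effect, "scans": scans, "hubs": hubs}


def toy_connectome(adjacency, coords=None):
    adjacency = np.asarray(adjacency)
    n = adjacency.shape[0]
    if coords is None:
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    return cs.Connectome(adjacency, d)


def path_graph(n):
    a = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return toy_connectome(a)


def star_graph(n_leaves):
    a = np.zeros((n_leaves + 1, n_leaves + 1), dtype=int)
    a[0, 1:] = a[1:, 0] = 1
    coords = np.vstack([[0, 0, 0.0]] + [
        [np.cos(t), np.sin(t), 0.0]
        for t in np.linspace(0, 2 * np.pi, n_leaves, endpoint=False)
    ])
    return toy_connectome(a, coords)


def complete_graph(n):
    a = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
    return toy_connectome(a)


def cycle_graph(n):
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
    coords = np.column_stack(
        [np.cos(np.linspace(0, 2 * np.pi, n, endpoint=False)),
         np.sin(np.linspace(0, 2 * np.pi, n, endpoint=False)),
         np.zeros(n)]
    )
    return toy_connectome(a, coords)
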