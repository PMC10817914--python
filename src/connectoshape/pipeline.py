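"""End-to-end orchestration with deterministic seeding.

``run_full_pipeline`` executes the whole analysis on a synthetic study --
simulate geometry and networks, build the consensus backbone, plant and
recover a maturation map, test the neighbor constraint against both nulls,
fit the diffusion model, predict the map with SVR, identify dominant nodes
(both methods), and contrast gene sets -- writing every stage artifact plus
a manifest of seeds and output hashes.  All randomness flows from the
config's seed through named substreams; no hidden global state.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .connectome import consensus_backbone, graph_diameter
from .constraint import constraint_correlation
from .diffusion import diffusion_profiles, system_diffusion_summary
from .dominance import dominant_nodes, rank_based_dominance
from .genes import dominant_contrast
from .maturation import model1_group_t, split_scan_pairs
from .nulls import rewired_surrogates, spin_surrogates
from .parcellation import gen_parcellation
from .prediction import prediction_significance, svr_predict_scale
from .synthetic import (
    gen_effect_map,
    gen_gene_panel,
    gen_individual_networks,
    gen_longitudinal_ct,
)


@dataclass
class RunConfig:
    seed: int
    n_nodes: int = 100
    n_systems: int = 7
    n_subject_networks: int = 12
    target_density: float = 0.12
    n_nulls: int = 99
    dominant_nodes: tuple[int, ...] = (7, 42)
    planted_scale: int = 2
    effect_weight: float = -0.6
    effect_noise_sd: float = 0.02
    n_single: int = 40
    n_double: int = 26
    n_triple: int = 13
    subject_sd: float = 0.10
    noise_sd: float = 0.05
    svr_scale: int | None = None  # default: planted scale
    k_folds: int = 10
    out_dir: str = "pipeline_out"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        if "seed" not in payload:
            raise ValueError("config must provide an explicit seed")
        payload["dominant_nodes"] = tuple(payload.get("dominant_nodes", (7, 42)))
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _substream(seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage on a synthetic study; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        parcellation = gen_parcellation(
            config.n_nodes, config.n_systems, seed=_substream(config.seed, "parcellation")
        )
        individuals = gen_individual_networks(
            parcellation,
            config.n_subject_networks,
            target_density=config.target_density,
            seed=_substream(config.seed, "networks"),
        )
        io.write_node_table(parcellation, out / "nodes.csv")
        io.write_spatial_adjacency(parcellation, out / "spatial_adjacency.tsv")

        stage = "backbone"
        from .parcellation import euclidean_distance_matrix

        backbone = consensus_backbone(
            individuals,
            euclidean_distance_matrix(parcellation),
            parcellation=parcellation,
        )
        io.write_edge_list(backbone, out / "backbone.tsv")

        stage = "diffuse"
        profiles = diffusion_profiles(backbone)
        diffusion_summary = system_diffusion_summary(profiles, parcellation.system)

        stage = "simulate-ct"
        effect = gen_effect_map(
            profiles,
            parcellation,
            dominant_nodes=list(config.dominant_nodes),
            scale_m=config.planted_scale,
            weights=[config.effect_weight] * len(config.dominant_nodes),
            noise_sd=config.effect_noise_sd,
            seed=_substream(config.seed, "effect"),
        )
        scans = gen_longitudinal_ct(
            parcellation,
            effect,
            n_single=config.n_single,
            n_double=config.n_double,
            n_triple=config.n_triple,
            subject_sd=config.subject_sd,
            noise_sd=config.noise_sd,
            seed=_substream(config.seed, "scans"),
        )
        io.write_scan_table(scans, out / "scan_meta.csv", out / "scan_ct.csv")

        stage = "maturation"
        t_map = model1_group_t(scans)
        io.write_maturation_map(t_map, out / "maturation_model1.csv")
        n_pairs = len(split_scan_pairs(scans))

        stage = "nulls"
        spin = spin_surrogates(
            t_map.value, parcellation, n=config.n_nulls, seed=_substream(config.seed, "spin")
        )
        rewired = rewired_surrogates(
            backbone, n=config.n_nulls, seed=_substream(config.seed, "rewire")
        )

        stage = "constraint"
        constraint = {
            variant: constraint_correlation(
                t_map.value,
                backbone,
                variant=variant,
                parcellation=parcellation,
                spin_ensemble=spin,
                rewired_ensemble=rewired,
            )
            for variant in ("plain", "excluded", "regressed")
        }

        stage = "predict"
        scale = config.svr_scale or config.planted_scale
        prediction = svr_predict_scale(
            profiles, t_map.value, m=scale, k_folds=config.k_folds,
            seed=_substream(config.seed, "svr"),
        )
        rewired_conn = rewired_surrogates(
            backbone, n=min(config.n_nulls, 25),
            seed=_substream(config.seed, "rewire-svr"), ensure_connected=True,
        )
        spin_small = spin_surrogates(
            t_map.value, parcellation, n=min(config.n_nulls, 25),
            seed=_substream(config.seed, "spin-svr"),
        )
        prediction = prediction_significance(
            prediction, t_map.value, profiles, spin_small, rewired_conn
        )

        stage = "dominance"
        cosine = dominant_nodes(
            profiles, t_map.value, parcellation, spin_ensemble=spin
        )
        ranked = rank_based_dominance(
            t_map.value, backbone, parcellation, spin_ensemble=spin
        )

        stage = "genes"
        conjunction_dominant = set(np.flatnonzero(cosine.conjunction >= 0.5))
        categories = {
            f"region-{i}": ("dominant" if i in conjunction_dominant else "non_dominant")
            for i in range(0, parcellation.n_nodes, max(parcellation.n_nodes // 11, 1))
        }
        if "dominant" not in set(categories.values()):
            categories[f"region-{next(iter(conjunction_dominant), 0)}"] = "dominant"
        panel = gen_gene_panel(
            region_categories=categories, seed=_substream(config.seed, "genes")
        )
        io.write_gene_panel(
            panel, out / "gene_expression.csv", out / "gene_samples.csv", out / "gene_sets.json"
        )
        contrast = dominant_contrast(
            panel, "set_a", n_resamples=config.n_nulls,
            seed=_substream(config.seed, "gene-null"),
        )
    except Exception as exc:  # pragma: no cover - error path contract
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    results = {
        "n_scans": scans.n_scans,
        "n_longitudinal_pairs": n_pairs,
        "backbone_density": backbone.density,
        "backbone_diameter": graph_diameter(backbone),
        "diffusion_within_scale1": float(diffusion_summary["within"][0]),
        "constraint": {
            v: {"r": c.r, "p_spin": c.p_spin, "p_rewired": c.p_rewired}
            for v, c in constraint.items()
        },
        "prediction": {
            "scale": prediction.scale,
            "accuracy_r": prediction.accuracy_r,
            "p_spin": prediction.p_spin,
            "p_rewired": prediction.p_rewired,
        },
        "dominance": {
            "planted": sorted(effect.dominant_truth),
            "n_dominant_conjunction": int((cosine.conjunction >= 0.5).sum()),
            "rank_vs_cosine_spearman": _spearman(
                ranked.likelihood[0], cosine.likelihood[0]
            ),
        },
        "gene_contrast": {"difference": contrast.difference, "p": contrast.p},
    }
    (out / "results.json").write_text(json.dumps(results, indent=1))

    manifest = {
        "config": asdict(config),
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
        "results": results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.stats import spearmanr

    return float(spearmanr(a, b).statistic)
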