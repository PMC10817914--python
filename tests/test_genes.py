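"""Gene-set PC1 scores, dominant contrasts, and map-gene correlation tables."""

import numpy as np
import pandas as pd
import pytest

import connectoshape as cs


class TestGenesetPC1:
    def test_rank_one_latent_recovered(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=60)
        loadings = rng.uniform(0.5, 1.5, size=8)
        expr = np.outer(latent, loadings) + 1e-9 * rng.normal(size=(60, 8))
        panel = cs.GenePanel(
            expression=pd.DataFrame(expr, columns=[f"g{i}" for i in range(8)]),
            samples=pd.DataFrame(
                {"region": ["r"] * 60, "category": ["dominant"] * 60, "age": 10.0}
            ),
            gene_sets={"s": [f"g{i}" for i in range(8)]},
        )
        scores = cs.geneset_pc1(panel, "s")
        assert abs(np.corrcoef(scores, latent)[0, 1]) >= 0.999

    def test_single_gene_set_is_standardized_expression(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(size=(30, 3))
        panel = cs.GenePanel(
            expression=pd.DataFrame(expr, columns=["a", "b", "c"]),
            samples=pd.DataFrame(
                {"region": ["r"] * 30, "category": ["dominant"] * 30, "age": 8.0}
            ),
            gene_sets={"solo": ["b"]},
        )
        scores = cs.geneset_pc1(panel, "solo")
        z = (expr[:, 1] - expr[:, 1].mean()) / expr[:, 1].std()
        assert np.allclose(np.abs(np.corrcoef(scores, z)[0, 1]), 1.0)
        # sign convention: nonnegative mean loading implies positive alignment
        assert np.corrcoef(scores, z)[0, 1] > 0

    def test_zero_variance_genes_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        expr = rng.normal(size=(20, 2))
        expr[:, 1] = 5.0
        panel = cs.GenePanel(
            expression=pd.DataFrame(expr, columns=["a", "b"]),
            samples=pd.DataFrame(
                {"region": ["r"] * 20, "category": ["dominant"] * 20, "age": 9.0}
            ),
            gene_sets={"s": ["a", "b"]},
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = cs.geneset_pc1(panel, "s")
        assert scores.shape == (20,)


class TestDominantContrast:
    def test_planted_divergence_detected(self):
        hits = 0
        for seed in range(10):
            panel = cs.gen_gene_panel(divergence=2.0, noise_sd=0.5, seed=seed)
            res = cs.dominant_contrast(panel, "set_a", n_resamples=199, seed=seed)
            hits += res.p <= 0.05
        assert hits >= 9

    def test_identical_categories_give_zero_difference(self):
        panel = cs.gen_gene_panel(divergence=1.0, seed=0)
        # duplicate the dominant samples as non-dominant: identical groups
        dup = panel.samples.copy()
        dup["category"] = np.where(
            dup["category"] == "dominant", "non_dominant", "dominant"
        )
        both = cs.GenePanel(
            expression=pd.concat([panel.expression, panel.expression], ignore_index=True),
            samples=pd.concat([panel.samples, dup], ignore_index=True),
            gene_sets=panel.gene_sets,
        )
        res = cs.dominant_contrast(both, "set_a", n_resamples=19, seed=1)
        assert res.difference == pytest.approx(0.0, abs=1e-10)

    def test_sample_order_invariance(self):
        panel = cs.gen_gene_panel(divergence=1.5, seed=3)
        perm = np.random.default_rng(4).permutation(len(panel.samples))
        shuffled = cs.GenePanel(
            expression=panel.expression.iloc[perm].reset_index(drop=True),
            samples=panel.samples.iloc[perm].reset_index(drop=True),
            gene_sets=panel.gene_sets,
        )
        a = cs.dominant_contrast(panel, "set_a", n_resamples=99, seed=5)
        b = cs.dominant_contrast(shuffled, "set_a", n_resamples=99, seed=5)
        assert a.difference == pytest.approx(b.difference, abs=1e-10)
        assert a.p == b.p

    def test_too_large_set_rejected(self):
        panel = cs.gen_gene_panel(n_genes=20, gene_sets={"s": 15}, seed=0)
        with pytest.raises(ValueError):
            cs.dominant_contrast(panel, "s", n_resamples=10, seed=0)


class TestMapGeneCorrelation:
    def test_identical_gene_map_tops_table(self, parc100):
        rng = np.random.default_rng(0)
        likelihood = cs.gen_autocorrelated_map(parc100, seed=1)
        maps = pd.DataFrame(
            {"match": likelihood, **{f"g{i}": rng.normal(size=100) for i in range(20)}}
        )
        table = cs.map_gene_correlation(
            likelihood, maps, parc100, spin_n=999, seed=2
        )
        assert table.table.loc["match", "r"] == pytest.approx(1.0)
        assert table.table.loc["match", "p_spin"] == pytest.approx(1 / 1000)
        assert "match" in table.positive

    def test_negation_antisymmetry(self, parc100):
        rng = np.random.default_rng(1)
        likelihood = cs.gen_autocorrelated_map(parc100, seed=3)
        g = rng.normal(size=100)
        maps = pd.DataFrame({"g": g, "neg": -g})
        table = cs.map_gene_correlation(likelihood, maps, parc100, spin_n=19, seed=4)
        assert table.table.loc["g", "r"] == pytest.approx(-table.table.loc["neg", "r"])

    def test_fdr_controls_false_discoveries(self, parc100):
        # independent random gene maps: average false-discovery proportion
        # stays at or below the nominal 5% level (with slack for MC error)
        fdp = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            likelihood = cs.gen_autocorrelated_map(parc100, seed=100 + seed)
            maps = pd.DataFrame(rng.normal(size=(100, 100)))
            maps.columns = [f"g{i}" for i in range(100)]
            table = cs.map_gene_correlation(likelihood, maps, parc100, spin_n=99, seed=seed)
            n_sig = table.table["significant"].sum()
            fdp.append(1.0 if n_sig else 0.0)
        assert np.mean(fdp) <= 0.10

    def test_constant_gene_map_skipped(self, parc100):
        likelihood = cs.gen_autocorrelated_map(parc100, seed=5)
        maps = pd.DataFrame(
            {"flat": np.ones(100), "ok": np.random.default_rng(6).normal(size=100)}
        )
        with pytest.warns(UserWarning, match="constant"):
            table = cs.map_gene_correlation(likelihood, maps, parc100, spin_n=9, seed=7)
        assert "flat" not in table.table.index
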