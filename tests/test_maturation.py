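"""Maturation models: group t-maps, trajectory rates, individual rates."""

import numpy as np
import pandas as pd
import pytest

import connectoshape as cs


def _ols_t_oracle(y, x):
    """Closed-form OLS t for the 'child' column (independent of statsmodels)."""
    xm = x.to_numpy(float)
    beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
    resid = y - xm @ beta
    df = len(y) - xm.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(xm.T @ xm)
    k = list(x.columns).index("child")
    return beta[k] / np.sqrt(cov[k, k])


class TestModel1:
    def test_planted_thinning_recovered(self, parc100, profiles100):
        effect = cs.gen_effect_map(
            profiles100, parc100, dominant_nodes=[8], weights=[-3.0],
            noise_sd=0.0, seed=0,
        )
        scans = cs.gen_longitudinal_ct(
            parc100, effect, 30, 20, 10, subject_sd=0.02, noise_sd=0.005, seed=1
        )
        m = cs.model1_group_t(scans)
        affected = np.abs(effect.beta) > np.quantile(np.abs(effect.beta), 0.9)
        assert (m.value[affected] > 0).all()  # thinning-positive convention
        assert m.significance_mask[affected].all()

    def test_single_scan_case_matches_ols_oracle(self, parc100, profiles100):
        effect = cs.gen_effect_map(profiles100, parc100, noise_sd=0.05, seed=2)
        scans = cs.gen_longitudinal_ct(
            parc100, effect, n_single=60, n_double=0, n_triple=0,
            subject_sd=0.0, noise_sd=0.05, seed=3,
        )
        m = cs.model1_group_t(scans)
        x = pd.DataFrame(
            {
                "const": 1.0,
                "child": (scans.meta["group"] == "child").astype(float),
                "sex": scans.meta["sex"].astype(float),
            }
        )
        for node in (0, 17, 50):
            assert m.value[node] == pytest.approx(
                _ols_t_oracle(scans.ct[:, node], x), abs=1e-6
            )

    def test_t_invariant_to_node_constant_shift(self, parc100, profiles100):
        effect = cs.gen_effect_map(profiles100, parc100, noise_sd=0.05, seed=4)
        scans = cs.gen_longitudinal_ct(parc100, effect, 20, 10, 5, seed=5)
        m1 = cs.model1_group_t(scans)
        shifted = cs.ScanTable(meta=scans.meta.copy(), ct=scans.ct + 1.0)
        m2 = cs.model1_group_t(shifted)
        assert np.allclose(m1.value, m2.value, atol=1e-8)

    def test_single_group_rejected(self, parc100, profiles100):
        effect = cs.gen_effect_map(profiles100, parc100, seed=0)
        scans = cs.gen_longitudinal_ct(
            parc100, effect, 20, 0, 0, age_range=(6.0, 9.5), seed=6
        )
        with pytest.raises(ValueError, match="group"):
            cs.model1_group_t(scans)

    def test_zero_variance_node_rejected(self, parc100, profiles100):
        effect = cs.gen_effect_map(profiles100, parc100, seed=0)
        scans = cs.gen_longitudinal_ct(parc100, effect, 20, 5, 2, seed=7)
        ct = scans.ct.copy()
        ct[:, 3] = 2.5
        with pytest.raises(ValueError, match="variance"):
            cs.model1_group_t(cs.ScanTable(meta=scans.meta, ct=ct))


def _linear_ct_roster(parc, slope, n_subj=120, seed=0, noise=0.002, curvature=0.0):
    """Roster whose CT follows baseline + slope*(age-10) + curvature*(age-10)^2."""
    rng = np.random.default_rng(seed)
    rows, ct = [], []
    for s in range(n_subj):
        age = rng.uniform(6.0, 14.0)
        sex = int(rng.integers(2))
        a = age - 10.0
        rows.append(
            {
                "subject": f"sub-{s}",
                "scan_index": 0,
                "age": age,
                "sex": sex,
                "group": "adolescent" if age >= 10 else "child",
            }
        )
        ct.append(
            3.0
            + slope * a
            + curvature * a * a
            + rng.normal(0, noise, size=parc.n_nodes)
        )
    return cs.ScanTable(meta=pd.DataFrame(rows), ct=np.asarray(ct))


class TestModel2:
    def test_linear_truth_rate_recovered(self, parc100):
        scans = _linear_ct_roster(parc100, slope=-0.1, seed=1)
        maps, _ = cs.model2_gam(scans, eval_ages=[8.0, 10.0, 12.0])
        for m in maps:
            assert np.abs(m.value + 0.1).max() < 0.02

    def test_constant_truth_rate_near_zero(self, parc100):
        scans = _linear_ct_roster(parc100, slope=0.0, seed=2)
        maps, _ = cs.model2_gam(scans, eval_ages=[8.0, 12.0])
        for m in maps:
            assert np.abs(m.value).max() < 0.01

    def test_quadratic_truth_sign_change_at_vertex(self, parc100):
        # truth vertex at age 10: rate negative before, positive after
        scans = _linear_ct_roster(parc100, slope=0.0, curvature=0.02, seed=3)
        maps, _ = cs.model2_gam(scans, eval_ages=[8.0, 12.0])
        assert (maps[0].value < 0).all()
        assert (maps[1].value > 0).all()

    def test_eval_age_outside_range_rejected(self, parc100):
        scans = _linear_ct_roster(parc100, slope=0.0, seed=4)
        with pytest.raises(ValueError, match="outside"):
            cs.model2_gam(scans, eval_ages=[20.0])


class TestModel3:
    def test_rate_arithmetic(self, parc100, profiles100):
        meta = pd.DataFrame(
            {
                "subject": ["a", "a"],
                "scan_index": [0, 1],
                "age": [9.0, 10.0],
                "sex": [0, 0],
                "group": ["child", "adolescent"],
            }
        )
        ct = np.vstack([np.full(5, 3.0), np.full(5, 2.8)])
        scans = cs.ScanTable(meta=meta, ct=ct)
        m = cs.model3_individual_rate(scans, (0, 1))
        assert np.allclose(m.value, -0.2)
        # half-year gap doubles the rate
        meta2 = meta.assign(age=[9.0, 9.5])
        ct2 = np.vstack([np.full(5, 2.5), np.full(5, 2.6)])
        m2 = cs.model3_individual_rate(cs.ScanTable(meta=meta2, ct=ct2), (0, 1))
        assert np.allclose(m2.value, 0.2)

    def test_antisymmetric_under_scan_swap(self, parc100, profiles100):
        effect = cs.gen_effect_map(profiles100, parc100, noise_sd=0.05, seed=0)
        scans = cs.gen_longitudinal_ct(parc100, effect, 0, 4, 0, seed=8)
        pair = cs.split_scan_pairs(scans)[0]
        fwd = cs.model3_individual_rate(scans, pair)
        swapped_meta = scans.meta.copy()
        rev_ct = scans.ct.copy()
        i, j = pair
        swapped_meta.loc[[i, j], "age"] = swapped_meta.loc[[j, i], "age"].to_numpy()
        rev_ct[[i, j]] = rev_ct[[j, i]]
        # swapping ages *and* rows leaves the physical pair unchanged;
        # swapping only CT rows negates the rate
        rev = cs.ScanTable(meta=scans.meta, ct=rev_ct)
        back = cs.model3_individual_rate(rev, pair)
        assert np.allclose(back.value, -fwd.value)

    def test_split_pairs_shapes(self, parc100, profiles100):
        effect = cs.gen_effect_map(profiles100, parc100, seed=0)
        scans = cs.gen_longitudinal_ct(parc100, effect, 5, 0, 1, seed=9)
        pairs = cs.split_scan_pairs(scans)
        assert len(pairs) == 2  # triple-scan subject gives (1,2) and (2,3)
        only_singles = cs.gen_longitudinal_ct(parc100, effect, 5, 0, 0, seed=10)
        assert cs.split_scan_pairs(only_singles) == []


class TestSystemEnrichment:
    def test_indicator_map_enriched(self, parc100):
        values = (parc100.system == 3).astype(float)
        ens = cs.spin_surrogates(values, parc100, n=300, seed=1)
        table = cs.system_enrichment(values, parc100.system, ens)
        assert table.loc[table["system"] == 3, "z"].iloc[0] > 3

    def test_constant_map_degenerate_null(self, parc100):
        values = np.ones(100)
        ens = cs.spin_surrogates(values, parc100, n=20, seed=2)
        with pytest.warns(UserWarning):
            table = cs.system_enrichment(values, parc100.system, ens)
        assert (table["z"] == 0).all()

    def test_size_weighted_mean_conserved(self, parc100):
        values = np.random.default_rng(5).normal(size=100)
        ens = cs.spin_surrogates(values, parc100, n=50, seed=3)
        labels = parc100.system
        sizes = np.array([(labels == lab).sum() for lab in np.unique(labels)])
        for surrogate in ens:
            s = np.asarray(surrogate)
            per_system = np.array(
                [s[labels == lab].mean() for lab in np.unique(labels)]
            )
            assert np.isclose((per_system * sizes).sum() / 100, s.mean())
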