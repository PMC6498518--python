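import math

import numpy as np
import pandas as pd
import pytest

from apnet.stats import (
    bh_fdr,
    cohens_d,
    compare_models,
    mediation,
    ols_regression,
    pearson_corr_table,
    permutation_edge_test,
    sweep_group_tests,
    welch_t,
    welch_t_from_stats,
    zscore_matrix,
)


def welch_oracle(x, y):
    """Closed-form Welch statistic evaluated independently."""
    x, y = np.asarray(x), np.asarray(y)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return t, df


class TestWelch:
    def test_group_summary_worked_examples(self):
        # Pitch-adjustment group summaries: AP 41.37+-36.49 (n=31) vs
        # RP 296.84+-86.12 (n=33) and SDfoM 52.31+-44.96 vs 329.77+-122.77.
        t, df, p = welch_t_from_stats(41.37, 36.49, 31, 296.84, 86.12, 33)
        assert abs(t) == pytest.approx(15.614, abs=5e-4)
        assert df == pytest.approx(43.7, abs=0.05)
        assert p < 1e-15
        t2, df2, _ = welch_t_from_stats(52.31, 44.96, 31, 329.77, 122.77, 33)
        assert abs(t2) == pytest.approx(12.145, abs=5e-4)
        assert df2 == pytest.approx(40.9, abs=0.05)

    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        t, _df, p = welch_t(x, list(x))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, int(rng.integers(5, 40)))
            y = rng.normal(0.3, 2, int(rng.integers(5, 40)))
            t, df, _ = welch_t(x, y)
            ot, odf = welch_oracle(x, y)
            assert t == pytest.approx(ot, abs=1e-10)
            assert df == pytest.approx(odf, abs=1e-10)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestCohensD:
    def test_unit_effect(self, rng):
        x = rng.normal(1, 1, 2000)
        y = rng.normal(0, 1, 2000)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=0.1)

    def test_equal_means_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(0.0)

    def test_direct_formula_oracle(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(1, 3, 20)
        pooled = math.sqrt(
            (11 * x.var(ddof=1) + 19 * y.var(ddof=1)) / 30
        )
        assert cohens_d(x, y) == pytest.approx((x.mean() - y.mean()) / pooled)


def _metrics_frame(rng, effect_densities=(), effect=1.0, densities=(0.1, 0.2, 0.3, 0.4, 0.5)):
    """Per-subject metric table: group B shifted at the given densities."""
    rows = []
    for group, n in (("AP", 16), ("RP", 16)):
        for s in range(n):
            for d in densities:
                mu = effect if (group == "AP" and d in effect_densities) else 0.0
                rows.append(
                    dict(subject_id=f"{group}{s}", group=group, band="beta",
                         condition="EO", density=d,
                         C=rng.normal(mu, 1.0), L=rng.normal(0, 1.0),
                         sigma=rng.normal(0, 1.0))
                )
    return pd.DataFrame(rows)


class TestSweep:
    def test_null_gives_empty_mask(self, rng):
        sweep = sweep_group_tests(_metrics_frame(rng), alpha=0.001)
        assert sweep.mask.sum() == 0
        assert len(sweep.representatives) == 0

    def test_isolated_significant_density_excluded(self, rng):
        frame = _metrics_frame(rng, effect_densities=(0.3,), effect=3.0)
        sweep = sweep_group_tests(frame)
        kept = sweep.surviving()
        assert kept[(kept.metric == "C") & (kept.density == 0.3)].empty

    def test_adjacent_run_detected_with_max_d_representative(self, rng):
        frame = _metrics_frame(rng, effect_densities=(0.2, 0.3, 0.4), effect=2.5)
        sweep = sweep_group_tests(frame)
        kept = sweep.surviving()
        c_kept = kept[kept.metric == "C"]
        assert set(c_kept["density"]) == {0.2, 0.3, 0.4}
        rep = sweep.representatives
        rep_c = rep[rep.metric == "C"]
        assert len(rep_c) == 1
        best = c_kept.loc[c_kept["d"].abs().idxmax()]
        assert rep_c.iloc[0]["density"] == best["density"]

    def test_mismatched_grids_rejected(self, rng):
        frame = _metrics_frame(rng)
        frame = frame[~((frame.group == "AP") & (frame.density == 0.5))]
        with pytest.raises(ValueError, match="grids differ"):
            sweep_group_tests(frame)


class TestZScoreMatrix:
    def test_standardization_identity(self, rng):
        w = rng.uniform(0, 1, (6, 6))
        w = np.triu(w, 1) + np.triu(w, 1).T
        z = zscore_matrix(w)
        vals = z[np.triu_indices(6, 1)]
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        assert np.allclose(z, z.T)
        assert np.all(np.diag(z) == 0)

    def test_affine_invariance(self, rng):
        w = rng.uniform(0, 1, (5, 5))
        w = np.triu(w, 1) + np.triu(w, 1).T
        np.testing.assert_allclose(zscore_matrix(2.5 * w + 3), zscore_matrix(w))

    def test_hand_fixture(self):
        w = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        z = zscore_matrix(w)
        # off-diagonal values {1, 2, 3}: mean 2, sd 1
        assert z[0, 1] == pytest.approx(-1.0)
        assert z[0, 2] == pytest.approx(0.0)
        assert z[1, 2] == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        w = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            zscore_matrix(w)


def _sym_stack(rng, n_sub, n_nodes, shift_edge=None, shift=0.0):
    mats = []
    for _ in range(n_sub):
        w = rng.normal(0, 1, (n_nodes, n_nodes))
        w = np.triu(w, 1)
        if shift_edge is not None:
            w[shift_edge] += shift
        mats.append(w + w.T)
    return mats


class TestPermutationEdges:
    def test_minimum_p_and_determinism(self, rng):
        g1 = _sym_stack(rng, 12, 5, shift_edge=(0, 1), shift=20.0)
        g2 = _sym_stack(rng, 12, 5)
        res = permutation_edge_test(g1, g2, n_perm=500, seed=3)
        assert res.p[0, 1] == pytest.approx(1 / 501)
        res2 = permutation_edge_test(g1, g2, n_perm=500, seed=3)
        np.testing.assert_array_equal(res.p, res2.p)

    def test_shifted_edge_detected(self, rng):
        g1 = _sym_stack(rng, 30, 6, shift_edge=(1, 4), shift=2.0)
        g2 = _sym_stack(rng, 30, 6)
        res = permutation_edge_test(g1, g2, n_perm=1000, seed=0)
        assert res.fdr_mask[1, 4]
        assert res.d[1, 4] > 1.0
        # only a small fraction of null edges swept in
        assert res.fdr_mask.sum() // 2 <= 3

    def test_standardized_variant_is_offset_invariant(self, rng):
        g1 = _sym_stack(rng, 10, 5)
        g2 = [m + 5.0 - 5.0 * np.eye(5) + 5.0 * np.eye(5) * 0 for m in _sym_stack(rng, 10, 5)]
        g2 = [m - np.diag(np.diag(m)) for m in g2]
        raw = permutation_edge_test(g1, g2, n_perm=300, seed=1)
        std = permutation_edge_test(g1, g2, n_perm=300, seed=1, standardized=True)
        # constant offset shifts every raw edge but no standardized edge
        assert abs(raw.observed_diff[0, 1]) > 1.0
        assert abs(std.observed_diff).max() < 2.0
        assert std.standardized and not raw.standardized

    def test_group_size_validated(self, rng):
        with pytest.raises(ValueError):
            permutation_edge_test(_sym_stack(rng, 1, 4), _sym_stack(rng, 5, 4))


def brute_bh(p, q):
    """Exhaustive step-up search over all k cutoffs."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order]
    k_max = 0
    for k in range(1, m + 1):
        if ranked[k - 1] <= q * k / m:
            k_max = k
    mask = np.zeros(m, dtype=bool)
    if k_max:
        mask[order[:k_max]] = True
    return mask


class TestBHFDR:
    FIXTURE = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212,
               0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.341, 0.384, 0.569,
               0.594, 0.696]

    def test_twenty_p_fixture_matches_brute_force(self):
        got = bh_fdr(self.FIXTURE, q=0.05)
        np.testing.assert_array_equal(got, brute_bh(self.FIXTURE, 0.05))
        # step-up: 0.001 <= 1*0.0025 but 0.008 > 2*0.0025, so only the
        # smallest p survives
        assert got[0] and got.sum() == 1

    def test_random_fixtures_match_brute_force(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            for q in (0.01, 0.05, 0.2):
                np.testing.assert_array_equal(bh_fdr(p, q), brute_bh(p, q))

    def test_edge_cases(self):
        assert not bh_fdr([1.0, 1.0, 1.0], 0.05).any()
        assert bh_fdr([0.01], 0.05).all()
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], 0.05)


def ols_oracle(y, X):
    """Normal equations + Gaussian AIC, independent of statsmodels."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    n, p = len(y), Xd.shape[1]
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - rss / tss
    ll = -n / 2 * (math.log(2 * math.pi * rss / n) + 1)
    return beta, r2, -2 * ll + 2 * p


class TestRegression:
    def test_exact_fit_and_intercept_only(self, rng):
        x = rng.normal(0, 1, 30)
        y = 2.0 + 3.0 * x
        fit = ols_regression(y, pd.DataFrame({"x": x}))
        assert fit.r2 == pytest.approx(1.0)
        y2 = rng.normal(0, 1, 30)
        fit2 = ols_regression(y2, pd.DataFrame(index=range(30)))
        assert fit2.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(0, 1, (40, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(0, 1, 40)
        fit = ols_regression(y, pd.DataFrame(X, columns=list("abc")))
        beta, r2, aic = ols_oracle(y, X)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)
        assert fit.r2 == pytest.approx(r2, abs=1e-12)
        assert fit.aic == pytest.approx(aic, abs=1e-8)

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(0, 1, 20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            ols_regression(rng.normal(0, 1, 20), X)

    def test_model_comparison_ranking(self, rng):
        x = rng.normal(0, 1, 60)
        noise_pred = rng.normal(0, 1, 60)
        y = 2 * x + rng.normal(0, 1, 60)
        fit_a = ols_regression(y, pd.DataFrame({"x": x}), name="signal")
        fit_b = ols_regression(
            y, pd.DataFrame({"x": x, "junk": noise_pred}), name="signal+junk"
        )
        table = compare_models([fit_a, fit_b])
        # the pure-noise predictor costs ~2 AIC and should rank second
        assert table.iloc[0]["name"] == "signal"
        dup = compare_models([fit_a, fit_a])
        assert list(dup["name"]) == ["signal", "signal"]
        exact = ols_regression(2 * x, pd.DataFrame({"x": x}), name="exact")
        assert compare_models([exact, fit_a, fit_b]).iloc[0]["name"] == "exact"

    def test_mismatched_n_rejected(self, rng):
        f1 = ols_regression(rng.normal(0, 1, 20), pd.DataFrame({"x": rng.normal(0, 1, 20)}))
        f2 = ols_regression(rng.normal(0, 1, 25), pd.DataFrame({"x": rng.normal(0, 1, 25)}))
        with pytest.raises(ValueError):
            compare_models([f1, f2])


class TestMediation:
    def test_full_mediation_detected(self, rng):
        x = rng.normal(0, 1, 80)
        m = x + rng.normal(0, 0.1, 80)
        y = m + rng.normal(0, 0.3, 80)
        res = mediation(x, m, y, n_boot=500, seed=0)
        assert res.significant
        assert res.indirect == pytest.approx(1.0, abs=0.25)

    def test_independent_mediator_not_significant(self, rng):
        x = rng.normal(0, 1, 80)
        m = rng.normal(0, 1, 80)
        y = x + rng.normal(0, 1, 80)
        res = mediation(x, m, y, n_boot=500, seed=0)
        assert not res.significant

    def test_null_coverage_calibration(self):
        # Nominal 95% percentile CIs should cover the zero indirect effect
        # in at least ~94% of independent-mediator replicates.
        covered = 0
        n_rep = 60
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            x = r.normal(0, 1, 50)
            m = r.normal(0, 1, 50)
            y = x + r.normal(0, 1, 50)
            res = mediation(x, m, y, n_boot=200, seed=rep)
            covered += not res.significant
        assert covered / n_rep >= 0.9

    def test_seed_determinism(self, rng):
        x = rng.normal(0, 1, 40)
        m = 0.5 * x + rng.normal(0, 1, 40)
        y = m + rng.normal(0, 1, 40)
        a = mediation(x, m, y, n_boot=300, seed=7)
        b = mediation(x, m, y, n_boot=300, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestCorrelations:
    def test_fixture_against_direct_formula(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (25, 3)), columns=list("xyz"))
        df["w"] = -2.0 * df["x"]  # exactly anti-linear
        r, p = pearson_corr_table(df)
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "w"] == pytest.approx(-1.0)
        xy = np.corrcoef(df["x"], df["y"])[0, 1]
        assert r.loc["x", "y"] == pytest.approx(xy, abs=1e-12)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)
        assert (p.to_numpy() >= 0).all() and (p.to_numpy() <= 1).all()

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            pearson_corr_table(df)
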