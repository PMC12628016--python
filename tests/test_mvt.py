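"""MVT battery: Wilcoxon against a sign-enumeration oracle, the optimality
regression, the IRT->IRS mixed model, and the Spearman/FDR battery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import semforage as sf
from semforage.errors import DataError, DegenerateTestError


def wilcoxon_enumeration_oracle(d):
    """Exact two-sided signed-rank p by exhaustive 2^n sign enumeration.

    Assumes no zero differences and no tied magnitudes.  p is twice the
    smaller tail of the null distribution of W+ (capped at 1).
    """
    d = np.asarray(d, float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    n_tot = len(ws)
    p_low = np.sum(ws <= w_obs) / n_tot
    p_high = np.sum(ws >= w_obs) / n_tot
    return w_obs, min(1.0, 2 * min(p_low, p_high))


class TestPairedWilcoxon:
    def test_all_positive_differences(self):
        w, p, n = sf.paired_wilcoxon([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert w == 15.0
        assert p == pytest.approx(0.0625)
        assert n == 5

    def test_single_pair(self):
        w, p, n = sf.paired_wilcoxon([1.0], [0.0])
        assert p == pytest.approx(1.0)

    def test_antisymmetric(self):
        _, p, _ = sf.paired_wilcoxon([-2.0, 2.0], [0.0, 0.0])
        assert p == pytest.approx(1.0)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateTestError):
            sf.paired_wilcoxon([1.0, 2.0], [1.0, 2.0])

    def test_zero_differences_dropped(self):
        w1, p1, n1 = sf.paired_wilcoxon([1, 2, 3, 0], [0, 0, 0, 0])
        w2, p2, n2 = sf.paired_wilcoxon([1, 2, 3], [0, 0, 0])
        assert (w1, p1, n1) == (w2, p2, n2)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(2, 10), st.integers(0, 10_000))
    def test_matches_enumeration_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        d = rng.standard_normal(n)
        d = d[d != 0]
        if len(d) < 2 or len(np.unique(np.abs(d))) < len(d):
            return
        w_ref, p_ref = wilcoxon_enumeration_oracle(d)
        w, p, _ = sf.paired_wilcoxon(d, np.zeros_like(d))
        assert w == pytest.approx(w_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_one_sided_ramp_probability(self):
        # all participants ramp up by the same analysis: exact 2/2^n two-sided
        n = 6
        d = np.linspace(0.1, 0.6, n)
        _, p, _ = sf.paired_wilcoxon(d, np.zeros(n))
        assert p == pytest.approx(2 / 2**n)


class TestOptimalityRegression:
    def _summaries(self, gaps, fluency):
        return pd.DataFrame({"pre_switch_gap": gaps,
                             "polyft_fluency": fluency})

    def test_collinear(self):
        r = sf.optimality_regression(self._summaries([0, 1, 2], [0, 1, 2]))
        assert r.slope == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_outcome(self):
        r = sf.optimality_regression(self._summaries([0, 1, 2], [5, 5, 5]))
        assert r.slope == pytest.approx(0.0)
        assert r.r_squared == pytest.approx(0.0)

    def test_hand_computed_ols(self):
        # x=(0,1,2,3), y=(1,3,4,8): Sxy=11, Sxx=5, Syy=26
        r = sf.optimality_regression(self._summaries([0, 1, 2, 3], [1, 3, 4, 8]))
        assert r.slope == pytest.approx(11 / 5)
        assert r.r_squared == pytest.approx(121 / 130, abs=1e-12)
        assert r.df == (1, 2)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        y = 2 * x + rng.standard_normal(40)
        r = sf.optimality_regression(self._summaries(x, y))
        rho = np.corrcoef(x, y)[0, 1]
        assert r.r_squared == pytest.approx(rho**2, abs=1e-10)
        # F consistency: F = r2 (n-2) / (1 - r2)
        assert r.F == pytest.approx(r.r_squared * 38 / (1 - r.r_squared),
                                    abs=1e-8)

    def test_degenerate_predictor(self):
        with pytest.raises(DegenerateTestError):
            sf.optimality_regression(self._summaries([1, 1, 1], [1, 2, 3]))

    def test_too_few_participants(self):
        with pytest.raises(DataError):
            sf.optimality_regression(self._summaries([1, 2], [1, 2]))


class TestPositionTests:
    def test_switching_above_clustering_on_mvt_cohort(self, small_scored):
        results = sf.test_position(small_scored.scored, small_scored.anchors)
        assert {r.position for r in results} <= {"-2", "-1", "+1", "+2"}
        for r in results:
            if r.position in ("-2", "-1"):
                assert r.mean_a > r.mean_b  # switching IRTr above clustering
                assert r.p < 0.01

    def test_ramping_direction(self, small_scored):
        r = sf.ramping_test(small_scored.scored, small_scored.anchors)
        assert r.mean_a > r.mean_b  # -1 runs slower than -2

    def test_fast_switch_subset_below_one(self, small_scored):
        results = sf.test_position(small_scored.scored, small_scored.anchors,
                                   switch_subset="fast")
        for r in results:
            assert r.mean_a < 1.0  # fast switches sit below the marginal value


class TestIrtIrsModel:
    def _scored(self, slope=-0.01, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(6):
            for cue in ("c0", "c1"):
                for k in range(2, 22):
                    irt = float(rng.uniform(1, 8))
                    rows.append(dict(participant=f"p{p}", cue=cue,
                                     response_index=k, irt=irt,
                                     irs=slope * irt + 0.3
                                     + noise * rng.standard_normal(),
                                     transition="clustering"))
        return pd.DataFrame(rows)

    def test_noiseless_coefficient_recovery(self):
        res = sf.irt_irs_model(self._scored(slope=-0.01, noise=0.0))
        assert res.coef_irt == pytest.approx(-0.01, abs=1e-6)

    def test_null_slope_covered(self):
        res = sf.irt_irs_model(self._scored(slope=0.0, noise=0.05, seed=3))
        assert abs(res.coef_irt) < 2.5 * res.se_irt + 1e-3

    def test_negative_irt_irs_dependence_on_cohort(self, small_scored):
        res = sf.irt_irs_model(small_scored.scored, "clustering")
        assert res.coef_irt < 0  # longer gaps -> less similar responses
        assert res.vc_participant >= 0 and res.vc_cue >= 0

    def test_requires_two_cues(self):
        df = self._scored()
        with pytest.raises(DataError):
            sf.irt_irs_model(df[df["cue"] == "c0"])


class TestCorrelationBattery:
    def test_monotone_pairs(self):
        counts = pd.DataFrame({"participant": list("abcdef"),
                               "n_fast": [1, 2, 3, 4, 5, 6]})
        scores = pd.DataFrame({"participant": list("abcdef"),
                               "up": [2, 4, 5, 7, 9, 11.0],
                               "down": [-1, -2, -3, -4, -5, -6.0]})
        out = sf.correlation_battery(counts, scores)
        rho = out.set_index("score")["rho"]
        assert rho["up"] == pytest.approx(1.0)
        assert rho["down"] == pytest.approx(-1.0)

    def test_bh_adjustment_matches_stepup_oracle(self, small_cohort,
                                                 small_scored):
        counts = small_scored.summaries[
            ["participant", "n_fast_switching", "n_slow_clustering"]]
        scores = small_cohort.covariates[
            ["participant", "CAT_CR", "AUT_fluency", "TMT_shifting"]]
        out = sf.correlation_battery(counts, scores)
        p = out["p"].to_numpy()
        # step-up oracle computed directly from the definition
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, i in enumerate(order[::-1]):
            k = m - rank_from_top
            running = min(running, p[i] * m / k)
            adj[i] = running
        assert np.allclose(out["p_fdr"].to_numpy(), adj)
        assert (out["p_fdr"] >= out["p"] - 1e-15).all()

    def test_constant_column_reported_missing(self):
        counts = pd.DataFrame({"participant": list("abcde"),
                               "n_fast": [1, 1, 1, 1, 1]})
        scores = pd.DataFrame({"participant": list("abcde"),
                               "s": [1, 2, 3, 4, 5.0]})
        out = sf.correlation_battery(counts, scores)
        assert np.isnan(out["rho"].iloc[0]) and np.isnan(out["p"].iloc[0])
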