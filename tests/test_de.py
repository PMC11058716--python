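"""Spline design, moderated F-test, BH adjustment and DE selection.

Frozen oracle values in this module were computed with R: the natural-spline
basis with splines::ns (R 4.3.3) and the moderated F-statistics with
limma::lmFit/eBayes (limma 3.58.1), on the deterministic fixtures
reconstructed below.
"""

import numpy as np
import pytest
from scipy import stats

from protgrn.datasets import CONTROL, TREATMENT, SampleSheet
from protgrn.de import (
    ModeratedSplineDE,
    bh_adjust,
    moderated_f_test,
    natural_spline_basis,
    select_de_proteins,
    spline_design,
)
from protgrn.errors import PipelineError, ValidationError
from protgrn.simulate import generate_truth, simulate_timeseries

PAPER_DAYS = np.array([1, 2, 3, 4, 7, 8, 9, 10, 11, 14, 21], dtype=float)

# splines::ns(c(1,2,3,4,7,8,9,10,11,14,21), df=3), R 4.3.3
R_NS_BASIS = np.array([
    [0.0, 0.0, 0.0],
    [-0.073618028178716058, 0.181027868865410224, -0.105967532994386479],
    [-0.132394345923273427, 0.347132065054772565, -0.203199257593037613],
    [-0.161487242799513375, 0.483388915892039084, -0.282959365400217988],
    [0.030427552544236038, 0.603918746902039838, -0.349593552193528556],
    [0.156090602482675284, 0.566739673327174565, -0.318520523062596927],
    [0.279166302407425737, 0.515275065105297414, -0.270265543336898839],
    [0.379150888790746154, 0.464561913539273452, -0.210716478800607676],
    [0.444398621446891740, 0.423673566960264814, -0.143807482524803493],
    [0.457286936111507669, 0.355073764810654391, 0.093062093195484974],
    [-0.160251374705420252, 0.386488609583660603, 0.773762765121759677],
])


def _hat(basis):
    design = np.column_stack([np.ones(len(basis)), basis])
    return design @ np.linalg.pinv(design)


def _two_group_days():
    days = np.tile(PAPER_DAYS, 2)
    groups = np.array([CONTROL] * 11 + [TREATMENT] * 11)
    return days, groups


class TestSplineDesign:
    def test_two_group_design_has_8_columns(self):
        days, groups = _two_group_days()
        design, interaction = spline_design(days, df=3, groups=groups)
        assert design.shape == (22, 8)  # 2 * (1 + 3)
        assert len(interaction) == 4  # group offset + 3 interactions
        assert np.linalg.matrix_rank(design) == 8

    def test_df1_is_linear_in_day(self):
        basis = natural_spline_basis(PAPER_DAYS, df=1)
        assert basis.shape == (11, 1)
        # a single natural-spline column with no interior knots is affine
        fit = np.polyfit(PAPER_DAYS, basis[:, 0], 1)
        resid = basis[:, 0] - np.polyval(fit, PAPER_DAYS)
        assert np.max(np.abs(resid)) < 1e-10

    def test_span_matches_r_ns_oracle(self):
        """Projection onto the spanned space equals R's ns() to 1e-10."""
        mine = natural_spline_basis(PAPER_DAYS, df=3)
        assert np.max(np.abs(_hat(mine) - _hat(R_NS_BASIS))) < 1e-10

    def test_too_few_days_rejected(self):
        with pytest.raises(ValidationError):
            spline_design(np.array([1.0, 2.0, 3.0]), df=3)


class TestModeratedF:
    def test_identical_groups_give_null_result(self):
        days, groups = _two_group_days()
        rng = np.random.default_rng(0)
        base = rng.normal(8, 1, (5, 11))
        X = np.hstack([base, base])  # identical curves in both groups
        model = ModeratedSplineDE().fit(X, days=days, groups=groups)
        assert np.all(model.f_stat_ < 1e-10)
        assert np.all(model.p_value_ > 0.999)

    def test_prior_df_zero_equals_ordinary_f(self):
        """With moderation disabled the statistic is the classical F."""
        days, groups = _two_group_days()
        rng = np.random.default_rng(1)
        X = rng.normal(8, 1, (20, 22))
        model = ModeratedSplineDE(prior_df=0).fit(X, days=days, groups=groups)
        design, inter = spline_design(days, df=3, groups=groups)
        reduced = np.delete(design, inter, axis=1)
        for i in range(20):
            b_full, *_ = np.linalg.lstsq(design, X[i], rcond=None)
            b_red, *_ = np.linalg.lstsq(reduced, X[i], rcond=None)
            rss1 = np.sum((X[i] - design @ b_full) ** 2)
            rss0 = np.sum((X[i] - reduced @ b_red) ** 2)
            dfr = 22 - design.shape[1]
            f = (rss0 - rss1) / len(inter) / (rss1 / dfr)
            assert model.f_stat_[i] == pytest.approx(f, rel=1e-10)

    def test_matches_limma_homoscedastic_fixture(self):
        """Gaussian fixture: F and prior match limma eBayes (infinite prior df)."""
        rng = np.random.default_rng(42)
        days, groups = _two_group_days()
        X = rng.normal(8.0, 1.0, (12, 22))
        X[0, 11:] += 1.5
        X[1, 11:] += np.linspace(0, 2, 11)
        model = ModeratedSplineDE().fit(X, days=days, groups=groups)
        assert np.isinf(model.prior_df_)
        assert model.prior_s2_ == pytest.approx(0.8507458, rel=1e-6)
        limma_f = [5.85493964432905134, 1.98871947615818878, 0.68516491736641172,
                   0.22461716082514621, 1.46155075354573771, 1.80240369500966735,
                   2.15294615166897785, 0.59249287953985963, 1.80428151320280961,
                   1.68351442800283024, 2.20427503333225117, 1.27743825998473648]
        np.testing.assert_allclose(model.f_stat_, limma_f, rtol=1e-9)
        limma_p0 = 0.00010437715786474872
        assert model.p_value_[0] == pytest.approx(limma_p0, rel=1e-9)

    def test_matches_limma_heteroscedastic_fixture(self):
        """Scaled-inv-chi-square variances: finite prior df matches limma."""
        rng = np.random.default_rng(7)
        days, groups = _two_group_days()
        n_prot = 30
        d0, s0 = 6.0, 0.5
        var = d0 * s0 / rng.chisquare(d0, n_prot)
        X = rng.normal(8.0, 1.0, (n_prot, 1)) + rng.normal(
            0, np.sqrt(var)[:, None], (n_prot, 22)
        )
        X[0, 11:] += 1.2
        model = ModeratedSplineDE().fit(X, days=days, groups=groups)
        assert model.prior_df_ == pytest.approx(8.1411771718289554, rel=1e-8)
        assert model.prior_s2_ == pytest.approx(0.52522082958847116, rel=1e-8)
        limma_f8 = [8.46604480501928336, 1.15288100971023844, 0.59434526361988649,
                    0.27554049179192491, 0.42838676326676972, 1.21501746614776618,
                    0.59296249452729266, 2.28160671773148316]
        np.testing.assert_allclose(model.f_stat_[:8], limma_f8, rtol=1e-9)

    def test_invariant_to_constant_shift(self):
        days, groups = _two_group_days()
        rng = np.random.default_rng(3)
        X = rng.normal(8, 1, (10, 22))
        a = ModeratedSplineDE().fit(X, days=days, groups=groups)
        b = ModeratedSplineDE().fit(X + 100.0, days=days, groups=groups)
        np.testing.assert_allclose(a.f_stat_, b.f_stat_, rtol=1e-8)

    def test_null_p_values_uniform(self):
        """500 Gaussian null proteins: p-values uniform (KS at 1%)."""
        days, groups = _two_group_days()
        rng = np.random.default_rng(0)
        X = rng.normal(8, 1, (500, 22))
        model = ModeratedSplineDE().fit(X, days=days, groups=groups)
        assert stats.kstest(model.p_value_, "uniform").pvalue > 0.01


class TestBH:
    def test_hand_computed_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_brute_force_oracle(self, rng):
        """Step-up BH by direct definition on 100 random vectors."""

        def brute(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * m / rank)
                adj[idx] = running
            return adj

        for _ in range(100):
            p = rng.uniform(1e-6, 1, rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), brute(p), rtol=1e-12)

    def test_monotone_and_at_least_input(self, rng):
        p = rng.uniform(1e-6, 1, 50)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


class TestSelection:
    def _results(self, p_values, p_adjusted):
        from protgrn.de import DEResult

        return [
            DEResult(f"P{i}", 1.0, pv, pa)
            for i, (pv, pa) in enumerate(zip(p_values, p_adjusted))
        ]

    def test_adjusted_path_when_available(self):
        res = self._results([0.001, 0.5], [0.01, 0.9])
        chosen, used_adjusted = select_de_proteins(res)
        assert used_adjusted and chosen == ["P0"]

    def test_fallback_to_nominal(self):
        res = self._results([0.01] * 45 + [0.5] * 55, [0.3] * 100)
        chosen, used_adjusted = select_de_proteins(res)
        assert not used_adjusted
        assert len(chosen) == 45

    def test_empty_even_nominal_is_error(self):
        res = self._results([0.5, 0.6], [0.9, 0.9])
        with pytest.raises(PipelineError):
            select_de_proteins(res)

    def test_count_matches_threshold_oracle(self, rng):
        p = rng.uniform(0, 1, 200)
        res = self._results(p, np.ones(200))
        chosen, _ = select_de_proteins(res, alpha=0.05)
        assert len(chosen) == int((p < 0.05).sum())


def test_treatment_touched_proteins_enriched(study_sheet):
    """Proteins touched by the condition effect dominate the DE selection.

    One-sided Fisher test of (touched x selected) pooled over seeds.
    """
    from scipy.stats import fisher_exact

    table = np.zeros((2, 2))
    for seed in range(6):
        truth = generate_truth(20, 0.15, 0.3, seed=seed)
        data = simulate_timeseries(truth, study_sheet, obs_noise_sd=0.1,
                                   seed=seed + 50)
        from protgrn.preprocess import log2_transform

        results = moderated_f_test(log2_transform(data))
        delta = truth.treatment_delta != 0
        touched = set()
        for j, i in np.argwhere(delta):
            touched.add(truth.proteins[i])  # direct target
            for k in np.nonzero(truth.adjacency[i])[0]:
                touched.add(truth.proteins[k])  # one step downstream
            touched.add(truth.proteins[j])
        for r in results:
            sel = r.p_value < 0.05
            t = r.protein in touched
            table[int(t), int(sel)] += 1
    _, p = fisher_exact(table[::-1, ::-1], alternative="greater")
    assert p < 0.05
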