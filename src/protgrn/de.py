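"""Time-series differential-expression screen.

Per protein, the log2 expression profile is modelled by natural cubic
regression splines over day (3 degrees of freedom by default), with a
two-group design (intercept, group offset, shared spline basis, and
group x basis interaction). The interaction coefficients are tested jointly
with an empirical-Bayes moderated F-statistic: per-protein residual variances
are shrunk toward a common prior estimated from the whole ensemble by the
standard hierarchical model (scaled inverse chi-square prior, moments matched
on log residual variances). P-values are Benjamini-Hochberg adjusted; the
screen first applies the adjusted threshold and falls back to nominal
p-values when nothing passes, logging the fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datasets import CONDITIONS, CONTROL, ExpressionDataset
from .errors import PipelineError, ValidationError

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Natural cubic spline basis (ns()-equivalent construction)
# --------------------------------------------------------------------------

def natural_spline_basis(x, df: int = 3, boundary=None) -> np.ndarray:
    """Natural cubic regression spline basis with ``df`` degrees of freedom.

    Interior knots sit at quantiles of ``x``; boundary knots at its extremes.
    The cubic B-spline basis is constrained to zero second derivative at the
    boundaries and the intercept column is excluded, yielding ``df`` columns
    that span the same space as R's splines::ns.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValidationError("df must be >= 1")
    if boundary is None:
        boundary = (x.min(), x.max())
    lo, hi = boundary
    if not hi > lo:
        raise ValidationError("degenerate day range")
    n_interior = df - 1
    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    interior = np.quantile(x, probs) if n_interior else np.array([])
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    m = n_interior + 4  # number of cubic B-spline columns

    def design(points, deriv=0):
        out = np.zeros((len(points), m))
        for j in range(m):
            coef = np.zeros(m)
            coef[j] = 1.0
            spl = BSpline(knots, coef, 3, extrapolate=False)
            if deriv:
                spl = spl.derivative(deriv)
            out[:, j] = spl(np.clip(points, lo, hi))
        return out

    basis = design(x)
    const = design(np.array([lo, hi]), deriv=2)
    # Drop the intercept column, then project out the two natural constraints.
    basis = basis[:, 1:]
    const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    natural = basis @ q[:, 2:]
    # Linear extrapolation beyond the boundary knots (natural splines are
    # linear outside [lo, hi]).
    below, above = x < lo, x > hi
    if below.any() or above.any():
        d1 = design(np.array([lo, hi]), deriv=1)[:, 1:] @ q[:, 2:]
        edge = design(np.array([lo, hi]))[:, 1:] @ q[:, 2:]
        if below.any():
            natural[below] = edge[0] + np.outer(x[below] - lo, d1[0])
        if above.any():
            natural[above] = edge[1] + np.outer(x[above] - hi, d1[1])
    return natural


def spline_design(days, df: int = 3, groups=None):
    """Design matrix for one- or two-group spline fits.

    One group: intercept + df spline columns. Two groups: intercept, group
    indicator, shared basis, and group x basis interaction — 2(1 + df)
    columns. Returns ``(design, interaction_cols)`` where ``interaction_cols``
    indexes the group-difference columns (offset + interactions) whose joint
    nullity means identical curves.
    """
    days = np.asarray(days, dtype=float)
    if len(np.unique(days)) < df + 2:
        raise ValidationError("need at least df + 2 distinct days")
    basis = natural_spline_basis(days, df=df)
    n = len(days)
    if groups is None:
        design = np.column_stack([np.ones(n), basis])
        interaction = np.array([], dtype=int)
    else:
        groups = np.asarray(groups)
        g = (groups != groups[0]).astype(float)
        if len(np.unique(groups)) != 2:
            raise ValidationError("two-group design requires exactly two groups")
        design = np.column_stack(
            [np.ones(n), g, basis, basis * g[:, None]]
        )
        interaction = np.arange(2 + df, 2 + 2 * df)
        interaction = np.concatenate([[1], interaction])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    return design, interaction


# --------------------------------------------------------------------------
# Empirical-Bayes moderated F
# --------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match a scaled inverse chi-square prior to residual variances.

    Returns ``(prior_df, prior_s2)``; ``prior_df`` may be ``inf`` when the
    observed spread of log variances is no wider than chi-square sampling
    noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df_resid / 2.0)
    if e_var > 0:
        prior_df = 2.0 * _trigamma_inverse(e_var)
        prior_s2 = np.exp(
            e_mean + special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0)
        )
    else:
        # No excess spread beyond chi-square sampling noise: infinite prior
        # df; the common variance is the plain mean of the sample variances.
        prior_df = np.inf
        prior_s2 = float(np.mean(s2[ok]))
    return float(prior_df), float(prior_s2)


@dataclass
class DEResult:
    protein: str
    f_stat: float
    p_value: float
    p_adjusted: float
    selected: bool = False


class ModeratedSplineDE(BaseEstimator):
    """Spline-curve differential-expression screen with a moderated F-test.

    Parameters
    ----------
    df : spline degrees of freedom per group curve.
    alpha : significance threshold on the configured p-value column.
    prior_df : override for the empirical-Bayes prior degrees of freedom;
        0 disables moderation (ordinary F), None estimates it from the data.
    """

    def __init__(self, df: int = 3, alpha: float = 0.05, prior_df: float | None = None):
        self.df = df
        self.alpha = alpha
        self.prior_df = prior_df

    def fit(self, X, days=None, groups=None):
        """X is protein x sample (complete); days/groups annotate samples."""
        X = np.asarray(X, dtype=float)
        if days is None or groups is None:
            raise ValidationError("days and groups are required")
        design, interaction = spline_design(days, df=self.df, groups=groups)
        n, p = design.shape
        df_resid = n - p
        if df_resid < 1:
            raise ValidationError("fewer than 1 residual degree of freedom")
        reduced = np.delete(design, interaction, axis=1)
        k = len(interaction)

        # Least squares for all proteins at once via pseudoinverses.
        def rss(D):
            coef, *_ = np.linalg.lstsq(D, X.T, rcond=None)
            resid = X.T - D @ coef
            return (resid**2).sum(axis=0)

        rss_full = rss(design)
        rss_red = rss(reduced)
        s2 = rss_full / df_resid

        if self.prior_df is None:
            prior_df, prior_s2 = fit_variance_prior(s2, df_resid)
        elif self.prior_df == 0:
            prior_df, prior_s2 = 0.0, 0.0
        else:
            prior_df = float(self.prior_df)
            _, prior_s2 = fit_variance_prior(s2, df_resid)

        if np.isinf(prior_df):
            s2_post = np.full_like(s2, prior_s2)
            df_total = np.inf
        else:
            s2_post = (prior_df * prior_s2 + df_resid * s2) / (prior_df + df_resid)
            df_total = df_resid + prior_df
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.maximum(rss_red - rss_full, 0.0) / k / s2_post
        f = np.where(np.isfinite(f), f, 0.0)
        if np.isinf(df_total):
            p_val = stats.chi2.sf(k * f, k)
        else:
            p_val = stats.f.sf(f, k, df_total)
        p_val = np.clip(p_val, np.finfo(float).tiny, 1.0)

        self.design_ = design
        self.interaction_cols_ = interaction
        self.df_residual_ = df_resid
        self.prior_df_ = prior_df
        self.prior_s2_ = prior_s2
        self.f_stat_ = f
        self.p_value_ = p_val
        self.p_adjusted_ = bh_adjust(p_val)
        return self

    def results(self, proteins) -> list[DEResult]:
        return [
            DEResult(p, float(f), float(pv), float(pa))
            for p, f, pv, pa in zip(
                proteins, self.f_stat_, self.p_value_, self.p_adjusted_
            )
        ]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderated_f_test(
    data: ExpressionDataset, df: int = 3, prior_df: float | None = None
) -> list[DEResult]:
    """Moderated spline F-test of curve equality between the two conditions."""
    if data.missing_mask.any():
        raise ValidationError("DE testing requires imputed (complete) data")
    groups = np.asarray(data.sheet.conditions)
    days = np.asarray(data.sheet.days, dtype=float)
    model = ModeratedSplineDE(df=df, prior_df=prior_df)
    model.fit(data.values, days=days, groups=groups)
    return model.results(data.proteins)


def select_de_proteins(
    results: list[DEResult], alpha: float = 0.05, use_adjusted: bool = True
) -> tuple[list[str], bool]:
    """Threshold the configured p-value column; fall back to nominal p-values.

    Returns ``(selected_proteins, used_adjusted)``. When the adjusted column
    selects nothing the screen falls back to nominal p-values (logged); an
    empty selection even then is a pipeline error.
    """
    used_adjusted = use_adjusted
    if use_adjusted:
        chosen = [r.protein for r in results if r.p_adjusted < alpha]
        if not chosen:
            logger.warning(
                "no proteins pass the adjusted threshold; falling back to nominal p-values"
            )
            used_adjusted = False
    if not used_adjusted:
        chosen = [r.protein for r in results if r.p_value < alpha]
    if not chosen:
        raise PipelineError("no differentially expressed proteins even at nominal p < alpha")
    for r in results:
        r.selected = r.protein in set(chosen)
    return chosen, used_adjusted


def de_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [r.protein for r in results],
            "F": [r.f_stat for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "selected": [r.selected for r in results],
        }
    )
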