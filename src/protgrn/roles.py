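"""Protein role analysis via Vester sensitivity analysis.

The top 75 % of a network's links (by weight) form the impact matrix; each
protein's active sum (AS, total outgoing weight) and passive sum (PS, total
incoming weight) place it in the AS-PS plane, split at the per-condition
75th percentiles into four roles: critical (both high), active (AS only),
reactive (PS only), neutral. Role changes between control and treatment are
tested per protein with Welch t-tests on the noise-ensemble AS and PS
distributions, combined per noise kind by a factor-2 corrected min-p; only
proteins significant under both AGN and MGN count as robust changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CONTROL, TREATMENT, GRNetwork
from .errors import ValidationError
from .robustness import AGN, MGN, NetworkEnsemble

logger = logging.getLogger(__name__)

ROLES = ("critical", "active", "reactive", "neutral")


@dataclass
class RoleRecord:
    protein: str
    as_score: float
    ps_score: float
    role: str
    condition: str


@dataclass
class RoleChangeResult:
    protein: str
    p_agn: float
    p_mgn: float
    significant: bool
    role_control: str
    role_treatment: str
    critical_transition: bool
    change_magnitude: float = 0.0


def impact_matrix(network: GRNetwork, keep_frac: float = 0.75) -> np.ndarray:
    """Zero out links below the (1 - keep_frac) weight quantile, keep magnitudes."""
    if not 0 < keep_frac <= 1:
        raise ValidationError("keep_frac must be in (0, 1]")
    w = network.weights.copy()
    if keep_frac < 1:
        off = network.offdiag_weights()
        thr = np.quantile(off, 1.0 - keep_frac)
        w[w < thr] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def as_ps(impact: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Active sum (row sums of |weights|) and passive sum (column sums)."""
    impact = np.asarray(impact, dtype=float)
    if not np.allclose(np.diag(impact), 0):
        raise ValidationError("impact matrix must have a zero diagonal")
    mag = np.abs(impact)
    return mag.sum(axis=1), mag.sum(axis=0)


def classify_roles(as_scores, ps_scores, proteins=None, condition: str = "",
                   pct: float = 75.0) -> list[RoleRecord]:
    """Quadrant assignment at the per-condition 75th percentile marks."""
    as_scores = np.asarray(as_scores, dtype=float)
    ps_scores = np.asarray(ps_scores, dtype=float)
    if as_scores.size < 4:
        raise ValidationError("need at least 4 proteins to mark percentiles")
    proteins = list(proteins) if proteins is not None else [str(i) for i in range(as_scores.size)]
    as_thr = np.percentile(as_scores, pct)
    ps_thr = np.percentile(ps_scores, pct)
    degenerate_as = np.all(as_scores == as_scores[0])
    degenerate_ps = np.all(ps_scores == ps_scores[0])
    if degenerate_as and degenerate_ps:
        logger.warning("degenerate AS/PS axes; all roles neutral")
    records = []
    for p, a, s in zip(proteins, as_scores, ps_scores):
        hi_as = a > as_thr
        hi_ps = s > ps_thr
        if hi_as and hi_ps:
            role = "critical"
        elif hi_as:
            role = "active"
        elif hi_ps:
            role = "reactive"
        else:
            role = "neutral"
        records.append(RoleRecord(p, float(a), float(s), role, condition))
    return records


def network_roles(network: GRNetwork, keep_frac: float = 0.75) -> list[RoleRecord]:
    imp = impact_matrix(network, keep_frac)
    a, s = as_ps(imp)
    return classify_roles(a, s, network.proteins, condition=network.condition)


def _ensemble_as_ps(ensemble: NetworkEnsemble, keep_frac: float):
    """Per-replicate AS and PS arrays, shape (n_reps, n_proteins)."""
    as_list, ps_list = [], []
    for net in ensemble.networks:
        a, s = as_ps(impact_matrix(net, keep_frac))
        as_list.append(a)
        ps_list.append(s)
    return np.stack(as_list), np.stack(ps_list)


def _welch_min_p(a_c, a_t, p_c, p_t) -> np.ndarray:
    """Per-protein min-p over the AS and PS Welch tests, doubled (Bonferroni)."""

    def welch(x, y):
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(x, y, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        return np.where(np.isfinite(p), p, 1.0)

    p_as = welch(a_c, a_t)
    p_ps = welch(p_c, p_t)
    return np.minimum(1.0, 2.0 * np.minimum(p_as, p_ps))


def role_change_test(
    ensembles: dict,
    control_network: GRNetwork,
    treatment_network: GRNetwork,
    alpha: float = 0.05,
    keep_frac: float = 0.75,
) -> list[RoleChangeResult]:
    """Dual-noise role-change testing.

    ``ensembles`` is ``{kind: {condition: NetworkEnsemble}}`` with AGN and
    MGN entries for both conditions. A protein's role change is significant
    only when its per-kind combined p-value passes ``alpha`` under both noise
    kinds; role labels come from the unperturbed networks.
    """
    for kind in (AGN, MGN):
        if kind not in ensembles:
            raise ValidationError(f"missing {kind} ensembles")
        for cond in (CONTROL, TREATMENT):
            ens = ensembles[kind].get(cond)
            if ens is None or len(ens.networks) < 2:
                raise ValidationError(f"need >= 2 replicates for {kind}/{cond}")

    proteins = control_network.proteins
    p_by_kind = {}
    mean_as, mean_ps = {}, {}
    for kind in (AGN, MGN):
        a_c, s_c = _ensemble_as_ps(ensembles[kind][CONTROL], keep_frac)
        a_t, s_t = _ensemble_as_ps(ensembles[kind][TREATMENT], keep_frac)
        p_by_kind[kind] = _welch_min_p(a_c, a_t, s_c, s_t)
        for cond, (a, s) in ((CONTROL, (a_c, s_c)), (TREATMENT, (a_t, s_t))):
            mean_as.setdefault(cond, []).append(a.mean(axis=0))
            mean_ps.setdefault(cond, []).append(s.mean(axis=0))

    roles_c = {r.protein: r.role for r in network_roles(control_network, keep_frac)}
    roles_t = {r.protein: r.role for r in network_roles(treatment_network, keep_frac)}

    # Role-change magnitude: Euclidean distance between condition-mean
    # (AS, PS) coordinates, averaged over the two noise kinds.
    d_as = np.mean(mean_as[CONTROL], axis=0) - np.mean(mean_as[TREATMENT], axis=0)
    d_ps = np.mean(mean_ps[CONTROL], axis=0) - np.mean(mean_ps[TREATMENT], axis=0)
    magnitude = np.hypot(d_as, d_ps)

    results = []
    for i, prot in enumerate(proteins):
        p_agn = float(p_by_kind[AGN][i])
        p_mgn = float(p_by_kind[MGN][i])
        significant = p_agn < alpha and p_mgn < alpha
        rc, rt = roles_c[prot], roles_t[prot]
        critical_transition = rc != rt and "critical" in (rc, rt)
        results.append(
            RoleChangeResult(prot, p_agn, p_mgn, significant, rc, rt,
                             critical_transition, float(magnitude[i]))
        )
    return results


def role_table(records: list[RoleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "AS": [r.as_score for r in records],
            "PS": [r.ps_score for r in records],
            "role": [r.role for r in records],
            "condition": [r.condition for r in records],
        }
    )


def role_change_table(results: list[RoleChangeResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "protein": [r.protein for r in results],
            "p_AGN": [r.p_agn for r in results],
            "p_MGN": [r.p_mgn for r in results],
            "significant": [r.significant for r in results],
            "role_control": [r.role_control for r in results],
            "role_treatment": [r.role_treatment for r in results],
            "critical_transition": [r.critical_transition for r in results],
            "change_magnitude": [r.change_magnitude for r in results],
        }
    )
    return df.sort_values("change_magnitude", ascending=False, ignore_index=True)
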