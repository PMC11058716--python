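"""Protein regulatory divergence analysis and target integration.

Per directed link, the control-vs-treatment weight difference (delta) on the
unperturbed networks ranks the links; the top 10 % by |delta| are flagged.
The Jensen-Shannon divergence between the link's control and treatment
noise-ensemble weight distributions (shared-histogram estimate, base-2 logs,
value in [0, 1]) quantifies how robustly the link diverges. A flagged link
also counts as *significant* when its |delta| exceeds a multiple of the
pooled ensemble standard deviation, which keeps the significant set empty
under the null; proteins incident to >= 4 significant links are regulatory
hubs. Targets integrate the role analysis (PRA) and this divergence analysis
(PRDA): principal targets are hubs, PRA-significant PRDA members, or
critical-transition proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .datasets import CONTROL, TREATMENT, GRNetwork
from .errors import ValidationError
from .roles import RoleChangeResult

logger = logging.getLogger(__name__)

#: |delta| must exceed this multiple of the pooled ensemble SD to be
#: significant. One SD unit is calibrated to the premise that the robustness
#: noise scale is at least the measurement uncertainty of the data; larger
#: data noise calls for a larger factor.
DELTA_SD_FACTOR = 1.0


@dataclass
class DivergenceRecord:
    regulator: str
    target: str
    delta: float
    js: float = float("nan")
    in_top_decile: bool = False
    significant: bool = False
    sd_control: float = float("nan")
    sd_treatment: float = float("nan")


@dataclass
class TargetReport:
    principal_targets: list
    hubs: list
    candidates: list
    evidence: pd.DataFrame


def link_deltas(
    control: GRNetwork, treatment: GRNetwork, top_frac: float = 0.10
) -> list[DivergenceRecord]:
    """Per-directed-link weight differences with top-|delta| flags.

    The flagged count is ceil(top_frac * n_links); when every delta is zero
    (identical networks) nothing is flagged.
    """
    if control.proteins != treatment.proteins:
        raise ValidationError("networks must share an identical protein universe")
    if not 0 < top_frac <= 1:
        raise ValidationError("top_frac must be in (0, 1]")
    n = control.n_proteins
    off = ~np.eye(n, dtype=bool)
    delta = treatment.weights - control.weights
    reg_idx, tgt_idx = np.nonzero(off)
    mags = np.abs(delta[reg_idx, tgt_idx])
    n_flag = int(np.ceil(top_frac * len(mags)))
    flags = np.zeros(len(mags), dtype=bool)
    if mags.max() > 0:
        order = np.argsort(-mags, kind="stable")
        chosen = order[:n_flag]
        flags[chosen[mags[chosen] > 0]] = True  # zero deltas are never flagged
    records = []
    for k, (j, i) in enumerate(zip(reg_idx, tgt_idx)):
        records.append(
            DivergenceRecord(
                control.proteins[j], control.proteins[i],
                float(delta[j, i]), in_top_decile=bool(flags[k]),
            )
        )
    return records


def js_divergence(samples_a, samples_b, min_bins: int = 8,
                  smoothing: float = 1e-10) -> float:
    """Jensen-Shannon divergence of two empirical distributions in [0, 1].

    Both samples are histogrammed on shared Freedman-Diaconis bins over the
    pooled range (floor ``min_bins``), epsilon-smoothed, and compared with
    base-2 logarithms so identical distributions give 0 and disjoint
    supports approach 1.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least two samples per side")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("samples must be finite")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        return 0.0
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    if iqr > 0:
        width = 2.0 * iqr / np.cbrt(pooled.size)
        n_bins = max(min_bins, int(np.ceil((hi - lo) / width)))
    else:
        n_bins = min_bins
    n_bins = min(n_bins, 512)
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    p = pa / pa.sum() + smoothing
    q = pb / pb.sum() + smoothing
    p /= p.sum()
    q /= q.sum()
    return float(jensenshannon(p, q, base=2) ** 2)


def prda(
    ensembles_by_condition: dict,
    control_network: GRNetwork,
    treatment_network: GRNetwork,
    top_frac: float = 0.10,
    restrict_to=None,
    sd_factor: float = DELTA_SD_FACTOR,
    significance: str = "delta-sd",
) -> list[DivergenceRecord]:
    """Full regulatory-divergence analysis.

    Deltas come from the unperturbed networks; JS divergences and ensemble
    SDs from the paired noise ensembles. ``significance`` selects how a
    flagged link qualifies as significant: ``delta-sd`` (top-decile and
    |delta| > sd_factor x pooled ensemble SD, the default), ``top-decile``
    (rank alone), or ``js`` (top-decile and JS above the link median).
    ``restrict_to`` keeps only links incident to the given proteins.
    """
    if significance not in ("delta-sd", "top-decile", "js"):
        raise ValidationError("unknown significance rule")
    stacks = {
        cond: ensembles_by_condition[cond].weight_stack()
        for cond in (CONTROL, TREATMENT)
    }
    records = link_deltas(control_network, treatment_network, top_frac)
    idx = {p: i for i, p in enumerate(control_network.proteins)}
    js_vals = []
    for rec in records:
        j, i = idx[rec.regulator], idx[rec.target]
        wc = stacks[CONTROL][:, j, i]
        wt = stacks[TREATMENT][:, j, i]
        rec.js = js_divergence(wc, wt)
        rec.sd_control = float(wc.std(ddof=1))
        rec.sd_treatment = float(wt.std(ddof=1))
        js_vals.append(rec.js)
    js_median = float(np.median(js_vals)) if js_vals else 0.0
    for rec in records:
        pooled_sd = float(np.hypot(rec.sd_control, rec.sd_treatment))
        if significance == "top-decile":
            rec.significant = rec.in_top_decile
        elif significance == "js":
            rec.significant = rec.in_top_decile and rec.js > js_median
        else:
            rec.significant = rec.in_top_decile and abs(rec.delta) > sd_factor * pooled_sd
    if restrict_to is not None:
        keep = set(restrict_to)
        records = [r for r in records if r.regulator in keep or r.target in keep]
    return records


def find_hubs(records: list[DivergenceRecord], min_links: int = 4,
              use_significant: bool = True) -> list[str]:
    """Proteins incident (either direction) to >= min_links qualifying links."""
    degree: dict[str, int] = {}
    for rec in records:
        if rec.significant if use_significant else rec.in_top_decile:
            for p in (rec.regulator, rec.target):
                degree[p] = degree.get(p, 0) + 1
    return sorted(p for p, d in degree.items() if d >= min_links)


def integrate_targets(
    pra_results: list[RoleChangeResult],
    prda_records: list[DivergenceRecord],
    hubs: list[str] | None = None,
    min_hub_links: int = 4,
) -> TargetReport:
    """Combine PRA and PRDA evidence into the principal-targets report.

    Candidates are PRA-significant proteins plus PRDA-network members
    (proteins incident to significant divergent links). Principal targets
    satisfy at least one of: (a) PRDA regulatory hub; (b) PRA-significant
    and a PRDA-network member; (c) PRA-significant critical-transition
    protein.
    """
    if hubs is None:
        hubs = find_hubs(prda_records, min_links=min_hub_links)
    pra_sig = {r.protein for r in pra_results if r.significant}
    critical = {
        r.protein for r in pra_results if r.significant and r.critical_transition
    }
    prda_members = set()
    for rec in prda_records:
        if rec.significant:
            prda_members.update((rec.regulator, rec.target))
    candidates = sorted(pra_sig | prda_members)
    hub_set = set(hubs)
    principal = sorted(hub_set | (pra_sig & prda_members) | critical)
    all_proteins = sorted(
        {r.protein for r in pra_results}
        | {p for rec in prda_records for p in (rec.regulator, rec.target)}
    )
    evidence = pd.DataFrame(
        {
            "protein": all_proteins,
            "pra_significant": [p in pra_sig for p in all_proteins],
            "critical_transition": [p in critical for p in all_proteins],
            "prda_member": [p in prda_members for p in all_proteins],
            "hub": [p in hub_set for p in all_proteins],
            "principal": [p in principal for p in all_proteins],
        }
    )
    return TargetReport(principal, sorted(hub_set), candidates, evidence)


def divergence_table(records: list[DivergenceRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "regulator": [r.regulator for r in records],
            "target": [r.target for r in records],
            "delta": [r.delta for r in records],
            "js": [r.js for r in records],
            "in_top_decile": [r.in_top_decile for r in records],
            "significant": [r.significant for r in records],
        }
    )
    return df.reindex(df["delta"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
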