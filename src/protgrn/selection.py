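"""Reference-based model selection: early precision and its random baseline.

A model's continuous weights are binarized at ten percentile cuts (75th to
90th, equally spaced), collapsed to unordered pairs, and compared with the
known-links reference. The Early Precision (EP) here is the percentage of
reference links (restricted to the model's protein universe) recovered; EPR
normalizes the ten-cut average EP by the mean EP of random weight matrices
of the same shape. Regression models additionally face an R^2 gate: their
median per-protein cross-validation R^2 must beat the mean-predictor
baseline (zero) in both conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import GRNetwork, ReferenceNetwork
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Ten equally spaced percentile cuts from the 75th to the 90th.
DEFAULT_PERCENTILES = tuple(np.round(np.linspace(0.75, 0.90, 10), 6))


@dataclass
class ModelScorecard:
    model_name: str
    ep: float
    epr: float
    percentile_rank: float
    r2_pass: bool | None = None  # None = not applicable (precision models)


def binarize(network: GRNetwork, percentile: float) -> set[frozenset]:
    """Unordered pairs whose directed weight reaches the given percentile."""
    if not 0 < percentile < 1:
        raise ValidationError("percentile must be in (0, 1)")
    w = network.offdiag_weights()
    thr = np.quantile(w, percentile)
    if w.min() == w.max():
        logger.warning("all weights equal; binarization retains every link")
    n = network.n_proteins
    keep = (network.weights >= thr) & ~np.eye(n, dtype=bool)
    reg, tgt = np.nonzero(keep)
    return {
        frozenset((network.proteins[j], network.proteins[i]))
        for j, i in zip(reg, tgt)
    }


def early_precision(links: set[frozenset], reference: ReferenceNetwork,
                    universe=None) -> float:
    """Percentage of reference links (restricted to the universe) recovered."""
    ref = reference.restricted(universe) if universe is not None else reference
    if len(ref) == 0:
        raise ValidationError("reference network is empty over the model's proteins")
    return 100.0 * len(links & ref.links) / len(ref)


def _reference_mask(proteins, reference: ReferenceNetwork) -> np.ndarray:
    """Upper-triangular boolean matrix of reference pairs over ``proteins``."""
    idx = {p: i for i, p in enumerate(proteins)}
    n = len(proteins)
    mask = np.zeros((n, n), dtype=bool)
    for pair in reference.links:
        a, b = tuple(pair)
        if a in idx and b in idx:
            i, j = sorted((idx[a], idx[b]))
            mask[i, j] = True
    return mask


def _pair_scores(weights: np.ndarray) -> np.ndarray:
    """Upper-triangular pair scores: max of the two directed weights."""
    sym = np.maximum(weights, weights.T)
    iu = np.triu_indices(weights.shape[0], 1)
    return sym[iu]


def _ep_for_weights(weights: np.ndarray, ref_mask: np.ndarray,
                    percentiles) -> float:
    """Average EP of one weight matrix over the percentile cuts.

    Scoring happens at the level of unordered pairs (a pair's score is the
    larger of its two directed weights) so that methods producing symmetric
    and asymmetric matrices retain the same number of candidate pairs at a
    given cut and are comparable against the same random baseline.
    """
    n = weights.shape[0]
    pair = _pair_scores(weights)
    iu = np.triu_indices(n, 1)
    ref_flat = (ref_mask | ref_mask.T)[iu]
    n_ref = int(ref_flat.sum())
    eps = []
    for p in percentiles:
        thr = np.quantile(pair, p)
        hits = int((ref_flat & (pair >= thr)).sum())
        eps.append(100.0 * hits / n_ref)
    return float(np.mean(eps))


def random_baseline_eps(
    n_proteins: int, ref_mask: np.ndarray, percentiles,
    n_random: int = 1000, seed: int = 0,
) -> np.ndarray:
    """EP scores of i.i.d. Uniform(0,1) weight matrices, vectorized."""
    rng = np.random.default_rng(seed)
    n = n_proteins
    iu = np.triu_indices(n, 1)
    ref_flat = (ref_mask | ref_mask.T)[iu]
    n_ref = int(ref_flat.sum())
    eps = np.zeros(n_random)
    batch = max(1, min(n_random, int(5e7 // (n * n) + 1)))
    done = 0
    while done < n_random:
        b = min(batch, n_random - done)
        W = rng.random((b, n, n))
        pair = np.maximum(W, np.transpose(W, (0, 2, 1)))[:, iu[0], iu[1]]
        for p in percentiles:
            thr = np.quantile(pair, p, axis=1)
            hits = (ref_flat[None, :] & (pair >= thr[:, None])).sum(axis=1)
            eps[done : done + b] += 100.0 * hits / n_ref
        done += b
    return eps / len(percentiles)


def epr(
    network: GRNetwork,
    reference: ReferenceNetwork,
    percentiles=DEFAULT_PERCENTILES,
    n_random: int = 1000,
    seed: int = 0,
    model_name: str = "",
) -> ModelScorecard:
    """EP over the ten cuts, EPR against the random baseline, percentile rank."""
    ref = reference.restricted(network.proteins)
    if len(ref) == 0:
        raise ValidationError("reference network is empty over the model's proteins")
    ref_mask = _reference_mask(network.proteins, ref)
    ep = _ep_for_weights(network.weights, ref_mask, percentiles)
    baseline = random_baseline_eps(
        network.n_proteins, ref_mask, percentiles, n_random=n_random, seed=seed
    )
    mean_base = float(baseline.mean())
    epr_value = ep / mean_base if mean_base > 0 else np.inf
    rank = 100.0 * float(np.mean(baseline >= ep))
    return ModelScorecard(model_name or network.method, ep, epr_value, rank)


def gate_regression_models(r2_by_condition: dict) -> bool:
    """True iff the median per-protein R^2 exceeds 0 in every condition."""
    if not r2_by_condition:
        raise ValidationError("no R^2 tables supplied")
    return all(float(np.median(v)) > 0 for v in r2_by_condition.values())


def random_regulator_control(
    data,
    infer,
    reference: ReferenceNetwork,
    de_proteins,
    n_sets: int = 100,
    set_size: int = 50,
    seed: int = 0,
    percentiles=DEFAULT_PERCENTILES,
) -> tuple[float, float, np.ndarray]:
    """Percentile of the DE-based model among random-regulator-set models.

    ``infer`` maps an ExpressionDataset (protein subset, one condition or
    pooled) to a GRNetwork. For each of ``n_sets`` random protein subsets of
    ``set_size`` the network is rebuilt and scored by cut-averaged EP; the
    DE model's percentile uses midranks for ties (lower = better). Returns
    ``(percentile, de_ep, random_eps)``.
    """
    universe = list(data.proteins)
    if len(universe) <= set_size:
        raise ValidationError("protein universe must exceed set_size")
    rng = np.random.default_rng(seed)

    def score(proteins) -> float:
        sub = data.select_proteins(list(proteins))
        net = infer(sub)
        ref = reference.restricted(net.proteins)
        if len(ref) == 0:
            return np.nan
        return _ep_for_weights(net.weights, _reference_mask(net.proteins, ref), percentiles)

    de_ep = score(de_proteins)
    random_eps = []
    for _ in range(n_sets):
        subset = rng.choice(universe, set_size, replace=False)
        random_eps.append(score(subset))
    random_eps = np.asarray(random_eps, dtype=float)
    valid = random_eps[np.isfinite(random_eps)]
    if valid.size == 0 or not np.isfinite(de_ep):
        raise ValidationError("EP undefined for every random regulator set")
    better = np.sum(valid > de_ep)
    ties = np.sum(valid == de_ep)
    percentile = 100.0 * (better + 0.5 * ties) / valid.size
    return float(percentile), float(de_ep), random_eps
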