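"""Noise-ensemble machinery for robustness analysis.

Expression data are perturbed with additive Gaussian noise
(AGN: x* = x + N(0, sigma_a)) or multiplicative Gaussian noise
(MGN: x* = x * N(1, sigma_m)) and the selected inference method is re-run,
yielding per-quantity distributions for the role-change tests and the
regulatory-divergence analysis. Default sigmas are 0.1 (AGN, data units) and
0.05 (MGN, unitless); replicate seeds are paired across conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .datasets import CONDITIONS, ExpressionDataset, GRNetwork
from .errors import ValidationError
from ._seeds import stage_rng

logger = logging.getLogger(__name__)

AGN = "AGN"
MGN = "MGN"
DEFAULT_SIGMA = {AGN: 0.1, MGN: 0.05}


@dataclass(frozen=True)
class NoiseSpec:
    kind: str = MGN
    sigma: float = 0.05
    n_reps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (AGN, MGN):
            raise ValidationError("kind must be 'AGN' or 'MGN'")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.n_reps < 2:
            raise ValidationError("n_reps must be >= 2")


@dataclass
class NetworkEnsemble:
    condition: str
    noise: NoiseSpec
    networks: list  # GRNetwork per surviving replicate

    def __post_init__(self) -> None:
        prots = {net.proteins for net in self.networks}
        if len(prots) > 1:
            raise ValidationError("ensemble networks must share protein order")

    @property
    def proteins(self):
        return self.networks[0].proteins

    def weight_stack(self) -> np.ndarray:
        """(n_reps, n, n) stack of weight matrices."""
        return np.stack([net.weights for net in self.networks])


def apply_noise(data: ExpressionDataset, spec: NoiseSpec, rep: int = 0) -> ExpressionDataset:
    """One noisy replicate; deterministic per (spec.seed, rep)."""
    if data.missing_mask.any():
        raise ValidationError("noise is applied to complete (imputed) data")
    rng = stage_rng(spec.seed, "noise", spec.kind, rep)
    x = data.values
    if spec.kind == AGN:
        noisy = x + rng.normal(0.0, spec.sigma, x.shape)
    else:
        noisy = x * rng.normal(1.0, spec.sigma, x.shape)
    return replace(data, values=noisy, truth_values=None)


def build_ensembles(
    data_by_condition: dict,
    infer,
    spec: NoiseSpec,
    min_survival: float = 0.8,
) -> dict:
    """n_reps perturb->infer cycles per condition with paired replicate seeds.

    ``infer`` maps a perturbed ExpressionDataset to a GRNetwork. A replicate
    whose inference fails is dropped with a warning; at least
    ``min_survival`` of replicates must survive in each condition.
    """
    ensembles = {}
    for cond, data in data_by_condition.items():
        nets = []
        for rep in range(spec.n_reps):
            noisy = apply_noise(data, spec, rep)
            try:
                net = infer(noisy)
            except Exception as exc:  # noqa: BLE001 - replicate-level tolerance
                logger.warning("replicate %d (%s) failed: %s", rep, cond, exc)
                continue
            nets.append(net)
        if len(nets) < min_survival * spec.n_reps:
            raise ValidationError(
                f"only {len(nets)}/{spec.n_reps} replicates survived for {cond}"
            )
        ensembles[cond] = NetworkEnsemble(cond, spec, nets)
    return ensembles


def build_dual_noise_ensembles(
    data_by_condition: dict,
    infer,
    n_reps: int = 50,
    seed: int = 0,
    sigmas: dict = DEFAULT_SIGMA,
) -> dict:
    """AGN and MGN ensembles for both conditions: {kind: {condition: ensemble}}."""
    out = {}
    for kind in (AGN, MGN):
        spec = NoiseSpec(kind=kind, sigma=sigmas[kind], n_reps=n_reps, seed=seed)
        out[kind] = build_ensembles(data_by_condition, infer, spec)
    return out
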