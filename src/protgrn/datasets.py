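"""Core in-memory containers for the pipeline.

Expression data travel as an :class:`ExpressionDataset` — a protein x sample
matrix with an explicit missing-value mask and a :class:`SampleSheet`
describing each sample's condition (control vs treatment) and measurement day.
Networks travel as :class:`GRNetwork` (directed, weighted, zero diagonal) and
ground truth for simulations as :class:`TruthNetwork`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

CONTROL = "control"
TREATMENT = "treatment"
CONDITIONS = (CONTROL, TREATMENT)

#: Measurement days of the study design (one sample per day per condition).
STUDY_DAYS = (1.0, 2.0, 3.0, 4.0, 7.0, 8.0, 9.0, 10.0, 11.0, 14.0, 21.0)
#: Days belonging to the short-term response phase.
SHORT_TERM_MAX_DAY = 11.0


@dataclass(frozen=True)
class SampleSheet:
    """Sample annotations: unique ids, condition labels and measurement days.

    Days must be strictly increasing within each condition and both
    conditions must share the same day grid (the study design takes one
    sample per day per condition).
    """

    sample_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    days: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.conditions) != n or len(self.days) != n:
            raise ValidationError("sample_ids, conditions and days must have equal length")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids must be unique")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValidationError(f"unknown condition {c!r}")
        if any(d <= 0 for d in self.days):
            raise ValidationError("days must be positive")
        per_cond = {}
        for c in set(self.conditions):
            days_c = [d for d, cc in zip(self.days, self.conditions) if cc == c]
            if any(b <= a for a, b in zip(days_c, days_c[1:])):
                raise ValidationError(f"days must be strictly increasing within condition {c!r}")
            per_cond[c] = days_c
        if len(per_cond) == 2:
            a, b = per_cond.values()
            if a != b:
                raise ValidationError("both conditions must share the same day grid")

    @classmethod
    def two_condition(cls, days=STUDY_DAYS) -> "SampleSheet":
        """One sample per day per condition on the given day grid."""
        ids, conds, ds = [], [], []
        for cond in CONDITIONS:
            for d in days:
                ids.append(f"{cond}_d{d:g}")
                conds.append(cond)
                ds.append(float(d))
        return cls(tuple(ids), tuple(conds), tuple(ds))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "condition": self.conditions, "day": self.days}
        )

    def subset(self, keep: np.ndarray) -> "SampleSheet":
        keep = np.asarray(keep)
        return SampleSheet(
            tuple(str(s) for s in np.asarray(self.sample_ids)[keep]),
            tuple(str(c) for c in np.asarray(self.conditions)[keep]),
            tuple(float(d) for d in np.asarray(self.days, dtype=float)[keep]),
        )

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.asarray([c == condition for c in self.conditions])

    def phase_mask(self, phase: str) -> np.ndarray:
        """Boolean sample mask for phase 'short' (days <= 11) or 'long' (all)."""
        if phase == "short":
            return np.asarray([d <= SHORT_TERM_MAX_DAY for d in self.days])
        if phase == "long":
            return np.ones(len(self.days), dtype=bool)
        raise ValidationError(f"unknown phase {phase!r}; expected 'short' or 'long'")


@dataclass
class ExpressionDataset:
    """Protein x sample abundance matrix with an explicit missing mask.

    ``values`` holds finite numbers wherever ``missing_mask`` is False; masked
    entries are ignored by every stage. ``truth_values``, when present, keeps
    the pre-masking values of synthetic data for imputation benchmarking.
    """

    proteins: tuple[str, ...]
    values: np.ndarray
    missing_mask: np.ndarray
    sheet: SampleSheet
    truth_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n_p, n_s = self.values.shape
        if len(self.proteins) != n_p:
            raise ValidationError("protein labels do not match value rows")
        if len(set(self.proteins)) != n_p:
            raise ValidationError("duplicate protein symbols")
        if len(self.sheet.sample_ids) != n_s:
            raise ValidationError("sample sheet does not match value columns")
        if self.missing_mask.shape != self.values.shape:
            raise ValidationError("mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValidationError("observed values must be finite")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_samples(self) -> int:
        return len(self.sheet.sample_ids)

    def observed(self) -> np.ndarray:
        """Values with NaN at masked cells."""
        out = self.values.copy()
        out[self.missing_mask] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.observed(), index=list(self.proteins),
                            columns=list(self.sheet.sample_ids))

    def select_samples(self, keep: np.ndarray) -> "ExpressionDataset":
        keep = np.asarray(keep)
        return replace(
            self,
            values=self.values[:, keep],
            missing_mask=self.missing_mask[:, keep],
            sheet=self.sheet.subset(keep),
            truth_values=None if self.truth_values is None else self.truth_values[:, keep],
        )

    def select_proteins(self, keep) -> "ExpressionDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool or np.issubdtype(keep.dtype, np.integer):
            pass
        else:
            idx = {p: i for i, p in enumerate(self.proteins)}
            keep = np.asarray([idx[p] for p in keep])
        return replace(
            self,
            proteins=tuple(str(p) for p in np.asarray(self.proteins)[keep]),
            values=self.values[keep],
            missing_mask=self.missing_mask[keep],
            truth_values=None if self.truth_values is None else self.truth_values[keep],
        )

    def condition(self, condition: str) -> "ExpressionDataset":
        return self.select_samples(self.sheet.condition_mask(condition))

    def phase(self, phase: str) -> "ExpressionDataset":
        return self.select_samples(self.sheet.phase_mask(phase))


@dataclass
class GRNetwork:
    """Directed weighted network: ``weights[j, i]`` scores regulator j -> target i."""

    proteins: tuple[str, ...]
    weights: np.ndarray
    method: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.proteins)
        if self.weights.shape != (n, n):
            raise ValidationError("weight matrix shape does not match proteins")
        if not np.allclose(np.diag(self.weights), 0.0):
            raise ValidationError("self-loops are not allowed (nonzero diagonal)")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("weights must be finite")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def offdiag_weights(self) -> np.ndarray:
        n = self.n_proteins
        return self.weights[~np.eye(n, dtype=bool)]

    def to_edge_frame(self) -> pd.DataFrame:
        n = self.n_proteins
        reg, tgt = np.nonzero(~np.eye(n, dtype=bool))
        return pd.DataFrame(
            {
                "regulator": np.asarray(self.proteins)[reg],
                "target": np.asarray(self.proteins)[tgt],
                "weight": self.weights[reg, tgt],
            }
        )


@dataclass
class TruthNetwork:
    """Ground truth for simulations.

    ``adjacency[j, i]`` is the signed effect of regulator j on target i in the
    linear regulation function; ``decay`` holds per-protein first-order decay
    rates (per day); ``treatment_delta`` is added to the adjacency under
    treatment and represents the condition effect.
    """

    proteins: tuple[str, ...]
    adjacency: np.ndarray
    decay: np.ndarray
    treatment_delta: np.ndarray
    basal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.decay = np.asarray(self.decay, dtype=float)
        self.treatment_delta = np.asarray(self.treatment_delta, dtype=float)
        n = len(self.proteins)
        if self.adjacency.shape != (n, n) or self.treatment_delta.shape != (n, n):
            raise ValidationError("adjacency shapes do not match proteins")
        if not np.allclose(np.diag(self.adjacency), 0) or not np.allclose(
            np.diag(self.treatment_delta), 0
        ):
            raise ValidationError("self-regulation is not modelled (diagonal must be zero)")
        if self.decay.shape != (n,) or np.any(self.decay <= 0):
            raise ValidationError("decay rates must be positive, one per protein")
        if self.basal is not None:
            self.basal = np.asarray(self.basal, dtype=float)
            if self.basal.shape != (n,):
                raise ValidationError("basal must have one entry per protein")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def condition_adjacency(self, condition: str) -> np.ndarray:
        if condition == TREATMENT:
            return self.adjacency + self.treatment_delta
        return self.adjacency

    def edge_pairs(self) -> set[frozenset]:
        """Undirected true-edge pairs (reference-network style)."""
        reg, tgt = np.nonzero(self.adjacency)
        return {
            frozenset((self.proteins[j], self.proteins[i]))
            for j, i in zip(reg, tgt)
        }


@dataclass(frozen=True)
class ReferenceNetwork:
    """Known functional links as unordered protein pairs (STRING-style)."""

    links: frozenset
    universe: frozenset

    def __post_init__(self) -> None:
        for pair in self.links:
            if len(pair) != 2:
                raise ValidationError("reference links must join two distinct proteins")
            if not pair <= self.universe:
                raise ValidationError("link endpoint missing from universe")

    @classmethod
    def from_pairs(cls, pairs, universe=None) -> "ReferenceNetwork":
        links = {frozenset(p) for p in pairs if len(set(p)) == 2}
        endpoints = set().union(*links) if links else set()
        return cls(frozenset(links), frozenset(universe or endpoints))

    def restricted(self, proteins) -> "ReferenceNetwork":
        prot = frozenset(proteins)
        return ReferenceNetwork(
            frozenset(p for p in self.links if p <= prot), prot
        )

    def __len__(self) -> int:
        return len(self.links)
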