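"""Delimited-text I/O for expression tables, sample sheets and reference links.

All tabular formats are TSV by default: diffable, and directly compatible
with STRING-style two-column edge lists.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, ReferenceNetwork, SampleSheet
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

_NA_STRINGS = ("", "NA", "NaN", "nan")


def read_sample_sheet(path, sep: str = "\t") -> SampleSheet:
    """Read a sample sheet with columns sample_id, condition, day."""
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "condition", "day"}
    if not required <= set(df.columns):
        raise SchemaError(f"sample sheet must have columns {sorted(required)}")
    return SampleSheet(
        tuple(df["sample_id"].astype(str)),
        tuple(df["condition"].astype(str)),
        tuple(df["day"].astype(float)),
    )


def write_sample_sheet(sheet: SampleSheet, path, sep: str = "\t") -> None:
    sheet.to_frame().to_csv(path, sep=sep, index=False)


def read_expression_table(path, sheet: SampleSheet, sep: str = "\t") -> ExpressionDataset:
    """Read a protein x sample table; blanks and "NA" denote missing.

    The first column holds protein symbols; the remaining columns must all
    appear in the sheet, and are reordered to follow it.
    """
    df = pd.read_csv(path, sep=sep, na_values=list(_NA_STRINGS), keep_default_na=False)
    protein_col = df.columns[0]
    proteins = df[protein_col].astype(str)
    if proteins.duplicated().any():
        dupes = proteins[proteins.duplicated()].unique()
        raise ValidationError(f"duplicate protein rows: {list(dupes)[:5]}")
    data_cols = list(df.columns[1:])
    unknown = set(data_cols) - set(sheet.sample_ids)
    if unknown:
        raise SchemaError(f"columns not in sample sheet: {sorted(unknown)}")
    absent = set(sheet.sample_ids) - set(data_cols)
    if absent:
        raise SchemaError(f"sample sheet columns missing from table: {sorted(absent)}")
    values = df[list(sheet.sample_ids)].to_numpy(dtype=float)
    mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    return ExpressionDataset(tuple(proteins), values, mask, sheet)


def write_expression_table(data: ExpressionDataset, path, sep: str = "\t") -> None:
    """Write a dataset as delimited text; masked cells become empty fields."""
    df = data.to_frame()
    df.index.name = "protein"
    df.to_csv(path, sep=sep, na_rep="")


def read_reference_links(path, sep: str = "\t") -> ReferenceNetwork:
    """Read a two-column edge list into an undirected reference network.

    Duplicates and reversed duplicates collapse to one unordered pair;
    self-pairs are dropped with a warning.
    """
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    # Tolerate a header row of non-data labels like "protein1  protein2".
    if len(df.columns) < 2:
        raise ValidationError("reference edge list needs two columns")
    if df.iloc[0, 0].lower() in {"protein1", "source", "regulator", "protein_a"}:
        df = df.iloc[1:]
    if df.empty:
        raise ValidationError("reference edge list is empty")
    pairs = []
    n_self = 0
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if a == b:
            n_self += 1
            continue
        pairs.append((a, b))
    if n_self:
        logger.warning("dropped %d self-pair(s) from reference links", n_self)
    universe = set(df.iloc[:, 0]) | set(df.iloc[:, 1])
    return ReferenceNetwork.from_pairs(pairs, universe)


def write_reference_links(ref: ReferenceNetwork, path, sep: str = "\t") -> None:
    rows = sorted(tuple(sorted(p)) for p in ref.links)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, header=False)


def write_network(network, path, sep: str = "\t") -> None:
    """Write a GRNetwork as a weighted directed edge-list TSV."""
    network.to_edge_frame().to_csv(path, sep=sep, index=False)


def read_network(path, sep: str = "\t"):
    from .datasets import GRNetwork

    df = pd.read_csv(path, sep=sep)
    proteins = sorted(set(df["regulator"]) | set(df["target"]))
    idx = {p: i for i, p in enumerate(proteins)}
    w = np.zeros((len(proteins), len(proteins)))
    for reg, tgt, wt in zip(df["regulator"], df["target"], df["weight"]):
        w[idx[reg], idx[tgt]] = wt
    return GRNetwork(tuple(proteins), w)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
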