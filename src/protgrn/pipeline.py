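"""End-to-end pipeline orchestration with a machine-readable run manifest.

A run takes raw abundance tables (or the synthetic generator), restricts to
the requested response phase, preprocesses and imputes, screens proteins by
the spline DE test, infers one network per condition with the chosen method,
scores it against the known-links reference, and runs the noise-ensemble
role (PRA) and divergence (PRDA) analyses to produce the principal-targets
report. Model naming follows ``{Phase}-{Imputation}-{Method}``
(e.g. LongTerm-KNN-Portia). All randomness derives from one root seed,
deterministically split per stage, so a manifest fully determines outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from ._seeds import stage_seed
from .datasets import CONDITIONS, CONTROL, TREATMENT, ExpressionDataset, ReferenceNetwork
from .de import de_table, moderated_f_test, select_de_proteins
from .divergence import divergence_table, find_hubs, integrate_targets, prda
from .errors import ValidationError
from .precision import PortiaGRN
from .preprocess import ImputationConfig, preprocess
from .regression import RegressionGRN
from .robustness import build_dual_noise_ensembles
from .roles import network_roles, role_change_table, role_change_test, role_table
from .simulate import make_study_fixture

logger = logging.getLogger(__name__)

_PHASE_LABEL = {"short": "ShortTerm", "long": "LongTerm"}
_IMPUTE_LABEL = {"knn": "KNN", "minprob": "MinProb"}
_METHOD_LABEL = {"ridge": "Ridge", "rf": "RF", "portia": "Portia"}


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults follow the study design."""

    outdir: str = "protgrn_run"
    seed: int = 0
    phase: str = "long"
    imputation: str = "knn"
    method: str = "portia"
    # Inputs: either file paths or a synthetic fixture scale.
    expression_path: str | None = None
    sheet_path: str | None = None
    reference_path: str | None = None
    simulate_scale: str = "toy"
    # Stage parameters.
    de_alpha: float = 0.05
    spline_df: int = 3
    max_missing_frac: float = 0.5
    knn_k: int = 10
    minprob_quantile: float = 0.01
    minprob_sigma_scale: float = 1.0
    shrinkage_lambda: float = 0.8
    n_random_networks: int = 1000
    n_noise_reps: int = 50
    keep_frac: float = 0.75
    top_frac: float = 0.10
    min_hub_links: int = 4
    max_de_proteins: int | None = None

    def __post_init__(self) -> None:
        if self.phase not in _PHASE_LABEL:
            raise ValidationError("phase must be 'short' or 'long'")
        if self.imputation not in _IMPUTE_LABEL:
            raise ValidationError("imputation must be 'knn' or 'minprob'")
        if self.method not in _METHOD_LABEL:
            raise ValidationError("method must be 'ridge', 'rf' or 'portia'")

    @property
    def model_name(self) -> str:
        return "-".join(
            [_PHASE_LABEL[self.phase], _IMPUTE_LABEL[self.imputation],
             _METHOD_LABEL[self.method]]
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _load_inputs(config: RunConfig):
    if config.expression_path:
        if not config.sheet_path:
            raise ValidationError("sheet_path is required with expression_path")
        sheet = pio.read_sample_sheet(config.sheet_path)
        data = pio.read_expression_table(config.expression_path, sheet)
        truth = None
    else:
        truth, data = make_study_fixture(config.simulate_scale,
                                         seed=stage_seed(config.seed, "simulate"))
    if config.reference_path:
        reference = pio.read_reference_links(config.reference_path)
    elif truth is not None:
        reference = ReferenceNetwork.from_pairs(truth.edge_pairs(),
                                                universe=truth.proteins)
    else:
        raise ValidationError("a reference network is required for model selection")
    return truth, data, reference


def _make_inferrer(config: RunConfig, stage: str):
    """A fresh network-inference callable for the configured method."""
    if config.method == "portia":
        def infer(data: ExpressionDataset):
            est = PortiaGRN(shrinkage_lambda=config.shrinkage_lambda)
            est.fit(data)
            return est.network()
        return infer

    def infer(data: ExpressionDataset):
        est = RegressionGRN(learner=config.method,
                            seed=stage_seed(config.seed, stage, "regression"))
        est.fit(data)
        return est.network()
    return infer


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write artifacts plus a manifest under outdir."""
    from .selection import epr, gate_regression_models  # local: avoids cycle

    out = pio.ensure_dir(config.outdir)
    artifacts: dict = {"config": config}

    truth, raw, reference = _load_inputs(config)
    raw = raw.phase(config.phase)
    pio.write_expression_table(raw, out / "expression_raw.tsv")
    pio.write_sample_sheet(raw.sheet, out / "sample_sheet.tsv")
    pio.write_reference_links(reference, out / "reference_links.tsv")

    imput_cfg = ImputationConfig(
        method=config.imputation, knn_k=config.knn_k,
        minprob_quantile=config.minprob_quantile,
        minprob_sigma_scale=config.minprob_sigma_scale,
    )
    processed = preprocess(
        raw, imput_cfg, seed=stage_seed(config.seed, "impute"),
        max_missing_frac=config.max_missing_frac,
    )
    pio.write_expression_table(processed, out / "expression_processed.tsv")
    artifacts["processed"] = processed

    results = moderated_f_test(processed, df=config.spline_df)
    de_proteins, used_adjusted = select_de_proteins(results, alpha=config.de_alpha)
    if config.max_de_proteins and len(de_proteins) > config.max_de_proteins:
        ranked = sorted(
            (r for r in results if r.protein in set(de_proteins)),
            key=lambda r: r.p_value,
        )
        de_proteins = [r.protein for r in ranked[: config.max_de_proteins]]
    table = de_table(results)
    table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    artifacts["de_table"] = table
    artifacts["de_proteins"] = de_proteins

    de_data = processed.select_proteins(de_proteins)
    networks, r2_tables = {}, {}
    infer = _make_inferrer(config, "infer")
    for cond in CONDITIONS:
        sub = de_data.condition(cond)
        if config.method in ("ridge", "rf"):
            est = RegressionGRN(learner=config.method,
                                seed=stage_seed(config.seed, "infer", cond))
            est.fit(sub)
            net = est.network()
            r2_tables[cond] = est.r2_
        else:
            net = infer(sub)
        net.condition = cond
        networks[cond] = net
        pio.write_network(net, out / f"network_{cond}.tsv")
    artifacts["networks"] = networks

    scorecards = {}
    for cond, net in networks.items():
        scorecards[cond] = epr(
            net, reference, n_random=config.n_random_networks,
            seed=stage_seed(config.seed, "epr", cond),
            model_name=f"{config.model_name}-{cond}",
        )
    r2_pass = gate_regression_models(r2_tables) if r2_tables else None
    artifacts["scorecards"] = scorecards
    artifacts["r2_pass"] = r2_pass
    artifacts["r2_tables"] = r2_tables

    ens_infer = _make_inferrer(config, "ensembles")
    ensembles = build_dual_noise_ensembles(
        {c: de_data.condition(c) for c in CONDITIONS},
        ens_infer, n_reps=config.n_noise_reps,
        seed=stage_seed(config.seed, "noise"),
    )
    pra_results = role_change_test(
        ensembles, networks[CONTROL], networks[TREATMENT],
        alpha=config.de_alpha, keep_frac=config.keep_frac,
    )
    for cond, net in networks.items():
        role_table(network_roles(net, config.keep_frac)).to_csv(
            out / f"roles_{cond}.tsv", sep="\t", index=False
        )
    role_change_table(pra_results).to_csv(out / "role_changes.tsv", sep="\t", index=False)
    artifacts["pra"] = pra_results

    from .robustness import MGN
    prda_records = prda(
        ensembles[MGN], networks[CONTROL], networks[TREATMENT],
        top_frac=config.top_frac,
    )
    divergence_table(prda_records).to_csv(out / "divergence.tsv", sep="\t", index=False)
    hubs = find_hubs(prda_records, min_links=config.min_hub_links)
    report = integrate_targets(pra_results, prda_records, hubs=hubs)
    report.evidence.to_csv(out / "target_evidence.tsv", sep="\t", index=False)
    artifacts["prda"] = prda_records
    artifacts["report"] = report

    manifest = {
        "model_name": config.model_name,
        "parameters": asdict(config),
        "used_adjusted_p": bool(used_adjusted),
        "n_de_proteins": len(de_proteins),
        "r2_gate_pass": r2_pass,
        "normality_p": getattr(infer, "normality_p_", None),
        "scorecards": {
            cond: {"ep": sc.ep, "epr": sc.epr, "percentile_rank": sc.percentile_rank}
            for cond, sc in scorecards.items()
        },
        "hubs": hubs,
        "principal_targets": report.principal_targets,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("simulate", "impute", "epr", "noise")
        },
    }
    with open(out / "targets.yaml", "w") as fh:
        yaml.safe_dump(
            {"principal_targets": report.principal_targets, "hubs": hubs,
             "candidates": report.candidates},
            fh, sort_keys=False,
        )
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    artifacts["manifest"] = manifest
    return artifacts
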