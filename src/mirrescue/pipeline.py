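"""End-to-end orchestration: simulate (or load) -> screen -> DE -> quadrants
-> enrichment -> clustering/PCA -> machine-readable report.

One :class:`PipelineConfig` (constructible from YAML) drives every stage with
a single seed; identical config + seed yields a byte-identical report.  Stage
outputs are written as they are produced, so a failing stage leaves earlier
artifacts on disk and aborts with the failing stage named.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import yaml

from . import cluster as _cluster
from . import diffexpr, io, rescue, screen, targets
from .pca import pca as _pca
from .pca import select_top_loadings
from .containers import ExpressionMatrix, MirnaCountMatrix
from .params import (CONDITIONS, CONTROL, MIR19A, PERTURBED, TREATED,
                     SimulationParams)
from .simulate import simulate_expression, simulate_mirna_counts, simulate_utrs

logger = logging.getLogger(__name__)

REQUIRED_REPORT_SECTIONS = ("mirna_screen", "diffexpr", "rescue", "enrichment",
                            "global_structure")
_RESCUE_FIELDS = ("n_altered", "n_intersect", "fraction_affected",
                  "fraction_inverse", "pearson_r", "pearson_p",
                  "quadrant_counts")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    params: SimulationParams = field(default_factory=SimulationParams)
    mirna_sequence: str = MIR19A
    simulate: bool = True
    input_dir: Optional[str] = None        # read matrices here when simulate=False
    outdir: Optional[str] = None
    condition_names: Tuple[str, str, str] = CONDITIONS
    # thresholds
    mirna_fc_threshold: float = 1.8
    rpm_threshold: float = 200.0
    fc_threshold: float = 1.3
    p_threshold: float = 0.05
    q_threshold: float = 0.05
    loading_quantile: float = 0.10
    de_method: str = "welch"
    # clustering
    n_boot: int = 1000
    scales: Tuple[float, ...] = _cluster.DEFAULT_SCALES
    cluster_metric: str = "correlation"
    cluster_linkage: str = "average"

    def __post_init__(self) -> None:
        if len(set(self.condition_names)) != 3:
            raise ValueError("three condition names must be distinct")
        for name in ("mirna_fc_threshold", "rpm_threshold", "fc_threshold",
                     "p_threshold", "q_threshold", "loading_quantile"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "params" in raw and isinstance(raw["params"], dict):
            raw["params"] = SimulationParams.from_dict(raw["params"])
        if "scales" in raw:
            raw["scales"] = tuple(raw["scales"])
        if "condition_names" in raw:
            raw["condition_names"] = tuple(raw["condition_names"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        return d


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        expr, truth = simulate_expression(config.params)
        counts, _ = simulate_mirna_counts(config.params)
        utrs, truth = simulate_utrs(config.params, config.mirna_sequence)
        return expr, counts, utrs, truth
    if not config.input_dir:
        raise PipelineError(
            "stage 'diffexpr' inputs missing: simulation disabled and no "
            "input_dir with an expression matrix "
            "(expression.tsv/_conditions.tsv/_probe_gene.tsv) was given")
    expr_path = os.path.join(config.input_dir, "expression.tsv")
    if not os.path.exists(expr_path):
        raise PipelineError(
            f"stage 'diffexpr' inputs missing: {expr_path} not found")
    expr = ExpressionMatrix.read(config.input_dir)
    counts_path = os.path.join(config.input_dir, "mirna_counts.tsv")
    counts = MirnaCountMatrix.read(counts_path) \
        if os.path.exists(counts_path) else None
    utr_path = os.path.join(config.input_dir, "utrs.fasta")
    utrs = io.read_fasta(utr_path) if os.path.exists(utr_path) else None
    return expr, counts, utrs, None


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return (and optionally write) the report."""
    outdir = config.outdir
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    expr, counts, utrs, truth = _stage("inputs")(_load_inputs)(config)
    report: dict = {
        "seed": config.params.seed,
        "config": {k: v for k, v in config.to_dict().items()
                   if k not in ("outdir",)},
    }

    # --- small-RNA screen --------------------------------------------------
    if counts is not None:
        screen_res = _stage("mirna_screen")(_run_screen)(config, counts, outdir)
        report["mirna_screen"] = {
            "n_pass": len(screen_res.pass_set()),
            "n_down": len(screen_res.down_set()),
            "n_up": len(screen_res.up_set()),
            "pass": sorted(screen_res.pass_set()),
        }
    else:
        report["mirna_screen"] = {"n_pass": None, "n_down": None,
                                  "n_up": None, "pass": []}

    # --- differential expression -------------------------------------------
    gene_matrix, c1, c2 = _stage("diffexpr")(_run_diffexpr)(config, expr, outdir)
    de1, de2 = c1.de_set(), c2.de_set()
    report["diffexpr"] = {
        "n_genes": int(gene_matrix.shape[0]),
        "n_de_perturbed_vs_control": len(de1),
        "n_de_treated_vs_perturbed": len(de2),
        "method": config.de_method,
    }

    # --- target prediction -------------------------------------------------
    predicted = None
    if utrs is not None:
        predicted = _stage("targets")(targets.predict_targets)(
            config.mirna_sequence, utrs)
        report["targets"] = {
            "n_predicted": len(predicted),
            "n_background": int(gene_matrix.shape[0]),
        }

    # --- rescue quadrants + enrichment -------------------------------------
    quad = _stage("rescue_quadrant")(rescue.build_quadrant_table)(
        c1, c2, de1, de2, target_flags=predicted)
    metrics = _stage("rescue_quadrant")(rescue.rescue_metrics)(quad, len(de1))
    report["rescue"] = {
        "n_altered": metrics.n_altered,
        "n_intersect": metrics.n_intersect,
        "fraction_affected": metrics.fraction_affected,
        "fraction_inverse": metrics.fraction_inverse,
        "quadrant_counts": metrics.quadrant_counts,
        "pearson_r": metrics.pearson_r,
        "pearson_p": metrics.pearson_p,
    }
    if outdir:
        quad.to_csv(os.path.join(outdir, "quadrant_table.tsv"), sep="\t",
                    float_format="%.6g")

    if predicted is not None:
        enr = _stage("enrichment")(targets.quadrant_enrichment)(
            quad, predicted, set(gene_matrix.index))
        report["enrichment"] = {
            q: dataclasses.asdict(res) for q, res in enr.items()}
    else:
        report["enrichment"] = {}

    # --- global structure: clustering with AU support, PCA -----------------
    gs = _stage("global_structure")(_run_global_structure)(
        config, gene_matrix_log2=None, expr=expr, outdir=outdir)
    report["global_structure"] = gs

    # --- truth recovery diagnostics ----------------------------------------
    if truth is not None:
        report["truth_recovery"] = _recovery(truth, report, de1, de2, predicted)

    if outdir:
        write_report(report, os.path.join(outdir, "report.json"))
    return report


def _run_screen(config, counts, outdir):
    rpm = screen.normalize_rpm(counts)
    groups = {
        CONTROL: [s for s in rpm.columns if s.startswith(CONTROL)],
        PERTURBED: [s for s in rpm.columns if s.startswith(PERTURBED)],
    }
    res = screen.screen_mirnas(rpm, groups,
                               fc_threshold=config.mirna_fc_threshold,
                               rpm_threshold=config.rpm_threshold)
    if outdir:
        res.table.rename_axis("mirna").to_csv(
            os.path.join(outdir, "mirna_screen.tsv"), sep="\t",
            float_format="%.4f")
    return res


def _run_diffexpr(config, expr, outdir):
    gene_matrix = diffexpr.summarize_probes(expr)
    ctrl = expr.samples_of(CONTROL)
    pert = expr.samples_of(PERTURBED)
    treat = expr.samples_of(TREATED)
    kwargs = dict(method=config.de_method, fc_threshold=config.fc_threshold,
                  p_threshold=config.p_threshold,
                  q_threshold=config.q_threshold)
    c1 = diffexpr.contrast(gene_matrix, ctrl, pert,
                           label_a=CONTROL, label_b=PERTURBED, **kwargs)
    c2 = diffexpr.contrast(gene_matrix, pert, treat,
                           label_a=PERTURBED, label_b=TREATED, **kwargs)
    if outdir:
        c1.write(os.path.join(outdir, "contrast_perturbed_vs_control.tsv"))
        c2.write(os.path.join(outdir, "contrast_treated_vs_perturbed.tsv"))
    return gene_matrix, c1, c2


def _run_global_structure(config, gene_matrix_log2, expr, outdir):
    log2 = expr.log2()
    tree = _cluster.au_bootstrap(log2, n_boot=config.n_boot,
                                 scales=config.scales,
                                 seed=config.params.seed,
                                 metric=config.cluster_metric,
                                 linkage=config.cluster_linkage)
    pca_res = _pca(log2)
    selection = select_top_loadings(pca_res, component=1,
                                    quantile=config.loading_quantile,
                                    probe_gene=expr.probe_gene)
    cond = expr.conditions
    pc1 = pca_res.scores["PC1"]
    group_means = {c: float(pc1[cond[cond == c].index].mean())
                   for c in config.condition_names}
    if outdir:
        with open(os.path.join(outdir, "dendrogram.nwk"), "w") as fh:
            fh.write(tree.to_newick() + "\n")
        pca_res.scores.rename_axis("sample").to_csv(
            os.path.join(outdir, "pca_scores.tsv"), sep="\t",
            float_format="%.6g")
        pca_res.variance_pct.rename_axis("component").to_csv(
            os.path.join(outdir, "pca_variance.tsv"), sep="\t",
            float_format="%.4f")
        with open(os.path.join(outdir, "selected_probes.txt"), "w") as fh:
            fh.write("\n".join(selection.probes) + "\n")
    return {
        "variance_pct": [float(v) for v in pca_res.variance_pct],
        "pc1_group_mean_scores": group_means,
        "selection": {
            "component": selection.component,
            "quantile": selection.quantile,
            "n_selected": len(selection.probes),
            "weight_fraction": selection.weight_fraction,
            "n_unique_genes": selection.n_unique_genes,
        },
        "clades": [{
            "members": sorted(c.members),
            "height": c.height,
            "au": c.au,
            "bp": c.bp,
        } for c in tree.clades],
    }


def _recovery(truth, report, de1, de2, predicted):
    planted = truth.screen_pass_set()
    found = set(report["mirna_screen"]["pass"])
    strong = {g for g, d in truth.altered.items() if abs(d) >= 1.0}
    out = {
        "screen_exact": bool(planted == found) if found or planted else None,
        "screen_missed": sorted(planted - found),
        "screen_spurious": sorted(found - planted),
        "de1_sensitivity_strong_effects":
            len(strong & de1) / len(strong) if strong else None,
        "rescued_in_intersection":
            len(truth.rescued_genes & de1 & de2) / len(truth.rescued_genes)
            if truth.rescued else None,
    }
    if predicted is not None:
        flagged = {g for g, f in truth.target_flags.items() if f}
        out["target_prediction_exact"] = bool(predicted == flagged)
    return out


def write_report(report: dict, path) -> None:
    """Schema-check and serialize the report (fixed precision, NaN -> null)."""
    missing = [s for s in REQUIRED_REPORT_SECTIONS if s not in report]
    if missing:
        raise ValueError(f"report missing required sections: {missing}")
    for f in _RESCUE_FIELDS:
        if f not in report["rescue"]:
            raise ValueError(f"report rescue section missing field {f!r}")
    io.dump_json(report, path)
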