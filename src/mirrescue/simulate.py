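"""Synthetic cohort generators with fully recorded planted truth.

Three generators share one planted-truth manifest:

* :func:`simulate_expression` -- probe-level microarray-like intensities for
  three conditions (control / perturbed / treated), Gaussian noise on the log2
  scale.
* :func:`simulate_mirna_counts` -- negative-binomial small-RNA counts for
  control vs perturbed libraries, with planted screen hits and decoys that
  each fail exactly one screening filter.
* :func:`simulate_utrs` -- random-composition 3'UTR sequences in which
  target-flagged genes carry one canonical seed-match site at a recorded
  position and non-targets are rejection-sampled to carry none (7mer or
  longer).

Determinism contract: one global seed drives independent per-stage substreams
(truth / probe map / expression noise / count noise / UTRs), so the same seed
yields byte-identical artifacts, and the planted truth is invariant to
noise-level changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MirnaCountMatrix
from .params import (CONDITIONS, CONTROL, PERTURBED, TREATED, SimulationParams,
                     SyntheticTruth)
from .targets import clean_rna, seed_patterns

_STREAM_TRUTH = 0
_STREAM_PROBE_MAP = 1
_STREAM_EXPR_NOISE = 2
_STREAM_COUNT_NOISE = 3
_STREAM_UTR = 4


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed), stream])


@dataclass
class _MirnaPanel:
    """Noise-free design of the small-RNA panel (per-group true rpm)."""

    mirnas: list
    rpm_control: np.ndarray
    rpm_perturbed: np.ndarray


def gene_ids(n: int) -> list:
    return [f"g{i:05d}" for i in range(n)]


def probe_ids(n: int) -> list:
    return [f"p{i:05d}" for i in range(n)]


def plant_truth(params: SimulationParams) -> Tuple[SyntheticTruth, _MirnaPanel]:
    """Draw every planted quantity; pure function of ``params``.

    All structural randomness lives in one substream so that the manifest is
    identical across the three generators and across noise settings.
    """
    rng = _rng(params, _STREAM_TRUTH)
    genes = gene_ids(params.n_genes)

    # --- perturbation effects ---------------------------------------------
    altered_idx = np.sort(rng.choice(params.n_genes, params.n_altered, replace=False))
    signs = rng.choice([-1.0, 1.0], size=params.n_altered)
    lo, hi = params.effect_log2_range
    delta = signs * rng.uniform(lo, hi, size=params.n_altered)

    # --- rescue: exact-count subsets, gain kappa, sign inversion ----------
    n_rescued = int(round(params.rescue_fraction * params.n_altered))
    resc_pos = np.sort(rng.choice(params.n_altered, n_rescued, replace=False))
    g0, g1 = params.rescue_gain_range
    kappa = rng.uniform(g0, g1, size=n_rescued)
    n_inverse = int(round(params.inverse_rate * n_rescued))
    inverse_mask = np.zeros(n_rescued, dtype=bool)
    if n_rescued:
        inverse_mask[rng.choice(n_rescued, n_inverse, replace=False)] = True
    y = kappa * delta[resc_pos]          # concordant remainder: +kappa*delta
    y[inverse_mask] *= -1.0              # inverse-modulated majority

    # --- target flags with planted odds ratio -----------------------------
    base = params.target_base_rate
    odds_enriched = params.target_odds * base / (1.0 - base)
    p_enriched = odds_enriched / (1.0 + odds_enriched)
    p_flag = np.full(params.n_genes, base)
    rescued_idx = altered_idx[resc_pos]
    up_rescued = rescued_idx[delta[resc_pos] > 0]
    p_flag[up_rescued] = p_enriched
    flags = rng.random(params.n_genes) < p_flag

    # --- per-gene baselines (shared by all samples) ------------------------
    baseline = rng.normal(params.baseline_mean, params.baseline_sd, params.n_genes)

    # --- small-RNA panel design -------------------------------------------
    truth = SyntheticTruth(
        seed=params.seed,
        params=params,
        genes=genes,
        altered={genes[i]: float(d) for i, d in zip(altered_idx, delta)},
        rescued={genes[i]: float(v) for i, v in zip(rescued_idx, y)},
        target_flags={g: bool(f) for g, f in zip(genes, flags)},
    )
    panel = _plant_mirna_panel(params, rng, truth)
    truth._baseline = baseline  # stashed for the expression generator
    return truth, panel


def _plant_mirna_panel(params: SimulationParams, rng: np.random.Generator,
                       truth: SyntheticTruth) -> _MirnaPanel:
    n = params.n_mirnas
    mirnas = [f"mir-{i:04d}" for i in range(n)]
    order = rng.permutation(n)
    n_down, n_up = params.n_planted_down, params.n_planted_up
    idx_down = order[:n_down]
    idx_up = order[n_down:n_down + n_up]
    idx_decoy_dim = order[n_down + n_up:n_down + n_up + 2]     # high fold, low rpm
    idx_decoy_flat = order[n_down + n_up + 2:n_down + n_up + 4]  # high rpm, low fold
    idx_null = order[n_down + n_up + 4:]

    rpm_ctrl = np.zeros(n)
    rpm_pert = np.zeros(n)

    f_lo, f_hi = params.planted_fold_range
    folds_down = rng.uniform(f_lo, f_hi, n_down)
    folds_up = rng.uniform(f_lo, f_hi, n_up)
    high_down = rng.uniform(400.0, 4000.0, n_down)
    high_up = rng.uniform(400.0, 4000.0, n_up)
    # down-regulated in the perturbed state: control is the abundant group
    rpm_ctrl[idx_down] = high_down
    rpm_pert[idx_down] = high_down / folds_down
    rpm_ctrl[idx_up] = high_up / folds_up
    rpm_pert[idx_up] = high_up

    # decoys fail exactly one filter each (at the noise-free limit)
    dim_dir = rng.random(2) < 0.5
    for j, i in enumerate(idx_decoy_dim):
        hi_side, lo_side = (rpm_ctrl, rpm_pert) if dim_dir[j] else (rpm_pert, rpm_ctrl)
        hi_side[i] = 50.0
        lo_side[i] = 50.0 / 3.0
    flat_dir = rng.random(2) < 0.5
    for j, i in enumerate(idx_decoy_flat):
        hi_side, lo_side = (rpm_ctrl, rpm_pert) if flat_dir[j] else (rpm_pert, rpm_ctrl)
        hi_side[i] = 1000.0
        lo_side[i] = 1000.0 / 1.4

    base_null = rng.lognormal(mean=np.log(30.0), sigma=2.0, size=idx_null.size)
    # scale the flat background so each library sums to ~1e6 rpm, keeping the
    # planted/decoy abundances on the intended scale
    fixed = 0.5 * (rpm_ctrl.sum() + rpm_pert.sum())
    scale = max(1e6 - fixed, 0.0) / base_null.sum()
    rpm_ctrl[idx_null] = base_null * scale
    rpm_pert[idx_null] = base_null * scale

    truth.planted_mirnas = {
        **{mirnas[i]: ("down", float(f)) for i, f in zip(idx_down, folds_down)},
        **{mirnas[i]: ("up", float(f)) for i, f in zip(idx_up, folds_up)},
    }
    truth.decoy_mirnas = {
        **{mirnas[i]: "fold 3.0 but abundance 50 rpm (< 200)" for i in idx_decoy_dim},
        **{mirnas[i]: "abundance 1000 rpm but fold 1.4 (< 1.8)" for i in idx_decoy_flat},
    }
    return _MirnaPanel(mirnas=mirnas, rpm_control=rpm_ctrl, rpm_perturbed=rpm_pert)


def _sample_names(params: SimulationParams, conditions=CONDITIONS) -> list:
    return [f"{c}_{r + 1}" for c in conditions for r in range(params.n_replicates)]


def simulate_expression(params: SimulationParams
                        ) -> Tuple[ExpressionMatrix, SyntheticTruth]:
    """Linear-scale probe intensities for the three-condition cohort.

    Gene g in sample s has log2 intensity
    ``mu_g + delta_g*[s perturbed or treated] + y_g*[s treated] + eps`` with
    ``eps ~ N(0, noise_sd)`` drawn per probe and sample; probes map onto genes
    surjectively (first ``n_genes`` probes 1:1, the rest uniformly at random).
    """
    truth, _ = plant_truth(params)
    baseline = truth._baseline
    n_g, n_p = params.n_genes, params.n_probes

    rng_map = _rng(params, _STREAM_PROBE_MAP)
    extra = rng_map.integers(0, n_g, size=n_p - n_g)
    probe_to_gene = np.concatenate([np.arange(n_g), extra])

    genes = np.array(truth.genes)
    delta = np.zeros(n_g)
    yvec = np.zeros(n_g)
    alt_idx = np.array([int(g[1:]) for g in truth.altered], dtype=int)
    delta[alt_idx] = np.fromiter(truth.altered.values(), float, len(truth.altered))
    resc_idx = np.array([int(g[1:]) for g in truth.rescued], dtype=int)
    if resc_idx.size:
        yvec[resc_idx] = np.fromiter(truth.rescued.values(), float, len(truth.rescued))

    cond_effect = {
        CONTROL: baseline,
        PERTURBED: baseline + delta,
        TREATED: baseline + delta + yvec,
    }
    samples = _sample_names(params)
    gene_log2 = np.column_stack([cond_effect[s.rsplit("_", 1)[0]] for s in samples])

    rng_noise = _rng(params, _STREAM_EXPR_NOISE)
    noise = rng_noise.normal(0.0, params.noise_sd, size=(n_p, len(samples)))
    log2_vals = gene_log2[probe_to_gene, :] + noise

    values = pd.DataFrame(np.exp2(log2_vals), index=probe_ids(n_p), columns=samples)
    conditions = pd.Series({s: s.rsplit("_", 1)[0] for s in samples}, name="condition")
    probe_gene = pd.Series(genes[probe_to_gene], index=probe_ids(n_p), name="gene")
    matrix = ExpressionMatrix(values=values, conditions=conditions,
                              probe_gene=probe_gene)
    return matrix, truth


def simulate_mirna_counts(params: SimulationParams
                          ) -> Tuple[MirnaCountMatrix, SyntheticTruth]:
    """Negative-binomial small-RNA counts for control vs perturbed libraries.

    Counts have mean ``true_rpm * library_size / 1e6`` and NB dispersion
    ``params.nb_dispersion`` (Poisson at dispersion 0).  Planted miRNAs carry a
    group fold >= 2 at > 200 rpm; two decoy classes fail exactly one filter
    each (fold 3 at 50 rpm; fold 1.4 at 1000 rpm).
    """
    if params.mirna_library_size <= 0:
        raise ValueError("library size must be positive")
    truth, panel = plant_truth(params)
    samples = _sample_names(params, conditions=(CONTROL, PERTURBED))
    lib = float(params.mirna_library_size)
    mu = np.column_stack([
        (panel.rpm_control if s.startswith(CONTROL) else panel.rpm_perturbed)
        * lib / 1e6
        for s in samples
    ])
    rng = _rng(params, _STREAM_COUNT_NOISE)
    if params.nb_dispersion > 0:
        size = 1.0 / params.nb_dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)
    frame = pd.DataFrame(counts.astype(np.int64), index=panel.mirnas, columns=samples)
    return MirnaCountMatrix(counts=frame), truth


def simulate_utrs(params: SimulationParams, mirna_sequence: str,
                  target_flags: Dict[str, bool] | None = None
                  ) -> Tuple[Dict[str, str], SyntheticTruth]:
    """Random-composition 3'UTRs with planted canonical sites for targets.

    Target-flagged genes receive one 8mer or 7mer-m8 site at a recorded
    offset; non-targets are rejection-sampled until they contain neither the
    7mer-m8 nor the 7mer-A1 pattern (hence no 7mer-or-longer match anywhere).
    ``target_flags`` defaults to the manifest's flags for ``params``.
    """
    mirna = clean_rna(mirna_sequence)
    if len(mirna) < 8:
        raise ValueError("miRNA sequence must be at least 8 nt")
    patterns = seed_patterns(mirna)
    truth, _ = plant_truth(params)
    flags = truth.target_flags if target_flags is None else target_flags

    rng = _rng(params, _STREAM_UTR)
    lo, hi = params.utr_length_range
    lengths = rng.integers(lo, hi + 1, size=params.n_genes)

    # AU-rich composition, drawn in one block for speed
    comp = np.array([0.31, 0.19, 0.19, 0.31])  # A C G U
    cum = np.cumsum(comp)
    letters = np.frombuffer(b"ACGU", dtype=np.uint8)
    codes = np.searchsorted(cum, rng.random(int(lengths.sum())))
    big = letters[codes].tobytes().decode("ascii")
    offsets = np.concatenate([[0], np.cumsum(lengths)])

    forbidden = (patterns["7mer-m8"], patterns["7mer-A1"])
    utrs: Dict[str, str] = {}
    truth.planted_sites = {}
    for i, gene in enumerate(truth.genes):
        seq = big[offsets[i]:offsets[i + 1]]
        if flags.get(gene, False):
            site_type = "8mer" if rng.random() < 0.5 else "7mer-m8"
            site = patterns[site_type]
            pos = int(rng.integers(0, len(seq) - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
            truth.planted_sites[gene] = (pos, site_type)
        else:
            while any(p in seq for p in forbidden):
                redraw = np.searchsorted(cum, rng.random(len(seq)))
                seq = letters[redraw].tobytes().decode("ascii")
        utrs[gene] = seq
    return utrs, truth
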