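"""Simulation parameters and the planted-truth manifest.

The synthetic cohort emulates a three-condition rescue experiment: control
embryos, embryos with a transcription-factor knockdown ("perturbed"), and
knockdown embryos co-injected with a miRNA mimic ("treated").  A large set of
genes is altered by the perturbation; a fraction of those is modulated back by
the treatment, almost always with inverted sign.  Everything that is planted
(effects, rescue gains, target flags, miRNA folds) is recorded in a
:class:`SyntheticTruth` manifest so that recovery by the analysis pipeline can
be measured exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

CONTROL = "control"
PERTURBED = "perturbed"
TREATED = "treated"
CONDITIONS = (CONTROL, PERTURBED, TREATED)

#: Mature dre-miR-19a-3p (the mimic used in the rescue); seed = positions 2-8.
MIR19A = "UGUGCAAAUCUAUGCAAAACUGA"


def _check_range(name: str, rng: Tuple[float, float], low=None, high=None) -> None:
    lo, hi = rng
    if not lo <= hi:
        raise ValueError(f"{name} must be ordered (low <= high), got {rng}")
    if low is not None and lo < low:
        raise ValueError(f"{name} must be >= {low}, got {rng}")
    if high is not None and hi > high:
        raise ValueError(f"{name} must be <= {high}, got {rng}")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic cohort generator.

    Defaults mirror the structure of the study being emulated: ~20k probes over
    15k genes, 3 biological replicates per condition, 8000 perturbation-altered
    genes of which 60% are rescued, 98.7% of rescues sign-inverted, and a small
    miRNA panel with 6 down- and 2 up-regulated planted hits.
    """

    seed: int = 0
    # expression cohort
    n_probes: int = 20000
    n_genes: int = 15000
    n_replicates: int = 3
    n_altered: int = 8000
    rescue_fraction: float = 0.60
    inverse_rate: float = 0.987
    effect_log2_range: Tuple[float, float] = (0.5, 2.0)
    rescue_gain_range: Tuple[float, float] = (0.6, 1.0)
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    # miRNA target flags
    target_odds: float = 3.0
    target_base_rate: float = 0.05
    # small-RNA panel
    n_mirnas: int = 300
    n_planted_down: int = 6
    n_planted_up: int = 2
    mirna_library_size: int = 500_000
    nb_dispersion: float = 0.01
    planted_fold_range: Tuple[float, float] = (2.5, 6.0)
    # 3'UTR simulation
    utr_length_range: Tuple[int, int] = (200, 1200)

    def __post_init__(self) -> None:
        if self.n_probes < self.n_genes:
            raise ValueError(
                f"n_probes ({self.n_probes}) must be >= n_genes ({self.n_genes}): "
                "every gene needs at least one probe"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_altered > self.n_genes:
            raise ValueError("n_altered must be <= n_genes")
        for name in ("rescue_fraction", "inverse_rate", "target_base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.target_odds <= 0:
            raise ValueError("target_odds must be positive")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.mirna_library_size <= 0:
            raise ValueError("mirna_library_size must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.n_planted_down + self.n_planted_up + 4 > self.n_mirnas:
            raise ValueError("n_mirnas too small for planted miRNAs plus decoys")
        _check_range("effect_log2_range", self.effect_log2_range, low=0.0)
        _check_range("rescue_gain_range", self.rescue_gain_range, low=0.0, high=1.0)
        if self.rescue_gain_range[0] <= 0:
            raise ValueError("rescue_gain_range must lie in (0, 1]")
        _check_range("utr_length_range", self.utr_length_range, low=20)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        for key in ("effect_log2_range", "rescue_gain_range", "planted_fold_range",
                    "utr_length_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Manifest of every planted effect of one simulated cohort.

    altered        gene id -> signed log2 perturbation effect (delta)
    rescued        gene id -> treatment effect (y); subset of ``altered``
    target_flags   gene id -> planted miRNA-target status
    planted_mirnas miRNA id -> (direction, true group fold >= threshold)
    decoy_mirnas   miRNA id -> short reason why it must fail the screen
    planted_sites  gene id -> (0-based UTR offset, site type); filled by the
                   UTR generator only
    """

    seed: int
    params: SimulationParams
    genes: List[str]
    altered: Dict[str, float]
    rescued: Dict[str, float]
    target_flags: Dict[str, bool]
    planted_mirnas: Dict[str, Tuple[str, float]] = field(default_factory=dict)
    decoy_mirnas: Dict[str, str] = field(default_factory=dict)
    planted_sites: Dict[str, Tuple[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.rescued) <= set(self.altered):
            raise ValueError("rescued genes must be a subset of altered genes")

    @property
    def altered_genes(self) -> set:
        return set(self.altered)

    @property
    def rescued_genes(self) -> set:
        return set(self.rescued)

    def screen_pass_set(self) -> set:
        """miRNAs planted to survive the fold-change/abundance screen."""
        return set(self.planted_mirnas)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params.to_dict(),
            "genes": self.genes,
            "altered": self.altered,
            "rescued": self.rescued,
            "target_flags": self.target_flags,
            "planted_mirnas": {k: list(v) for k, v in self.planted_mirnas.items()},
            "decoy_mirnas": self.decoy_mirnas,
            "planted_sites": {k: list(v) for k, v in self.planted_sites.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            seed=payload["seed"],
            params=SimulationParams.from_dict(payload["params"]),
            genes=payload["genes"],
            altered={k: float(v) for k, v in payload["altered"].items()},
            rescued={k: float(v) for k, v in payload["rescued"].items()},
            target_flags={k: bool(v) for k, v in payload["target_flags"].items()},
            planted_mirnas={k: (v[0], float(v[1]))
                            for k, v in payload["planted_mirnas"].items()},
            decoy_mirnas=payload["decoy_mirnas"],
            planted_sites={k: (int(v[0]), v[1])
                           for k, v in payload["planted_sites"].items()},
        )
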