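"""Canonical seed-match target prediction and hypergeometric set enrichment.

Site vocabulary (all defined by exact Watson-Crick complementarity to the
miRNA seed, scanned on the sense strand of the supplied 3'UTR):

* ``8mer``     reverse complement of miRNA positions 2-8, followed by A
* ``7mer-m8``  reverse complement of miRNA positions 2-8
* ``7mer-A1``  reverse complement of miRNA positions 2-7, followed by A
* ``6mer``     reverse complement of miRNA positions 2-7

At overlapping loci the longest type wins: a shorter site whose interval is
contained in a longer site's interval is not reported.  Coordinates are
0-based half-open.

The enrichment side is an exact hypergeometric tail computed by summation in
log space, applied per fold-change quadrant against a user-supplied
background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def clean_rna(sequence: str) -> str:
    """Uppercase, map T->U, and validate the alphabet."""
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid RNA alphabet characters: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    return clean_rna(sequence).translate(_COMPLEMENT)[::-1]


def seed_patterns(mirna: str) -> Dict[str, str]:
    """Exact site patterns for a mature miRNA (length >= 8)."""
    mirna = clean_rna(mirna)
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt to define seed sites")
    core7 = reverse_complement(mirna[1:8])   # positions 2-8
    core6 = reverse_complement(mirna[1:7])   # positions 2-7
    return {
        "8mer": core7 + "A",
        "7mer-m8": core7,
        "7mer-A1": core6 + "A",
        "6mer": core6,
    }


@dataclass(frozen=True)
class SeedSite:
    transcript: str
    start: int           # 0-based, half-open interval [start, start + length)
    site_type: str

    @property
    def length(self) -> int:
        return {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[self.site_type]

    @property
    def end(self) -> int:
        return self.start + self.length


def seed_sites(mirna: str, utr: str, transcript: str = "") -> List[SeedSite]:
    """All canonical seed sites of ``mirna`` in one UTR, longest type wins.

    Scans every position for the 7-nt seed core (reporting 8mer when followed
    by A) and for the 6-nt core (7mer-A1 when followed by A), then drops any
    shorter site whose interval is contained in a longer one.
    """
    pats = seed_patterns(mirna)
    seq = clean_rna(utr)
    core7, core6 = pats["7mer-m8"], pats["6mer"]

    long_sites: List[SeedSite] = []
    start = seq.find(core7)
    while start != -1:
        if seq[start + 7:start + 8] == "A":
            long_sites.append(SeedSite(transcript, start, "8mer"))
        else:
            long_sites.append(SeedSite(transcript, start, "7mer-m8"))
        start = seq.find(core7, start + 1)

    long_spans = [(s.start, s.end) for s in long_sites]
    short_sites: List[SeedSite] = []
    start = seq.find(core6)
    while start != -1:
        if seq[start + 6:start + 7] == "A":
            cand = SeedSite(transcript, start, "7mer-A1")
        else:
            cand = SeedSite(transcript, start, "6mer")
        if not any(a <= cand.start and cand.end <= b for a, b in long_spans):
            short_sites.append(cand)
        start = seq.find(core6, start + 1)

    return sorted(long_sites + short_sites, key=lambda s: (s.start, -s.length))


@dataclass(frozen=True)
class TargetRule:
    """Stringency rule standing in for a multi-algorithm prediction consensus."""

    site_types: Tuple[str, ...] = ("8mer", "7mer-m8")
    min_sites: int = 1

    def __post_init__(self):
        unknown = set(self.site_types) - set(SITE_TYPES)
        if unknown:
            raise ValueError(f"unknown site types: {sorted(unknown)}")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")


def predict_targets(mirna: str, utrs: Dict[str, str],
                    rule: TargetRule = TargetRule()) -> Set[str]:
    """Transcripts with at least ``rule.min_sites`` sites of the given types."""
    if not utrs:
        raise ValueError("empty UTR set")
    hits: Set[str] = set()
    wanted = set(rule.site_types)
    for tid, seq in utrs.items():
        n = sum(1 for s in seed_sites(mirna, seq, tid) if s.site_type in wanted)
        if n >= rule.min_sites:
            hits.add(tid)
    return hits


def all_seed_sites(mirna: str, utrs: Dict[str, str]) -> List[SeedSite]:
    out: List[SeedSite] = []
    for tid, seq in utrs.items():
        out.extend(seed_sites(mirna, seq, tid))
    return out


def hypergeom_tail(k, K: int, n: int, N: int, tail: str = "over"):
    """Exact hypergeometric tail probability, summed in log space.

    Drawing ``n`` items without replacement from ``N`` of which ``K`` are
    special, with ``k`` special items observed: ``over`` returns P(X >= k),
    ``under`` returns P(X <= k).  ``k`` may be a scalar or an array (one tail
    value per entry); the summation runs over the whole support once, with
    tails accumulated by log-space addition.
    """
    K, n, N = int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if tail not in ("over", "under"):
        raise ValueError("tail must be 'over' or 'under'")
    k_lo, k_hi = max(0, n + K - N), min(K, n)
    karr = np.atleast_1d(np.asarray(k, dtype=int))
    if np.any((karr < k_lo) | (karr > k_hi)):
        raise ValueError(f"k={k} outside support [{k_lo}, {k_hi}]")

    support = np.arange(k_lo, k_hi + 1)
    log_terms = (_log_comb(K, support) + _log_comb(N - K, n - support)
                 - _log_comb(N, n))
    if tail == "over":  # suffix sums: P(X >= k)
        acc = np.logaddexp.accumulate(log_terms[::-1])[::-1]
    else:               # prefix sums: P(X <= k)
        acc = np.logaddexp.accumulate(log_terms)
    out = np.minimum(np.exp(acc[karr - k_lo]), 1.0)
    return float(out[0]) if np.isscalar(k) or np.ndim(k) == 0 else out


def _log_comb(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


@dataclass(frozen=True)
class EnrichmentResult:
    quadrant: str
    N: int      # background size
    K: int      # targets in background
    n: int      # quadrant size
    k: int      # targets in quadrant
    p_over: float
    p_under: float


def quadrant_enrichment(table, targets: Iterable[str], background: Iterable[str]
                        ) -> Dict[str, EnrichmentResult]:
    """Two-tailed hypergeometric target enrichment per fold-change quadrant.

    ``table`` is a quadrant table (index = gene, column ``quadrant``); the
    background is typically every gene measured on the array.  Target ids
    absent from the background are dropped with a logged warning.
    """
    background = set(background)
    targets = set(targets)
    dropped = targets - background
    if dropped:
        warnings.warn(f"{len(dropped)} target ids absent from background; dropped",
                      stacklevel=2)
        logger.warning("dropped %d target ids absent from background", len(dropped))
        targets &= background
    missing = set(table.index) - background
    if missing:
        raise ValueError(f"{len(missing)} quadrant genes missing from background")

    N, K = len(background), len(targets)
    out: Dict[str, EnrichmentResult] = {}
    for quadrant in ("QI", "QII", "QIII", "QIV"):
        members = set(table.index[table["quadrant"] == quadrant])
        n, k = len(members), len(members & targets)
        out[quadrant] = EnrichmentResult(
            quadrant=quadrant, N=N, K=K, n=n, k=k,
            p_over=hypergeom_tail(k, K, n, N, "over"),
            p_under=hypergeom_tail(k, K, n, N, "under"),
        )
    return out
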