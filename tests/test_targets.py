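"""Seed-site scanning, target rules, and exact hypergeometric tails."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirrescue import (MIR19A, TargetRule, hypergeom_tail, predict_targets,
                       quadrant_enrichment, seed_sites)
from mirrescue.rescue import quadrant_of
from mirrescue.targets import reverse_complement, seed_patterns


def brute_force_sites(mirna, utr):
    """Independent oracle: check every position by explicit slicing."""
    core7 = reverse_complement(mirna[1:8])
    core6 = reverse_complement(mirna[1:7])
    sites = []
    spans = []
    for i in range(len(utr) - 6):
        if utr[i:i + 7] == core7:
            if i + 7 < len(utr) and utr[i + 7] == "A":
                sites.append((i, "8mer"))
                spans.append((i, i + 8))
            else:
                sites.append((i, "7mer-m8"))
                spans.append((i, i + 7))
    for j in range(len(utr) - 5):
        if utr[j:j + 6] == core6:
            if j + 6 < len(utr) and utr[j + 6] == "A":
                cand = (j, "7mer-A1", j + 7)
            else:
                cand = (j, "6mer", j + 6)
            if not any(a <= cand[0] and cand[2] <= b for a, b in spans):
                sites.append((cand[0], cand[1]))
    return sorted(sites)


class TestSeedSites:
    def test_mir19a_8mer_at_recorded_offset(self):
        # seed (positions 2-8) GUGCAAA -> site core UUUGCAC, 8mer = +A
        utr = "CCGCGCGG" + "UUUGCACA" + "GGCGC"
        sites = seed_sites(MIR19A, utr)
        assert [(s.start, s.site_type) for s in sites] == [(8, "8mer")]
        assert sites[0].end == 16

    def test_absence_case(self):
        assert seed_sites(MIR19A, "CCCCGGGGCCCCGGGG") == []

    def test_minimal_7mer_m8(self):
        core = seed_patterns(MIR19A)["7mer-m8"]
        sites = seed_sites(MIR19A, core)
        assert [(s.start, s.site_type) for s in sites] == [(0, "7mer-m8")]

    def test_seven_a1_and_6mer_not_subsumed_by_distant_long_site(self):
        pats = seed_patterns(MIR19A)
        utr = pats["7mer-A1"] + "GG" + pats["6mer"] + "GG" + pats["7mer-m8"]
        found = {(s.start, s.site_type) for s in seed_sites(MIR19A, utr)}
        assert found == {(0, "7mer-A1"), (9, "6mer"), (17, "7mer-m8")}

    def test_dna_alphabet_accepted(self):
        utr_dna = "TTTGCACA"
        sites = seed_sites(MIR19A, utr_dna)
        assert sites[0].site_type == "8mer"

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            seed_sites(MIR19A, "ACGUN")
        with pytest.raises(ValueError):
            seed_sites("ACGU", "ACGUACGU")  # miRNA too short

    def test_matches_brute_force_scan_on_random_utrs(self):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGU"))
        for trial in range(300):
            mirna = "".join(rng.choice(bases, size=22))
            # seed-enriched alphabet so matches actually occur
            utr = "".join(rng.choice(bases, size=rng.integers(30, 120)))
            if trial % 3 == 0:
                pats = seed_patterns(mirna)
                pos = rng.integers(0, max(1, len(utr) - 8))
                utr = utr[:pos] + pats[rng.choice(list(pats))] + utr[pos + 8:]
            got = sorted((s.start, s.site_type)
                         for s in seed_sites(mirna, utr))
            assert got == brute_force_sites(mirna, utr)


class TestPredictTargets:
    def test_default_rule(self):
        pats = seed_patterns(MIR19A)
        utrs = {
            "t8": "GG" + pats["8mer"] + "CC",
            "t6": "GG" + pats["6mer"] + "CC",
            "none": "GCGCGCGGCC",
        }
        assert predict_targets(MIR19A, utrs) == {"t8"}

    def test_min_sites_rule(self):
        pats = seed_patterns(MIR19A)
        utrs = {"one": "GG" + pats["8mer"] + "CC"}
        assert predict_targets(MIR19A, utrs,
                               TargetRule(min_sites=2)) == set()

    def test_empty_utr_set_rejected(self):
        with pytest.raises(ValueError):
            predict_targets(MIR19A, {})


class TestHypergeomTail:
    def test_enumerated_example(self):
        assert hypergeom_tail(4, 4, 5, 10, "over") == pytest.approx(6 / 252)

    def test_boundaries(self):
        assert hypergeom_tail(0, 0, 5, 10, "under") == pytest.approx(1.0)
        assert hypergeom_tail(0, 3, 5, 10, "over") == pytest.approx(1.0)

    def test_matches_scipy_on_random_parameters(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            N = int(rng.integers(2, 500))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(K, n) + 1))
            dist = stats.hypergeom(N, K, n)
            assert hypergeom_tail(k, K, n, N, "over") \
                == pytest.approx(dist.sf(k - 1), rel=1e-10, abs=1e-300)
            assert hypergeom_tail(k, K, n, N, "under") \
                == pytest.approx(dist.cdf(k), rel=1e-10, abs=1e-300)

    def test_rejects_inconsistent_counts(self):
        with pytest.raises(ValueError):
            hypergeom_tail(1, 11, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_tail(6, 6, 5, 10)  # k > min(K, n)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 2, 3, 10, tail="sideways")


def _quadrant_frame(assignments):
    return pd.DataFrame({"quadrant": pd.Series(assignments)})


class TestQuadrantEnrichment:
    def test_matches_direct_tail_computation(self):
        background = {f"g{i}" for i in range(100)}
        targets = {f"g{i}" for i in range(10)}
        # QII of 20 genes containing 8 targets
        quad = _quadrant_frame({f"g{i}": "QII" for i in list(range(8)) +
                                list(range(30, 42))})
        res = quadrant_enrichment(quad, targets, background)
        assert res["QII"].p_over == pytest.approx(
            hypergeom_tail(8, 10, 20, 100, "over"))
        assert res["QII"].k == 8 and res["QII"].n == 20

    def test_empty_quadrant_is_vacuous(self):
        res = quadrant_enrichment(
            _quadrant_frame({"g0": "QII"}), {"g0"}, {"g0", "g1"})
        assert res["QIII"].p_over == 1.0
        assert res["QIII"].p_under == 1.0

    def test_targets_equal_background_degenerate(self):
        background = {f"g{i}" for i in range(10)}
        quad = _quadrant_frame({f"g{i}": quadrant_of((-1) ** i, (-1) ** (i // 2))
                                for i in range(10)})
        res = quadrant_enrichment(quad, background, background)
        for r in res.values():
            assert r.k == r.n
            assert r.p_over == pytest.approx(1.0)

    def test_foreign_targets_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="absent from background"):
            res = quadrant_enrichment(_quadrant_frame({"g0": "QI"}),
                                      {"g0", "alien"}, {"g0", "g1"})
        assert res["QI"].K == 1

    def test_quadrant_gene_outside_background_raises(self):
        with pytest.raises(ValueError, match="missing from background"):
            quadrant_enrichment(_quadrant_frame({"gX": "QI"}), set(), {"g0"})

    def test_tails_share_point_mass(self):
        res = quadrant_enrichment(
            _quadrant_frame({f"g{i}": "QIV" for i in range(5)}),
            {f"g{i}" for i in range(3)}, {f"g{i}" for i in range(20)})
        r = res["QIV"]
        assert r.p_over + r.p_under >= 1.0
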