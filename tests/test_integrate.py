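"""Interval extension, feature overlap, enrichment and gene-set comparison
against brute-force and combinatorial oracles."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from slopescan import (
    GeneAnnotation,
    extend_intervals,
    features_in,
    find_peaks,
    hypergeom_enrichment,
    set_overlaps,
    term_enrichment,
)
from slopescan.synthdata import random_genes, split_rng

from conftest import toy_variant_table


def _slopes(rows):
    return pd.DataFrame(rows, columns=["trait", "chrom", "start", "end"])


class TestExtendIntervals:
    def test_clipping_to_chromosome(self):
        s = _slopes([("T", "chr1", 5000, 8000)])
        iv = extend_intervals(s, {"chr1": 12_000}, pad=10_000)
        assert iv.iloc[0]["start"] == 1 and iv.iloc[0]["end"] == 12_000

    def test_merging_overlapping_padded_intervals(self):
        s = _slopes([("T", "chr1", 100_000, 110_000), ("T", "chr1", 115_000, 120_000)])
        iv = extend_intervals(s, {"chr1": 1_000_000}, pad=10_000)
        assert len(iv) == 1
        assert (iv.iloc[0]["start"], iv.iloc[0]["end"]) == (90_000, 130_000)

    def test_zero_pad_identity(self):
        s = _slopes([("T", "chr1", 5000, 8000)])
        iv = extend_intervals(s, {"chr1": 100_000}, pad=0)
        assert (iv.iloc[0]["start"], iv.iloc[0]["end"]) == (5000, 8000)

    def test_traits_not_merged_together(self):
        s = _slopes([("A", "chr1", 100_000, 110_000), ("B", "chr1", 105_000, 120_000)])
        iv = extend_intervals(s, {"chr1": 1_000_000}, pad=1000)
        assert len(iv) == 2


class TestFeaturesIn:
    def test_partial_overlap_counts(self):
        genes = GeneAnnotation(pd.DataFrame(
            [{"gene_id": "g1", "chrom": "chr1", "start": 200, "end": 300,
              "strand": "+"}]))
        iv = pd.DataFrame([{"trait": "T", "chrom": "chr1", "start": 250,
                            "end": 400, "pad": 0}])
        assign, counts = features_in(iv, genes)
        assert assign["feature"].tolist() == ["g1"]
        assert counts["T"] == 1

    def test_snp_on_boundary_included(self):
        vt = toy_variant_table([400])
        iv = pd.DataFrame([{"trait": "T", "chrom": "chr1", "start": 250,
                            "end": 400, "pad": 0}])
        assign, counts = features_in(iv, vt)
        assert len(assign) == 1

    def test_matches_brute_force_oracle(self):
        genes = random_genes({"chr1": 100_000, "chr2": 50_000}, 10, seed=1)
        rng = split_rng(2, "ivs")
        rows = []
        for i in range(3):
            chrom = "chr1" if i < 2 else "chr2"
            a = int(rng.integers(1, 80_000))
            rows.append({"trait": "T", "chrom": chrom, "start": a,
                         "end": a + int(rng.integers(1000, 20_000)), "pad": 0})
        iv = pd.DataFrame(rows)
        assign, counts = features_in(iv, genes)
        got = set(zip(assign["interval"], assign["feature"]))
        expected = set()
        for i, r in iv.iterrows():
            for _, g in genes.table.iterrows():
                if (g["chrom"] == r["chrom"] and g["start"] <= r["end"]
                        and g["end"] >= r["start"]):
                    expected.add((i, g["gene_id"]))
        assert got == expected


class TestHypergeom:
    def test_exact_combinatorial_value(self):
        universe = set(range(10))
        top = set(range(5))
        inside = set(range(6, 10)) | {0, 1, 2, 3} - set(range(6, 10))
        inside = {0, 1, 2, 3}
        res = hypergeom_enrichment(universe, top, inside)
        expected = Fraction(comb(5, 4) * comb(5, 0), comb(10, 4))
        assert res.p == pytest.approx(float(expected), abs=1e-9)
        assert res.k == 4

    def test_null_centered_overlap_not_significant(self):
        universe = set(range(1000))
        top = set(range(100))
        inside = set(range(50, 550))  # overlap k = 50 = K·n/N exactly
        res = hypergeom_enrichment(universe, top, inside)
        assert 0.4 < res.p <= 1.0

    def test_zero_overlap_gives_p_one(self):
        res = hypergeom_enrichment(set(range(20)), set(range(5)),
                                   set(range(10, 14)))
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(set(), set(), set())

    def test_log_gamma_vs_rational_oracle(self):
        """scipy's tail sum matches exact rational arithmetic to 1e-12."""
        rng = split_rng(3, "hyp")
        for _ in range(20):
            N = int(rng.integers(10, 60))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = set(range(N))
            top = set(rng.choice(N, K, replace=False).tolist())
            inside = set(rng.choice(N, n, replace=False).tolist())
            res = hypergeom_enrichment(universe, top, inside)
            exact = sum(
                Fraction(comb(K, j) * comb(N - K, res.n - j), comb(N, res.n))
                for j in range(res.k, min(K, res.n) + 1)
            )
            assert res.p == pytest.approx(float(exact), rel=1e-12, abs=1e-12)


class TestFindPeaks:
    def _scan(self, positions, scores, chrom="chr1"):
        return pd.DataFrame({"chrom": chrom, "pos": positions, "score": scores})

    def test_single_snp_is_peak(self):
        peaks = find_peaks(self._scan([5000], [1.0]), "score", pct=1.0)
        assert len(peaks) == 1

    def test_windowed_maximum_by_hand(self):
        peaks = find_peaks(self._scan([1000, 5000, 9000], [1, 3, 2]), "score",
                           half_width=10_000, pct=1.0)
        assert peaks["pos"].tolist() == [5000]

    def test_leftmost_tie_wins(self):
        peaks = find_peaks(self._scan([1000, 5000], [2.0, 2.0]), "score",
                           half_width=10_000, pct=1.0)
        assert peaks["pos"].tolist() == [1000]

    def test_top_percentile_retention(self):
        rng = split_rng(4, "peaks")
        pos = np.sort(rng.choice(10_000_000, 2000, replace=False))
        sc = rng.standard_normal(2000)
        peaks_all = find_peaks(self._scan(pos, sc), "score", pct=1.0)
        peaks_top = find_peaks(self._scan(pos, sc), "score", pct=0.001)
        assert len(peaks_top) <= len(peaks_all)
        # retained peaks sit in the global top 0.1 percentile
        from slopescan import top_percentile

        flags, cut = top_percentile(sc, 0.001)
        assert (peaks_top["score"] >= cut).all()


class TestSetOverlaps:
    def test_disjoint_sets(self):
        out = set_overlaps({"a": {1, 2}, "b": {3, 4}})
        pair = out[out["labels"].apply(len) == 2]
        assert (pair["size"] == 0).all()

    def test_simple_intersection(self):
        out = set_overlaps({"x": {"a", "b", "c"}, "y": {"b", "c", "d"}})
        row = out[out["labels"] == ("x", "y")].iloc[0]
        assert row["size"] == 2 and row["members"] == ["b", "c"]

    def test_four_sets_match_power_set_oracle(self):
        rng = split_rng(5, "sets")
        sets = {lab: set(rng.choice(30, rng.integers(5, 15), replace=False).tolist())
                for lab in "abcd"}
        out = set_overlaps(sets).set_index("labels")
        combos = [c for r in range(2, 5) for c in combinations("abcd", r)]
        assert len(combos) == 11
        for combo in combos:
            expected = set.intersection(*(sets[l] for l in combo))
            assert out.loc[[combo]]["size"].iloc[0] == len(expected)


class TestTermEnrichment:
    def test_minimum_two_candidate_genes(self):
        universe = {f"g{i}" for i in range(50)}
        cands = {"g0", "g1", "g2"}
        tmap = {"g0": ["T1"], "g5": ["T1"], "g1": ["T2"], "g2": ["T2"]}
        out = term_enrichment(cands, universe, tmap)
        assert "T1" not in set(out["term"])  # only one candidate gene
        assert "T2" in set(out["term"])

    def test_hypergeometric_tail_value(self):
        universe = {f"g{i}" for i in range(100)}
        cands = {f"g{i}" for i in range(10)}
        # term covers 5 universe genes, 3 of them candidates
        tmap = {f"g{i}": ["T"] for i in [0, 1, 2, 50, 51]}
        out = term_enrichment(cands, universe, tmap).set_index("term")
        from scipy import stats

        expected = stats.hypergeom.sf(2, 100, 5, 10)
        assert out.loc["T", "p"] == pytest.approx(expected, rel=1e-9)

    def test_ubiquitous_term_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        cands = {f"g{i}" for i in range(5)}
        tmap = {g: ["ALL"] for g in universe}
        out = term_enrichment(cands, universe, tmap).set_index("term")
        assert out.loc["ALL", "p"] == pytest.approx(1.0)

    def test_empty_candidates(self):
        out = term_enrichment(set(), {"g1"}, {"g1": ["T"]})
        assert out.empty
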