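"""Cross-referencing slopes, genes and selection scans.

Significant-slope intervals are padded by the LD-decay scale (±10 kbp by
default) and intersected with gene annotations and scan outliers; overlap
excess is tested with exact hypergeometric upper tails, and candidate gene
sets are compared and tested for term enrichment (one-sided Fisher with BH
correction, minimum two candidate genes per term).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneAnnotation, VariantTable

__all__ = [
    "EnrichmentResult",
    "extend_intervals",
    "features_in",
    "hypergeom_enrichment",
    "find_peaks",
    "set_overlaps",
    "term_enrichment",
]


def extend_intervals(
    slopes: pd.DataFrame,
    chrom_lengths: dict,
    pad: int = 10_000,
) -> pd.DataFrame:
    """Pad slope intervals by ±``pad`` bp, clip to the chromosome, and merge
    overlapping intervals of the same trait.

    Returns a table (trait, chrom, start, end, pad) of closed 1-based
    intervals.
    """
    rows = []
    for (trait, chrom), grp in slopes.groupby(["trait", "chrom"], sort=False):
        if chrom not in chrom_lengths:
            raise KeyError(f"unknown chromosome length for {chrom}")
        L = chrom_lengths[chrom]
        ivs = sorted(
            (max(1, int(s) - pad), min(L, int(e) + pad))
            for s, e in zip(grp["start"], grp["end"])
        )
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            rows.append({"trait": trait, "chrom": chrom, "start": s, "end": e, "pad": pad})
    return pd.DataFrame(rows, columns=["trait", "chrom", "start", "end", "pad"])


def features_in(intervals: pd.DataFrame, features) -> tuple[pd.DataFrame, dict]:
    """Features whose span intersects each closed interval.

    ``features`` is a :class:`GeneAnnotation` (genes, partial overlap
    counts) or a :class:`VariantTable` (SNPs as points; boundary positions
    included). Returns ``(assignments, per-trait unique counts)``; counts
    deduplicate features shared between intervals of the same trait.
    """
    if isinstance(features, GeneAnnotation):
        fid = features.table["gene_id"].to_numpy()
        fchrom = features.table["chrom"].to_numpy()
        fstart = features.table["start"].to_numpy()
        fend = features.table["end"].to_numpy()
    elif isinstance(features, VariantTable):
        fid = features.vid
        fchrom = features.chrom
        fstart = features.pos
        fend = features.pos
    else:
        raise TypeError("features must be GeneAnnotation or VariantTable")

    rows = []
    for i, iv in intervals.iterrows():
        m = (fchrom == iv["chrom"]) & (fstart <= iv["end"]) & (fend >= iv["start"])
        for f in fid[np.asarray(m)]:
            rows.append({"interval": i, "trait": iv["trait"], "chrom": iv["chrom"],
                         "start": iv["start"], "end": iv["end"], "feature": f})
    assign = pd.DataFrame(
        rows, columns=["interval", "trait", "chrom", "start", "end", "feature"]
    )
    counts = (
        assign.groupby("trait")["feature"].nunique().to_dict() if len(assign) else {}
    )
    for t in intervals["trait"].unique():
        counts.setdefault(t, 0)
    return assign, counts


@dataclass
class EnrichmentResult:
    trait: str
    source: str
    N: int  # universe size
    K: int  # top-percentile count
    n: int  # in-slope count
    k: int  # overlap
    p: float  # hypergeometric upper tail P(X >= k)


def hypergeom_enrichment(
    universe: set, top: set, inside: set, trait: str = "", source: str = ""
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric test of overlap between the
    top-percentile set and the in-interval set within a common universe."""
    if not universe:
        raise ValueError("empty universe")
    if not top <= universe or not inside <= universe:
        raise ValueError("top and inside sets must be subsets of the universe")
    N, K, n = len(universe), len(top), len(inside)
    k = len(top & inside)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(trait, source, N, K, n, k, min(p, 1.0))


def find_peaks(
    scan: pd.DataFrame,
    score_col: str,
    half_width: int = 10_000,
    pct: float = 0.001,
) -> pd.DataFrame:
    """Local maxima of a selection scan in centered windows of 2·half_width+1 bp.

    A SNP is a peak iff no SNP within ±``half_width`` bp has a strictly
    higher score (equal scores: leftmost wins). Only peaks whose score lies
    in the global top ``pct`` quantile of the statistic are retained.
    """
    from .popgen import top_percentile

    scan = scan.dropna(subset=[score_col])
    flags, cut = top_percentile(scan[score_col].to_numpy(), pct)
    rows = []
    for c in scan["chrom"].unique():
        sub = scan[scan["chrom"] == c].sort_values("pos").reset_index(drop=True)
        pos = sub["pos"].to_numpy()
        sc = sub[score_col].to_numpy()
        for i in range(len(sub)):
            lo = np.searchsorted(pos, pos[i] - half_width, side="left")
            hi = np.searchsorted(pos, pos[i] + half_width, side="right")
            window = slice(lo, hi)
            higher = sc[window] > sc[i]
            tie_left = (sc[window] == sc[i]) & (pos[window] < pos[i])
            if not higher.any() and not tie_left.any():
                rows.append({"chrom": c, "pos": int(pos[i]), "score": float(sc[i]),
                             "half_width": half_width})
    peaks = pd.DataFrame(rows, columns=["chrom", "pos", "score", "half_width"])
    if peaks.empty or not np.isfinite(cut):
        return peaks
    return peaks[peaks["score"] >= cut].reset_index(drop=True)


def set_overlaps(sets: dict) -> pd.DataFrame:
    """Intersection cardinalities and members for every label combination
    of size ≥ 2 (plus singleton sizes)."""
    labels = list(sets)
    rows = []
    for lab in labels:
        rows.append({"labels": (lab,), "size": len(sets[lab]),
                     "members": sorted(sets[lab])})
    for r in range(2, len(labels) + 1):
        for combo in combinations(labels, r):
            inter = set.intersection(*(set(sets[l]) for l in combo))
            rows.append({"labels": combo, "size": len(inter), "members": sorted(inter)})
    return pd.DataFrame(rows, columns=["labels", "size", "members"])


def term_enrichment(
    candidates: set,
    universe: set,
    term_map: dict,
    alpha: float = 0.05,
    min_genes: int = 2,
) -> pd.DataFrame:
    """Per-term one-sided Fisher exact tests with BH correction.

    Terms with fewer than ``min_genes`` candidate genes are not tested;
    genes absent from ``term_map`` still count in the background. A term is
    flagged enriched iff its BH-adjusted p-value is below ``alpha``.
    """
    from statsmodels.stats.multitest import multipletests

    if not candidates:
        return pd.DataFrame(
            columns=["term", "n_cand", "n_univ", "odds", "p", "p_adj", "enriched"]
        )
    if not candidates <= universe:
        raise ValueError("candidates must be a subset of the universe")
    term_genes: dict = {}
    for gene, terms in term_map.items():
        if gene in universe:
            for t in terms:
                term_genes.setdefault(t, set()).add(gene)
    N, n = len(universe), len(candidates)
    rows = []
    for term, genes in sorted(term_genes.items()):
        k = len(genes & candidates)
        if k < min_genes:
            continue
        K = len(genes)
        table = [[k, n - k], [K - k, N - K - n + k]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"term": term, "n_cand": k, "n_univ": K, "odds": odds, "p": p})
    out = pd.DataFrame(rows, columns=["term", "n_cand", "n_univ", "odds", "p"])
    if len(out):
        rej, p_adj, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
        out["p_adj"] = p_adj
        out["enriched"] = p_adj < alpha
    else:
        out["p_adj"] = []
        out["enriched"] = []
    return out
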