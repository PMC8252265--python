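"""LD decay and haplotype-based selection statistics (EHH, iHS, H12).

LD decay follows the classic drift expectation for E[r²] as a function of
C = ρ·d (population recombination between two sites d bp apart), fitted by
nonlinear least squares to pairwise r² within physical windows; its
characteristic scale motivates the ±10 kbp candidate-gene padding.

iHS compares the integrated extended-haplotype-homozygosity (EHH) decay
around the ancestral versus the derived allele of each core SNP, on the
genetic-distance scale; long unbroken haplotypes around a recently selected
allele make the ratio extreme. H12 is the window haplotype homozygosity
with the two most common haplotypes pooled, which keeps power when a sweep
rises from standing variation spread over several backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import GeneticMap, GenotypeMatrix, HaplotypeSet, VariantTable
from .synthdata import split_rng

__all__ = [
    "LdDecayFit",
    "hill_weir_expectation",
    "ld_decay",
    "genetic_positions",
    "ehh_profile",
    "ihs_scan",
    "h12_scan",
    "top_percentile",
]


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def hill_weir_expectation(C: np.ndarray, n: int) -> np.ndarray:
    """Drift expectation of r² at population recombination parameter C.

    E[r²] = (10+C)/((2+C)(11+C)) · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]
    with the n-dependent bracket accounting for sample-size inflation; at
    C = 0 and n → ∞ this is 10/22.
    """
    C = np.asarray(C, dtype=float)
    base = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C * C)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    return base * corr


@dataclass
class LdDecayFit:
    rho_per_bp: float
    n: int
    r2_at_zero: float
    half_decay_bp: float
    n_pairs: int
    binned: pd.DataFrame  # distance-bin midpoints and mean r²

    def predict(self, d_bp: np.ndarray) -> np.ndarray:
        return hill_weir_expectation(self.rho_per_bp * np.asarray(d_bp, float), self.n)


def _pairwise_r2(dos: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-imputed)."""
    X = dos.copy()
    mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = mean[nan_c]
    sd = X.std(axis=0)
    ok = sd > 0
    R = np.full((X.shape[1], X.shape[1]), np.nan)
    if ok.sum() >= 2:
        Rok = np.corrcoef(X[:, ok], rowvar=False)
        R[np.ix_(ok, ok)] = Rok**2
    return R


def ld_decay(
    gm: GenotypeMatrix,
    vt: VariantTable,
    thin_to: int = 100_000,
    window_bp: int = 50_000,
    seed: int = 0,
    n_bins: int = 50,
) -> LdDecayFit:
    """Fit the decay of pairwise r² with physical distance.

    Markers are randomly thinned to at most ``thin_to``; r² is computed
    between all pairs within non-overlapping ``window_bp`` windows and the
    drift expectation is fitted over ρ by nonlinear least squares on the
    pooled pairs. Also reports the distance at which the fitted curve drops
    to half its d → 0 value.
    """
    n = gm.n_samples
    idx = np.arange(vt.n_variants)
    if vt.n_variants > thin_to:
        rng = split_rng(seed, "ld_thin")
        idx = np.sort(rng.choice(vt.n_variants, size=thin_to, replace=False))
    dists, r2s = [], []
    for c in vt.chromosomes():
        sel = idx[np.asarray(vt.chrom[idx] == c)]
        pos = vt.pos[sel]
        for w in np.unique(pos // window_bp):
            inwin = sel[(pos // window_bp) == w]
            if len(inwin) < 2:
                continue
            R = _pairwise_r2(gm.dosages[:, inwin])
            pw = vt.pos[inwin]
            iu, ju = np.triu_indices(len(inwin), k=1)
            r2 = R[iu, ju]
            ok = np.isfinite(r2)
            dists.append(np.abs(pw[ju] - pw[iu])[ok])
            r2s.append(r2[ok])
    if not dists:
        raise ValueError("no marker pairs available for LD decay")
    d = np.concatenate(dists).astype(float)
    r2 = np.concatenate(r2s)

    try:
        popt, _ = optimize.curve_fit(
            lambda dd, rho: hill_weir_expectation(rho * dd, n),
            d, r2, p0=[1e-3], bounds=(0.0, np.inf), maxfev=10_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"LD decay fit did not converge: {exc}") from exc
    rho = float(popt[0])

    r2_zero = float(hill_weir_expectation(np.array(0.0), n))
    half = r2_zero / 2.0
    asymptote = 1.0 / n
    if half <= asymptote or rho == 0:
        half_bp = np.inf
    else:
        f = lambda x: float(hill_weir_expectation(rho * x, n) - half)
        hi = 1.0
        while f(hi) > 0 and hi < 1e12:
            hi *= 10
        half_bp = np.inf if f(hi) > 0 else float(optimize.brentq(f, 1e-9, hi))

    edges = np.linspace(0, d.max() + 1, n_bins + 1)
    which = np.digitize(d, edges) - 1
    binned = pd.DataFrame(
        {
            "dist_bp": [(edges[i] + edges[i + 1]) / 2 for i in range(n_bins)],
            "mean_r2": [r2[which == i].mean() if (which == i).any() else np.nan
                        for i in range(n_bins)],
            "n_pairs": [(which == i).sum() for i in range(n_bins)],
        }
    )
    return LdDecayFit(rho, n, r2_zero, half_bp, len(d), binned)


def genetic_positions(vt: VariantTable, gmap: GeneticMap) -> np.ndarray:
    """Genetic coordinates (cM) of every variant by map interpolation.

    Anchored intervals whose local rate is missing contribute zero genetic
    distance, so consecutive SNPs inside them share a cM coordinate; beyond
    the outermost anchors the map extends flat.
    """
    out = np.empty(vt.n_variants, dtype=float)
    for c in vt.chromosomes():
        m = vt.chrom_mask(c)
        out[m] = gmap.interpolate(c, vt.pos[m])
    return out


# ---------------------------------------------------------------------------
# EHH / iHS
# ---------------------------------------------------------------------------

def _ehh_walk(H: np.ndarray, carriers: np.ndarray, core: int, step: int, cutoff: float):
    """EHH values walking outward from ``core`` in direction ``step`` (±1).

    Yields (marker index, EHH) pairs starting with the first marker away
    from the core; stops after EHH first drops below ``cutoff`` (that
    marker is included) or at the chromosome edge. Returns the pairs and
    whether the walk was truncated by the edge while still above cutoff.
    """
    n = len(carriers)
    denom = comb(n, 2)
    labels = np.zeros(n, dtype=np.int64)
    j = core + step
    out = []
    S = H.shape[1]
    while 0 <= j < S:
        # refine the partition by this column; np.unique relabels compactly
        key = labels * 2 + H[carriers, j]
        _, labels = np.unique(key, return_inverse=True)
        counts = np.bincount(labels)
        ehh = sum(comb(int(c), 2) for c in counts) / denom
        out.append((j, ehh))
        if ehh < cutoff:
            return out, False
        j += step
    return out, True  # hit the edge while EHH still >= cutoff


def ehh_profile(H: np.ndarray, core: int, allele: int, cutoff: float = 0.05):
    """EHH decay around one core allele, both directions.

    ``H`` is the (n_hap × n_snp) haplotype matrix of a single chromosome.
    Returns a DataFrame (index, direction, ehh) including the core itself
    (EHH = 1 at distance zero), or None with a logged reason when the core
    allele has fewer than two carriers.
    """
    carriers = np.where(H[:, core] == allele)[0]
    if len(carriers) < 2:
        return None
    rows = [{"index": core, "direction": 0, "ehh": 1.0}]
    for step, name in ((-1, -1), (1, 1)):
        walk, _ = _ehh_walk(H, carriers, core, step, cutoff)
        for j, e in walk:
            rows.append({"index": j, "direction": name, "ehh": e})
    return pd.DataFrame(rows)


def _ihh_walk_kernel(H, carriers, core, step, cm, cutoff):
    """One-sided iHH: trapezoidal integral of EHH over cM until cutoff.

    Returns ``(area, truncated)``; the first marker where EHH drops below
    the cutoff is still included in the integral. Written with explicit
    loops so numba can compile it; the pure-Python path is the fallback.
    """
    n = carriers.shape[0]
    denom = n * (n - 1) / 2.0
    order = carriers.copy()
    starts = np.empty(n + 1, np.int64)
    starts[0] = 0
    starts[1] = n
    n_seg = 1
    area = 0.0
    prev_e = 1.0
    prev_cm = cm[core]
    j = core + step
    S = H.shape[1]
    new_order = np.empty(n, np.int64)
    new_starts = np.empty(n + 1, np.int64)
    while 0 <= j < S:
        # stable-partition every group by this column's allele
        m = 0
        new_n_seg = 0
        new_starts[0] = 0
        num = 0.0
        for s in range(n_seg):
            a, b = starts[s], starts[s + 1]
            c0 = 0
            for t in range(a, b):
                if H[order[t], j] == 0:
                    new_order[m] = order[t]
                    m += 1
                    c0 += 1
            for t in range(a, b):
                if H[order[t], j] != 0:
                    new_order[m] = order[t]
                    m += 1
            c1 = b - a - c0
            if c0 > 0:
                new_n_seg += 1
                new_starts[new_n_seg] = new_starts[new_n_seg - 1] + c0
                num += c0 * (c0 - 1) / 2.0
            if c1 > 0:
                new_n_seg += 1
                new_starts[new_n_seg] = new_starts[new_n_seg - 1] + c1
                num += c1 * (c1 - 1) / 2.0
        order, new_order = new_order, order
        tmp = starts
        starts = new_starts
        new_starts = tmp
        n_seg = new_n_seg
        ehh = num / denom
        area += 0.5 * (prev_e + ehh) * abs(cm[j] - prev_cm)
        if ehh < cutoff:
            return area, False
        prev_e = ehh
        prev_cm = cm[j]
        j += step
    return area, True


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _ihh_walk_fast = njit(cache=True)(_ihh_walk_kernel)
except Exception:  # pragma: no cover
    _ihh_walk_fast = _ihh_walk_kernel


def _ihh_one_side(H, carriers, core, step, cm, cutoff, trunc_drop):
    """Trapezoidal integral of the EHH decay over genetic distance, one side."""
    area, truncated = _ihh_walk_fast(
        H, np.asarray(carriers, np.int64), core, step, cm, cutoff
    )
    if truncated and trunc_drop:
        return None
    return area


def ihs_scan(
    hs: HaplotypeSet,
    vt: VariantTable,
    gmap: GeneticMap,
    maf_min: float = 0.05,
    cutoff: float = 0.05,
    bins: int = 50,
    trunc_policy: str = "drop",
) -> pd.DataFrame:
    """Integrated haplotype score for every qualifying core SNP.

    The reference allele is treated as ancestral. For each core with minor
    allele frequency ≥ ``maf_min``, the EHH profile of each allele is
    integrated over genetic distance out to where EHH < ``cutoff``;
    unstandardized iHS = ln(iHH_ancestral/iHH_derived), standardized to
    mean 0 / sd 1 within derived-allele-frequency bins. Cores with a zero
    integral (e.g. zero genetic distance throughout the surrounding region)
    or, under the default truncation policy, with an EHH profile cut off by
    the chromosome edge, yield no estimate.
    """
    if trunc_policy not in ("drop", "keep"):
        raise ValueError("trunc_policy must be 'drop' or 'keep'")
    cm_all = genetic_positions(vt, gmap)
    rows = []
    for c in vt.chromosomes():
        mask = vt.chrom_mask(c)
        idx = np.where(mask)[0]
        H = hs.haplotypes[:, idx]
        cm = cm_all[idx]
        pos = vt.pos[idx]
        daf = H.mean(axis=0)
        for jj in range(H.shape[1]):
            f = daf[jj]
            if min(f, 1 - f) < maf_min:
                continue
            unstd = np.nan
            ihh = {}
            for allele in (0, 1):
                carriers = np.where(H[:, jj] == allele)[0]
                if len(carriers) < 2:
                    ihh[allele] = None
                    continue
                left = _ihh_one_side(H, carriers, jj, -1, cm, cutoff, trunc_policy == "drop")
                right = _ihh_one_side(H, carriers, jj, +1, cm, cutoff, trunc_policy == "drop")
                ihh[allele] = None if (left is None or right is None) else left + right
            iA, iD = ihh.get(0), ihh.get(1)
            if iA is not None and iD is not None and iA > 0 and iD > 0:
                unstd = float(np.log(iA / iD))
            rows.append(
                {"chrom": c, "pos": int(pos[jj]), "daf": float(f),
                 "ihh_a": np.nan if iA is None else iA,
                 "ihh_d": np.nan if iD is None else iD,
                 "ihs_unstd": unstd}
            )
    scan = pd.DataFrame(rows)
    if scan.empty:
        scan["ihs_std"] = []
        scan["abs_ihs"] = []
        return scan

    # standardize within derived-allele-frequency bins
    scan["ihs_std"] = np.nan
    edges = np.linspace(0.0, 1.0, bins + 1)
    which = np.clip(np.digitize(scan["daf"], edges) - 1, 0, bins - 1)
    for b in range(bins):
        m = (which == b) & scan["ihs_unstd"].notna()
        if m.sum() >= 2:
            v = scan.loc[m, "ihs_unstd"]
            sd = v.std(ddof=0)
            if sd > 0:
                scan.loc[m, "ihs_std"] = (v - v.mean()) / sd
    scan["abs_ihs"] = scan["ihs_std"].abs()
    return scan


# ---------------------------------------------------------------------------
# H12
# ---------------------------------------------------------------------------

def _spectrum_h(sub: np.ndarray):
    """H1 and H12 from the haplotype frequency spectrum of a window."""
    _, counts = np.unique(sub, axis=0, return_counts=True)
    p = np.sort(counts / sub.shape[0])[::-1]
    h1 = float(np.sum(p**2))
    if len(p) >= 2:
        h12 = float((p[0] + p[1]) ** 2 + np.sum(p[2:] ** 2))
    else:
        h12 = h1
    return h1, h12


def h12_scan(
    hs: HaplotypeSet,
    vt: VariantTable,
    window_snps: int = 100,
    step_snps: int = 50,
) -> pd.DataFrame:
    """Garud H1/H12 in sliding SNP windows, assigned to the central SNP."""
    rows = []
    for c in vt.chromosomes():
        idx = np.where(vt.chrom_mask(c))[0]
        if len(idx) < window_snps:
            continue
        H = hs.haplotypes[:, idx]
        pos = vt.pos[idx]
        for a in range(0, len(idx) - window_snps + 1, step_snps):
            sub = H[:, a : a + window_snps]
            h1, h12 = _spectrum_h(sub)
            rows.append(
                {"chrom": c, "pos": int(pos[a + window_snps // 2]),
                 "window_start": int(pos[a]), "window_end": int(pos[a + window_snps - 1]),
                 "h1": h1, "h12": h12}
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "window_start", "window_end", "h1", "h12"])


def top_percentile(values, pct: float = 0.001):
    """Flag the ⌈pct·m⌉ largest finite values (ties: first by position).

    Returns ``(flags, cut_value)``; missing estimates are excluded from m
    and never flagged.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    m = int(finite.sum())
    flags = np.zeros(len(v), dtype=bool)
    if m == 0:
        return flags, np.nan
    k = int(np.ceil(pct * m))
    if k <= 0:
        return flags, np.nan
    order = np.lexsort((np.arange(len(v)), -np.where(finite, v, -np.inf)))
    top = order[:k]
    flags[top] = True
    return flags, float(v[top].min())
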