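"""Canonical synthetic study conditions and replicate experiments.

These functions pin down the desk-scale simulation conditions used to
validate the analysis chain — null calibration genomes, planted-QTL
recovery, heritability recovery and sweep-detection batteries — so that the
test suite and the reproduction script exercise exactly the same setups.

Scaling note: desk-scale genomes compress a tree genome ~100-fold, raising
per-bp mutation and recombination rates accordingly; consistent rescaling
also raises the sweep selection coefficient so that the population-scaled
strength α = 2·N_e·s stays that of a strong natural sweep (α ≈ 400 here).
The sweep battery uses a higher recombination rate than the LD/GWAS
conditions so that the sweep footprint (≈ s/(r·ln α)) matches the ±50 kbp
windows used to score localization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc, integrate, localscore, phenology, popgen
from .synthdata import (
    SimulationConfig,
    SweepSpec,
    default_cross_design,
    make_crosses,
    simulate_population,
    split_rng,
)

__all__ = [
    "null_genome_experiment",
    "qtl_recovery_experiment",
    "h2_recovery_experiment",
    "mask_recover_experiment",
    "sweep_genome",
    "ihs_sweep_enrichment",
    "h12_top_window",
    "integrated_sweep_enrichment",
]

#: interior margin excluded from selection-scan universes: cores this close
#: to a chromosome end have a one-sided EHH runway and integrate poorly
EDGE_BP = 100_000

#: half-width of the "near the sweep" window used to score localization
NEAR_BP = 50_000


# ---------------------------------------------------------------------------
# Null calibration (no QTL, neutral, unstructured panel)
# ---------------------------------------------------------------------------

def null_genome_experiment(seed: int, xi: float = 2.0, alpha: float = 0.05,
                           n_null: int = 500) -> dict:
    """GWAS + Lindley segmentation of a pure-noise trait on a neutral panel.

    Returns the KS uniformity p-value of the association p-values (computed
    on markers thinned to ≥ 10 kbp spacing, the LD scale, since the KS test
    needs approximately independent draws) and the per-chromosome
    indicator of ≥ 1 slope call at level ``alpha``.
    """
    cfg = SimulationConfig(seed=seed, N_e=100, L=500_000, n_chromosomes=2,
                           mu=4e-7, r=2e-7)
    hs, vt, gmap, _ = simulate_population(cfg)
    gm = hs.to_dosages()
    rng = split_rng(seed, "null_trait")
    y = rng.standard_normal(gm.n_samples)
    K = assoc.compute_kinship(gm, "centered")
    track = assoc.lmm_gwas(y, np.ones((gm.n_samples, 1)), K, gm, vt,
                           per_snp_lambda=False)

    thinned = []
    last: dict = {}
    for _, row in track.dropna(subset=["p"]).iterrows():
        if row["chrom"] not in last or row["pos"] - last[row["chrom"]] >= 10_000:
            thinned.append(row["p"])
            last[row["chrom"]] = row["pos"]
    ks_p = float(stats.kstest(thinned, "uniform").pvalue)

    scores = localscore.lindley_scores(track, xi)
    thr = localscore.chromosome_threshold(track, xi, alpha, n_null, seed=seed)
    calls = localscore.call_slopes(scores, thr)
    called = {c: bool((calls["chrom"] == c).any()) for c in thr}
    return {"ks_p": ks_p, "called_per_chrom": called}


# ---------------------------------------------------------------------------
# Planted-QTL recovery (120 clones, 34 families, 20% variance)
# ---------------------------------------------------------------------------

def qtl_recovery_experiment(seed: int, h2_qtl: float = 0.2, xi: float = 2.0,
                            pad: int = 10_000) -> dict:
    """Family-structured GWAS of a single planted QTL; was it covered by an
    extended slope?"""
    cfg = SimulationConfig(seed=seed, N_e=200, L=1_000_000, mu=2e-7, r=2e-7)
    hs, vt, gmap, _ = simulate_population(cfg)
    design = default_cross_design(hs.samples, seed)
    off, _ = make_crosses(hs, vt, gmap, design, seed)
    gm = off.to_dosages()
    rng = split_rng(seed, "qtl")
    freq = gm.dosages.mean(axis=0) / 2.0
    eligible = np.where((freq > 0.2) & (freq < 0.8))[0]
    qtl = int(rng.choice(eligible))
    x = gm.dosages[:, qtl]
    g = x - x.mean()
    y = g + rng.normal(0.0, np.sqrt(g.var() * (1 - h2_qtl) / h2_qtl), len(g))
    K = assoc.compute_kinship(gm, "centered")
    track = assoc.lmm_gwas(y, np.ones((len(y), 1)), K, gm, vt,
                           per_snp_lambda=True)
    scores = localscore.lindley_scores(track, xi)
    thr = localscore.chromosome_threshold(track, xi, n_null=500, seed=seed)
    slopes = localscore.call_slopes(scores, thr, trait="QTL")
    covered = False
    if len(slopes):
        iv = integrate.extend_intervals(slopes, {"chr1": cfg.L}, pad)
        qpos = vt.pos[qtl]
        covered = bool(
            ((iv["start"] <= qpos) & (qpos <= iv["end"])).any()
        )
    return {"covered": covered, "n_slopes": int(len(slopes)),
            "qtl_pos": int(vt.pos[qtl])}


# ---------------------------------------------------------------------------
# Heritability recovery (n = 200 clones, true h² = 0.5)
# ---------------------------------------------------------------------------

def h2_recovery_experiment(seed: int, h2_true: float = 0.5, reps: int = 3) -> float:
    """Marker-based narrow-sense h² recovered from a polygenic trait
    generated under the standardized-kinship model itself."""
    cfg = SimulationConfig(seed=seed, N_e=200, L=500_000, mu=4e-7, r=2e-7)
    hs, vt, gmap, _ = simulate_population(cfg)
    gm = hs.to_dosages()
    rng = split_rng(seed, "h2")
    X = gm.dosages
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    Xs = Xc[:, sd > 0] / sd[sd > 0]
    g = Xs @ rng.normal(0.0, 1.0, Xs.shape[1])
    g = (g - g.mean()) / g.std()
    sd_e = np.sqrt((1 - h2_true) / h2_true)
    rows = [
        {"clone_id": c, "value": g[i] + rng.normal(0.0, sd_e)}
        for i, c in enumerate(gm.samples)
        for _ in range(reps)
    ]
    K = assoc.compute_kinship(gm, "standardized")
    est = phenology.estimate_heritability(pd.DataFrame(rows), "narrow_marker",
                                          kinship=K)
    return float(est.h2)


def mask_recover_experiment(seed: int, n_trials: int = 120) -> float:
    """Mean absolute error of re-imputing one masked transition per ramet on
    noiseless near-linear trajectories (grid spacing bound: 4 days)."""
    rng = split_rng(seed, "mask")
    rows, truth = [], {}
    for trial in range(n_trials):
        onset = 100 + rng.normal(0, 5)
        slope = rng.uniform(2.0, 5.0)
        curve = rng.uniform(-0.3, 0.3)
        days = {s: onset + slope * (s - 2) + curve * (s - 2) ** 2
                for s in range(2, 6)}
        masked = int(rng.integers(3, 5))
        truth[f"r{trial}"] = (masked, days[masked])
        rows += [
            {"ramet_id": f"r{trial}", "clone_id": f"c{trial}", "trait": "LS",
             "stage": s, "day": d, "provenance": "observed"}
            for s, d in days.items() if s != masked
        ]
    out = phenology.impute_loess(pd.DataFrame(rows))
    errs = []
    for ramet, (masked, day) in truth.items():
        got = out[(out["ramet_id"] == ramet) & (out["stage"] == masked)]
        errs.append(abs(float(got["day"].iloc[0]) - day))
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# Sweep battery
# ---------------------------------------------------------------------------

def sweep_genome(seed: int, kind: str = "hard"):
    """Two-chromosome genome with a sweep on chr1 (α = 2·N_e·s = 400).

    The second, neutral chromosome keeps the iHS standardization bins
    anchored to neutral variation — at desk scale most high-frequency SNPs
    on the swept chromosome are hitchhikers.
    """
    cfg = SimulationConfig(
        seed=seed, N_e=200, L=1_000_000, n_chromosomes=2, mu=8e-7, r=1.6e-6,
        sweep=SweepSpec(position=500_000, s=1.0, kind=kind, final_freq=0.9),
    )
    return simulate_population(cfg)


def _interior(scan: pd.DataFrame, L: int = 1_000_000) -> pd.DataFrame:
    return scan[(scan["pos"] > EDGE_BP) & (scan["pos"] < L - EDGE_BP)]


def ihs_sweep_enrichment(hs, vt, gmap, sweep_pos: int = 500_000,
                         pct: float = 0.001):
    """Hypergeometric enrichment of top-percentile |iHS| near the sweep.

    Returns ``(p, scan, top_set)``; the universe is every interior core
    with a finite standardized score.
    """
    scan = popgen.ihs_scan(hs, vt, gmap, trunc_policy="keep")
    ok = _interior(scan.dropna(subset=["abs_ihs"]))
    flags, _ = popgen.top_percentile(ok["abs_ihs"].to_numpy(), pct)
    universe = set(zip(ok["chrom"], ok["pos"]))
    top = set(zip(ok["chrom"].to_numpy()[flags], ok["pos"].to_numpy()[flags]))
    nearm = ((ok["chrom"] == "chr1")
             & (ok["pos"] >= sweep_pos - NEAR_BP)
             & (ok["pos"] <= sweep_pos + NEAR_BP))
    near = set(zip(ok.loc[nearm, "chrom"], ok.loc[nearm, "pos"]))
    res = integrate.hypergeom_enrichment(universe, top, near)
    return res.p, scan, top


def h12_top_window(hs, vt) -> tuple:
    """Chromosome and central position of the genome-wide top H12 window."""
    h12 = popgen.h12_scan(hs, vt, window_snps=100, step_snps=50)
    best = h12.loc[h12["h12"].idxmax()]
    return str(best["chrom"]), int(best["pos"])


def integrated_sweep_enrichment(genome, scan, top, linked: bool, seed: int,
                                h2_qtl: float = 0.2, xi: float = 2.0,
                                pad: int = NEAR_BP):
    """Full chain on a sweep genome: crosses → GWAS → slopes → extension →
    enrichment of top |iHS| inside extended slopes.

    ``linked`` plants the trait's causal SNP at the sweep site; otherwise on
    the neutral chromosome. Slopes are padded by the sweep-condition's
    footprint scale (±50 kbp): in this high-recombination condition the
    association signal is much narrower than the sweep footprint, so the
    LD-decay pad would compare mismatched scales. Returns the
    hypergeometric p (1.0 when no slope is called).
    """
    hs, vt, gmap, _ = genome
    design = default_cross_design(hs.samples, seed)
    off, _ = make_crosses(hs, vt, gmap, design, seed)
    gm = off.to_dosages()
    rng = split_rng(seed, "integrated_qtl")
    freq = gm.dosages.mean(axis=0) / 2.0
    if linked:
        cand = np.where((vt.chrom == "chr1")
                        & (np.abs(vt.pos - 500_000) < 20_000)
                        & (freq > 0.05) & (freq < 0.95))[0]
        qtl = int(cand[np.argmin(np.abs(vt.pos[cand] - 500_000))])
    else:
        cand = np.where((vt.chrom == "chr2") & (freq > 0.2) & (freq < 0.8))[0]
        qtl = int(rng.choice(cand))
    x = gm.dosages[:, qtl]
    g = x - x.mean()
    if g.var() == 0:
        return None
    y = g + rng.normal(0.0, np.sqrt(g.var() * (1 - h2_qtl) / h2_qtl), len(g))
    K = assoc.compute_kinship(gm, "centered")
    track = assoc.lmm_gwas(y, np.ones((len(y), 1)), K, gm, vt,
                           per_snp_lambda=False)
    scores = localscore.lindley_scores(track, xi)
    thr = localscore.chromosome_threshold(track, xi, n_null=500, seed=seed)
    slopes = localscore.call_slopes(scores, thr, trait="T")
    if not len(slopes):
        return 1.0
    iv = integrate.extend_intervals(slopes, {"chr1": 1_000_000, "chr2": 1_000_000}, pad)
    ok = _interior(scan.dropna(subset=["abs_ihs"]))
    universe = set(zip(ok["chrom"], ok["pos"]))
    inside: set = set()
    for _, r in iv.iterrows():
        m = ((ok["chrom"] == r["chrom"]) & (ok["pos"] >= r["start"])
             & (ok["pos"] <= r["end"]))
        inside |= set(zip(ok.loc[m, "chrom"], ok.loc[m, "pos"]))
    return integrate.hypergeom_enrichment(universe, top, inside).p
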