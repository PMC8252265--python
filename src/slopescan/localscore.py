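"""Lindley (local score) segmentation of GWAS p-value tracks.

Each SNP contributes X_i = −log10(p_i) − ξ; the Lindley process
h_i = max(0, h_{i−1} + X_i) accumulates evidence over linked neighbours and
resets at zero, so an excursion above a chromosome-specific null threshold
marks a run of associated SNPs even when no single test is genome-wide
significant. The reported interval is the leading edge of the excursion:
from the SNP where the process leaves zero to the SNP where it peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import split_rng

__all__ = [
    "lindley_scores",
    "chromosome_threshold",
    "call_slopes",
]

_P_FLOOR = 1e-300


def _lindley(x: np.ndarray) -> np.ndarray:
    """h_i = max(0, h_{i-1} + x_i), vectorized via the running-minimum identity."""
    s = np.cumsum(x)
    return s - np.minimum(np.minimum.accumulate(s), 0.0)


def lindley_scores(track: pd.DataFrame, xi: float) -> pd.DataFrame:
    """Per-SNP scores and the Lindley process, per chromosome independently.

    ``track`` needs columns chrom, pos, p (sorted by position within
    chromosome). Zero p-values are clamped to the smallest positive
    representable value with a warning; missing p-values are skipped.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    t = track.dropna(subset=["p"]).copy()
    p = t["p"].to_numpy(dtype=float)
    if np.any(p == 0):
        warnings.warn("p = 0 clamped to smallest positive representable value")
        p = np.maximum(p, _P_FLOOR)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside (0, 1]")
    t["score"] = -np.log10(p) - xi
    t["lindley"] = 0.0
    for c in t["chrom"].unique():
        m = t["chrom"] == c
        t.loc[m, "lindley"] = _lindley(t.loc[m, "score"].to_numpy())
    t.attrs["xi"] = xi
    return t.reset_index(drop=True)


def _max_lindley_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise maxima of the Lindley process for a matrix of scores."""
    S = np.cumsum(X, axis=1)
    M = np.minimum(np.minimum.accumulate(S, axis=1), 0.0)
    return np.max(S - M, axis=1)


def chromosome_threshold(
    track: pd.DataFrame,
    xi: float,
    alpha: float = 0.05,
    n_null: int = 1000,
    method: str = "ar1_montecarlo",
    seed: int = 0,
    block_len: int = 20,
) -> dict:
    """Per-chromosome null thresholds for the maximum Lindley score.

    ``ar1_montecarlo`` matches the observed lag-1 autocorrelation of
    −log10(p) with a Gaussian AR(1) null, maps it through the normal CDF to
    uniform p-values and takes the empirical (1−α) quantile of the maximum
    Lindley score over ``n_null`` replicates. ``block_permutation`` instead
    circularly shifts the observed scores in blocks. A single-SNP
    chromosome admits the closed form −log10(α) − ξ (floored at 0), which
    is used directly.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    out = {}
    for c in track["chrom"].unique():
        sub = track[(track["chrom"] == c)].dropna(subset=["p"])
        p = np.maximum(sub["p"].to_numpy(dtype=float), _P_FLOOR)
        m = len(p)
        if m == 0:
            continue
        if m == 1:
            out[c] = max(0.0, -np.log10(alpha) - xi)
            continue
        rng = split_rng(seed, "threshold", c)
        nlp = -np.log10(p)
        if method == "ar1_montecarlo":
            if m < 50:
                warnings.warn(
                    f"chromosome {c} has {m} SNPs; autocorrelation estimate is noisy"
                )
            rho = float(np.corrcoef(nlp[:-1], nlp[1:])[0, 1]) if m > 2 else 0.0
            if not np.isfinite(rho):
                rho = 0.0
            rho = float(np.clip(rho, -0.99, 0.99))
            Z = np.empty((n_null, m))
            Z[:, 0] = rng.standard_normal(n_null)
            innov_sd = np.sqrt(1.0 - rho * rho)
            eps = rng.standard_normal((n_null, m - 1))
            for j in range(1, m):
                Z[:, j] = rho * Z[:, j - 1] + innov_sd * eps[:, j - 1]
            U = np.maximum(stats.norm.sf(Z), _P_FLOOR)
            X = -np.log10(U) - xi
            maxima = _max_lindley_rows(X)
        elif method == "block_permutation":
            x_obs = nlp - xi
            n_blocks = int(np.ceil(m / block_len))
            maxima = np.empty(n_null)
            for b in range(n_null):
                order = rng.permutation(n_blocks)
                idx = np.concatenate(
                    [np.arange(o * block_len, min((o + 1) * block_len, m)) for o in order]
                )
                maxima[b] = _max_lindley_rows(x_obs[idx][None, :])[0]
        else:
            raise ValueError(f"unknown threshold method {method!r}")
        out[c] = float(np.quantile(maxima, 1.0 - alpha))
    return out


def call_slopes(
    scores: pd.DataFrame,
    thresholds: dict,
    trait: str = "",
    full_excursion: bool = False,
) -> pd.DataFrame:
    """Significant Lindley excursions, reported start → peak.

    One call per maximal run with h > 0 whose maximum reaches the
    chromosome's threshold. The interval spans the first SNP of the
    excursion to its (leftmost) argmax — the leading-edge slope — unless
    ``full_excursion`` extends it to the last SNP of the run.
    """
    calls = []
    for c in scores["chrom"].unique():
        if c not in thresholds:
            continue
        thr = thresholds[c]
        sub = scores[scores["chrom"] == c].reset_index(drop=True)
        h = sub["lindley"].to_numpy()
        pos = sub["pos"].to_numpy()
        above = h > 0
        if not above.any():
            continue
        edges = np.diff(above.astype(int))
        starts = list(np.where(edges == 1)[0] + 1)
        if above[0]:
            starts.insert(0, 0)
        ends = list(np.where(edges == -1)[0])
        if above[-1]:
            ends.append(len(h) - 1)
        for s, e in zip(starts, ends):
            seg = h[s : e + 1]
            peak = s + int(np.argmax(seg))  # leftmost tie
            h_max = float(h[peak])
            if h_max >= thr:
                calls.append(
                    {"trait": trait, "chrom": c,
                     "start": int(pos[s]),
                     "end": int(pos[e] if full_excursion else pos[peak]),
                     "start_idx": s, "peak_idx": peak, "end_idx": e,
                     "h_max": h_max, "threshold": thr}
                )
    return pd.DataFrame(
        calls,
        columns=["trait", "chrom", "start", "end", "start_idx", "peak_idx",
                 "end_idx", "h_max", "threshold"],
    )
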