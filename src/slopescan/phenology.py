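"""Ordinal phenology stages → transition days, imputation, traits, heritability.

Scoring visits every few days gives, per ramet and trait, a monotone ordinal
stage series contaminated by occasional reversals (observer disagreement,
leaf shed un-yellowing). The running-maximum rule dates each stage at the
first visit the series reaches it and discards later reversals; the first
stage, which means "no change yet", is dated at the last visit still there.
Missed transitions are filled per individual by local regression of day on
stage (LOESS), with an isotonic post-adjustment because the local fit is not
constrained to be monotone while the truth is. Clone means over ramets are
the stage-specific phenotypes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assoc import KinshipMatrix, reml_profile

__all__ = [
    "TraitCatalog",
    "HeritabilityEstimate",
    "transitions_from_stages",
    "impute_loess",
    "clone_summary",
    "compare_years",
    "estimate_heritability",
]

_NAME_RE = re.compile(r"^([A-Z]+)(\d+)(?:-(\w+))?$")


@dataclass
class TraitCatalog:
    """Named analysis traits like ``LS5-17`` = leaf shed, stage 5, 2017.

    Each name decomposes as trait code + stage + optional context (year or
    phytotron bud class).
    """

    entries: list  # dicts with name, trait, stage, context

    @classmethod
    def parse(cls, names) -> "TraitCatalog":
        entries = []
        seen = set()
        for name in names:
            m = _NAME_RE.match(name)
            if not m:
                raise ValueError(f"trait name {name!r} does not parse")
            if name in seen:
                raise ValueError(f"duplicate trait name {name!r}")
            seen.add(name)
            entries.append(
                {"name": name, "trait": m.group(1), "stage": int(m.group(2)),
                 "context": m.group(3)}
            )
        return cls(entries)


def transitions_from_stages(obs: pd.DataFrame) -> pd.DataFrame:
    """Date each ramet's stage transitions from ordinal visit records.

    For stage ≥ 2 the transition day is the first visit on which the running
    maximum of the stage series reaches that stage (later reversals are
    discarded); for stage 1 it is the last visit on which the running
    maximum is still 1. Stages never attained are absent from the output.

    Returns a long table (ramet_id, clone_id, trait, stage, day, provenance).
    """
    required = {"ramet_id", "clone_id", "julian_day", "trait", "stage"}
    if not required.issubset(obs.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    dup = obs.groupby(["ramet_id", "trait", "julian_day"])["stage"].nunique()
    if (dup > 1).any():
        key = dup[dup > 1].index[0]
        raise ValueError(f"conflicting stages for same ramet/trait/day: {key}")

    rows = []
    for (ramet, trait), grp in obs.groupby(["ramet_id", "trait"], sort=False):
        grp = grp.sort_values("julian_day")
        days = grp["julian_day"].to_numpy()
        runmax = np.maximum.accumulate(grp["stage"].to_numpy())
        clone = grp["clone_id"].iloc[0]
        at_one = runmax == 1
        if at_one.any():
            rows.append(
                {"ramet_id": ramet, "clone_id": clone, "trait": trait,
                 "stage": 1, "day": float(days[at_one][-1]), "provenance": "observed"}
            )
        for stage in range(2, int(runmax.max()) + 1):
            reached = runmax >= stage
            if reached.any():
                rows.append(
                    {"ramet_id": ramet, "clone_id": clone, "trait": trait,
                     "stage": stage, "day": float(days[reached][0]),
                     "provenance": "observed"}
                )
    return pd.DataFrame(
        rows, columns=["ramet_id", "clone_id", "trait", "stage", "day", "provenance"]
    )


def _fit_fill(stages_obs, days_obs, stages_missing, span):
    """Local-regression fill of missing stages; linear fallback at 2 points."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if len(stages_obs) >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filled = lowess(
                days_obs, stages_obs, frac=max(span, 2.0 / len(stages_obs)),
                xvals=np.asarray(stages_missing, dtype=float),
            )
        filled = np.atleast_1d(filled)
        if np.all(np.isfinite(filled)):
            return filled
    # two points, or a degenerate local fit: straight line through the data
    slope, icept = np.polyfit(stages_obs, days_obs, 1)
    return slope * np.asarray(stages_missing, dtype=float) + icept


def impute_loess(td: pd.DataFrame, span: float = 0.75) -> pd.DataFrame:
    """Fill missed stage transitions per individual by LOESS of day on stage.

    A ramet×trait series with at least two dated stages is completed at
    every stage of that trait's grid (stage 2 and up); filled cells are
    flagged ``imputed``. An isotonic post-adjustment (ties allowed, observed
    cells pinned) restores monotonicity where the local fit broke it.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    from sklearn.isotonic import IsotonicRegression

    out = [td]
    grid = {t: sorted(g["stage"].unique()) for t, g in td.groupby("trait")}
    for (ramet, trait), grp in td.groupby(["ramet_id", "trait"], sort=False):
        have = set(grp["stage"])
        want = [s for s in grid[trait] if s >= 2 and s not in have]
        if not want or len(grp) < 2:
            continue
        grp = grp.sort_values("stage")
        filled = _fit_fill(
            grp["stage"].to_numpy(dtype=float), grp["day"].to_numpy(), want, span
        )
        clone = grp["clone_id"].iloc[0]
        out.append(
            pd.DataFrame(
                {"ramet_id": ramet, "clone_id": clone, "trait": trait,
                 "stage": want, "day": filled, "provenance": "imputed"}
            )
        )
    full = pd.concat(out, ignore_index=True)

    # isotonic post-adjustment per series; observed points carry huge weight
    # (they are already monotone by the running-maximum construction)
    iso = IsotonicRegression(increasing=True)
    pieces = []
    for (ramet, trait), grp in full.groupby(["ramet_id", "trait"], sort=False):
        grp = grp.sort_values("stage").copy()
        if (grp["provenance"] == "imputed").any():
            w = np.where(grp["provenance"] == "observed", 1e9, 1.0)
            grp["day"] = iso.fit_transform(
                grp["stage"].to_numpy(dtype=float), grp["day"].to_numpy(), sample_weight=w
            )
        pieces.append(grp)
    return pd.concat(pieces, ignore_index=True)


def clone_summary(td: pd.DataFrame, catalog: TraitCatalog):
    """Per-clone arithmetic means of (imputed) transition days for each
    catalogued trait. Returns ``(values, counts)`` clone × trait tables."""
    vals = {}
    counts = {}
    for e in catalog.entries:
        sub = td[(td["trait"] == e["trait"]) & (td["stage"] == e["stage"])]
        g = sub.groupby("clone_id")["day"]
        vals[e["name"]] = g.mean()
        counts[e["name"]] = g.size()
    return pd.DataFrame(vals), pd.DataFrame(counts)


def compare_years(values_y1, values_y2):
    """Welch two-sample t-test between per-clone values of two years.

    Returns ``(t, dof, p)`` with Satterthwaite degrees of freedom.
    """
    a = np.asarray(values_y1, dtype=float)
    b = np.asarray(values_y2, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    trait: str
    mode: str
    h2: float
    sigma2_g: float
    sigma2_e: float
    overfit: bool
    extra: dict = field(default_factory=dict)


def _incidence(labels) -> tuple[np.ndarray, list]:
    levels = list(dict.fromkeys(labels))
    idx = {l: i for i, l in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for r, l in enumerate(labels):
        Z[r, idx[l]] = 1.0
    return Z, levels


def _narrow_marker(values: pd.DataFrame, kinship: KinshipMatrix, covariates, trait):
    """REML of clone values (replicated over ramets) with covariance σ²_g·K."""
    clones = values["clone_id"].tolist()
    order = {s: i for i, s in enumerate(kinship.samples)}
    missing = [c for c in clones if c not in order]
    if missing:
        raise KeyError(f"clone {missing[0]} absent from kinship")
    kinship.check_psd()
    Z, levels = _incidence(clones)
    Ksub = kinship.values[np.ix_([order[l] for l in levels], [order[l] for l in levels])]
    H = Z @ Ksub @ Z.T
    y = values["value"].to_numpy(dtype=float)
    W = np.ones((len(y), 1))
    if covariates is not None:
        W = np.column_stack([W, np.asarray(covariates, dtype=float)])
    d, U = np.linalg.eigh(H)
    d = np.clip(d, 0.0, None)
    lam, alpha, s2e, _ = reml_profile(U.T @ y, U.T @ W, d)
    h2 = lam / (1.0 + lam)
    overfit = lam < 1e-4 or lam > 1e4
    return HeritabilityEstimate(trait, "narrow_marker", float(np.clip(h2, 0, 1)),
                                lam * s2e, s2e, overfit)


def _v_star(gammas, ZZts):
    V = np.eye(ZZts[0].shape[0])
    for g, ZZt in zip(gammas, ZZts):
        V = V + g * ZZt
    return V


def _multi_reml(y, X, ZZts):
    """REML over variance ratios γ_k = σ²_k/σ²_e for several random terms."""
    n, c = X.shape

    def crit(log_g):
        g = 10.0 ** np.asarray(log_g)
        V = _v_star(g, ZZts)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        sign, logdetX = np.linalg.slogdet(XtViX)
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        rss = float(r @ np.linalg.solve(V, r))
        if rss <= 0:
            return np.inf
        return logdetV + logdetX + (n - c) * np.log(rss)

    x0 = np.zeros(len(ZZts))
    res = optimize.minimize(crit, x0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000})
    g = 10.0**res.x
    V = _v_star(g, ZZts)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    s2e = float(r @ np.linalg.solve(V, r)) / (n - c)
    return g, s2e, beta, V


def _broad_cullis(values: pd.DataFrame, covariates, trait):
    """Cullis H² = 1 − v̄_Δ/(2σ²_g) from genotype-BLUP prediction errors."""
    y = values["value"].to_numpy(dtype=float)
    Zg, clones = _incidence(values["clone_id"].tolist())
    ZZts = [Zg @ Zg.T]
    has_block = "block" in values.columns and values["block"].nunique() > 1
    if has_block:
        Zb, _ = _incidence(values["block"].tolist())
        ZZts.append(Zb @ Zb.T)
    X = np.ones((len(y), 1))
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])

    g, s2e, beta, V = _multi_reml(y, X, ZZts)
    gamma_g = float(g[0])
    sigma2_g = gamma_g * s2e
    overfit = gamma_g < 1e-4
    if overfit or sigma2_g <= 0:
        return HeritabilityEstimate(trait, "broad_cullis", 0.0, sigma2_g, s2e, True)

    Vi = np.linalg.inv(V)
    XtViX_inv = np.linalg.inv(X.T @ Vi @ X)
    P = Vi - Vi @ X @ XtViX_inv @ X.T @ Vi
    # PEV of genotype BLUPs, in σ²_e units: γI − γ² ZᵀPZ
    q = Zg.shape[1]
    C = s2e * (gamma_g * np.eye(q) - gamma_g**2 * (Zg.T @ P @ Zg))
    trC = float(np.trace(C))
    S = float(C.sum())
    vbar = 2.0 * (q * trC - S) / (q * (q - 1))
    H2 = 1.0 - vbar / (2.0 * sigma2_g)
    return HeritabilityEstimate(trait, "broad_cullis", float(np.clip(H2, 0, 1)),
                                sigma2_g, s2e, False, {"vbar_delta": vbar})


def estimate_heritability(
    values: pd.DataFrame,
    mode: str,
    kinship: KinshipMatrix | None = None,
    covariates=None,
    trait: str = "",
) -> HeritabilityEstimate:
    """Narrow-sense (marker-based REML) or broad-sense (Cullis) heritability.

    ``values`` is a ramet-level table with columns ``clone_id``, ``value``
    and optionally ``block``. The narrow-sense mode fits a genetic effect
    with covariance σ²_g·K over clones, using the imputed per-ramet values
    as replicates; the broad-sense mode fits genotype and block as
    independent random terms and converts the mean variance of a BLUP
    difference into H². A genetic variance pinned at the zero boundary sets
    the overfit flag.
    """
    if values["clone_id"].nunique() < 10:
        warnings.warn("fewer than 10 clones; heritability estimate unstable")
    if mode == "narrow_marker":
        if kinship is None:
            raise ValueError("narrow_marker mode needs a kinship matrix")
        return _narrow_marker(values, kinship, covariates, trait)
    if mode == "broad_cullis":
        return _broad_cullis(values, covariates, trait)
    raise ValueError(f"unknown mode {mode!r}")
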