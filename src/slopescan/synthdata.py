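"""Synthetic genotypes, crosses, sweeps, genes and ordinal phenology scores.

The generator emulates the structure of a small introduced breeding
population of *Populus*-like trees: an outbred founder pool at coalescent
equilibrium, full-sib families produced by crosses among founders, clonal
replication of offspring into field blocks, ordinal phenology stages scored
on a 2–5 day visit grid, and optional hard/soft selective sweeps in the
founders' history.

Founders come from the coalescent: neutral chromosomes at equilibrium (a
burn-in shortcut), swept chromosomes through the structured-coalescent
sweep model, which conditions on the sweep's start and end frequencies by
construction. The crosses are simulated forward with explicit recombinant
gametes, because the pedigree needs haplotype-level bookkeeping.

All randomness flows from one integer seed through labelled
``numpy.random.SeedSequence`` splits (:func:`split_rng`), so each stage can
be re-seeded independently and reruns are bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneAnnotation, GeneticMap, GenotypeMatrix, HaplotypeSet, VariantTable
from .io_core import constant_rate_map

__all__ = [
    "SweepSpec",
    "SimulationConfig",
    "CrossDesign",
    "TraitModel",
    "split_rng",
    "simulate_population",
    "make_crosses",
    "simulate_phenology",
    "random_genes",
    "default_family_sizes",
    "default_cross_design",
]

#: 34 full-sib family sizes (1 to 21 sibs, 121 offspring in total), matching
#: the family-structure scale of a small clonal screening trial.
DEFAULT_FAMILY_SIZES: tuple = tuple(
    [1] * 11 + [2] * 8 + [3] * 4 + [4] * 3 + [5] * 2 + [6, 7, 8, 8, 10, 21]
)


def default_family_sizes() -> tuple:
    return DEFAULT_FAMILY_SIZES


def split_rng(seed: int, *labels) -> np.random.Generator:
    """Derive an independent generator from ``seed`` and a label path.

    Labels are hashed with CRC32 so the scheme is stable across runs and
    platforms; every stochastic routine in this module draws from one of
    these splits and nothing else.
    """
    keys = tuple(zlib.crc32(str(lab).encode()) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=keys))


def _seed_int(seed: int, *labels) -> int:
    """A 31-bit integer sub-seed (for libraries that take plain seeds)."""
    return int(split_rng(seed, *labels).integers(1, 2**31 - 1))


@dataclass
class SweepSpec:
    """A selective sweep ending at one focal site just before sampling.

    ``kind='hard'`` starts from a single new copy; ``'soft'`` starts from
    standing variation at ``start_freq`` (default 0.05), i.e. on multiple
    haplotype backgrounds. ``s`` is the per-generation selective advantage
    of the beneficial homozygote; at desk-scale population sizes the
    meaningful quantity is the scaled strength α = 2·N_e·s, so a sweep that
    is strong in a large natural population is emulated by a large ``s``.
    The run is conditioned on the allele reaching ``final_freq``.
    """

    position: int
    s: float = 0.05
    kind: str = "hard"
    start_freq: float = 0.05
    final_freq: float = 0.8
    chrom: str | None = None  # default: first chromosome


@dataclass
class SimulationConfig:
    seed: int = 0
    N_e: int = 200
    L: int = 1_000_000
    n_chromosomes: int = 1
    mu: float = 1e-8
    r: float = 1e-8
    sweep: SweepSpec | None = None

    def __post_init__(self) -> None:
        if self.mu < 0 or self.r < 0:
            raise ValueError("rates must be non-negative")
        if self.sweep is not None and not (1 <= self.sweep.position <= self.L):
            raise ValueError("sweep position outside chromosome")


@dataclass
class CrossDesign:
    """Parent pairs, offspring counts, and the clonal field design."""

    families: list  # list of (mother_id, father_id, n_offspring)
    n_blocks: int = 5
    ramets_per_clone: int = 5
    allow_selfing: bool = False

    def __post_init__(self) -> None:
        for m, f, k in self.families:
            if k < 1:
                raise ValueError("offspring counts must be >= 1")
            if m == f and not self.allow_selfing:
                raise ValueError(f"selfing requested for parent {m} but disallowed")

    @property
    def n_offspring(self) -> int:
        return sum(k for _, _, k in self.families)


@dataclass
class TraitModel:
    """Additive genetic architecture and observation process for one trait.

    Stage-onset baselines are Julian days and must be strictly increasing;
    the observation grid visits every 2–5 days and reports the largest stage
    whose onset has passed, with optional reversal errors and missed visits.
    """

    trait: str = "LS"
    causal_idx: tuple = ()
    effects: tuple = ()
    h2: float = 0.5
    stage_baselines: tuple = (250.0, 258.0, 266.0, 274.0)  # onsets of stages 2..5
    visit_gap_days: tuple = (2, 3, 4, 5)
    reversal_error: float = 0.0
    missing_visit: float = 0.0
    env_sd_if_no_genetics: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        if np.any(np.diff(self.stage_baselines) <= 0):
            raise ValueError("stage baselines must be strictly increasing")
        if len(self.causal_idx) != len(self.effects):
            raise ValueError("causal_idx and effects must have equal length")


# ---------------------------------------------------------------------------
# Founder population
# ---------------------------------------------------------------------------

def _coalescent_founders(cfg: SimulationConfig, chrom: str, lab: str, sweep: SweepSpec | None):
    """Equilibrium founders for one chromosome via the coalescent.

    With a sweep, the structured-coalescent sweep model runs first (the
    sweep finishes just before sampling, conditioned on its start and end
    frequencies by construction) and the standard coalescent completes the
    older history at equilibrium diversity.
    """
    import msprime

    if sweep is None:
        model = msprime.StandardCoalescent()
    else:
        start = 1.0 / (2 * cfg.N_e) if sweep.kind == "hard" else sweep.start_freq
        model = [
            msprime.SweepGenicSelection(
                position=min(max(sweep.position, 1), cfg.L - 1),
                start_frequency=start,
                end_frequency=sweep.final_freq,
                s=sweep.s,
                dt=1e-6,
            ),
            msprime.StandardCoalescent(),
        ]
    ts = msprime.sim_ancestry(
        samples=cfg.N_e,
        population_size=cfg.N_e,
        sequence_length=cfg.L,
        recombination_rate=cfg.r,
        model=model,
        random_seed=_seed_int(cfg.seed, "ancestry", lab),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=cfg.mu,
        model=msprime.BinaryMutationModel(),
        random_seed=_seed_int(cfg.seed, "mutations", lab),
    )
    positions, cols = [], []
    last_pos = 0
    for var in ts.variants():
        if len(var.alleles) != 2:
            continue
        p = int(var.site.position) + 1
        if p <= last_pos:
            continue  # collapse multiple hits in the same discrete bp
        positions.append(p)
        cols.append(var.genotypes.astype(np.int8))
        last_pos = p
    H = (
        np.array(cols, dtype=np.int8).T
        if cols
        else np.empty((2 * cfg.N_e, 0), dtype=np.int8)
    )
    return np.array(positions, dtype=np.int64), H


def simulate_population(cfg: SimulationConfig):
    """Simulate phased founders, variants and a genetic map.

    Returns ``(HaplotypeSet, VariantTable, GeneticMap, info)`` where ``info``
    holds the sweep site (if any) and its end frequency. A sweep is placed
    on its chromosome's recent history via the structured-coalescent sweep
    model, which is conditioned on the requested start and end frequencies
    by construction; neutral diversity elsewhere stays at equilibrium.
    """
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    all_pos, all_chrom, all_H = [], [], []
    info: dict = {"sweep": None}
    for ci, chrom in enumerate(chrom_names):
        sweep = cfg.sweep
        sweep_here = (
            sweep is not None and (sweep.chrom or chrom_names[0]) == chrom
        )
        pos, H = _coalescent_founders(cfg, chrom, chrom, sweep if sweep_here else None)
        if sweep_here:
            info["sweep"] = {
                "chrom": chrom, "position": int(sweep.position),
                "final_freq": sweep.final_freq, "kind": sweep.kind,
            }
        # drop sites monomorphic in the founders
        freq = H.mean(axis=0)
        keep = (freq > 0) & (freq < 1)
        pos, H = pos[keep], H[:, keep]
        all_pos.append(pos)
        all_chrom.append(np.array([chrom] * len(pos), dtype=object))
        all_H.append(H)

    pos = np.concatenate(all_pos)
    chroms = np.concatenate(all_chrom)
    H = np.concatenate(all_H, axis=1) if all_H else np.empty((2 * cfg.N_e, 0), np.int8)
    samples = [f"F{i:03d}" for i in range(cfg.N_e)]
    vt = VariantTable(
        chroms,
        pos,
        np.array(["A"] * len(pos), dtype=object),
        np.array(["T"] * len(pos), dtype=object),
        np.array([f"{c}_{p}" for c, p in zip(chroms, pos)], dtype=object),
    )
    vt.validate()
    hs = HaplotypeSet(samples, H)
    gmap = constant_rate_map({c: cfg.L for c in chrom_names}, cfg.r * 1e8)
    return hs, vt, gmap, info


# ---------------------------------------------------------------------------
# Crosses
# ---------------------------------------------------------------------------

def default_cross_design(
    founder_ids: list,
    seed: int,
    family_sizes: tuple | None = None,
    n_blocks: int = 5,
    ramets_per_clone: int = 5,
) -> CrossDesign:
    """34-family full-sib design with 1–21 sibs per family (121 offspring)."""
    sizes = family_sizes or DEFAULT_FAMILY_SIZES
    rng = split_rng(seed, "design")
    fams = []
    for k in sizes:
        m, f = rng.choice(len(founder_ids), size=2, replace=False)
        fams.append((founder_ids[m], founder_ids[f], int(k)))
    return CrossDesign(fams, n_blocks=n_blocks, ramets_per_clone=ramets_per_clone)


def make_crosses(
    founders: HaplotypeSet,
    vt: VariantTable,
    gmap: GeneticMap,
    design: CrossDesign,
    seed: int,
):
    """Mate founders to produce full-sib families of clonal offspring.

    Each offspring haplotype is a recombinant mosaic of one parent's two
    haplotypes with Poisson crossovers placed uniformly on the genetic map.
    Returns ``(HaplotypeSet, pedigree)`` with pedigree columns
    ``clone_id, mother, father, family``.
    """
    rng = split_rng(seed, "crosses")
    sample_index = {s: i for i, s in enumerate(founders.samples)}
    for m, f, _ in design.families:
        if m not in sample_index or f not in sample_index:
            raise KeyError(f"parent {m if m not in sample_index else f} not among founders")

    chroms = vt.chromosomes()
    chrom_idx = {c: np.where(vt.chrom_mask(c))[0] for c in chroms}
    # genetic coordinates per chromosome (cM) for crossover placement
    chrom_cm = {c: gmap.interpolate(c, vt.pos[chrom_idx[c]]) for c in chroms}
    chrom_len_cm = {
        c: float(gmap.table.loc[gmap.table["chrom"] == c, "cum_cM"].max()) for c in chroms
    }

    def meiosis(parent: str) -> np.ndarray:
        i = sample_index[parent]
        pair = founders.haplotypes[2 * i : 2 * i + 2]
        out = np.empty(vt.n_variants, dtype=np.int8)
        for c in chroms:
            idx = chrom_idx[c]
            total_cm = chrom_len_cm[c]
            k = rng.poisson(total_cm / 100.0)
            start = int(rng.integers(2))
            if k == 0:
                out[idx] = pair[start, idx]
            else:
                bp = np.sort(rng.uniform(0, total_cm, k))
                seg = np.searchsorted(bp, chrom_cm[c])
                out[idx] = np.where((seg + start) % 2 == 0, pair[0, idx], pair[1, idx])
        return out

    rows, hap_rows, ped = [], [], []
    clone_no = 0
    for fam_no, (mother, father, k) in enumerate(design.families):
        for _ in range(k):
            cid = f"C{clone_no:03d}"
            hap_rows.append(meiosis(mother))
            hap_rows.append(meiosis(father))
            ped.append({"clone_id": cid, "mother": mother, "father": father, "family": fam_no})
            rows.append(cid)
            clone_no += 1
    hs = HaplotypeSet(rows, np.array(hap_rows, dtype=np.int8))
    return hs, pd.DataFrame(ped)


# ---------------------------------------------------------------------------
# Phenology observation process
# ---------------------------------------------------------------------------

def simulate_phenology(
    genotypes: GenotypeMatrix,
    model: TraitModel,
    seed: int,
    n_blocks: int = 5,
    ramets_per_clone: int = 5,
):
    """Simulate ordinal stage observations for clonally replicated genotypes.

    True stage-onset days are ``baseline + genetic value + ramet noise``; the
    environmental variance is scaled so the clone-level heritability of the
    onset day equals the target ``h2``. Visits fall on a grid with gaps drawn
    from ``visit_gap_days``; each visit reports the largest stage whose onset
    has passed, dropped with probability ``missing_visit`` and understated by
    one stage with probability ``reversal_error``.

    Returns ``(PhenologyTable DataFrame, truth onsets DataFrame, genetic values)``.
    """
    rng = split_rng(seed, "phenology", model.trait)
    n_clones = genotypes.n_samples
    dos = genotypes.dosages
    g = np.zeros(n_clones)
    for j, beta in zip(model.causal_idx, model.effects):
        x = dos[:, j]
        x = np.where(np.isnan(x), np.nanmean(x), x)
        g += beta * x
    g = g - g.mean()
    var_g = float(g.var())
    if model.h2 == 0 or var_g == 0:
        g = np.zeros(n_clones)
        sigma_e = model.env_sd_if_no_genetics
    elif model.h2 == 1:
        sigma_e = 0.0
    else:
        sigma_e = float(np.sqrt(var_g * (1 - model.h2) / model.h2))

    baselines = np.asarray(model.stage_baselines, dtype=float)
    n_stages = len(baselines) + 1  # stage 1 = "no change yet"

    obs_rows, truth_rows = [], []
    for c in range(n_clones):
        clone = genotypes.samples[c]
        for rep in range(ramets_per_clone):
            block = rep % n_blocks + 1
            ramet = f"{clone}_r{rep}"
            e = rng.normal(0.0, sigma_e) if sigma_e > 0 else 0.0
            onsets = baselines + g[c] + e  # onset of stages 2..n_stages
            truth_rows.append(
                {"ramet_id": ramet, "clone_id": clone, "block": block,
                 **{f"stage{k + 2}": onsets[k] for k in range(len(onsets))}}
            )
            day = float(np.floor(onsets[0])) - float(rng.choice(model.visit_gap_days)) - 6.0
            end = float(np.ceil(onsets[-1])) + 6.0
            while day <= end:
                iday = int(round(day))
                if rng.random() >= model.missing_visit:
                    stage = 1 + int(np.sum(onsets <= day))
                    if stage > 1 and rng.random() < model.reversal_error:
                        stage -= 1
                    obs_rows.append(
                        {"ramet_id": ramet, "clone_id": clone, "block": block,
                         "julian_day": iday, "trait": model.trait, "stage": stage}
                    )
                day += float(rng.choice(model.visit_gap_days))

    obs = pd.DataFrame(obs_rows)
    truth = pd.DataFrame(truth_rows)
    return obs, truth, g


# ---------------------------------------------------------------------------
# Gene annotation generator
# ---------------------------------------------------------------------------

def random_genes(
    chrom_lengths: dict,
    n_genes: int,
    seed: int,
    min_len: int = 1000,
    max_len: int = 5000,
) -> GeneAnnotation:
    """Place non-overlapping genes of length 1–5 kbp uniformly per chromosome."""
    rng = split_rng(seed, "genes")
    rows = []
    gi = 0
    per_chrom = max(1, n_genes // max(len(chrom_lengths), 1))
    for chrom, L in chrom_lengths.items():
        taken: list = []
        attempts = 0
        while len(taken) < per_chrom and attempts < per_chrom * 200:
            attempts += 1
            length = int(rng.integers(min_len, max_len + 1))
            start = int(rng.integers(1, max(L - length, 2)))
            end = start + length - 1
            if any(s <= end and start <= e for s, e in taken):
                continue
            taken.append((start, end))
        for start, end in sorted(taken):
            rows.append(
                {"gene_id": f"g{gi:04d}", "chrom": chrom, "start": start,
                 "end": end, "strand": "+" if rng.random() < 0.5 else "-"}
            )
            gi += 1
    return GeneAnnotation(pd.DataFrame(rows))
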