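"""Configuration, stage orchestration and provenance for a reproducible run.

Stages mirror the analysis order: synthetic data (or user inputs) →
phenology processing → kinship LMM GWAS → Lindley segmentation → LD decay →
selection scans → integration. Each stage reads its inputs from the run
directory, so stages can be rerun independently; a manifest records the
config hash, seeds and package version, and every output table carries the
config hash in a header comment.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import GeneticMap
from . import assoc, integrate, io_core, localscore, phenology, popgen, synthdata

log = logging.getLogger("slopescan")

__all__ = ["PipelineError", "ConfigError", "load_config", "run_stage", "run_pipeline", "STAGES"]


class PipelineError(RuntimeError):
    pass


class ConfigError(ValueError):
    pass


_SCHEMA = {
    "seed": int,
    "outdir": str,
    "simulate": {
        "N_e": int, "L": int, "n_chromosomes": int, "mu": float, "r": float,
        "n_genes": int, "ramets_per_clone": int, "n_blocks": int,
        "sweep": {"position": int, "s": float, "kind": str, "start_freq": float,
                  "final_freq": float, "chrom": str},
        "trait": {"name": str, "h2": float, "n_causal": int, "causal_at": str,
                  "effect": float, "reversal_error": float, "missing_visit": float},
    },
    "inputs": {"vcf": str, "gff3": str, "map": str, "phenology": str, "covariates": str},
    "filter": {"maf_min": float, "hwe_p_min": float, "max_missing": float,
               "het_excess_fdr": float},
    "traits": list,
    "gwas": {"per_snp_lambda": bool, "kinship_flavor": str},
    "localscore": {"xi": float, "alpha": float, "n_null": int, "method": str,
                   "block_len": int},
    "ldscan": {"thin_to": int, "window_bp": int},
    "selscan": {"maf_min": float, "cutoff": float, "bins": int, "trunc_policy": str,
                "h12_window": int, "h12_step": int},
    "integrate": {"pad": int, "peak_half_width": int, "pct": float},
}

_DEFAULTS = {
    "seed": 1,
    "outdir": "slopescan_run",
    "simulate": {
        "N_e": 200, "L": 1_000_000, "n_chromosomes": 1, "mu": 2e-7, "r": 2e-7,
        "n_genes": 60, "ramets_per_clone": 5, "n_blocks": 5,
        "trait": {"name": "LS", "h2": 0.4, "n_causal": 1, "causal_at": "random",
                  "effect": 1.0, "reversal_error": 0.02, "missing_visit": 0.02},
    },
    "filter": {"maf_min": 0.05, "hwe_p_min": 1e-6, "max_missing": 0.30,
               "het_excess_fdr": 0.01},
    "traits": ["LS2-17", "LS5-17"],
    "gwas": {"per_snp_lambda": True, "kinship_flavor": "centered"},
    "localscore": {"xi": 2.0, "alpha": 0.05, "n_null": 1000,
                   "method": "ar1_montecarlo", "block_len": 20},
    "ldscan": {"thin_to": 100_000, "window_bp": 50_000},
    "selscan": {"maf_min": 0.05, "cutoff": 0.05, "bins": 50, "trunc_policy": "keep",
                "h12_window": 100, "h12_step": 50},
    "integrate": {"pad": 10_000, "peak_half_width": 10_000, "pct": 0.001},
}


def _check_keys(node, schema, path=""):
    if isinstance(schema, dict):
        if not isinstance(node, dict):
            raise ConfigError(f"expected a mapping at {path or 'top level'}")
        for key, val in node.items():
            if key not in schema:
                raise ConfigError(f"unknown config key {path + key!r}")
            if isinstance(schema[key], dict):
                _check_keys(val, schema[key], path + key + ".")


def _merge(defaults, user):
    out = dict(defaults)
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Load, validate and default-fill a YAML pipeline config."""
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    _check_keys(user, _SCHEMA)
    cfg = _merge(_DEFAULTS, user)
    for k, v in (overrides or {}).items():
        if v is not None:
            cfg[k] = v
    if "inputs" in cfg:
        for name, p in cfg["inputs"].items():
            if not Path(p).exists():
                raise ConfigError(f"input path for {name!r} does not exist: {p}")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash(cfg)} version={__version__}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: Path, stage: str) -> pd.DataFrame:
    if not path.exists():
        raise PipelineError(
            f"missing {path.name}; run stage {stage!r} first"
        )
    return pd.read_csv(path, sep="\t", comment="#")


def _outdir(cfg) -> Path:
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _manifest(cfg, out: Path, stage: str) -> None:
    mpath = out / "manifest.json"
    man = json.loads(mpath.read_text()) if mpath.exists() else {"stages": {}}
    man.update({"config_hash": config_hash(cfg), "seed": cfg["seed"],
                "version": __version__})
    man["stages"][stage] = {"time": time.strftime("%Y-%m-%dT%H:%M:%S")}
    mpath.write_text(json.dumps(man, indent=2))
    (out / "config.effective.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict) -> None:
    """Generate genotypes, genes, map, phenology and truth tables."""
    out = _outdir(cfg)
    sim = cfg["simulate"]
    sweep = None
    if "sweep" in sim:
        sweep = synthdata.SweepSpec(**sim["sweep"])
    scfg = synthdata.SimulationConfig(
        seed=cfg["seed"], N_e=sim["N_e"], L=sim["L"],
        n_chromosomes=sim["n_chromosomes"], mu=sim["mu"], r=sim["r"], sweep=sweep,
    )
    founders, vt, gmap, info = synthdata.simulate_population(scfg)
    design = synthdata.default_cross_design(
        founders.samples, cfg["seed"], n_blocks=sim["n_blocks"],
        ramets_per_clone=sim["ramets_per_clone"],
    )
    offspring, ped = synthdata.make_crosses(founders, vt, gmap, design, cfg["seed"])
    gm = offspring.to_dosages()

    tr = sim["trait"]
    rng = synthdata.split_rng(cfg["seed"], "causal")
    freq = gm.dosages.mean(axis=0) / 2.0
    eligible = np.where((freq > 0.15) & (freq < 0.85))[0]
    if tr["causal_at"] == "sweep" and info["sweep"] is not None:
        target = info["sweep"]["position"]
        causal = [int(eligible[np.argmin(np.abs(vt.pos[eligible] - target))])]
    else:
        causal = sorted(rng.choice(eligible, size=min(tr["n_causal"], len(eligible)),
                                   replace=False).tolist())
    model = synthdata.TraitModel(
        trait=tr["name"], causal_idx=tuple(int(c) for c in causal),
        effects=tuple([tr["effect"]] * len(causal)), h2=tr["h2"],
        reversal_error=tr["reversal_error"], missing_visit=tr["missing_visit"],
    )
    obs, truth, g = synthdata.simulate_phenology(
        gm, model, cfg["seed"], n_blocks=sim["n_blocks"],
        ramets_per_clone=sim["ramets_per_clone"],
    )
    genes = synthdata.random_genes(
        {c: sim["L"] for c in vt.chromosomes()}, sim["n_genes"], cfg["seed"]
    )

    io_core.write_vcf(out / "genotypes.vcf", vt, gm, offspring)
    io_core.write_gff3(out / "genes.gff3", genes)
    io_core.write_genetic_map(out / "map.tsv", gmap)
    obs.to_csv(out / "phenology.csv", index=False)
    truth.to_csv(out / "truth_onsets.csv", index=False)
    ped.to_csv(out / "pedigree.csv", index=False)
    _write_tsv(
        pd.DataFrame({"causal_idx": model.causal_idx,
                      "chrom": vt.chrom[list(model.causal_idx)],
                      "pos": vt.pos[list(model.causal_idx)]}),
        out / "truth_causal.tsv", cfg,
    )
    (out / "sim_info.json").write_text(json.dumps(info, default=str, indent=2))
    _manifest(cfg, out, "simulate")
    log.info("simulate: %d variants, %d clones", vt.n_variants, len(offspring.samples))


def _load_genotypes(cfg):
    out = _outdir(cfg)
    if "inputs" in cfg and "vcf" in cfg["inputs"]:
        path = cfg["inputs"]["vcf"]
    else:
        path = out / "genotypes.vcf"
        if not Path(path).exists():
            raise PipelineError("missing genotypes.vcf; run stage 'simulate' first")
    vt, gm, hs, _ = io_core.read_vcf(str(path))
    f = cfg["filter"]
    vt2, gm2, flog = io_core.filter_variants(
        vt, gm, f["maf_min"], f["hwe_p_min"], f["max_missing"], f["het_excess_fdr"]
    )
    if hs is not None:
        kept = set(zip(vt2.chrom, vt2.pos))
        keep = np.array([(c, p) in kept for c, p in zip(vt.chrom, vt.pos)])
        hs = hs.subset_variants(np.where(keep)[0])
    return vt2, gm2, hs, flog


def _load_map(cfg) -> GeneticMap:
    out = _outdir(cfg)
    path = cfg.get("inputs", {}).get("map", out / "map.tsv")
    if not Path(path).exists():
        raise PipelineError("missing genetic map; run stage 'simulate' first")
    return io_core.read_genetic_map(str(path))


def stage_phenology(cfg: dict) -> None:
    """Transitions, LOESS imputation, clone means, heritability."""
    out = _outdir(cfg)
    path = cfg.get("inputs", {}).get("phenology", out / "phenology.csv")
    if not Path(path).exists():
        raise PipelineError("missing phenology.csv; run stage 'simulate' first")
    obs = pd.read_csv(path)
    td = phenology.transitions_from_stages(obs)
    td = phenology.impute_loess(td)
    catalog = phenology.TraitCatalog.parse(cfg["traits"])
    vals, counts = phenology.clone_summary(td, catalog)
    _write_tsv(td, out / "transitions.tsv", cfg)
    _write_tsv(vals.reset_index(), out / "trait_values.tsv", cfg)

    vt, gm, hs, _ = _load_genotypes(cfg)
    K = assoc.compute_kinship(gm, "standardized")
    herit = []
    for e in catalog.entries:
        sub = td[(td["trait"] == e["trait"]) & (td["stage"] == e["stage"])]
        ram = sub.rename(columns={"day": "value"})[["clone_id", "value"]].copy()
        ram = ram[ram["clone_id"].isin(gm.samples)]
        if ram.empty:
            continue
        hn = phenology.estimate_heritability(ram, "narrow_marker", kinship=K,
                                             trait=e["name"])
        hb = phenology.estimate_heritability(ram, "broad_cullis", trait=e["name"])
        herit.append({"trait": e["name"], "h2_narrow": hn.h2, "H2_broad": hb.h2,
                      "overfit": hn.overfit or hb.overfit})
    _write_tsv(pd.DataFrame(herit), out / "heritability.tsv", cfg)
    _manifest(cfg, out, "phenology")


def stage_gwas(cfg: dict) -> None:
    """Kinship LMM association for every catalogued trait."""
    out = _outdir(cfg)
    vals = _read_tsv(out / "trait_values.tsv", "phenology").set_index("clone_id")
    vt, gm, hs, _ = _load_genotypes(cfg)
    K = assoc.compute_kinship(gm, cfg["gwas"]["kinship_flavor"])
    for trait in cfg["traits"]:
        if trait not in vals.columns:
            continue
        y = vals[trait].reindex(gm.samples)
        ok = y.notna().to_numpy()
        sub_gm = assoc.GenotypeMatrix(
            [s for s, m in zip(gm.samples, ok) if m], gm.dosages[ok]
        )
        Ksub = assoc.KinshipMatrix(K.values[np.ix_(ok, ok)], K.flavor, sub_gm.samples)
        W = np.ones((ok.sum(), 1))
        track = assoc.lmm_gwas(y.to_numpy()[ok], W, Ksub, sub_gm, vt,
                               per_snp_lambda=cfg["gwas"]["per_snp_lambda"])
        _write_tsv(track, out / f"gwas_{trait}.tsv", cfg)
    _manifest(cfg, out, "gwas")


def stage_localscore(cfg: dict) -> None:
    """Lindley process, per-chromosome thresholds, slope calls per trait."""
    out = _outdir(cfg)
    ls = cfg["localscore"]
    all_slopes = []
    for trait in cfg["traits"]:
        p = out / f"gwas_{trait}.tsv"
        if not p.exists():
            raise PipelineError(f"missing {p.name}; run stage 'gwas' first")
        track = _read_tsv(p, "gwas")
        scores = localscore.lindley_scores(track, ls["xi"])
        thr = localscore.chromosome_threshold(
            track, ls["xi"], ls["alpha"], ls["n_null"], ls["method"],
            seed=cfg["seed"], block_len=ls["block_len"],
        )
        slopes = localscore.call_slopes(scores, thr, trait=trait)
        all_slopes.append(slopes)
        _write_tsv(scores, out / f"lindley_{trait}.tsv", cfg)
        _plot_lindley(scores, thr, out / f"lindley_{trait}.png", trait)
    _write_tsv(pd.concat(all_slopes, ignore_index=True), out / "slopes.tsv", cfg)
    _manifest(cfg, out, "localscore")


def stage_ldscan(cfg: dict) -> None:
    """Pairwise r² in windows and the drift-expectation decay fit."""
    out = _outdir(cfg)
    vt, gm, hs, _ = _load_genotypes(cfg)
    fit = popgen.ld_decay(gm, vt, cfg["ldscan"]["thin_to"],
                          cfg["ldscan"]["window_bp"], seed=cfg["seed"])
    _write_tsv(fit.binned, out / "ld_bins.tsv", cfg)
    summary = pd.DataFrame([{
        "rho_per_bp": fit.rho_per_bp, "n": fit.n, "r2_at_zero": fit.r2_at_zero,
        "half_decay_bp": fit.half_decay_bp, "n_pairs": fit.n_pairs,
    }])
    _write_tsv(summary, out / "ld_fit.tsv", cfg)
    _manifest(cfg, out, "ldscan")


def stage_selscan(cfg: dict) -> None:
    """iHS and H12 selection scans on phased haplotypes."""
    out = _outdir(cfg)
    vt, gm, hs, _ = _load_genotypes(cfg)
    if hs is None:
        raise PipelineError("selection scans need fully phased genotypes")
    gmap = _load_map(cfg)
    sel = cfg["selscan"]
    ihs = popgen.ihs_scan(hs, vt, gmap, sel["maf_min"], sel["cutoff"], sel["bins"],
                          sel["trunc_policy"])
    h12 = popgen.h12_scan(hs, vt, sel["h12_window"], sel["h12_step"])
    pct = cfg["integrate"]["pct"]
    ihs["top_flag"], _ = popgen.top_percentile(ihs["abs_ihs"].to_numpy(), pct)
    h12["top_flag"], _ = popgen.top_percentile(h12["h12"].to_numpy(), pct)
    _write_tsv(ihs, out / "ihs.tsv", cfg)
    _write_tsv(h12, out / "h12.tsv", cfg)
    _manifest(cfg, out, "selscan")


def stage_integrate(cfg: dict) -> None:
    """Candidate genes, peaks, slope-vs-scan enrichment, gene-set overlaps."""
    out = _outdir(cfg)
    slopes = _read_tsv(out / "slopes.tsv", "localscore")
    ihs = _read_tsv(out / "ihs.tsv", "selscan")
    h12 = _read_tsv(out / "h12.tsv", "selscan")
    genes_path = cfg.get("inputs", {}).get("gff3", out / "genes.gff3")
    if not Path(genes_path).exists():
        raise PipelineError("missing gene annotation; run stage 'simulate' first")
    genes = io_core.read_gff3(str(genes_path))
    vt, gm, _, _ = _load_genotypes(cfg)
    chrom_lengths = {c: int(cfg["simulate"]["L"]) for c in vt.chromosomes()}

    pad = cfg["integrate"]["pad"]
    iv = integrate.extend_intervals(slopes, chrom_lengths, pad) if len(slopes) else \
        pd.DataFrame(columns=["trait", "chrom", "start", "end", "pad"])
    assign, gene_counts = integrate.features_in(iv, genes)
    _write_tsv(assign, out / "candidate_genes.tsv", cfg)
    _write_tsv(
        pd.DataFrame([{"trait": t, "n_slopes": int((slopes["trait"] == t).sum()),
                       "n_genes": gene_counts.get(t, 0)}
                      for t in cfg["traits"]]),
        out / "trait_summary.tsv", cfg,
    )

    enrich_rows = []
    for label, scan, col in (("ihs", ihs, "abs_ihs"), ("h12", h12, "h12")):
        scan_ok = scan.dropna(subset=[col])
        universe = set(zip(scan_ok["chrom"], scan_ok["pos"]))
        top = set(zip(scan_ok.loc[scan_ok["top_flag"], "chrom"],
                      scan_ok.loc[scan_ok["top_flag"], "pos"]))
        peaks = integrate.find_peaks(scan_ok, col, cfg["integrate"]["peak_half_width"],
                                     cfg["integrate"]["pct"])
        _write_tsv(peaks, out / f"peaks_{label}.tsv", cfg)
        for trait in cfg["traits"]:
            sub_iv = iv[iv["trait"] == trait]
            inside = set()
            for _, r in sub_iv.iterrows():
                m = (scan_ok["chrom"] == r["chrom"]) & \
                    (scan_ok["pos"] >= r["start"]) & (scan_ok["pos"] <= r["end"])
                inside |= set(zip(scan_ok.loc[m, "chrom"], scan_ok.loc[m, "pos"]))
            if universe:
                res = integrate.hypergeom_enrichment(universe, top, inside,
                                                     trait=trait, source=label)
                enrich_rows.append(vars(res))
    _write_tsv(pd.DataFrame(enrich_rows), out / "enrichment.tsv", cfg)

    gene_sets = {
        t: set(assign.loc[assign["trait"] == t, "feature"]) for t in cfg["traits"]
    }
    ov = integrate.set_overlaps(gene_sets)
    ov = ov.assign(labels=ov["labels"].apply(lambda l: "+".join(l)),
                   members=ov["members"].apply(",".join))
    _write_tsv(ov, out / "gene_overlaps.tsv", cfg)
    _manifest(cfg, out, "integrate")


def _plot_lindley(scores, thresholds, path, trait) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    for c in scores["chrom"].unique():
        sub = scores[scores["chrom"] == c]
        ax.plot(sub["pos"], sub["lindley"], lw=0.8, label=str(c))
        if c in thresholds:
            ax.axhline(thresholds[c], color="red", lw=0.8)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("Lindley score")
    ax.set_title(trait)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


STAGES = {
    "simulate": stage_simulate,
    "phenology": stage_phenology,
    "gwas": stage_gwas,
    "localscore": stage_localscore,
    "ldscan": stage_ldscan,
    "selscan": stage_selscan,
    "integrate": stage_integrate,
}


def run_stage(name: str, cfg: dict) -> None:
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}")
    t0 = time.time()
    STAGES[name](cfg)
    log.info("stage %s finished in %.1f s", name, time.time() - t0)


def run_pipeline(cfg: dict) -> Path:
    """Run every stage in order; returns the run directory."""
    for name in STAGES:
        run_stage(name, cfg)
    return _outdir(cfg)
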