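"""Readers/writers for VCF, GFF3 and genetic maps, plus site-level filtering.

Site filters mirror a standard resequencing pipeline for a small outbred
panel: biallelic-only, MAF, exact Hardy–Weinberg, per-site missingness, and
a BH-corrected one-sided heterozygote-excess screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    GeneAnnotation,
    GeneticMap,
    GenotypeMatrix,
    HaplotypeSet,
    VariantTable,
)

__all__ = [
    "VcfParseError",
    "PhaseError",
    "read_vcf",
    "write_vcf",
    "filter_variants",
    "hwe_exact",
    "read_gff3",
    "write_gff3",
    "read_genetic_map",
    "write_genetic_map",
    "constant_rate_map",
]


class VcfParseError(RuntimeError):
    pass


class PhaseError(RuntimeError):
    pass


def read_vcf(path: str, require_phase: bool = False):
    """Read a VCF 4.x file into the shared data model.

    Returns ``(VariantTable, GenotypeMatrix, HaplotypeSet | None, drop_log)``.
    Non-biallelic records are dropped (never split) and logged with reason
    ``non_biallelic``. Haplotypes are returned only when every genotype is
    present and phased; homozygous calls count as trivially phased. With
    ``require_phase`` an unphased heterozygote raises :class:`PhaseError`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # pragma: no cover - depends on htslib message
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    chroms, poss, refs, alts, vids = [], [], [], [], []
    dosage_rows = []
    hap_rows = []
    phased_ok = True
    dropped = []

    for lineno, var in enumerate(vcf, start=1):
        try:
            alt = var.ALT
        except Exception as exc:
            raise VcfParseError(f"malformed VCF record at data line {lineno}") from exc
        if len(alt) != 1:
            dropped.append((var.CHROM, var.POS, "non_biallelic"))
            continue
        gts = var.genotypes  # [[a, b, phased], ...]
        dos = np.empty(len(samples))
        haps = np.empty((len(samples), 2), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                dos[i] = np.nan
                phased_ok = False
                continue
            dos[i] = a + b
            haps[i, 0], haps[i, 1] = a, b
            if a != b and not g[2]:
                if require_phase:
                    raise PhaseError(
                        f"unphased heterozygote at {var.CHROM}:{var.POS} "
                        f"sample {samples[i]}"
                    )
                phased_ok = False
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(alt[0])
        vids.append(var.ID or f"{var.CHROM}_{var.POS}")
        dosage_rows.append(dos)
        hap_rows.append(haps)

    n_var = len(poss)
    vt = VariantTable(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.array(vids, dtype=object),
    )
    vt.validate()
    dosages = (
        np.array(dosage_rows).T if n_var else np.empty((len(samples), 0))
    )
    gm = GenotypeMatrix(samples, dosages)
    hs = None
    if phased_ok and n_var:
        h = np.array(hap_rows)  # (n_var, n_samples, 2)
        hs = HaplotypeSet(samples, h.transpose(1, 2, 0).reshape(2 * len(samples), n_var))
    drop_log = pd.DataFrame(dropped, columns=["chrom", "pos", "reason"])
    return vt, gm, hs, drop_log


def write_vcf(path: str, vt: VariantTable, gm: GenotypeMatrix, hs: HaplotypeSet | None = None) -> None:
    """Write a minimal VCF 4.2 with GT fields; phased bars when haplotypes given."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in vt.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(vt.n_variants):
            fields = [
                str(vt.chrom[j]),
                str(vt.pos[j]),
                str(vt.vid[j]),
                str(vt.ref[j]),
                str(vt.alt[j]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            for i in range(gm.n_samples):
                if hs is not None:
                    a = hs.haplotypes[2 * i, j]
                    b = hs.haplotypes[2 * i + 1, j]
                    gt = f"{a}|{b}"
                else:
                    d = gm.dosages[i, j]
                    gt = "./." if np.isnan(d) else {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test (enumeration over heterozygote counts)
# ---------------------------------------------------------------------------

def hwe_exact(n_het: int, n_hom_ref: int, n_hom_alt: int) -> tuple[float, float]:
    """Exact HWE test by enumeration over heterozygote counts.

    Returns ``(p_hwe, p_het_excess)``: the two-sided exact p-value (sum of
    configurations no more probable than the observed one) and the one-sided
    upper-tail p-value for heterozygote excess. Robust at panel sizes around
    one hundred where the chi-square approximation is not.
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0, 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # enumerate P(het = h | allele counts) via the standard recurrence
    h_min = n_rare % 2
    h_vals = list(range(h_min, n_rare + 1, 2))
    # unnormalized probabilities via log factorials for stability
    lf = [math.lgamma(k + 1) for k in range(2 * n + 1)]
    logp = []
    for h in h_vals:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        if hom_c < 0:
            logp.append(-np.inf)
            continue
        lp = (
            h * math.log(2)
            + lf[n]
            - lf[h]
            - lf[hom_r]
            - lf[hom_c]
        )
        logp.append(lp)
    logp = np.array(logp)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs_idx = h_vals.index(n_het)
    p_obs = probs[obs_idx]
    p_hwe = float(np.sum(probs[probs <= p_obs * (1 + 1e-12)]))
    p_excess = float(np.sum(probs[obs_idx:]))
    return min(p_hwe, 1.0), min(p_excess, 1.0)


def _site_counts(dosages: np.ndarray):
    """Genotype counts (hom-ref, het, hom-alt, missing) per site."""
    d = dosages
    miss = np.isnan(d)
    n0 = np.sum(d == 0, axis=0)
    n1 = np.sum(d == 1, axis=0)
    n2 = np.sum(d == 2, axis=0)
    return n0, n1, n2, miss.sum(axis=0)


def filter_variants(
    vt: VariantTable,
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    max_missing: float = 0.30,
    het_excess_fdr: float = 0.01,
):
    """Apply site-level filters, returning retained data and a removal log.

    Rules are applied in order — MAF, exact HWE, missingness, heterozygote
    excess — and each dropped site is logged with its first failing rule.
    The heterozygote-excess exact p-values are BH-corrected across the sites
    that survived the earlier rules, which makes the whole filter idempotent.
    """
    from statsmodels.stats.multitest import multipletests

    if vt.n_variants == 0:
        import warnings

        warnings.warn("filter_variants called on empty input")
        return vt, gm, pd.DataFrame(columns=["chrom", "pos", "reason"])

    n0, n1, n2, n_miss = _site_counts(gm.dosages)
    n_called = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = (n1 + 2 * n2) / (2 * np.maximum(n_called, 1))
    maf = np.minimum(p_alt, 1 - p_alt)
    miss_frac = n_miss / gm.n_samples

    reasons = np.array([None] * vt.n_variants, dtype=object)
    reasons[(maf <= maf_min) | (n_called == 0)] = "maf"

    p_hwe = np.ones(vt.n_variants)
    p_hx = np.ones(vt.n_variants)
    for j in range(vt.n_variants):
        if reasons[j] is None and n_called[j] > 0:
            p_hwe[j], p_hx[j] = hwe_exact(int(n1[j]), int(n0[j]), int(n2[j]))
    mask = (reasons == None) & (p_hwe < hwe_p_min)  # noqa: E711
    reasons[mask] = "hwe"

    mask = (reasons == None) & (miss_frac > max_missing)  # noqa: E711
    reasons[mask] = "missingness"

    cand = np.where(reasons == None)[0]  # noqa: E711
    if len(cand):
        rej, _, _, _ = multipletests(p_hx[cand], alpha=het_excess_fdr, method="fdr_bh")
        reasons[cand[rej]] = "het_excess"

    keep = reasons == None  # noqa: E711
    log = pd.DataFrame(
        {
            "chrom": vt.chrom[~keep],
            "pos": vt.pos[~keep],
            "reason": reasons[~keep],
        }
    )
    return vt.subset(keep), gm.subset_variants(keep), log


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str) -> GeneAnnotation:
    """Read gene features from a GFF3 file (other feature types ignored)."""
    import gffutils

    # cheap pre-scan so ID errors carry a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[2] == "gene" and "ID=" not in parts[8]:
                raise ValueError(f"gene feature without ID attribute at line {lineno}")

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": feat.id,
                "chrom": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def write_gff3(path: str, genes: GeneAnnotation) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in genes.table.iterrows():
            fh.write(
                f"{r.chrom}\tslopescan\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID={r.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

def _integrate_rates(grp: pd.DataFrame) -> np.ndarray:
    """Cumulative cM from piecewise-constant local rates; missing rate → 0 cM."""
    pos = grp["pos"].to_numpy(dtype=float)
    rate = grp["rate_cM_per_Mb"].to_numpy(dtype=float)
    cum = np.zeros(len(pos))
    for i in range(1, len(pos)):
        r = rate[i - 1]
        seg = 0.0 if np.isnan(r) else r * (pos[i] - pos[i - 1]) / 1e6
        cum[i] = cum[i - 1] + seg
    return cum


def read_genetic_map(path: str) -> GeneticMap:
    """Read a 4-column TSV map (chrom, pos, rate_cM_per_Mb, cum_cM).

    Cumulative positions are recomputed by integrating the local rates
    between consecutive anchors; an interval with missing ("NA") rate
    contributes exactly zero genetic distance.
    """
    t = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = {"chrom", "pos", "rate_cM_per_Mb"}
    if not required.issubset(t.columns):
        raise ValueError(f"genetic map must have columns {sorted(required)}")
    out = []
    for c, grp in t.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
            raise ValueError(f"map positions not increasing on chromosome {c}")
        grp = grp.assign(cum_cM=_integrate_rates(grp))
        out.append(grp[["chrom", "pos", "rate_cM_per_Mb", "cum_cM"]])
    return GeneticMap(pd.concat(out, ignore_index=True))


def write_genetic_map(path: str, gmap: GeneticMap) -> None:
    gmap.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def constant_rate_map(chrom_lengths: dict, rate_cM_per_Mb: float, n_anchors: int = 2) -> GeneticMap:
    """Synthesize a constant-rate map with anchors at 1 and each chromosome end."""
    rows = []
    for c, L in chrom_lengths.items():
        anchors = np.linspace(1, L, n_anchors).astype(np.int64)
        for p in anchors:
            rows.append({"chrom": c, "pos": int(p), "rate_cM_per_Mb": rate_cM_per_Mb})
    t = pd.DataFrame(rows)
    out = []
    for c, grp in t.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        grp = grp.assign(cum_cM=_integrate_rates(grp))
        out.append(grp)
    return GeneticMap(pd.concat(out, ignore_index=True))
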