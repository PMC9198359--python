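"""VCF reading/writing and the site-filter cascade.

Reading goes through cyvcf2; writing emits a minimal VCF v4.2 with GT and
GQ and an ``ANN_CLASS`` INFO key carrying the functional class of each
site (SYN / NONSYN / NONE).  Filters mirror a standard short-read
population-genomics cascade: genotype-quality masking at read time,
near-indel exclusion, depth-quantile trimming, missingness and
polymorphism requirements, and greedy window-based LD pruning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, FilterReport, GenotypeMatrix, MaskSet

__all__ = [
    "read_vcf",
    "write_vcf",
    "filter_cascade",
    "ld_prune",
    "near_indel_mask",
    "EmptyFilterResult",
]


class EmptyFilterResult(Exception):
    """Raised when a filter cascade removes every site."""


# ----------------------------------------------------------------------
# reading / writing
# ----------------------------------------------------------------------

def read_vcf(
    path,
    mask: MaskSet | None = None,
    gq_min: int = 10,
    sample_meta: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Calls with GQ below ``gq_min`` are set missing.  Multi-allelic
    records are dropped (not split), as are indels and sites inside
    ``mask`` intervals.  ``sample_meta`` (columns ``sample, pond, year,
    source``) is joined onto the sample table when given.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, site_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # multi-allelic: removed, not split
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue  # indel
        if mask is not None and mask.contains(var.CHROM, np.array([var.POS]))[0]:
            continue
        gts = var.genotype.array()
        if gts.shape[1] < 3:
            raise ValueError(
                f"non-diploid GT at {var.CHROM}:{var.POS}"
            )
        alleles = gts[:, :2]
        dosage = alleles.clip(min=0).sum(axis=1).astype(np.int8)
        missing = (alleles < 0).any(axis=1)
        if (alleles > 1).any():
            raise ValueError(
                f"malformed record at {var.CHROM}:{var.POS}: allele index > 1 "
                "in a biallelic record"
            )
        gq = var.gt_quals
        if gq is not None and len(gq) == len(sample_ids):
            missing |= (gq >= 0) & (gq < gq_min)
        dosage[missing] = MISSING
        info_depth = var.INFO.get("DP")
        depth = int(info_depth) if info_depth is not None else 0
        ann = var.INFO.get("ANN_CLASS") or "NONE"
        rows.append(dosage)
        site_rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], ann, depth))

    if not site_rows:
        raise ValueError(f"no biallelic SNPs loaded from {path}")
    dosages = np.vstack(rows).T  # sites-major -> samples x sites
    sites = pd.DataFrame(
        site_rows, columns=["chrom", "pos", "ref", "alt", "ann_class", "depth"]
    )
    samples = pd.DataFrame({"sample": sample_ids})
    for col, default in (("pond", ""), ("year", 0), ("source", "")):
        samples[col] = default
    samples["median_depth"] = np.nan
    if sample_meta is not None:
        meta = sample_meta.set_index("sample")
        for col in meta.columns:
            samples[col] = samples["sample"].map(meta[col]).to_numpy()
    return GenotypeMatrix(dosages, sites, samples)


def write_vcf(gm: GenotypeMatrix, path, gq: int = 99, seed: int | None = None) -> None:
    """Write the matrix as an unphased diploid VCF v4.2 (GT:GQ)."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs = list(dict.fromkeys(gm.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if seed is not None:
            fh.write(f"##clonalmap_seed={seed}\n")
        for chrom in contigs:
            end = int(gm.sites.loc[gm.sites["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={end + 1000}>\n")
        fh.write(
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n'
            '##INFO=<ID=ANN_CLASS,Number=1,Type=String,'
            'Description="Functional class: SYN, NONSYN or NONE">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,'
            'Description="Genotype quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids) + "\n"
        )
        sites = gm.sites
        for j in range(gm.n_sites):
            info = (
                f"DP={int(sites['depth'].iat[j])};"
                f"ANN_CLASS={sites['ann_class'].iat[j]}"
            )
            calls = "\t".join(
                f"{gt_of[int(d)]}:{gq}" for d in gm.dosages[:, j]
            )
            fh.write(
                f"{sites['chrom'].iat[j]}\t{int(sites['pos'].iat[j])}\t.\t"
                f"{sites['ref'].iat[j]}\t{sites['alt'].iat[j]}\t.\tPASS\t"
                f"{info}\tGT:GQ\t{calls}\n"
            )


# ----------------------------------------------------------------------
# filters
# ----------------------------------------------------------------------

def near_indel_mask(
    sites: pd.DataFrame, indel_positions: pd.DataFrame, radius_bp: int = 10
) -> np.ndarray:
    """Indices of SNPs within ``radius_bp`` of any indel (|dist| <= radius).

    ``indel_positions`` needs columns ``chrom, pos``; an empty frame
    removes nothing.
    """
    removed = []
    if len(indel_positions) == 0:
        return np.array([], dtype=int)
    by_chrom = {c: g["pos"].to_numpy() for c, g in indel_positions.groupby("chrom")}
    for chrom, grp in sites.groupby("chrom", sort=False):
        ipos = by_chrom.get(chrom)
        if ipos is None:
            continue
        ipos = np.sort(ipos)
        pos = grp["pos"].to_numpy()
        left = np.searchsorted(ipos, pos)
        dist = np.full(len(pos), np.inf)
        ok = left < len(ipos)
        dist[ok] = np.abs(ipos[left[ok]] - pos[ok])
        ok = left > 0
        dist[ok] = np.minimum(dist[ok], np.abs(ipos[left[ok] - 1] - pos[ok]))
        removed.append(grp.index.to_numpy()[dist <= radius_bp])
    if not removed:
        return np.array([], dtype=int)
    return np.sort(np.concatenate(removed))


def filter_cascade(
    gm: GenotypeMatrix,
    depth_quantiles: tuple[float, float] = (0.05, 0.95),
    missing_rate_max: float = 0.5,
    polymorphic_only: bool = True,
    mask: MaskSet | None = None,
    indel_positions: pd.DataFrame | None = None,
    near_indel_radius: int = 10,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the ordered site-filter cascade and record marginal losses.

    Order: near-indel exclusion, masked intervals, depth-quantile trim
    (nearest-rank quantiles; the bottom tail ``depth <= q_lo`` and the
    top tail ``depth > q_hi`` are dropped, so depths 1..100 at 5%/95%
    leave exactly 90 sites), missing-rate cap (a site must be
    genotyped in at least ``1 - missing_rate_max`` of samples), and
    optionally a polymorphism requirement.  Overlapping filters mean
    marginal losses need not be additive.
    """
    report = FilterReport()
    keep = np.ones(gm.n_sites, dtype=bool)

    def record(name: str, new_keep: np.ndarray):
        nonlocal keep
        removed = int((keep & ~new_keep).sum())
        keep = keep & new_keep
        report.add(name, removed, int(keep.sum()))

    if indel_positions is not None:
        hit = near_indel_mask(gm.sites, indel_positions, near_indel_radius)
        new = np.ones(gm.n_sites, dtype=bool)
        new[hit] = False
        record("near_indel", new)

    if mask is not None:
        masked = np.zeros(gm.n_sites, dtype=bool)
        for chrom, grp in gm.sites.groupby("chrom", sort=False):
            masked[grp.index.to_numpy()] = mask.contains(
                chrom, grp["pos"].to_numpy()
            )
        record("masked_regions", ~masked)

    if depth_quantiles is not None:
        depth = gm.sites["depth"].to_numpy(dtype=float)[keep]
        lo_q, hi_q = depth_quantiles
        lo = np.quantile(depth, lo_q, method="inverted_cdf")
        hi = np.quantile(depth, hi_q, method="inverted_cdf")
        all_depth = gm.sites["depth"].to_numpy(dtype=float)
        if lo >= hi:  # degenerate spread (near-constant depth): trim nothing
            record("depth_quantile", (all_depth >= lo) & (all_depth <= hi))
        else:
            record("depth_quantile", (all_depth > lo) & (all_depth <= hi))

    if missing_rate_max is not None:
        record("missing_rate", gm.missing_rate() <= missing_rate_max)

    if polymorphic_only:
        ac, an = gm.allele_counts()
        record("monomorphic", (ac > 0) & (ac < an))

    if not keep.any():
        raise EmptyFilterResult(
            "filter cascade removed all sites: " + repr(report.steps)
        )
    return gm.take_sites(keep), report


def _pairwise_r2(
    x: np.ndarray, y: np.ndarray, min_shared: int = 10
) -> float:
    """Squared Pearson correlation over pairwise-complete calls.

    Pairs sharing fewer than ``min_shared`` calls, or with a
    zero-variance column, are treated as uncorrelated (r2 = 0).
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < min_shared:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    maf_min: float = 0.001,
    missing_max: float = 0.15,
    window_bp: int = 500,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns kept site indices.

    After MAF/missingness pre-filters, a site is kept iff its genotype
    r-squared with every already-kept site within ``window_bp``
    (|pos_i - pos_j| <= window_bp) is at most ``r2_max``.
    """
    if gm.n_sites < 2:
        return np.arange(gm.n_sites)
    maf = gm.minor_allele_frequency()
    eligible = (maf >= maf_min) & (gm.missing_rate() <= missing_max)
    kept: list[int] = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        kept_chrom: list[int] = []
        kept_pos: list[int] = []
        for j, p in zip(idx, pos):
            if not eligible[j]:
                continue
            ok = True
            for kj, kp in zip(reversed(kept_chrom), reversed(kept_pos)):
                if p - kp > window_bp:
                    break
                if _pairwise_r2(gm.dosages[:, kj], gm.dosages[:, j]) > r2_max:
                    ok = False
                    break
            if ok:
                kept_chrom.append(j)
                kept_pos.append(p)
        kept.extend(kept_chrom)
    return np.array(sorted(kept), dtype=int)
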