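"""Sliding-window IBS and divergence-ratio scans.

The focal question: are the two dominant lineages in a pond unusually
similar (or divergent) anywhere in the genome relative to other lineage
pairs?  IBS is computed in overlapping windows (250 kb width, 10 kb step
by default), averaged over all member-level pairs of each clone pair,
and each window's focal-pair IBS is divided by the comparison pair's IBS
to give a ratio: values > 1 mean the comparison clones are more
divergent than the focal pair, < 1 more similar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clonal import CloneMap
from .genotypes import MISSING, GenotypeMatrix

__all__ = ["WindowGrid", "window_ibs", "divergence_ratio", "make_grid"]


@dataclass
class WindowGrid:
    """Per-chromosome window coordinates (1-based inclusive)."""

    windows: pd.DataFrame  # chrom, start, end

    def __len__(self) -> int:
        return len(self.windows)


def make_grid(
    sites: pd.DataFrame, width: int = 250_000, step: int = 10_000
) -> WindowGrid:
    """Windows starting at 1, 1+step, ... spanning each chromosome's sites.

    The last partial window is retained (it is dropped later only if it
    fails the SNP-count minimum).
    """
    rows = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        last = int(grp["pos"].max())
        start = 1
        while start <= last:
            rows.append((chrom, start, start + width - 1))
            start += step
    return WindowGrid(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _pair_site_values(
    gm: GenotypeMatrix, i: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """(per-site IBS value, co-called mask) for one sample pair."""
    di, dj = gm.dosages[i], gm.dosages[j]
    ok = (di != MISSING) & (dj != MISSING)
    vals = 1.0 - np.abs(di.astype(float) - dj.astype(float)) / 2.0
    vals[~ok] = 0.0
    return vals, ok


def window_ibs(
    gm: GenotypeMatrix,
    clones: CloneMap,
    grid: WindowGrid | None = None,
    width: int = 250_000,
    step: int = 10_000,
    min_snps: int = 1000,
    missing_max: float = 0.15,
    exclude_singletons: bool = True,
    min_depth: float = 5.0,
) -> pd.DataFrame:
    """Clone-pair mean IBS per window.

    Samples with median read depth below ``min_depth`` are dropped, then
    singleton and high-missingness sites are removed once from the whole
    analysis subset.  Per window and clone pair, IBS is averaged across
    all member-level cross pairs (a single cross pair's raw value is used
    when a lineage has one member).  Windows with fewer than ``min_snps``
    sites are excluded and reported with reason.

    Returns a long DataFrame: chrom, start, end, n_snps, clone_a,
    clone_b, ibs, n_used (pair-wise co-called site count summed over
    member pairs).
    """
    med = gm.samples["median_depth"].to_numpy(dtype=float)
    keep_samples = ~(med < min_depth)  # NaN medians are kept
    if not keep_samples.all():
        gm = gm.take_samples(np.flatnonzero(keep_samples))

    site_keep = gm.missing_rate() <= missing_max
    if exclude_singletons:
        ac, an = gm.allele_counts()
        site_keep &= np.minimum(ac, an - ac) != 1
    if site_keep.sum() < gm.n_sites:
        gm = gm.take_sites(site_keep)

    if grid is None:
        grid = make_grid(gm.sites, width, step)

    clone_of = clones.assignment
    ids = gm.sample_ids
    clone_list = sorted({clone_of[s] for s in ids if s in clone_of})
    members = {
        c: [k for k, s in enumerate(ids) if clone_of.get(s) == c]
        for c in clone_list
    }

    # per clone-pair: summed per-site values and co-called counts over
    # member cross pairs, then cumulative sums for O(1) window queries
    pos_by_chrom = {
        chrom: grp["pos"].to_numpy()
        for chrom, grp in gm.sites.groupby("chrom", sort=False)
    }
    idx_by_chrom = {
        chrom: grp.index.to_numpy()
        for chrom, grp in gm.sites.groupby("chrom", sort=False)
    }

    pair_sums: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for a_i, ca in enumerate(clone_list):
        for cb in clone_list[a_i + 1:]:
            vals = np.zeros(gm.n_sites)
            cnts = np.zeros(gm.n_sites)
            for i in members[ca]:
                for j in members[cb]:
                    v, ok = _pair_site_values(gm, i, j)
                    vals += v
                    cnts += ok
            pair_sums[(ca, cb)] = (np.cumsum(vals), np.cumsum(cnts))

    rows = []
    for chrom, start, end in grid.windows.itertuples(index=False):
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        gidx = idx_by_chrom[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        n_snps = hi - lo
        if n_snps < min_snps:
            continue
        glo, ghi = gidx[lo], gidx[hi - 1] + 1
        for (ca, cb), (cv, cc) in pair_sums.items():
            vsum = cv[ghi - 1] - (cv[glo - 1] if glo else 0.0)
            csum = cc[ghi - 1] - (cc[glo - 1] if glo else 0.0)
            ibs = vsum / csum if csum > 0 else np.nan
            rows.append((chrom, start, end, n_snps, ca, cb, ibs, int(csum)))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_snps", "clone_a", "clone_b",
                 "ibs", "n_used"],
    )


def divergence_ratio(
    wibs: pd.DataFrame,
    focal_pair: tuple[str, str],
    comparison_pairs: list[tuple[str, str]] | None = None,
    weighted: bool = False,
) -> pd.DataFrame:
    """Genome-wide mean of window-wise IBS(focal) / IBS(comparison).

    Ratios are computed only in windows where both pairs are defined and
    the comparison IBS is nonzero (zero-IBS windows are skipped and
    counted).  The unweighted window mean is the default; ``weighted``
    weights windows by the comparison pair's used-SNP count.
    """
    def key(a, b):
        return (min(a, b), max(a, b))

    tab = wibs.assign(pair=[key(a, b) for a, b in zip(wibs.clone_a, wibs.clone_b)])
    focal = tab[tab.pair == key(*focal_pair)].set_index(["chrom", "start"])
    if focal.empty:
        raise ValueError(f"focal pair {focal_pair} absent from window table")
    if comparison_pairs is None:
        comparison_pairs = sorted(
            {p for p in tab.pair.unique() if p != key(*focal_pair)}
        )

    rows = []
    for comp in comparison_pairs:
        ctab = tab[tab.pair == key(*comp)].set_index(["chrom", "start"])
        joined = focal[["ibs"]].join(
            ctab[["ibs", "n_used"]], how="inner", lsuffix="_focal", rsuffix="_comp"
        ).dropna()
        usable = joined[joined.ibs_comp > 0]
        n_skipped = len(joined) - len(usable)
        if usable.empty:
            rows.append((comp[0], comp[1], np.nan, 0, n_skipped))
            continue
        ratios = usable.ibs_focal / usable.ibs_comp
        if weighted:
            mean = float(np.average(ratios, weights=usable.n_used))
        else:
            mean = float(ratios.mean())
        rows.append((comp[0], comp[1], mean, len(usable), n_skipped))
    out = pd.DataFrame(
        rows, columns=["clone_a", "clone_b", "mean_ratio", "n_windows",
                       "n_skipped_zero"]
    )
    out["more_divergent_than_focal"] = out["mean_ratio"] > 1.0
    return out
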