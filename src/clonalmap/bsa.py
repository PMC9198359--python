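"""Bulk-segregant analysis of male/female pooled sequencing.

Pooled sequencing of phenotypic extremes (here, males versus asexual
females drawn from the same pond) localises QTL as allele-frequency
contrasts between the bulks.  Two layers of binomial noise act on pooled
counts: sampling of individuals into the pool and sampling of reads from
the pool.  The effective depth ``C_eff = C * 2N / (C + 2N)`` is the
information-equivalent depth after both stages; counts are downsampled
to it before testing.  The per-site statistic is the log-likelihood
ratio G on the 2x2 bulk x allele table; G' is its tricube-weighted local
average, with significance from a log-normal null fitted robustly to the
genome-wide G' distribution and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING

__all__ = [
    "PoolCounts",
    "GprimeResult",
    "QTLRegionSet",
    "effective_depth",
    "downsample_counts",
    "g_statistic",
    "tricube_smooth",
    "gprime_scan",
    "call_regions",
    "validate_pools",
    "overlap_test",
]


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------

@dataclass
class PoolCounts:
    """Per-site ref/alt read counts for a high (male) and low (female) bulk."""

    table: pd.DataFrame  # chrom, pos, ref_high, alt_high, ref_low, alt_low
    pool_n_high: int
    pool_n_low: int
    raw_depth: int | None = None

    def __post_init__(self) -> None:
        need = {"chrom", "pos", "ref_high", "alt_high", "ref_low", "alt_low"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"pool count table missing columns {missing}")
        counts = self.table[["ref_high", "alt_high", "ref_low", "alt_low"]]
        if (counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    def depths(self) -> tuple[np.ndarray, np.ndarray]:
        t = self.table
        return (
            (t.ref_high + t.alt_high).to_numpy(),
            (t.ref_low + t.alt_low).to_numpy(),
        )

    def downsampled(self, mode: str = "proportional", seed: int = 0) -> "PoolCounts":
        """Downsample each bulk to its per-site effective depth."""
        rng = np.random.default_rng(seed)
        t = self.table.copy()
        for bulk, pool_n in (("high", self.pool_n_high), ("low", self.pool_n_low)):
            ref = t[f"ref_{bulk}"].to_numpy()
            alt = t[f"alt_{bulk}"].to_numpy()
            raw = ref + alt
            eff = np.round(effective_depth(np.maximum(raw, 1), pool_n)).astype(int)
            new_ref, new_alt = downsample_counts(ref, alt, eff, mode=mode, rng=rng)
            t[f"ref_{bulk}"] = new_ref
            t[f"alt_{bulk}"] = new_alt
        return PoolCounts(t, self.pool_n_high, self.pool_n_low, self.raw_depth)

    def to_tsv(self, path) -> None:
        out = self.table.rename(columns={
            "ref_high": "ref_count_bulk1", "alt_high": "alt_count_bulk1",
            "ref_low": "ref_count_bulk2", "alt_low": "alt_count_bulk2",
        })
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, pool_n_high: int, pool_n_low: int) -> "PoolCounts":
        t = pd.read_csv(path, sep="\t").rename(columns={
            "ref_count_bulk1": "ref_high", "alt_count_bulk1": "alt_high",
            "ref_count_bulk2": "ref_low", "alt_count_bulk2": "alt_low",
        })
        return cls(t, pool_n_high, pool_n_low)


@dataclass
class GprimeResult:
    """Per-site G, G', p and q values plus the fitted null parameters."""

    table: pd.DataFrame  # chrom, pos, g, gprime, p, q
    null_location: float
    null_scale: float


@dataclass
class QTLRegionSet:
    """Significant genomic intervals from one mapping procedure."""

    regions: pd.DataFrame  # chrom, start, end, peak_pos, peak_score
    method: str = "bsa"
    replicate: str | None = None

    def __post_init__(self) -> None:
        cols = {"chrom", "start", "end"}
        if not cols <= set(self.regions.columns):
            raise ValueError(f"region table needs columns {cols}")
        self.regions = (
            self.regions.sort_values(["chrom", "start"]).reset_index(drop=True)
        )
        for chrom, grp in self.regions.groupby("chrom"):
            if (grp["start"].to_numpy()[1:] <= grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping regions within set on {chrom}")

    def __len__(self) -> int:
        return len(self.regions)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.regions.itertuples(index=False):
                fh.write(f"{r.chrom}\t{int(r.start) - 1}\t{int(r.end)}\n")


# ----------------------------------------------------------------------
# depth correction
# ----------------------------------------------------------------------

def effective_depth(raw_depth, pool_n_diploid):
    """Information-equivalent depth of a pooled sample.

    ``C_eff = C * 2N / (C + 2N)`` factors out the double binomial
    sampling of Pool-Seq: it approaches the raw depth when the pool is
    large and saturates at 2N chromosomes when reads are abundant.
    Returns the real value; round to the nearest integer for
    downsampling.
    """
    raw = np.asarray(raw_depth, dtype=float)
    if (raw <= 0).any() if raw.ndim else raw <= 0:
        raise ValueError("raw depth must be positive")
    if pool_n_diploid <= 0:
        raise ValueError("pool size must be positive")
    two_n = 2.0 * pool_n_diploid
    out = raw * two_n / (raw + two_n)
    return out if out.ndim else float(out)


def downsample_counts(ref, alt, eff_depth, mode: str = "proportional", rng=None):
    """Downsample ref/alt counts to the effective depth.

    Proportional mode keeps the observed allele ratio exactly
    (``ref' = round(ref * eff / (ref + alt))``, ``alt' = eff - ref'``);
    hypergeometric mode draws reads without replacement with the given
    seeded generator.  Sites where ``eff`` exceeds the raw depth pass
    through unchanged with a warning.
    """
    ref = np.atleast_1d(np.asarray(ref, dtype=int))
    alt = np.atleast_1d(np.asarray(alt, dtype=int))
    eff = np.atleast_1d(np.asarray(eff_depth, dtype=int))
    eff = np.broadcast_to(eff, ref.shape).copy()
    raw = ref + alt
    if (raw <= 0).any():
        raise ValueError("ref + alt must be positive")
    over = eff > raw
    if over.any():
        warnings.warn(
            f"effective depth exceeds raw depth at {int(over.sum())} sites; "
            "passing counts through unchanged",
            stacklevel=2,
        )
        eff[over] = raw[over]
    if mode == "proportional":
        new_ref = np.round(ref * eff / raw).astype(int)
        new_alt = eff - new_ref
    elif mode == "hypergeometric":
        if rng is None:
            rng = np.random.default_rng(0)
        new_ref = rng.hypergeometric(ref, alt, eff)
        new_alt = eff - new_ref
    else:
        raise ValueError(f"unknown downsampling mode {mode!r}")
    return new_ref, new_alt


def g_statistic(n_hr, n_ha, n_lr, n_la):
    """Log-likelihood-ratio statistic of the 2x2 bulk x allele table.

    ``G = 2 * sum n_i * ln(n_i / e_i)`` with expected counts from the
    table margins; zero cells contribute nothing.  Vectorized over
    sites.
    """
    obs = np.stack(
        [np.asarray(x, dtype=float) for x in (n_hr, n_ha, n_lr, n_la)]
    )
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    scalar = obs.ndim == 1
    obs = obs.reshape(4, -1)
    high = obs[0] + obs[1]
    low = obs[2] + obs[3]
    ref = obs[0] + obs[2]
    alt = obs[1] + obs[3]
    total = high + low
    if (total <= 0).any():
        raise ValueError("table total must be positive")
    exp = np.stack([high * ref, high * alt, low * ref, low * alt]) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / np.where(exp > 0, exp, 1.0)), 0.0)
    g = 2.0 * terms.sum(axis=0)
    g = np.maximum(g, 0.0)  # clip tiny negative rounding residue
    return float(g[0]) if scalar else g


# ----------------------------------------------------------------------
# G' scan
# ----------------------------------------------------------------------

def _tricube_weights(dist: np.ndarray, bandwidth: float) -> np.ndarray:
    w = (1.0 - (np.abs(dist) / bandwidth) ** 3) ** 3
    w[np.abs(dist) > bandwidth] = 0.0
    return w


def tricube_smooth(pos: np.ndarray, values: np.ndarray, window_bp: float) -> np.ndarray:
    """Tricube-kernel local mean with bandwidth ``window_bp / 2``.

    Weights are renormalized to sum to one within each site's window, so
    chromosome edges need no reflection.  A site alone in its window
    keeps its raw value.
    """
    pos = np.asarray(pos, dtype=float)
    values = np.asarray(values, dtype=float)
    half = window_bp / 2.0
    out = np.empty_like(values)
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    for i in range(len(pos)):
        sl = slice(lo[i], hi[i])
        w = _tricube_weights(pos[sl] - pos[i], half)
        s = w.sum()
        out[i] = (w @ values[sl]) / s if s > 0 else values[i]
    return out


def _fit_lognull(gprime: np.ndarray, hampel_k: float = 5.2) -> tuple[float, float]:
    """Robust normal fit to log G' after Hampel-type outlier trimming.

    QTL inflate the right tail of G'; trimming at median +/- k*MAD of
    log G' before estimating location and scale keeps the null fit
    anchored on non-QTL sites.
    """
    lg = np.log(gprime[gprime > 0])
    if len(lg) < 2:
        return float(np.nan), float(np.nan)
    med = np.median(lg)
    mad = stats.median_abs_deviation(lg, scale="normal")
    if mad == 0:
        keep = lg
    else:
        keep = lg[np.abs(lg - med) <= hampel_k * mad]
    return float(np.mean(keep)), float(np.std(keep, ddof=1))


def gprime_scan(
    pool: PoolCounts,
    maf_min: float = 0.15,
    min_total_depth: int = 20,
    min_sample_depth: int = 20,
    window_bp: int = 250_000,
    hampel_k: float = 5.2,
    already_downsampled: bool = False,
    downsample_mode: str = "proportional",
    seed: int = 0,
) -> GprimeResult:
    """G' scan over a pool-count table.

    Counts are first downsampled to the per-bulk effective depth (unless
    ``already_downsampled``).  Sites are kept when the combined-bulk MAF
    exceeds ``maf_min`` and total / per-bulk depths meet their minima.
    G is smoothed to G' per chromosome with a tricube kernel; a one-sided
    p-value comes from the robustly fitted log-normal null and q-values
    from Benjamini-Hochberg.  Chromosomes with fewer than two passing
    sites are skipped.
    """
    if not already_downsampled:
        pool = pool.downsampled(mode=downsample_mode, seed=seed)
    t = pool.table
    d_high, d_low = pool.depths()
    total = d_high + d_low
    alt = (t.alt_high + t.alt_low).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    keep = (
        (maf > maf_min)
        & (total >= min_total_depth)
        & (d_high >= min_sample_depth)
        & (d_low >= min_sample_depth)
    )
    t = t.loc[keep].reset_index(drop=True)
    if t.empty:
        raise ValueError("no sites pass the G' scan filters")

    g = g_statistic(
        t.ref_high.to_numpy(), t.alt_high.to_numpy(),
        t.ref_low.to_numpy(), t.alt_low.to_numpy(),
    )
    gprime = np.full(len(t), np.nan)
    skipped: list[str] = []
    for chrom, grp in t.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            skipped.append(str(chrom))
            continue
        gprime[idx] = tricube_smooth(grp.pos.to_numpy(), g[idx], window_bp)
    ok = np.isfinite(gprime)

    loc, scale = _fit_lognull(gprime[ok], hampel_k)
    p = np.ones(len(t))
    if np.isfinite(loc) and scale > 0:
        pos_g = ok & (gprime > 0)
        p[pos_g] = stats.norm.sf(np.log(gprime[pos_g]), loc=loc, scale=scale)
    q = np.ones(len(t))
    q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    out = t[["chrom", "pos"]].copy()
    out["g"] = g
    out["gprime"] = gprime
    out["p"] = p
    out["q"] = q
    if skipped:
        out.attrs["skipped_chromosomes"] = skipped
    return GprimeResult(out, loc, scale)


def call_regions(
    gp: GprimeResult,
    q_max: float = 0.05,
    merge_gap_bp: int = 250_000,
    method: str = "bsa",
    replicate: str | None = None,
) -> QTLRegionSet:
    """Merge significant sites (q < q_max) into QTL intervals.

    Runs of significant sites are merged across gaps up to
    ``merge_gap_bp``; each region's peak is its maximum-G' site.  An
    empty set is a valid result.
    """
    t = gp.table
    sig = t[t.q < q_max]
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp.pos.to_numpy()
        gprime = grp.gprime.to_numpy()
        block_start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > merge_gap_bp:
                block = slice(block_start, i)
                peak = block_start + int(np.argmax(gprime[block]))
                rows.append((
                    chrom, int(pos[block][0]), int(pos[block][-1]),
                    int(pos[peak]), float(gprime[peak]),
                ))
                block_start = i
    regions = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "peak_pos", "peak_score"]
    )
    return QTLRegionSet(regions, method=method, replicate=replicate)


# ----------------------------------------------------------------------
# validation & overlap
# ----------------------------------------------------------------------

def validate_pools(
    pool: PoolCounts,
    parent_a: np.ndarray,
    parent_c: np.ndarray,
    maf_min: float = 0.05,
) -> dict:
    """Check that the pools behave like an F1 panel of the two parents.

    Reports the fraction of MAF-filtered pool sites at which the parents
    have different genotypes, and the observed mean pooled allele
    frequency within each parental genotype combination against its F1
    expectation ``(g_A + g_C) / 4`` (e.g. 0x2 -> 0.5, 1x1 -> 0.5,
    0x1 -> 0.25).  Sites with a missing parental call are excluded and
    counted.
    """
    t = pool.table
    parent_a = np.asarray(parent_a)
    parent_c = np.asarray(parent_c)
    if len(parent_a) != len(t) or len(parent_c) != len(t):
        raise ValueError("parental genotypes must align with pool sites")
    d_high, d_low = pool.depths()
    total = d_high + d_low
    alt_total = (t.alt_high + t.alt_low).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, alt_total / np.maximum(total, 1), np.nan)
    maf = np.minimum(freq, 1.0 - freq)

    called = (parent_a != MISSING) & (parent_c != MISSING)
    n_missing_parent = int((~called).sum())
    sel = called & (maf > maf_min) & np.isfinite(freq)
    differ = parent_a[sel] != parent_c[sel]
    out = {
        "n_sites": int(sel.sum()),
        "n_missing_parent": n_missing_parent,
        "parent_diff_fraction": float(differ.mean()) if sel.any() else np.nan,
        "classes": {},
    }
    for ga in (0, 1, 2):
        for gc in (0, 1, 2):
            m = sel & (parent_a == ga) & (parent_c == gc)
            if not m.any():
                continue
            out["classes"][(ga, gc)] = {
                "n": int(m.sum()),
                "observed_freq": float(np.mean(freq[m])),
                "expected_freq": (ga + gc) / 4.0,
            }
    return out


def _count_overlaps(set1: QTLRegionSet, set2: QTLRegionSet) -> int:
    by_chrom = {c: g for c, g in set2.regions.groupby("chrom")}
    n = 0
    for r in set1.regions.itertuples(index=False):
        other = by_chrom.get(r.chrom)
        if other is None:
            continue
        if ((other.start <= r.end) & (other.end >= r.start)).any():
            n += 1
    return n


def overlap_test(
    set1: QTLRegionSet,
    set2: QTLRegionSet,
    null_sets: list[QTLRegionSet],
    min_null: int = 20,
) -> dict:
    """Permutation z-test for interval-set overlap.

    The statistic is the number of ``set1`` regions intersecting at
    least one ``set2`` region; ``null_sets`` (one per permutation of the
    mapping that produced ``set1``) give its null distribution.  The
    empirical p uses the add-one rule ``(1 + #null >= obs) / (1 + n)``.
    """
    if len(null_sets) < min_null:
        raise ValueError(f"need at least {min_null} null sets")
    observed = _count_overlaps(set1, set2)
    null = np.array([_count_overlaps(ns, set2) for ns in null_sets], dtype=float)
    sd = null.std(ddof=1)
    z = (observed - null.mean()) / sd if sd > 0 else np.nan
    p = (1.0 + (null >= observed).sum()) / (1.0 + len(null))
    return {
        "observed": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(sd),
        "z": float(z) if np.isfinite(z) else np.nan,
        "p_empirical": float(p),
    }
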