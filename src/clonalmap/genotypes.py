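"""Core genotype containers shared across the analysis stack.

Genotypes are stored as diploid alternate-allele dosages (0, 1, 2) with -1
marking missing calls, in a dense ``int8`` samples x sites matrix.  Site and
sample metadata travel alongside as pandas DataFrames, mirroring how a VCF
carries per-record and per-sample annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "ann_class", "depth"]
SAMPLE_COLUMNS = ["sample", "pond", "year", "source", "median_depth"]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-sites dosage matrix with metadata.

    Parameters
    ----------
    dosages : ndarray of int8, shape (n_samples, n_sites)
        Alternate-allele dosage per call; -1 is missing.
    sites : DataFrame
        One row per site with columns ``chrom, pos, ref, alt, ann_class,
        depth`` (1-based positions, strictly increasing within chromosome).
    samples : DataFrame
        One row per sample with columns ``sample, pond, year, source,
        median_depth``.
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        n_samples, n_sites = self.dosages.shape
        if len(self.samples) != n_samples:
            raise ValueError(
                f"sample table has {len(self.samples)} rows for "
                f"{n_samples} genotype rows"
            )
        if len(self.sites) != n_sites:
            raise ValueError(
                f"site table has {len(self.sites)} rows for "
                f"{n_sites} genotype columns"
            )
        if n_sites == 0:
            raise ValueError("site count must be > 0")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or -1 (missing)")
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on {chrom}"
                )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample"])

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosages != MISSING

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.sites.iloc[index],
            self.samples,
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        """Subset to the given sample indices or ids."""
        if len(index) and isinstance(index[0], str):
            lookup = {s: i for i, s in enumerate(self.samples["sample"])}
            index = [lookup[s] for s in index]
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            self.sites,
            self.samples.iloc[index],
        )

    def sample_index(self, sample_id: str) -> int:
        hits = np.flatnonzero((self.samples["sample"] == sample_id).to_numpy())
        if len(hits) != 1:
            raise KeyError(f"sample {sample_id!r} not found (or duplicated)")
        return int(hits[0])

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele count) over samples."""
        called = self.called()
        d = np.where(called, self.dosages, 0)
        return d.sum(axis=0), 2 * called.sum(axis=0)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-site MAF over called alleles; NaN where nothing is called."""
        ac, an = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        """Per-site fraction of samples with a missing call."""
        return (self.dosages == MISSING).mean(axis=0)


@dataclass
class MaskSet:
    """Excluded genomic intervals, 1-based inclusive per chromosome."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {
            chrom: _normalize(ivals) for chrom, ivals in self.intervals.items()
        }

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorized membership test for 1-based positions."""
        pos = np.asarray(pos)
        out = np.zeros(pos.shape, dtype=bool)
        for start, end in self.intervals.get(chrom, ()):
            out |= (pos >= start) & (pos <= end)
        return out

    @classmethod
    def from_bed(cls, path) -> "MaskSet":
        """Read a BED file (0-based half-open) into 1-based inclusive form."""
        ivals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                ivals.setdefault(chrom, []).append((int(start) + 1, int(end)))
        return cls(ivals)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for start, end in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def _normalize(ivals) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent 1-based inclusive intervals."""
    ivals = sorted((int(a), int(b)) for a, b in ivals)
    merged: list[tuple[int, int]] = []
    for start, end in ivals:
        if start > end:
            raise ValueError(f"interval start {start} > end {end}")
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class FilterReport:
    """Ordered record of a site-filter cascade.

    Each step stores ``(name, sites_removed, sites_remaining)`` in the order
    filters were applied.  Losses are marginal: filters may overlap, so
    successive removed counts need not sum to the total loss.
    """

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, removed: int, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1][2]:
            raise ValueError("remaining site counts must be non-increasing")
        self.steps.append((name, int(removed), int(remaining)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["filter", "sites_removed", "sites_remaining"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
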