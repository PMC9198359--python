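"""Clonal lineage assignment from genome-wide identity-by-state.

In a cyclical parthenogen, field isolates that are asexual copies of one
another differ only by clone-private mutations and genotyping error, so
their pairwise IBS sits near 1 while sexually related individuals sit
well below.  A hard IBS threshold (default 0.965) on the pairwise graph,
closed under single linkage, partitions samples into clonal lineages;
lineages sampled more than once in the wild are "superclones".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "IBSMatrix",
    "CloneMap",
    "pairwise_ibs",
    "assign_clones",
    "shannon_diversity",
    "individual_heterozygosity",
    "pnps",
    "ibs_to_dxy",
]


@dataclass
class IBSMatrix:
    """Symmetric pairwise IBS with per-pair usable-site counts."""

    values: np.ndarray
    n_sites_used: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("IBS matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


@dataclass
class CloneMap:
    """Sample -> clonal-lineage partition with field-abundance context."""

    assignment: dict[str, str]
    members: dict[str, list[str]] = field(default_factory=dict)
    superclones: set[str] = field(default_factory=set)
    composition: pd.DataFrame | None = None  # pond, year, clone, count

    def __post_init__(self) -> None:
        if not self.members:
            self.members = {}
            for s, c in self.assignment.items():
                self.members.setdefault(c, []).append(s)
        covered = {s for mm in self.members.values() for s in mm}
        if covered != set(self.assignment):
            raise ValueError("members must partition the assigned samples")

    def clone_of(self, sample: str) -> str:
        return self.assignment[sample]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s, c, c in self.superclones)
            for s, c in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows, columns=["sample", "clone", "superclone"])


# ----------------------------------------------------------------------

def pairwise_ibs(
    gm: GenotypeMatrix,
    exclude_singletons: bool = True,
    missing_max: float = 0.15,
    min_sites: int = 1,
) -> IBSMatrix:
    """Genome-wide pairwise IBS over co-called sites.

    Per pair, IBS is the mean of ``1 - |d_i - d_j| / 2`` over sites
    called in both samples.  Singleton sites (minor-allele count 1 across
    the samples entering the computation) and sites with missing rate
    above ``missing_max`` are excluded first, mirroring the conventions
    of genome-wide IBS clustering.  Pairs with no co-called sites get NaN.
    """
    if gm.n_samples < 2:
        raise ValueError("pairwise IBS needs at least two samples")
    keep = gm.missing_rate() <= missing_max
    if exclude_singletons:
        ac, an = gm.allele_counts()
        mac = np.minimum(ac, an - ac)
        keep &= mac != 1
    sub = gm.take_sites(keep) if keep.sum() < gm.n_sites else gm

    called = sub.called()
    ind = [
        ((sub.dosages == d) & called).astype(np.float64) for d in (0, 1, 2)
    ]
    calledf = called.astype(np.float64)
    co_called = calledf @ calledf.T
    # site-wise |d_i - d_j| summed per pair, from dosage-class cross counts
    abs_sum = np.zeros_like(co_called)
    for a in range(3):
        for b in range(3):
            w = abs(a - b)
            if w:
                abs_sum += w * (ind[a] @ ind[b].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = 1.0 - abs_sum / (2.0 * co_called)
    ibs[co_called < min_sites] = np.nan
    np.fill_diagonal(ibs, 1.0)
    ibs = (ibs + ibs.T) / 2.0  # exact symmetry
    return IBSMatrix(ibs, co_called.astype(int), sub.sample_ids)


def assign_clones(
    ibs: IBSMatrix,
    threshold: float = 0.965,
    samples: pd.DataFrame | None = None,
) -> CloneMap:
    """Partition samples into clonal lineages at an IBS threshold.

    Pairs with IBS >= threshold are edges; clonal lineages are the
    single-linkage (connected) components, labelled by their
    lexicographically smallest member.  When a sample table with
    ``pond, year, source`` is given, superclone flags (>= 2 wild
    members) and per-pond-year composition are filled in.
    """
    ids = ibs.sample_ids
    n = len(ids)
    adj = np.nan_to_num(ibs.values, nan=-np.inf) >= threshold
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    assignment: dict[str, str] = {}
    for comp in range(n_comp):
        member_ids = sorted(ids[i] for i in range(n) if labels[i] == comp)
        name = member_ids[0]
        for s in member_ids:
            assignment[s] = name

    superclones: set[str] = set()
    composition = None
    if samples is not None:
        meta = samples.set_index("sample")
        counts: dict[str, int] = {}
        for s, c in assignment.items():
            if s in meta.index and meta.loc[s].get("source", "wild") == "wild":
                counts[c] = counts.get(c, 0) + 1
        superclones = {c for c, k in counts.items() if k >= 2}
        rows = []
        for s, c in assignment.items():
            if s in meta.index:
                rows.append((meta.loc[s, "pond"], meta.loc[s, "year"], c))
        composition = (
            pd.DataFrame(rows, columns=["pond", "year", "clone"])
            .value_counts()
            .rename("count")
            .reset_index()
            .sort_values(["pond", "year", "clone"])
            .reset_index(drop=True)
        )
    return CloneMap(assignment, superclones=superclones, composition=composition)


def shannon_diversity(counts) -> float:
    """Shannon's diversity index H = -sum p_i ln p_i over clone counts."""
    counts = np.asarray(list(counts), dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one clone count must be positive")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def individual_heterozygosity(
    gm: GenotypeMatrix, callable_bp: int | None = None
) -> pd.Series:
    """Fraction of called sites heterozygous per sample.

    With ``callable_bp`` the proportion is rescaled to a per-bp rate
    (het sites / callable genome length) instead of a per-SNP proportion.
    """
    called = gm.called()
    het = (gm.dosages == 1).sum(axis=1).astype(float)
    n_called = called.sum(axis=1).astype(float)
    if callable_bp is not None:
        values = het / float(callable_bp)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
        values[n_called == 0] = np.nan
    return pd.Series(values, index=gm.sample_ids, name="heterozygosity")


def pnps(
    gm: GenotypeMatrix,
    clone_members: list[str],
    freq_class: str = "new",
    new_freq_max: float = 0.25,
    shared_freq_tol: float = 0.05,
    opportunity: float = 1.0,
    n_boot: int = 100,
    seed: int = 0,
    max_members: int | None = 8,
) -> dict:
    """Within-clone pN/pS for a polymorphism frequency class.

    Variants segregating among the clone's members are binned by
    within-clone alternate... minor-allele frequency: "new" mutations
    segregate below ``new_freq_max`` (private mutations on one or a few
    copies), "shared" variants near 0.5 (ancestral heterozygosity carried
    by every copy).  pN/pS is the nonsynonymous/synonymous count ratio
    times an opportunity factor (default 1), with a percentile bootstrap
    CI over variants (``n_boot`` resamples).  At most ``max_members``
    members are used (randomly drawn when more are available).
    """
    if len(clone_members) < 2:
        raise ValueError("need at least two clone members")
    if freq_class not in ("new", "shared"):
        raise ValueError(f"unknown frequency class {freq_class!r}")
    rng = np.random.default_rng(seed)
    members = list(clone_members)
    if max_members is not None and len(members) > max_members:
        members = sorted(rng.choice(members, size=max_members, replace=False))
    sub = gm.take_samples(members)
    ac, an = sub.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    minor = np.minimum(freq, 1.0 - freq)
    segregating = (ac > 0) & (ac < an)
    if freq_class == "new":
        in_class = segregating & (minor < new_freq_max)
    else:
        in_class = segregating & (np.abs(minor - 0.5) <= shared_freq_tol)
    ann = sub.sites["ann_class"].to_numpy()
    is_n = in_class & (ann == "NONSYN")
    is_s = in_class & (ann == "SYN")
    n_count, s_count = int(is_n.sum()), int(is_s.sum())
    if s_count == 0:
        return {
            "estimate": np.nan, "ci": (np.nan, np.nan),
            "n_nonsyn": n_count, "n_syn": s_count, "defined": False,
        }
    estimate = opportunity * n_count / s_count

    variant_is_n = ann[in_class] == "NONSYN"
    boots = []
    m = len(variant_is_n)
    for _ in range(n_boot):
        draw = variant_is_n[rng.integers(0, m, size=m)]
        s = int((~draw).sum())
        boots.append(opportunity * int(draw.sum()) / s if s else np.nan)
    boots = np.asarray(boots, dtype=float)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return {
        "estimate": float(estimate), "ci": (float(lo), float(hi)),
        "n_nonsyn": n_count, "n_syn": s_count, "defined": True,
    }


def ibs_to_dxy(ibs: float, n_snps: int, genome_bp: int) -> float:
    """Convert a table-based IBS value to per-bp divergence.

    IBS computed over a polymorphism table has the number of polymorphic
    sites as denominator; rescaling by ``(1 - IBS) * n_snps / genome_bp``
    expresses it per genomic base pair.
    """
    return (1.0 - ibs) * n_snps / genome_bp
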