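"""QTL association in a recombinant F1 panel with permutation thresholds.

An F1 panel between two divergent parents segregates in large linkage
blocks: most informative markers are perfectly correlated within a
block, so association is tested once per "tag" SNP (one representative
per group of identical dosage columns) and propagated to the block.
The per-tag statistic is a likelihood-ratio test from a one-variance-
component mixed model (y = mu + x*beta + g + e, Var(g) = sigma_g^2 * K)
fitted by profiling heritability on the eigenbasis of a genomic
relatedness matrix rebuilt without the focal tag's linkage group, which
avoids proximal contamination of the polygenic term.  Significance
thresholds come from phenotype permutations, with the empirical FDR
computed per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bsa import PoolCounts, QTLRegionSet
from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "F1Panel",
    "TagMap",
    "DosageScore",
    "find_tags",
    "grm",
    "scan",
    "ScanResult",
    "qtl_boundaries",
    "tag_ld",
    "polarize_and_score",
    "dosage_glm",
    "proportion_test",
]


@dataclass
class F1Panel:
    """Recombinant F1 lines: marker dosages plus count phenotypes."""

    genotypes: GenotypeMatrix          # lines x informative markers
    phenotypes: pd.DataFrame           # line, cross, males, total[, embryos, ephippia]

    def __post_init__(self) -> None:
        lines = list(self.phenotypes["line"])
        if lines != self.genotypes.sample_ids:
            self.genotypes = self.genotypes.take_samples(lines)
        bad = self.phenotypes["males"] > self.phenotypes["total"]
        if bad.any():
            raise ValueError("males counted cannot exceed total counted")

    @classmethod
    def from_simulation(cls, gm: GenotypeMatrix, phenotypes: pd.DataFrame) -> "F1Panel":
        lines = phenotypes.loc[phenotypes["cross"] != "parent"]
        return cls(gm.take_samples(list(lines["line"])), lines.reset_index(drop=True))

    @property
    def n_lines(self) -> int:
        return self.genotypes.n_samples

    def male_proportion(self) -> np.ndarray:
        ph = self.phenotypes
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ph.total > 0, ph.males / np.maximum(ph.total, 1), np.nan)


@dataclass
class TagMap:
    """Tag marker -> perfectly linked member markers (panel site indices)."""

    groups: dict[int, np.ndarray]          # tag site index -> member indices
    excluded: np.ndarray                   # markers dropped for missingness
    sites: pd.DataFrame                    # panel site table (for positions)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for tag, members in self.groups.items():
            ms = set(int(m) for m in members)
            if tag not in ms:
                raise ValueError("tag must belong to its own group")
            if seen & ms:
                raise ValueError("tag groups must partition the markers")
            seen |= ms

    @property
    def tags(self) -> np.ndarray:
        return np.array(sorted(self.groups), dtype=int)

    def tags_by_chromosome(self) -> dict[str, np.ndarray]:
        chrom = self.sites["chrom"].to_numpy()
        out: dict[str, list[int]] = {}
        for t in self.tags:
            out.setdefault(chrom[t], []).append(int(t))
        return {c: np.array(v, dtype=int) for c, v in out.items()}

    def propagate(self, per_tag: dict[int, float]) -> dict[int, float]:
        """Copy a tag-level value to every member of its linkage group."""
        out: dict[int, float] = {}
        for tag, members in self.groups.items():
            if tag in per_tag:
                for m in members:
                    out[int(m)] = per_tag[tag]
        return out


def find_tags(panel: F1Panel, missing_max: float = 0.5) -> TagMap:
    """Group markers by identical dosage pattern across lines (up to a
    global ref/alt flip); the group's smallest-position marker is its tag.

    Markers missing in more than ``missing_max`` of lines are excluded
    and counted.  Grouping is per chromosome: physically unlinked markers
    that happen to co-segregate are still distinct linkage blocks.
    """
    gm = panel.genotypes
    if gm.n_sites < 2:
        raise ValueError("need at least two markers")
    miss = gm.missing_rate()
    excluded = np.flatnonzero(miss > missing_max)
    ok = miss <= missing_max

    chrom = gm.sites["chrom"].to_numpy()
    groups: dict[int, np.ndarray] = {}
    buckets: dict[tuple, list[int]] = {}
    for j in np.flatnonzero(ok):
        col = gm.dosages[:, j]
        flip = np.where(col == MISSING, MISSING, 2 - col)
        key = (chrom[j], min(tuple(col), tuple(flip)))
        buckets.setdefault(key, []).append(j)
    pos = gm.sites["pos"].to_numpy()
    for _, members in buckets.items():
        members = np.asarray(members, dtype=int)
        tag = int(members[np.argmin(pos[members])])
        groups[tag] = members
    return TagMap(groups, excluded, gm.sites)


def grm(
    panel: F1Panel, exclude_markers: np.ndarray | None = None
) -> np.ndarray:
    """Additive genomic relatedness matrix from centered dosages.

    ``K = Z Z^T / (2 * sum p_k (1 - p_k))`` with Z the column-centered
    dosage matrix (missing calls imputed to the column mean) and p_k the
    panel allele frequency; ``exclude_markers`` removes the focal tag's
    linkage group before construction.
    """
    gm = panel.genotypes
    if gm.n_samples < 2 or gm.n_sites < 2:
        raise ValueError("GRM needs at least two lines and two markers")
    use = np.ones(gm.n_sites, dtype=bool)
    if exclude_markers is not None and len(exclude_markers):
        use[np.asarray(exclude_markers, dtype=int)] = False
    d = gm.dosages[:, use].astype(float)
    d[d == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    with np.errstate(invalid="ignore"):
        col_sd = np.nanstd(d, axis=0)
    informative = np.isfinite(p) & (p > 0) & (p < 1) & (col_sd > 0)
    if not informative.any():
        raise ValueError("no informative (variable) markers left for the GRM")
    d = d[:, informative]
    p = p[informative]
    col_mean = 2.0 * p
    z = np.where(np.isnan(d), 0.0, d - col_mean)
    denom = 2.0 * np.sum(p * (1.0 - p))
    return (z @ z.T) / denom


# ----------------------------------------------------------------------
# mixed-model scan
# ----------------------------------------------------------------------

def _profile_ll(
    yrot: np.ndarray, xrot: np.ndarray, eigvals: np.ndarray,
    h2_grid: np.ndarray,
) -> np.ndarray:
    """Max profile log-likelihood over the heritability grid.

    ``yrot`` may hold many phenotype columns (observed + permutations);
    returns the per-column maximum over the grid.
    """
    n, n_col = yrot.shape
    best = np.full(n_col, -np.inf)
    for h2 in h2_grid:
        v = h2 * eigvals + (1.0 - h2)
        w = 1.0 / v
        xw = xrot * w[:, None]
        a = xrot.T @ xw                      # p x p
        b = xw.T @ yrot                      # p x n_col
        try:
            beta = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            continue
        resid = yrot - xrot @ beta
        rss = (w[:, None] * resid * resid).sum(axis=0)
        rss = np.maximum(rss, 1e-300)
        ll = -0.5 * (
            n * np.log(2.0 * np.pi * rss / n) + np.log(v).sum() + n
        )
        best = np.maximum(best, ll)
    return best


@dataclass
class ScanResult:
    """Per-tag statistics, per-chromosome empirical FDR, significant set."""

    table: pd.DataFrame         # tag, chrom, pos, stat, fdr
    n_perm: int
    perm_stats: np.ndarray      # n_tags x n_perm (aligned with table rows)
    fallback_tags: list[int] = field(default_factory=list)

    def significant(self, fdr_max: float = 0.05) -> pd.DataFrame:
        return self.table[self.table.fdr <= fdr_max].reset_index(drop=True)


def scan(
    panel: F1Panel,
    tags: TagMap,
    grm_mode: str = "exclude_tag_group",
    n_perm: int = 100,
    seed: int = 0,
    phenotype: str = "male",
    model: str = "mixed",
    h2_grid: np.ndarray | None = None,
) -> ScanResult:
    """Per-tag association scan with chromosome-wise permutation FDR.

    ``grm_mode`` controls proximal-contamination handling: per-tag GRM
    excluding the focal linkage group (default), leave-one-chromosome-out
    (``"loco"``), or a single global GRM (``"global"``).  Phenotypes
    (male proportion by default, ephippial fill rate with
    ``phenotype="fill"``) are permuted across lines ``n_perm`` times --
    count pairs move together, preserving within-line totals -- and the
    empirical FDR at threshold t is the mean permuted exceedance count
    divided by the observed exceedance count, per chromosome, made
    monotone in t.  ``model="regression"`` replaces the mixed model with
    weighted least squares (also the automatic fallback at tags where
    the variance fit degenerates).
    """
    if grm_mode not in ("exclude_tag_group", "loco", "global"):
        raise ValueError(f"unknown grm_mode {grm_mode!r}")
    ph = panel.phenotypes
    if phenotype == "male":
        y = panel.male_proportion()
        weights = ph["total"].to_numpy(dtype=float)
    elif phenotype == "fill":
        y = (ph["embryos"] / ph["ephippia"].clip(lower=1)).to_numpy(dtype=float)
        weights = ph["ephippia"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    ok_lines = np.isfinite(y) & (weights > 0)
    if ok_lines.sum() < 3:
        raise ValueError("need at least three phenotyped lines")
    y = y[ok_lines]
    weights = weights[ok_lines]
    n = len(y)

    rng = np.random.default_rng(seed)
    perm_idx = np.stack([rng.permutation(n) for _ in range(n_perm)])
    ymat = np.column_stack([y] + [y[p] for p in perm_idx])  # n x (1 + n_perm)

    gm = panel.genotypes.take_samples(np.flatnonzero(ok_lines))
    sub_panel = F1Panel(gm, ph.loc[ok_lines].reset_index(drop=True))
    chrom = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    if h2_grid is None:
        h2_grid = np.linspace(0.0, 0.98, 25)

    tag_list = tags.tags
    stats_mat = np.zeros((len(tag_list), 1 + n_perm))
    fallback_tags: list[int] = []

    k_global = None
    if grm_mode == "global" and model == "mixed":
        k_global = grm(sub_panel)
    k_loco: dict[str, np.ndarray] = {}
    if grm_mode == "loco" and model == "mixed":
        for c in np.unique(chrom):
            k_loco[c] = grm(sub_panel, np.flatnonzero(chrom == c))

    ones = np.ones((n, 1))
    for ti, tag in enumerate(tag_list):
        x = gm.dosages[:, tag].astype(float)
        x[x == MISSING] = np.nan
        xf = np.where(np.isfinite(x), x, np.nanmean(x))
        if np.nanstd(xf) == 0:
            continue
        xmat = np.column_stack([ones, xf])

        use_mixed = model == "mixed"
        if use_mixed:
            try:
                if grm_mode == "exclude_tag_group":
                    k = grm(sub_panel, tags.groups[tag])
                elif grm_mode == "loco":
                    k = k_loco[chrom[tag]]
                else:
                    k = k_global
                eigvals, u = np.linalg.eigh(k)
                eigvals = np.maximum(eigvals, 0.0)
                yrot = u.T @ ymat
                x0 = u.T @ ones
                x1 = u.T @ xmat
                ll0 = _profile_ll(yrot, x0, eigvals, h2_grid)
                ll1 = _profile_ll(yrot, x1, eigvals, h2_grid)
                lrt = 2.0 * (ll1 - ll0)
                if not np.all(np.isfinite(lrt)):
                    raise FloatingPointError("non-finite likelihood")
                stats_mat[ti] = np.maximum(lrt, 0.0)
                continue
            except (np.linalg.LinAlgError, FloatingPointError, ValueError):
                fallback_tags.append(int(tag))
                use_mixed = False
        # weighted regression on the observed scale (fallback / explicit)
        stats_mat[ti] = _wls_stat(ymat, xmat, weights)

    table = pd.DataFrame({
        "tag": tag_list,
        "chrom": chrom[tag_list],
        "pos": pos[tag_list],
        "stat": stats_mat[:, 0],
    })
    table["fdr"] = _chromosome_fdr(table, stats_mat[:, 1:])
    return ScanResult(table, n_perm, stats_mat[:, 1:], fallback_tags)


def _wls_stat(ymat: np.ndarray, xmat: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted-LS likelihood-ratio statistic for the marker column."""
    w = weights / weights.mean()
    n = len(w)

    def rss(x: np.ndarray) -> np.ndarray:
        xw = x * w[:, None]
        beta = np.linalg.solve(x.T @ xw, xw.T @ ymat)
        resid = ymat - x @ beta
        return (w[:, None] * resid * resid).sum(axis=0)

    rss0 = rss(xmat[:, :1])
    rss1 = rss(xmat)
    return n * np.log(np.maximum(rss0, 1e-300) / np.maximum(rss1, 1e-300))


def _chromosome_fdr(table: pd.DataFrame, perm: np.ndarray) -> np.ndarray:
    """Empirical FDR per chromosome from permutation statistics.

    For each observed statistic t on a chromosome: mean permuted count of
    statistics >= t divided by the observed count >= t, then made
    monotone (step-up) so a larger statistic never has a larger FDR.
    """
    fdr = np.ones(len(table))
    for _, grp in table.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        obs = grp["stat"].to_numpy()
        pstats = perm[idx]  # tags on chrom x n_perm
        order = np.argsort(-obs)
        raw = np.empty(len(obs))
        for rank, oi in enumerate(order, start=1):
            t = obs[oi]
            mean_exceed = (pstats >= t).sum() / perm.shape[1]
            raw[oi] = mean_exceed / rank
        sorted_raw = raw[order]
        monotone = np.minimum.accumulate(sorted_raw[::-1])[::-1]
        out = np.empty_like(monotone)
        out[np.argsort(-obs)] = monotone
        fdr[idx] = np.minimum(out, 1.0)
    return fdr


# ----------------------------------------------------------------------
# boundaries, LD, dosage scoring
# ----------------------------------------------------------------------

def _segment_costs(pos: np.ndarray) -> np.ndarray:
    """cost[i, j] = within-segment sum of squared deviations of pos[i..j]."""
    n = len(pos)
    pref = np.concatenate([[0.0], np.cumsum(pos)])
    pref2 = np.concatenate([[0.0], np.cumsum(pos.astype(float) ** 2)])
    cost = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = pref[j + 1] - pref[i]
            s2 = pref2[j + 1] - pref2[i]
            m = j - i + 1
            cost[i, j] = max(s2 - s * s / m, 0.0)
    return cost


def _optimal_segmentation(pos: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Dynamic-programming optimal k-segmentation of sorted positions."""
    n = len(pos)
    cost = _segment_costs(pos)
    dp = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            for i in range(kk - 1, j):
                c = dp[kk - 1, i] + cost[i, j - 1]
                if c < dp[kk, j]:
                    dp[kk, j] = c
                    back[kk, j] = i
    bounds = []
    j = n
    for kk in range(k, 0, -1):
        i = back[kk, j]
        bounds.append((i, j - 1))
        j = i
    return bounds[::-1]


def _segmentation_bic(pos: np.ndarray, segments, min_sd: float) -> float:
    """Gaussian-mixture BIC with a per-cluster variance floor.

    The floor (``min_sd``, in bp) prevents the exact-fit degeneracy in
    which every point becomes its own zero-variance cluster; clusters
    tighter than the floor gain no further likelihood.
    """
    n = len(pos)
    ll = 0.0
    for i, j in segments:
        seg = pos[i:j + 1]
        m = len(seg)
        var = max(np.var(seg), min_sd ** 2)
        ss = np.sum((seg - seg.mean()) ** 2)
        ll += -0.5 * m * np.log(2 * np.pi * var) - ss / (2 * var)
        ll += m * np.log(m / n)
    k = len(segments)
    n_params = 3 * k - 1  # means, variances, mixing proportions
    return -2.0 * ll + n_params * np.log(n)


def qtl_boundaries(
    significant: pd.DataFrame,
    k_max: int = 10,
    min_sd_bp: float = 10_000.0,
    method: str = "f1_map",
) -> QTLRegionSet:
    """QTL intervals from 1-D clustering of significant tag positions.

    Per chromosome, positions are segmented by an exact dynamic program
    minimizing within-cluster sum of squares for each k = 1..min(k_max,
    n); k is chosen by BIC (variance floored at ``min_sd_bp``).  Each
    cluster's boundaries are the min and max member positions; a single
    tag gives a degenerate interval.  ``significant`` needs columns
    ``chrom, pos`` and optionally ``stat`` (used for the peak).
    """
    if significant.empty:
        return QTLRegionSet(
            pd.DataFrame(columns=["chrom", "start", "end", "peak_pos", "peak_score"]),
            method=method,
        )
    rows = []
    for chrom, grp in significant.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=float)
        stat = grp["stat"].to_numpy() if "stat" in grp else np.ones(len(pos))
        best_bic, best_segments = np.inf, [(0, len(pos) - 1)]
        for k in range(1, min(k_max, len(pos)) + 1):
            segs = _optimal_segmentation(pos, k)
            bic = _segmentation_bic(pos, segs, min_sd_bp)
            if bic < best_bic:
                best_bic, best_segments = bic, segs
        for i, j in best_segments:
            peak = i + int(np.argmax(stat[i:j + 1]))
            rows.append((chrom, int(pos[i]), int(pos[j]),
                         int(pos[peak]), float(stat[peak])))
    return QTLRegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_pos", "peak_score"]),
        method=method,
    )


def tag_ld(panel: F1Panel, tags_a: np.ndarray, tags_b: np.ndarray) -> np.ndarray:
    """r^2 between tag dosage columns over pairwise-complete lines."""
    gm = panel.genotypes
    out = np.full((len(tags_a), len(tags_b)), np.nan)
    for ai, a in enumerate(tags_a):
        xa = gm.dosages[:, int(a)].astype(float)
        for bi, b in enumerate(tags_b):
            xb = gm.dosages[:, int(b)].astype(float)
            ok = (xa != MISSING) & (xb != MISSING)
            if ok.sum() < 2:
                continue
            va, vb = xa[ok], xb[ok]
            if va.std() == 0 or vb.std() == 0:
                continue
            r = np.corrcoef(va, vb)[0, 1]
            out[ai, bi] = r * r
    return out


@dataclass
class DosageScore:
    """Per-line count of male+ alleles summed over a QTL set."""

    per_line: pd.Series                 # line -> total male+ dosage
    qtl_alleles: pd.DataFrame           # chrom, peak_pos, male_plus_allele
    n_skipped: int = 0
    n_unpolarized: int = 0


def polarize_and_score(
    pool: PoolCounts,
    qtl: QTLRegionSet,
    panel: F1Panel,
) -> DosageScore:
    """Polarize each QTL by its bulk frequency contrast and score lines.

    The male+ allele at a QTL peak is the allele at higher frequency in
    the male (high) bulk than in the female (low) bulk; each line's
    score is its summed male+ dosage over all polarizable QTL whose peak
    site is present in the panel.
    """
    t = pool.table.set_index(["chrom", "pos"])
    gm = panel.genotypes
    site_index = {
        (c, p): j
        for j, (c, p) in enumerate(zip(gm.sites["chrom"], gm.sites["pos"]))
    }
    score = np.zeros(gm.n_samples)
    allele_rows = []
    n_skipped = n_unpolarized = 0
    for r in qtl.regions.itertuples(index=False):
        key = (r.chrom, int(r.peak_pos))
        j = site_index.get(key)
        if j is None or key not in t.index:
            n_skipped += 1
            continue
        row = t.loc[key]
        d_high = row.ref_high + row.alt_high
        d_low = row.ref_low + row.alt_low
        if d_high <= 0 or d_low <= 0:
            n_skipped += 1
            continue
        delta = row.alt_high / d_high - row.alt_low / d_low
        if delta == 0:
            n_unpolarized += 1
            allele_rows.append((r.chrom, int(r.peak_pos), "undefined"))
            continue
        male_plus_is_alt = delta > 0
        allele_rows.append(
            (r.chrom, int(r.peak_pos), "alt" if male_plus_is_alt else "ref")
        )
        d = gm.dosages[:, j].astype(float)
        d[d == MISSING] = np.nan
        contrib = d if male_plus_is_alt else 2.0 - d
        score += np.nan_to_num(contrib)
    return DosageScore(
        per_line=pd.Series(score, index=gm.sample_ids, name="male_plus_dosage"),
        qtl_alleles=pd.DataFrame(
            allele_rows, columns=["chrom", "peak_pos", "male_plus_allele"]
        ),
        n_skipped=n_skipped,
        n_unpolarized=n_unpolarized,
    )


def dosage_glm(score: DosageScore, panel: F1Panel) -> dict:
    """Binomial GLM of male counts on total male+ dosage.

    Fits ``(males, total - males) ~ dosage`` by IRLS and reports the
    slope with a likelihood-ratio test against the intercept-only model.
    """
    import statsmodels.api as sm

    ph = panel.phenotypes
    if len(ph) < 3:
        raise ValueError("need at least three phenotyped lines")
    x = score.per_line.reindex(ph["line"]).to_numpy(dtype=float)
    males = ph["males"].to_numpy(dtype=float)
    total = ph["total"].to_numpy(dtype=float)
    ok = np.isfinite(x) & (total > 0)
    x, males, total = x[ok], males[ok], total[ok]
    endog = np.column_stack([males, total - males])

    if np.std(x) == 0:
        return {"slope": np.nan, "lrt": 0.0, "p": 1.0,
                "separation": False, "note": "constant dosage"}
    separation = bool(np.all(males == 0) or np.all(males == total))

    exog1 = sm.add_constant(x)
    fit1 = sm.GLM(endog, exog1, family=sm.families.Binomial()).fit()
    fit0 = sm.GLM(endog, np.ones((len(x), 1)),
                  family=sm.families.Binomial()).fit()
    lrt = 2.0 * (fit1.llf - fit0.llf)
    return {
        "slope": float(fit1.params[1]),
        "lrt": float(max(lrt, 0.0)),
        "p": float(stats.chi2.sf(max(lrt, 0.0), df=1)),
        "separation": separation,
    }


def proportion_test(successes: int, n: int, p0: float = 0.5) -> tuple[float, float]:
    """One-sample proportion test with Yates continuity correction.

    ``chi2 = max(0, |x - n p0| - 1/2)^2 * (1/(n p0) + 1/(n (1 - p0)))``
    with a two-tailed p from the chi-square distribution (1 df).  E.g.
    11 of 14 QTL younger than the genome-wide average gives chi2 = 3.5,
    p ~= 0.061.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be between 0 and n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    dev = max(0.0, abs(successes - n * p0) - 0.5)
    chi2 = dev * dev * (1.0 / (n * p0) + 1.0 / (n * (1.0 - p0)))
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
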