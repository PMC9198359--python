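"""Tag SNPs, GRM, mixed-model scan, boundaries, dosage scoring."""

import numpy as np
import pandas as pd
import pytest

from clonalmap import bsa, f1qtl, sim
from clonalmap.genotypes import MISSING

from conftest import make_gm


def panel_from(dosages, positions=None, chrom="chr1", males=None, total=200):
    dosages = np.asarray(dosages, dtype=np.int8)
    n = dosages.shape[0]
    gm = make_gm(dosages, positions=positions, chrom=chrom,
                 sample_ids=[f"L{i}" for i in range(n)])
    phen = pd.DataFrame({
        "line": gm.sample_ids,
        "cross": "AxC",
        "males": males if males is not None else [50] * n,
        "total": total if np.ndim(total) else [total] * n,
    })
    return f1qtl.F1Panel(gm, phen)


class TestFindTags:
    def test_identical_columns_grouped(self):
        cols = np.array([[0, 0, 1], [1, 1, 2], [2, 2, 0], [1, 1, 1]],
                        dtype=np.int8)
        panel = panel_from(cols)
        tags = f1qtl.find_tags(panel)
        assert len(tags.tags) == 2
        groups = {tuple(sorted(v)) for v in
                  (g.tolist() for g in tags.groups.values())}
        assert (0, 1) in groups

    def test_allele_flip_same_group(self):
        col = np.array([0, 1, 2, 1], dtype=np.int8)
        cols = np.stack([col, 2 - col], axis=1)
        panel = panel_from(cols)
        tags = f1qtl.find_tags(panel)
        assert len(tags.tags) == 1

    def test_cross_chromosome_columns_not_merged(self):
        col = np.array([0, 1, 2, 1], dtype=np.int8)
        cols = np.stack([col, col], axis=1)
        panel = panel_from(cols, chrom=["chr1", "chr2"])
        tags = f1qtl.find_tags(panel)
        assert len(tags.tags) == 2

    def test_tag_count_matches_distinct_recombination_patterns(
            self, f1_panel_sim):
        """Tags = distinct dosage patterns, counted directly from the
        simulated gametes (independent enumeration oracle)."""
        gm, phen, truth = f1_panel_sim
        panel = f1qtl.F1Panel.from_simulation(gm, phen)
        tags = f1qtl.find_tags(panel)
        lines = panel.genotypes
        chrom = lines.sites.chrom.to_numpy()
        distinct = 0
        for c in np.unique(chrom):
            block = lines.dosages[:, chrom == c]
            flip = 2 - block
            keys = {min(tuple(block[:, j]), tuple(flip[:, j]))
                    for j in range(block.shape[1])}
            distinct += len(keys)
        assert len(tags.tags) == distinct
        assert len(tags.tags) < lines.n_sites / 2

    def test_partition_and_propagation_idempotent(self, f1_panel_sim):
        gm, phen, truth = f1_panel_sim
        panel = f1qtl.F1Panel.from_simulation(gm, phen)
        tags = f1qtl.find_tags(panel)
        members = sorted(m for g in tags.groups.values() for m in g)
        expected = sorted(set(range(panel.genotypes.n_sites))
                          - set(tags.excluded.tolist()))
        assert members == expected
        per_tag = {int(t): float(i) for i, t in enumerate(tags.tags)}
        spread = tags.propagate(per_tag)
        for tag, group in tags.groups.items():
            assert all(spread[int(m)] == per_tag[int(tag)] for m in group)


class TestGRM:
    def test_identical_lines_match_diagonal(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=20).astype(np.int8)
        other = rng.integers(0, 3, size=20).astype(np.int8)
        panel = panel_from(np.stack([base, base, other]))
        k = f1qtl.grm(panel)
        assert k[0, 1] == pytest.approx(k[0, 0])

    def test_psd_and_symmetry(self, f1_panel_sim):
        gm, phen, truth = f1_panel_sim
        panel = f1qtl.F1Panel.from_simulation(gm, phen)
        k = f1qtl.grm(panel)
        assert np.allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() >= -1e-8

    def test_exclusion_equals_direct_rebuild(self):
        rng = np.random.default_rng(1)
        dosages = rng.integers(0, 3, size=(12, 10)).astype(np.int8)
        panel = panel_from(dosages)
        k_excl = f1qtl.grm(panel, exclude_markers=[3])
        # independent reconstruction from the other 9 columns
        d = np.delete(dosages.astype(float), 3, axis=1)
        p = d.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        z = d[:, keep] - 2 * p[keep]
        expected = z @ z.T / (2 * np.sum(p[keep] * (1 - p[keep])))
        assert np.allclose(k_excl, expected)

    def test_zero_variance_panel_errors(self):
        panel = panel_from(np.ones((4, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            f1qtl.grm(panel)


class TestScan:
    def test_identical_tag_columns_same_statistic(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 2, size=30).astype(np.int8)
        noise = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
        dosages = np.column_stack([col, noise, col])
        males = rng.binomial(200, 0.2 + 0.2 * col)
        panel = panel_from(dosages, chrom=["chr1"] * 4 + ["chr2"] * 4,
                           males=males)
        tags = f1qtl.find_tags(panel)
        res = f1qtl.scan(panel, tags, model="regression", n_perm=10, seed=0)
        t = res.table.set_index("tag")
        # the two copies of `col` sit on different chromosomes -> two tags
        stats_by_chrom = {}
        for tag in tags.tags:
            if np.array_equal(panel.genotypes.dosages[:, tag], col):
                stats_by_chrom[t.loc[tag, "chrom"]] = t.loc[tag, "stat"]
        assert len(stats_by_chrom) == 2
        a, b = stats_by_chrom.values()
        assert a == pytest.approx(b)

    def test_null_scan_finds_nothing(self):
        cfg = sim.SimConfig(seed=60, n_sites=1500, n_chromosomes=2,
                            chromosome_length_bp=5_000_000,
                            qtl_spec=[sim.QTL(0, 2_500_000, 0.0)])
        gm, phen, truth = sim.simulate_f1_panel(cfg, 40)
        panel = f1qtl.F1Panel.from_simulation(gm, phen)
        tags = f1qtl.find_tags(panel)
        res = f1qtl.scan(panel, tags, n_perm=50, seed=1)
        assert len(res.significant()) <= 1

    def test_planted_qtl_top_tag_in_its_linkage_group(self, f1_panel_sim):
        gm, phen, truth = f1_panel_sim
        panel = f1qtl.F1Panel.from_simulation(gm, phen)
        tags = f1qtl.find_tags(panel)
        res = f1qtl.scan(panel, tags, n_perm=50, seed=2)
        top = res.table.loc[res.table.stat.idxmax()]
        j = panel.genotypes.sites.index[
            (panel.genotypes.sites.chrom == "chr1")
            & (panel.genotypes.sites.pos == 2_500_000)][0]
        qtl_group = next(g for g in tags.groups.values() if j in g)
        top_group = tags.groups[int(top.tag)]
        # the top tag's dosage column matches the QTL column (up to flip)
        d = panel.genotypes.dosages
        same = (np.array_equal(d[:, int(top.tag)], d[:, j])
                or np.array_equal(2 - d[:, int(top.tag)], d[:, j]))
        assert int(top.tag) in qtl_group or same

    def test_observed_equals_permutation_gives_fdr_near_one(self):
        """Using a permuted phenotype as the observed one, the empirical
        FDR at any attained threshold is ~1 (null-on-null contract)."""
        rng = np.random.default_rng(5)
        dosages = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        males = rng.binomial(200, 0.3, size=30)
        panel = panel_from(dosages, males=males)
        tags = f1qtl.find_tags(panel)
        res = f1qtl.scan(panel, tags, model="regression", n_perm=60, seed=3)
        assert len(res.significant(0.05)) == 0
        assert res.table.fdr.median() > 0.3


class TestBoundaries:
    def test_two_clusters_from_three_positions(self):
        sig = pd.DataFrame({"chrom": ["chr1"] * 3,
                            "pos": [1_000_000, 1_010_000, 5_000_000],
                            "stat": [4.0, 5.0, 6.0]})
        out = f1qtl.qtl_boundaries(sig)
        spans = list(zip(out.regions.start, out.regions.end))
        assert spans == [(1_000_000, 1_010_000), (5_000_000, 5_000_000)]

    def test_identical_positions_one_cluster(self):
        sig = pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [7_000] * 4,
                            "stat": [1.0] * 4})
        out = f1qtl.qtl_boundaries(sig)
        assert len(out) == 1

    def test_chromosomes_never_merged(self):
        sig = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [100, 100],
                            "stat": [1.0, 1.0]})
        out = f1qtl.qtl_boundaries(sig)
        assert len(out) == 2

    def test_matches_exhaustive_segmentation(self):
        """DP segmentation reproduces exhaustive search over all k-splits
        of sorted positions (brute-force oracle, n <= 8)."""
        import itertools
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(10**6, size=8, replace=False)).astype(float)
        for k in (1, 2, 3, 4):
            segs = f1qtl._optimal_segmentation(pos, k)
            dp_cost = sum(np.var(pos[i:j + 1]) * (j - i + 1) for i, j in segs)
            best = np.inf
            for cuts in itertools.combinations(range(1, len(pos)), k - 1):
                bounds = [0, *cuts, len(pos)]
                cost = sum(
                    np.var(pos[bounds[b]:bounds[b + 1]])
                    * (bounds[b + 1] - bounds[b])
                    for b in range(k))
                best = min(best, cost)
            assert dp_cost == pytest.approx(best, rel=1e-9)


class TestTagLD:
    def test_self_and_group_r2_one(self):
        col = np.array([0, 1, 2, 1, 0, 2], dtype=np.int8)
        other = np.array([0, 0, 1, 2, 2, 1], dtype=np.int8)
        panel = panel_from(np.stack([col, 2 - col, other], axis=1))
        r2 = f1qtl.tag_ld(panel, np.array([0]), np.array([0, 1]))
        assert r2[0, 0] == pytest.approx(1.0)
        assert r2[0, 1] == pytest.approx(1.0)  # flipped copy

    def test_independent_chromosomes_null_level(self):
        """Mean r^2 between unlinked markers ~ 1/(n_lines - 1)."""
        rng = np.random.default_rng(12)
        n = 60
        a = rng.integers(0, 2, size=(n, 40)).astype(np.int8)
        b = rng.integers(0, 2, size=(n, 40)).astype(np.int8)
        panel = panel_from(np.column_stack([a, b]),
                           chrom=["chr1"] * 40 + ["chr2"] * 40)
        r2 = f1qtl.tag_ld(panel, np.arange(40), np.arange(40, 80))
        assert np.nanmean(r2) == pytest.approx(1 / (n - 1), rel=0.4)

    def test_zero_variance_flagged_nan(self):
        panel = panel_from(np.array([[0, 1], [0, 2], [0, 0]], dtype=np.int8))
        r2 = f1qtl.tag_ld(panel, np.array([0]), np.array([1]))
        assert np.isnan(r2[0, 0])


class TestDosageScore:
    def make_pool_with_peak(self, sites, peak_idx, male_up=True):
        n = len(sites)
        ah = np.full(n, 50)
        al = np.full(n, 50)
        if male_up:
            ah[peak_idx] = 70
        else:
            al[peak_idx] = 70
        return bsa.PoolCounts(pd.DataFrame({
            "chrom": sites.chrom, "pos": sites.pos,
            "ref_high": 100 - ah, "alt_high": ah,
            "ref_low": 100 - al, "alt_low": al,
        }), pool_n_high=35, pool_n_low=50)

    def test_homozygous_lines_reach_bound(self):
        dosages = np.full((3, 14), 2, dtype=np.int8)
        dosages[1] = 1
        dosages[2, :7] = 0
        panel = panel_from(dosages)
        pool = self.make_pool_with_peak(panel.genotypes.sites,
                                        np.arange(14))
        regions = bsa.QTLRegionSet(pd.DataFrame({
            "chrom": "chr1",
            "start": panel.genotypes.sites.pos,
            "end": panel.genotypes.sites.pos,
            "peak_pos": panel.genotypes.sites.pos,
            "peak_score": 1.0,
        }))
        score = f1qtl.polarize_and_score(pool, regions, panel)
        assert score.per_line["L0"] == 28          # male+ hom at 14 QTL
        assert score.per_line["L1"] == 14

    def test_equal_bulk_frequencies_flagged(self):
        dosages = np.array([[0], [1], [2]], dtype=np.int8)
        panel = panel_from(dosages)
        pool = self.make_pool_with_peak(panel.genotypes.sites, [],
                                        male_up=True)
        regions = bsa.QTLRegionSet(pd.DataFrame({
            "chrom": ["chr1"], "start": [100], "end": [100],
            "peak_pos": [100], "peak_score": [1.0]}))
        score = f1qtl.polarize_and_score(pool, regions, panel)
        assert score.n_unpolarized == 1
        assert (score.per_line == 0).all()

    def test_score_tracks_true_male_probability(self, f1_panel_sim):
        gm, phen, truth = f1_panel_sim
        panel = f1qtl.F1Panel.from_simulation(gm, phen)
        pool = sim.simulate_pools(gm, phen, raw_depth=400, seed=6)
        j = gm.sites.index[(gm.sites.chrom == "chr1")
                           & (gm.sites.pos == 2_500_000)][0]
        regions = bsa.QTLRegionSet(pd.DataFrame({
            "chrom": ["chr1"], "start": [2_400_000], "end": [2_600_000],
            "peak_pos": [2_500_000], "peak_score": [5.0]}))
        score = f1qtl.polarize_and_score(pool, regions, panel)
        from scipy import stats as sps
        lines = phen[phen.cross != "parent"]
        rho = sps.spearmanr(score.per_line[lines.line].to_numpy(),
                            lines.true_male_prob.to_numpy()).statistic
        assert rho > 0.5


class TestDosageGLM:
    def test_constant_dosage_degenerate(self):
        panel = panel_from(np.zeros((4, 3), dtype=np.int8),
                           males=[10, 20, 30, 40])
        score = f1qtl.DosageScore(
            per_line=pd.Series(2.0, index=panel.genotypes.sample_ids),
            qtl_alleles=pd.DataFrame())
        out = f1qtl.dosage_glm(score, panel)
        assert out["lrt"] == 0.0 and out["p"] == 1.0

    def test_positive_slope_recovered(self):
        rng = np.random.default_rng(10)
        n = 40
        dosage = rng.integers(0, 15, size=n).astype(float)
        p = 1 / (1 + np.exp(-(-2.0 + 0.3 * dosage)))
        males = rng.binomial(200, p)
        panel = panel_from(np.zeros((n, 2), dtype=np.int8), males=males)
        score = f1qtl.DosageScore(
            per_line=pd.Series(dosage, index=panel.genotypes.sample_ids),
            qtl_alleles=pd.DataFrame())
        out = f1qtl.dosage_glm(score, panel)
        assert out["slope"] > 0
        assert out["p"] < 0.05

    def test_sign_of_slope(self):
        panel = panel_from(np.zeros((3, 2), dtype=np.int8),
                           males=[20, 80, 20], total=200)
        score = f1qtl.DosageScore(
            per_line=pd.Series([0.0, 2.0, 0.0],
                               index=panel.genotypes.sample_ids),
            qtl_alleles=pd.DataFrame())
        out = f1qtl.dosage_glm(score, panel)
        assert out["slope"] > 0


class TestProportionTest:
    @pytest.mark.parametrize("x,n,chi2", [
        (11, 14, 3.5),        # printed TMRCA test value
        (7, 14, 0.0),         # at the null, continuity correction clips
        (14, 14, 12.0714),    # hand evaluation of the corrected formula
    ])
    def test_yates_chi2(self, x, n, chi2):
        got, p = f1qtl.proportion_test(x, n, 0.5)
        assert got == pytest.approx(chi2, abs=1e-3)
        assert 0 <= p <= 1

    def test_two_tailed_p_value(self):
        chi2, p = f1qtl.proportion_test(11, 14, 0.5)
        assert p == pytest.approx(0.0614, abs=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            f1qtl.proportion_test(5, 0)
        with pytest.raises(ValueError):
            f1qtl.proportion_test(15, 14)
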