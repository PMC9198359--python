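"""Robust kinship estimation, relationship classes, and pedigree assembly."""

import numpy as np
import pandas as pd
import pytest

from clonalmap import clonal, kinship, sim
from clonalmap.genotypes import MISSING

from conftest import make_gm


def kinship_calibration_config(seed=11):
    """Panmictic founders (the regime in which the textbook expectations
    0.5 / 1/3 / 0.25 hold) with clonal, selfed and outcrossed relatives."""
    return sim.SimConfig(
        seed=seed, n_sites=60_000, n_chromosomes=12,
        chromosome_length_bp=1_000_000, n_founder_clones=5,
        clonal_mutation_rate=0.0, founder_divergence=0.0,
        pond_year_design=[
            sim.PondYearBlock("D8", 2016, 2, {name: 1.0})
            for name in ("A", "C", "K2", "K3", "K4")
        ],
        offspring_design=(
            [sim.OffspringSpec(f"self_{i}", "C", None, year=2017)
             for i in range(5)]
            + [sim.OffspringSpec(f"out_{i}", "A", "C", year=2017)
               for i in range(5)]
        ),
    )


def true_pair_class(truth, a, b):
    clone_of = truth.clone_id
    if clone_of[a] == clone_of[b]:
        return "clonal"
    ped = {c: (m, f, k) for c, m, f, k in truth.pedigree}
    for child, other in ((a, b), (b, a)):
        if child in ped and ped[child][2] in ("self", "outcross"):
            m, f, k = ped[child]
            if clone_of.get(other) in (m, f):
                return "PO_self" if k == "self" else "PO_outcross"
    return "other"


class TestKingKinship:
    def test_identical_noninbred_pair_is_half(self):
        # identical genotypes with H het sites, no opposite homozygotes
        row = np.array([0, 1, 2, 1, 0, 1, 2, 1], dtype=np.int8)
        other = np.array([0, 2, 2, 1, 0, 1, 0, 1], dtype=np.int8)
        gm = make_gm(np.stack([row, row, other]), sample_ids=list("abc"))
        pt = kinship.king_kinship(gm, maf_min=0.0)
        pair = pt.pair("a", "b")
        assert pair.kinship == pytest.approx(0.5)
        assert pair.ibs0 == 0.0

    def test_allele_flip_invariance(self, small_population):
        gm, _ = small_population
        sub = gm.take_sites(np.arange(500))
        pt1 = kinship.king_kinship(sub, maf_min=0.0)
        flipped = make_gm(
            np.where(sub.dosages == MISSING, MISSING, 2 - sub.dosages),
            positions=sub.sites.pos.to_numpy(),
            sample_ids=sub.sample_ids,
        )
        pt2 = kinship.king_kinship(flipped, maf_min=0.0)
        assert np.allclose(pt1.table.kinship, pt2.table.kinship, equal_nan=True)
        assert np.allclose(pt1.table.ibs0, pt2.table.ibs0)

    def test_calibration_against_pedigree_expectations(self):
        """Clonal ~0.5, outcrossed PO ~0.25, selfed PO ~1/3, IBS0 ~0
        (analytic oracle: both-het H/2 over (H + H/2) gives 1/3)."""
        gm, truth = sim.simulate_population(kinship_calibration_config())
        pt = kinship.classify_pairs(kinship.king_kinship(gm, maf_min=0.05))
        groups = {"clonal": [], "PO_self": [], "PO_outcross": []}
        mis = 0
        for r in pt.table.itertuples():
            cls = true_pair_class(truth, r.sample_i, r.sample_j)
            if cls in groups:
                groups[cls].append(r.kinship)
                if r.relationship != cls:
                    mis += 1
                assert r.ibs0 < 0.002
        assert all(groups.values()), "need all three relationship classes"
        assert np.mean(groups["clonal"]) == pytest.approx(0.5, abs=0.02)
        assert np.mean(groups["PO_outcross"]) == pytest.approx(0.25, abs=0.02)
        assert np.mean(groups["PO_self"]) == pytest.approx(1 / 3, abs=0.03)
        assert mis == 0


class TestClassifyPairs:
    @pytest.mark.parametrize("kin,ibs0,expected", [
        (0.50, 0.0, "clonal"),
        (0.25, 0.0005, "PO_outcross"),
        (0.33, 0.0005, "PO_self"),
        (0.20, 0.01, "close_relative"),
        (0.01, 0.05, "unrelated"),
    ])
    def test_rules(self, kin, ibs0, expected):
        pt = kinship.PairTable(pd.DataFrame({
            "sample_i": ["a"], "sample_j": ["b"],
            "kinship": [kin], "ibs0": [ibs0], "n_sites": [10_000],
        }))
        out = kinship.classify_pairs(pt)
        assert out.table.relationship.iloc[0] == expected

    def test_low_site_count_unclassified(self):
        pt = kinship.PairTable(pd.DataFrame({
            "sample_i": ["a"], "sample_j": ["b"],
            "kinship": [0.5], "ibs0": [0.0], "n_sites": [10],
        }))
        out = kinship.classify_pairs(pt)
        assert out.table.relationship.iloc[0] == "unclassified"


class TestVerifyPO:
    def test_error_free_trio_passes(self):
        gm, truth = sim.simulate_population(kinship_calibration_config())
        # out_0 is an A x C offspring; find one member of each parent clone
        members = {}
        for s, c in truth.clone_id.items():
            members.setdefault(c, s)
        rep = kinship.verify_po(gm, "out_0", members["A"], members["C"])
        assert rep["conclusive"] and rep["pass"]
        assert rep["inconsistency_rate"] == 0.0

    def test_impossible_genotype_counted(self):
        child = np.zeros(300, dtype=np.int8)
        parent = np.full(300, 2, dtype=np.int8)
        gm = make_gm(np.stack([child, parent, parent]),
                     sample_ids=["kid", "p1", "p2"])
        rep = kinship.verify_po(gm, "kid", "p1", "p2")
        assert rep["inconsistency_rate"] == 1.0
        assert not rep["pass"]

    def test_fixed_difference_heterozygosity_with_genotype_error(self):
        """An AxC F1 is het at parental fixed differences; 1% genotype
        error leaves the observed fraction >= 0.97 (binomial expectation)."""
        cfg = sim.SimConfig(
            seed=21, n_sites=8000, n_founder_clones=2,
            clonal_mutation_rate=0.0, founder_divergence=0.7,
            pond_year_design=[
                sim.PondYearBlock("D8", 2016, 1, {"A": 1.0}),
                sim.PondYearBlock("D8", 2016, 1, {"C": 1.0}),
            ],
            offspring_design=[sim.OffspringSpec("f1", "A", "C")],
        )
        gm, truth = sim.simulate_population(cfg)
        rng = np.random.default_rng(5)
        noisy = gm.dosages.copy()
        flip = rng.random(noisy.shape) < 0.01
        noisy[flip] = rng.integers(0, 3, size=int(flip.sum()))
        gm_noisy = make_gm(noisy, positions=gm.sites.pos.to_numpy(),
                           chrom=gm.sites.chrom.tolist(),
                           sample_ids=gm.sample_ids)
        members = {}
        for s, c in truth.clone_id.items():
            members.setdefault(c, s)
        rep = kinship.verify_po(gm_noisy, "f1", members["A"], members["C"])
        assert rep["n_fixed_diff"] >= 1000
        assert rep["fixed_diff_het_fraction"] >= 0.97

    def test_duo_below_min_sites_inconclusive(self):
        gm = make_gm(np.zeros((2, 50), dtype=np.int8), sample_ids=["a", "b"])
        rep = kinship.verify_po(gm, "a", "b")
        assert not rep["conclusive"]


class TestPedigree:
    def test_three_generations_recovered(self):
        cfg = sim.SimConfig(
            seed=9, n_sites=40_000, n_chromosomes=12,
            chromosome_length_bp=1_000_000, n_founder_clones=2,
            clonal_mutation_rate=0.0, founder_divergence=0.0,
            pond_year_design=[sim.PondYearBlock("D8", 2016, 6,
                                                {"A": 0.5, "C": 0.5})],
            offspring_design=[
                sim.OffspringSpec("F1a", "A", "C", year=2017),
                sim.OffspringSpec("F1b", "A", "C", year=2017),
                sim.OffspringSpec("F2x", "F1a", "F1b", year=2018),
                sim.OffspringSpec("F2s", "F1a", None, year=2018),
            ],
        )
        gm, truth = sim.simulate_population(cfg)
        cmap = clonal.assign_clones(clonal.pairwise_ibs(gm), 0.965, gm.samples)
        pairs = kinship.king_kinship(gm)
        ped = kinship.build_pedigree(cmap, pairs, gm.samples, gm=gm)
        edges = ped.edges_frame().set_index("child")
        label_of = {truth.clone_id[s]: cmap.assignment[s]
                    for s in gm.sample_ids}
        for child, mother, father, kind in truth.pedigree:
            if kind == "clonal":
                continue
            row = edges.loc[label_of[child]]
            assert row.type == kind
            assert {row.mother, row.father} == {label_of[mother],
                                                label_of[father]}
        assert ped.conflicts == []
        assert ped.placeholders == []

    def test_single_sampled_parent_gets_placeholder(self):
        cfg = sim.SimConfig(
            seed=14, n_sites=30_000, n_chromosomes=12,
            chromosome_length_bp=1_000_000, n_founder_clones=3,
            clonal_mutation_rate=0.0, founder_divergence=0.0,
            # K2 (the co-parent) is never sampled
            pond_year_design=[sim.PondYearBlock("D8", 2016, 4,
                                                {"A": 0.5, "C": 0.5})],
            offspring_design=[sim.OffspringSpec("kid", "A", "K2", year=2017)],
        )
        gm, truth = sim.simulate_population(cfg)
        cmap = clonal.assign_clones(clonal.pairwise_ibs(gm), 0.965, gm.samples)
        ped = kinship.build_pedigree(cmap, kinship.king_kinship(gm),
                                     gm.samples, gm=gm)
        assert len(ped.placeholders) == 1
        kid_clone = cmap.assignment["kid"]
        parents = set(ped.graph.predecessors(kid_clone))
        assert any(p.startswith("unsampled_") for p in parents)

    def test_clone_spanning_years_is_one_node(self, small_population):
        gm, truth = small_population
        cmap = clonal.assign_clones(clonal.pairwise_ibs(gm), 0.965, gm.samples)
        ped = kinship.build_pedigree(cmap, kinship.king_kinship(gm),
                                     gm.samples)
        # A and C are sampled in both 2016 and 2017: one node each
        assert len(ped.graph.nodes) == len(cmap.members)


def test_flag_clone_outliers_reports_low_kinship_member():
    """A selfed parent absorbed into its offspring's IBS cluster shows
    depressed median within-clone kinship and is reported, not removed."""
    ids = [f"m{i}" for i in range(4)] + ["parent"]
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            kin = 0.34 if "parent" in (a, b) else 0.5
            rows.append((a, b, kin, 0.0, 10_000))
    pt = kinship.PairTable(pd.DataFrame(
        rows, columns=["sample_i", "sample_j", "kinship", "ibs0", "n_sites"]))
    cmap = clonal.CloneMap({s: "m0" for s in ids})
    out = kinship.flag_clone_outliers(pt, cmap)
    assert out["sample"].tolist() == ["parent"]
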