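"""Robust kinship, relationship classification, and pedigree assembly.

The kinship estimator is the within-family robust estimator popularised
by KING: over co-called sites,

    kinship = (N_het,het - 2 * N_opp) / (N_het(i) + N_het(j))
    IBS0    = N_opp / N_co-called

where N_het,het counts sites heterozygous in both samples and N_opp
counts opposite homozygotes.  In a facultatively sexual population the
(IBS0, kinship) plane separates three parent-offspring-like classes:
clonal copies (kinship ~= 0.5, IBS0 ~= 0), selfed parent-offspring
(~1/3), and outcrossed parent-offspring (~1/4), all with IBS0 near 0;
anything with appreciable IBS0 is at most a close relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .clonal import CloneMap
from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "PairTable",
    "Pedigree",
    "ClassThresholds",
    "king_kinship",
    "classify_pairs",
    "verify_po",
    "build_pedigree",
    "flag_clone_outliers",
]


@dataclass(frozen=True)
class ClassThresholds:
    """Boundaries in the (IBS0, kinship) plane.

    Defaults sit midway between the expected values of adjacent classes:
    0.42 between clonal (0.5) and selfed PO (1/3), 0.29 between selfed
    (1/3) and outcrossed PO (0.25); IBS0 below 0.002 tolerates ~1%
    genotype error in true parent-offspring pairs.
    """

    clonal_kinship_min: float = 0.42
    po_kinship_min: float = 0.15
    self_kinship_min: float = 0.29
    po_ibs0_max: float = 0.002
    related_kinship_min: float = 0.05
    min_sites: int = 100


@dataclass
class PairTable:
    """Per unordered sample pair: kinship, IBS0, sites used, class."""

    table: pd.DataFrame  # columns: sample_i, sample_j, kinship, ibs0, n_sites[, relationship]

    def pair(self, a: str, b: str) -> pd.Series:
        t = self.table
        hit = t[((t.sample_i == a) & (t.sample_j == b))
                | ((t.sample_i == b) & (t.sample_j == a))]
        if hit.empty:
            raise KeyError(f"pair ({a}, {b}) not in table")
        return hit.iloc[0]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def king_kinship(gm: GenotypeMatrix, maf_min: float = 0.05) -> PairTable:
    """Pairwise robust kinship and IBS0 over MAF-filtered sites."""
    if gm.n_samples < 2:
        raise ValueError("kinship needs at least two samples")
    if maf_min > 0:
        keep = gm.minor_allele_frequency() >= maf_min
        gm = gm.take_sites(keep) if keep.sum() < gm.n_sites else gm

    het = (gm.dosages == 1).astype(np.float64)
    hom_ref = (gm.dosages == 0).astype(np.float64)
    hom_alt = (gm.dosages == 2).astype(np.float64)
    called = gm.called().astype(np.float64)

    n_hethet = het @ het.T
    n_opp = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    het_in_co = het @ called.T          # het in row-sample over co-called sites
    denom = het_in_co + het_in_co.T
    co_called = called @ called.T

    with np.errstate(invalid="ignore", divide="ignore"):
        kinship = (n_hethet - 2.0 * n_opp) / denom
        ibs0 = n_opp / co_called
    kinship[denom == 0] = np.nan

    ids = gm.sample_ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append((ids[i], ids[j], kinship[i, j], ibs0[i, j],
                         int(co_called[i, j])))
    return PairTable(pd.DataFrame(
        rows, columns=["sample_i", "sample_j", "kinship", "ibs0", "n_sites"]
    ))


def classify_pairs(
    pairs: PairTable, thresholds: ClassThresholds | None = None
) -> PairTable:
    """Attach a relationship class to every pair passing the site minimum."""
    th = thresholds or ClassThresholds()
    t = pairs.table.copy()

    def rule(row) -> str:
        if row.n_sites < th.min_sites or not np.isfinite(row.kinship):
            return "unclassified"
        if row.kinship > th.clonal_kinship_min:
            return "clonal"
        if row.ibs0 < th.po_ibs0_max and th.po_kinship_min <= row.kinship <= th.clonal_kinship_min:
            return "PO_self" if row.kinship >= th.self_kinship_min else "PO_outcross"
        if row.kinship > th.related_kinship_min:
            return "close_relative"
        return "unrelated"

    t["relationship"] = t.apply(rule, axis=1)
    return PairTable(t)


# ----------------------------------------------------------------------

def verify_po(
    gm: GenotypeMatrix,
    child: str,
    parent1: str,
    parent2: str | None = None,
    max_inconsistency: float = 0.005,
    min_informative: int = 100,
) -> dict:
    """Check Mendelian segregation for a candidate parent-offspring set.

    Reports (a) the trio Mendelian-inconsistency rate (child dosage
    impossible given both parents), (b) for duos the opposite-homozygote
    rate, and (c) when two parents are given, the fraction of child
    heterozygous calls at parental fixed-difference sites (an A x C F1
    should be heterozygous at essentially all of them).
    """
    ci = gm.sample_index(child)
    p1 = gm.sample_index(parent1)
    c = gm.dosages[ci]
    g1 = gm.dosages[p1]
    out: dict = {"child": child, "parent1": parent1, "parent2": parent2}

    if parent2 is None:
        ok = (c != MISSING) & (g1 != MISSING)
        opp = ((c == 0) & (g1 == 2)) | ((c == 2) & (g1 == 0))
        n = int(ok.sum())
        out["n_informative"] = n
        if n < min_informative:
            out["conclusive"] = False
            return out
        rate = float(opp[ok].mean())
        out["opp_hom_rate"] = rate
        out["inconsistency_rate"] = rate
        out["pass"] = rate <= max_inconsistency
        out["conclusive"] = True
        return out

    p2 = gm.sample_index(parent2)
    g2 = gm.dosages[p2]
    ok = (c != MISSING) & (g1 != MISSING) & (g2 != MISSING)

    # allele sets transmissible by each parent: 0->{0}, 1->{0,1}, 2->{1}
    lo = (g1 == 2).astype(np.int8) + (g2 == 2).astype(np.int8)
    hi = (g1 != 0).astype(np.int8) + (g2 != 0).astype(np.int8)
    consistent = (c >= lo) & (c <= hi)
    n = int(ok.sum())
    out["n_informative"] = n
    if n < min_informative:
        out["conclusive"] = False
        return out
    rate = float((~consistent[ok]).mean())
    out["inconsistency_rate"] = rate

    fixed_diff = ok & (((g1 == 0) & (g2 == 2)) | ((g1 == 2) & (g2 == 0)))
    out["n_fixed_diff"] = int(fixed_diff.sum())
    if fixed_diff.any():
        out["fixed_diff_het_fraction"] = float((c[fixed_diff] == 1).mean())
    else:
        out["fixed_diff_het_fraction"] = np.nan
    out["pass"] = rate <= max_inconsistency
    out["conclusive"] = True
    return out


def flag_clone_outliers(
    pairs: PairTable,
    clones: CloneMap,
    lower_kinship: float = 0.42,
) -> pd.DataFrame:
    """Report clone members whose median within-clone kinship falls below
    the clonal cluster's lower bound.

    Such individuals are typically the sexual parent of the lineage (a
    selfed family collapsing into one IBS cluster) or a close relative;
    they are reported as candidates, never removed automatically.
    """
    t = pairs.table
    rows = []
    for clone, members in clones.members.items():
        if len(members) < 3:
            continue
        mset = set(members)
        for s in members:
            kin = t.loc[
                ((t.sample_i == s) & t.sample_j.isin(mset - {s}))
                | ((t.sample_j == s) & t.sample_i.isin(mset - {s})),
                "kinship",
            ].to_numpy()
            if len(kin) and np.nanmedian(kin) < lower_kinship:
                rows.append((clone, s, float(np.nanmedian(kin))))
    return pd.DataFrame(rows, columns=["clone", "sample", "median_kinship"])


# ----------------------------------------------------------------------

@dataclass
class Pedigree:
    """Clone-level pedigree with explicit placeholder parents."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    conflicts: list[str] = field(default_factory=list)

    def add_edge(self, parent: str, child: str, kind: str) -> None:
        self.graph.add_edge(parent, child, type=kind)
        if not nx.is_directed_acyclic_graph(self.graph):
            self.graph.remove_edge(parent, child)
            self.conflicts.append(
                f"edge {parent}->{child} ({kind}) would create a cycle"
            )

    def edges_frame(self) -> pd.DataFrame:
        rows = []
        for child in self.graph.nodes:
            parents = list(self.graph.predecessors(child))
            if not parents:
                continue
            kinds = {self.graph.edges[p, child]["type"] for p in parents}
            kind = kinds.pop() if len(kinds) == 1 else "mixed"
            if kind == "self":
                rows.append((child, parents[0], parents[0], "self"))
            elif len(parents) == 1:
                rows.append((child, parents[0], parents[0], kind))
            else:
                mother, father = sorted(parents)[:2]
                rows.append((child, mother, father, kind))
        return pd.DataFrame(rows, columns=["child", "mother", "father", "type"])

    @property
    def placeholders(self) -> list[str]:
        return [n for n in self.graph.nodes if str(n).startswith("unsampled_")]

    def to_gml(self, path) -> None:
        nx.write_gml(self.graph, str(path))


def aggregate_pairs_by_clone(pairs: PairTable, clones: CloneMap) -> PairTable:
    """Average pair statistics over all member-level cross pairs."""
    t = pairs.table.copy()
    t["clone_i"] = t["sample_i"].map(clones.assignment)
    t["clone_j"] = t["sample_j"].map(clones.assignment)
    t = t[t.clone_i != t.clone_j]
    a = np.minimum(t.clone_i, t.clone_j)
    b = np.maximum(t.clone_i, t.clone_j)
    t = t.assign(clone_a=a, clone_b=b)
    agg = (
        t.groupby(["clone_a", "clone_b"], as_index=False)
        .agg(kinship=("kinship", "mean"), ibs0=("ibs0", "mean"),
             n_sites=("n_sites", "min"))
        .rename(columns={"clone_a": "sample_i", "clone_b": "sample_j"})
    )
    return PairTable(agg)


def build_pedigree(
    clones: CloneMap,
    pairs: PairTable,
    metadata: pd.DataFrame,
    gm: GenotypeMatrix | None = None,
    thresholds: ClassThresholds | None = None,
) -> Pedigree:
    """Greedy multi-year pedigree assembly from classified clone pairs.

    Pair statistics are first averaged to the clone level and classified.
    Each clone is then linked to the parent set with the strongest
    verified parent-offspring support among clones first observed no
    later than itself; a single identified outcross parent gets an
    explicit unsampled co-parent node; PO_self support yields a selfing
    edge.  Conflicting assignments are reported, never silently resolved.
    """
    th = thresholds or ClassThresholds()
    clone_pairs = classify_pairs(aggregate_pairs_by_clone(pairs, clones), th)
    meta = metadata.set_index("sample")

    first_year: dict[str, int] = {}
    abundance: dict[str, int] = {}
    for s, c in clones.assignment.items():
        if s in meta.index:
            year = int(meta.loc[s, "year"])
            first_year[c] = min(first_year.get(c, year), year)
            abundance[c] = abundance.get(c, 0) + 1

    ped = Pedigree()
    for clone, members in clones.members.items():
        ped.graph.add_node(
            clone,
            pond=str(meta.loc[members[0], "pond"]) if members[0] in meta.index else "",
            first_year=first_year.get(clone, 0),
            abundance=abundance.get(clone, 0),
        )

    t = clone_pairs.table

    def po_candidates(clone: str) -> pd.DataFrame:
        hit = t[
            (((t.sample_i == clone) | (t.sample_j == clone))
             & t.relationship.isin(["PO_self", "PO_outcross"]))
        ].copy()
        hit["other"] = np.where(hit.sample_i == clone, hit.sample_j, hit.sample_i)
        return hit

    def support(child: str, parent: str, co_parent: str | None) -> float:
        """Verified-PO support: het-segregation score from genotypes when
        available, else the kinship estimate itself."""
        if gm is None:
            return float(pairs_pair_kinship(child, parent))
        rep_child = clones.members[child][0]
        rep_parent = clones.members[parent][0]
        rep_co = clones.members[co_parent][0] if co_parent else None
        rep = verify_po(gm, rep_child, rep_parent, rep_co)
        if not rep.get("conclusive"):
            return -np.inf
        return 1.0 - rep["inconsistency_rate"]

    def pairs_pair_kinship(a: str, b: str) -> float:
        try:
            return float(clone_pairs.pair(a, b)["kinship"])
        except KeyError:
            return -np.inf

    for clone in sorted(clones.members, key=lambda c: (first_year.get(c, 0), c)):
        cands = po_candidates(clone)
        cands = cands[[first_year.get(o, 0) <= first_year.get(clone, 0)
                       for o in cands["other"]]]
        if cands.empty:
            continue  # founder (no sampled parent)

        selfing = cands[cands.relationship == "PO_self"]
        outcross = cands[cands.relationship == "PO_outcross"]
        if not selfing.empty:
            best = max(selfing["other"], key=lambda p: support(clone, p, None))
            if len(selfing) > 1:
                ped.conflicts.append(
                    f"{clone}: multiple selfing parents supported "
                    f"{sorted(selfing['other'])}; kept {best}"
                )
            ped.add_edge(best, clone, "self")
            continue
        if outcross.empty:
            continue
        parents = sorted(outcross["other"])
        if len(parents) == 1:
            placeholder = f"unsampled_{clone}"
            ped.graph.add_node(placeholder, pond="", first_year=0, abundance=0)
            ped.add_edge(parents[0], clone, "outcross")
            ped.add_edge(placeholder, clone, "outcross")
            continue
        if len(parents) > 2:
            scored = sorted(
                parents,
                key=lambda p: support(clone, p, None),
                reverse=True,
            )
            ped.conflicts.append(
                f"{clone}: >2 outcross parents supported {parents}; "
                f"kept {scored[:2]}"
            )
            parents = sorted(scored[:2])
        ped.add_edge(parents[0], clone, "outcross")
        ped.add_edge(parents[1], clone, "outcross")
    return ped
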