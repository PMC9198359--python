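"""Forward simulation of cyclically parthenogenetic populations.

The generator emulates the sampling structure the downstream analyses
assume: a handful of divergent founder clonal lineages spread over ponds
and years, field samples that are clonal copies (carrying clone-private
heterozygous mutations), selfed or outcrossed offspring produced during
episodic sex, a recombinant F1 panel between two focal parents ("A" and
"C") segregating for planted male-production QTL, and male/female pooled
sequencing with double-binomial read sampling.

Founders are simulated as explicit haplotype pairs so that meiosis can
recombine them; emitted genotypes are unphased dosages.  All randomness
flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SimConfig",
    "QTL",
    "OffspringSpec",
    "PondYearBlock",
    "TruthSet",
    "simulate_population",
    "simulate_f1_panel",
    "simulate_pools",
]


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class QTL:
    """A planted male-production locus: additive effect on the log-odds
    that an offspring develops as male, per copy of the male+ allele."""

    chrom: int
    pos: int
    effect: float


@dataclass(frozen=True)
class PondYearBlock:
    """Sampling design for one pond-year: how many individuals and from
    which clonal lineages (frequencies must sum to 1)."""

    pond: str
    year: int
    sample_size: int
    clone_freqs: dict[str, float]


@dataclass(frozen=True)
class OffspringSpec:
    """A sexually produced individual to include in the sample.

    ``father is None`` or ``father == mother`` denotes selfing (an
    intraclonal cross); otherwise the offspring is an outcross between
    the two named lineages.
    """

    child_id: str
    mother: str
    father: str | None
    pond: str = "D8"
    year: int = 2017


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    Defaults describe a desk-scale version of a multi-pond, multi-year
    survey: 4 founder lineages, 2 chromosomes of 5 Mb carrying 20,000
    SNPs, founder allele frequencies from a Beta law, and clone-private
    heterozygous mutations accumulating at ~0.1% of sites per sampled
    copy.  The crossover rate (5 per chromosome per meiosis) is chosen
    so an F1 panel's ratio of distinct linkage-block patterns to
    informative markers matches the granularity observed in real A x C
    panels (a few percent of markers are distinct "tag" patterns).
    """

    n_chromosomes: int = 2
    chromosome_length_bp: int = 5_000_000
    n_sites: int = 20_000
    founder_freq_beta: tuple[float, float] = (1.0, 1.0)
    founder_divergence: float = 0.0      # F_ST-like drift between founder origins
    n_founder_clones: int = 4
    clonal_mutation_rate: float = 20.0   # expected new het mutations / copy
    nonsyn_fraction: float = 0.5
    crossover_rate: float = 5.0          # expected crossovers / chrom / meiosis
    selfing_rate: float = 0.0
    pond_year_design: list[PondYearBlock] = field(default_factory=list)
    offspring_design: list[OffspringSpec] = field(default_factory=list)
    qtl_spec: list[QTL] = field(default_factory=list)
    baseline_male_logit: float = -1.5
    pool_size_male: int = 35
    pool_size_female: int = 50
    raw_depth: int = 100
    seed: int = 0

    def founder_names(self) -> list[str]:
        names = ["A", "C"]
        names += [f"K{i}" for i in range(2, self.n_founder_clones)]
        return names[: self.n_founder_clones]

    def validate(self) -> None:
        a, b = self.founder_freq_beta
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")
        if self.n_founder_clones < 1:
            raise ValueError("need at least one founder clone")
        if not 0.0 <= self.nonsyn_fraction <= 1.0:
            raise ValueError("nonsyn_fraction must be in [0, 1]")
        founders = set(self.founder_names())
        for block in self.pond_year_design:
            if block.sample_size < 1:
                raise ValueError("sample sizes must be >= 1")
            unknown = set(block.clone_freqs) - founders
            if unknown:
                raise ValueError(
                    f"clone frequencies reference undefined clones: {unknown}"
                )
            total = sum(block.clone_freqs.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(
                    f"clone frequencies for {block.pond}/{block.year} "
                    f"sum to {total}, not 1"
                )
        known = set(founders)
        for off in self.offspring_design:
            parents = {off.mother} | ({off.father} if off.father else set())
            unknown = parents - known
            if unknown:
                raise ValueError(
                    f"offspring {off.child_id} references undefined "
                    f"parents: {unknown}"
                )
            known.add(off.child_id)  # later offspring may descend from it
        for q in self.qtl_spec:
            if not 0 <= q.chrom < self.n_chromosomes:
                raise ValueError(f"QTL chromosome {q.chrom} out of range")
            if not 1 <= q.pos <= self.chromosome_length_bp:
                raise ValueError(f"QTL position {q.pos} out of range")


@dataclass
class TruthSet:
    """Machine-readable ground truth emitted alongside each simulation."""

    clone_id: dict[str, str]
    pedigree: list[tuple[str, str, str, str]]   # child, mother, father, type
    qtl: list[QTL]
    expected_male_prop: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for child, mother, father, kind in self.pedigree:
            if kind == "self" and mother != father:
                raise ValueError("self edges must have mother == father")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "clone_id": self.clone_id,
            "pedigree": [list(e) for e in self.pedigree],
            "qtl": [asdict(q) for q in self.qtl],
            "expected_male_prop": self.expected_male_prop,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            clone_id=payload["clone_id"],
            pedigree=[tuple(e) for e in payload["pedigree"]],
            qtl=[QTL(**q) for q in payload["qtl"]],
            expected_male_prop=payload.get("expected_male_prop", {}),
            seed=payload.get("seed", 0),
        )


# ----------------------------------------------------------------------
# internal machinery
# ----------------------------------------------------------------------

def _site_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Random sorted site positions with syn/nonsyn labels, QTL included."""
    per_chrom = np.full(config.n_chromosomes, config.n_sites // config.n_chromosomes)
    per_chrom[: config.n_sites % config.n_chromosomes] += 1
    frames = []
    for c in range(config.n_chromosomes):
        want = int(per_chrom[c])
        forced = sorted({q.pos for q in config.qtl_spec if q.chrom == c})
        n_free = want - len(forced)
        if n_free < 0:
            raise ValueError("more QTL than sites on a chromosome")
        pool = rng.choice(
            config.chromosome_length_bp, size=min(want * 3 + 16, config.chromosome_length_bp),
            replace=False,
        ) + 1
        if forced:
            pool = pool[~np.isin(pool, np.asarray(forced, dtype=pool.dtype))]
        if len(pool) < n_free:
            raise ValueError("chromosome too short for requested site count")
        pos = np.sort(np.concatenate([pool[:n_free], forced]).astype(np.int64))
        frames.append(pd.DataFrame({"chrom": f"chr{c + 1}", "pos": pos}))
    sites = pd.concat(frames, ignore_index=True)
    nonsyn = rng.random(len(sites)) < config.nonsyn_fraction
    sites["ref"] = "A"
    sites["alt"] = "T"
    sites["ann_class"] = np.where(nonsyn, "NONSYN", "SYN")
    sites["depth"] = 0
    return sites


def _founder_haplotypes(
    config: SimConfig, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_founders, 2, n_sites) haplotypes from the founder frequency law.

    Each founder lineage descends from its own drifted deme: its site
    frequencies follow the Balding-Nichols model around the ancestral
    frequency with differentiation ``founder_divergence`` (F_ST-like).
    This makes distinct lineages divergent -- their heterozygous sites
    are largely disjoint, as observed for coexisting superclones --
    while ``founder_divergence = 0`` recovers a single panmictic law.
    """
    a, b = config.founder_freq_beta
    freqs = rng.beta(a, b, size=n_sites)
    f = config.founder_divergence
    if f > 0:
        scale = (1.0 - f) / f
        alpha = np.maximum(freqs * scale, 1e-9)
        beta_par = np.maximum((1.0 - freqs) * scale, 1e-9)
        per_founder = rng.beta(
            alpha, beta_par, size=(config.n_founder_clones, n_sites)
        )
    else:
        per_founder = np.broadcast_to(freqs, (config.n_founder_clones, n_sites))
    haps = (
        rng.random((config.n_founder_clones, 2, n_sites))
        < per_founder[:, None, :]
    ).astype(np.int8)
    return haps


def _chrom_slices(sites: pd.DataFrame) -> list[tuple[str, slice, np.ndarray]]:
    out = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        out.append((chrom, slice(idx[0], idx[-1] + 1), grp["pos"].to_numpy()))
    return out


def _gamete(
    haps: np.ndarray,
    sites: pd.DataFrame,
    crossover_rate: float,
    chrom_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a (2, n_sites) haplotype pair.

    Crossovers per chromosome are Poisson with uniform placement and no
    interference; the starting haplotype is chosen uniformly per
    chromosome (free recombination between chromosomes).
    """
    gamete = np.empty(haps.shape[1], dtype=np.int8)
    for _, sl, pos in _chrom_slices(sites):
        n_co = rng.poisson(crossover_rate)
        breaks = np.sort(rng.integers(1, chrom_length + 1, size=n_co))
        phase = int(rng.integers(2))
        which = (phase + np.searchsorted(breaks, pos, side="right")) % 2
        block = haps[:, sl]
        gamete[sl] = np.where(which == 0, block[0], block[1])
    return gamete


def _apply_private_mutations(
    genotype: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Add Poisson(rate) new heterozygous mutations at homozygous sites.

    Asexual lineages accumulate mutations in the heterozygous state (no
    segregation to expose them), so every new mutation turns a homozygous
    site into a heterozygote.
    """
    genotype = genotype.copy()
    n_mut = rng.poisson(rate)
    if n_mut == 0:
        return genotype
    hom = np.flatnonzero(genotype != 1)
    if len(hom) == 0:
        return genotype
    hit = rng.choice(hom, size=min(n_mut, len(hom)), replace=False)
    genotype[hit] = 1
    return genotype


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def simulate_population(config: SimConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate a multi-pond, multi-year sample of a clonal metapopulation.

    Returns a :class:`GenotypeMatrix` (unphased dosages) and the
    :class:`TruthSet` recording every sample's clonal lineage and the
    pedigree of sexually produced individuals.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sites = _site_table(config, rng)
    n_sites = len(sites)
    founders = _founder_haplotypes(config, n_sites, rng)
    names = config.founder_names()
    hap_of = {name: founders[i] for i, name in enumerate(names)}

    design = config.pond_year_design or [
        PondYearBlock("D8", 2017, 12, {n: 1.0 / len(names) for n in names})
    ]

    rows, meta_rows = [], []
    clone_id: dict[str, str] = {}
    pedigree: list[tuple[str, str, str, str]] = []

    counter: dict[tuple[str, int], int] = {}
    for block in design:
        clones = sorted(block.clone_freqs)
        probs = np.array([block.clone_freqs[c] for c in clones])
        picks = rng.choice(len(clones), size=block.sample_size, p=probs)
        for pick in picks:
            clone = clones[pick]
            k = counter.get((block.pond, block.year), 0)
            counter[(block.pond, block.year)] = k + 1
            sid = f"{block.pond}_{block.year}_{k}"
            geno = hap_of[clone].sum(axis=0).astype(np.int8)
            geno = _apply_private_mutations(geno, config.clonal_mutation_rate, rng)
            rows.append(geno)
            meta_rows.append((sid, block.pond, block.year, "wild", np.nan))
            clone_id[sid] = clone
            pedigree.append((sid, clone, clone, "clonal"))

    for off in config.offspring_design:
        father = off.father if off.father is not None else off.mother
        g1 = _gamete(hap_of[off.mother], sites, config.crossover_rate,
                     config.chromosome_length_bp, rng)
        g2 = _gamete(hap_of[father], sites, config.crossover_rate,
                     config.chromosome_length_bp, rng)
        geno = (g1 + g2).astype(np.int8)
        kind = "self" if father == off.mother else "outcross"
        hap_of[off.child_id] = np.vstack([g1, g2])  # may parent later offspring
        rows.append(geno)
        meta_rows.append((off.child_id, off.pond, off.year, "wild", np.nan))
        clone_id[off.child_id] = off.child_id
        pedigree.append((off.child_id, off.mother, father, kind))

    if not rows:
        raise ValueError("simulation design produced no samples")

    dosages = np.vstack(rows)
    samples = pd.DataFrame(
        meta_rows, columns=["sample", "pond", "year", "source", "median_depth"]
    )
    sites = sites.copy()
    sites["depth"] = (dosages != -1).sum(axis=0) * 10  # nominal uniform depth
    gm = GenotypeMatrix(dosages, sites, samples)
    truth = TruthSet(clone_id, pedigree, list(config.qtl_spec), seed=config.seed)
    return gm, truth


def _force_parent_qtl_genotypes(
    hap_a: np.ndarray, hap_c: np.ndarray, qtl_idx: np.ndarray
) -> None:
    """Plant mappable QTL genotypes: A homozygous reference (male-/male-),
    C heterozygous (male+/male-).  A fixed difference between the parents
    would be monomorphic across the F1 panel and carry no mapping signal."""
    hap_a[:, qtl_idx] = 0
    hap_c[0, qtl_idx] = 1
    hap_c[1, qtl_idx] = 0


def simulate_f1_panel(
    config: SimConfig,
    n_f1: int,
    cross: str = "AxC",
    offspring_per_line: int = 200,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthSet]:
    """Simulate a panel of recombinant F1 isofemale lines with phenotypes.

    Each line receives one recombinant gamete from each parent ("AxC") or
    two independent gametes from C ("CxC", selfing).  Its probability of
    producing a male offspring is ``invlogit(baseline + sum(effect *
    male+ dosage))`` over the planted QTL; observed male counts are
    binomial draws out of ``offspring_per_line`` scored individuals.
    """
    config.validate()
    if config.n_founder_clones < 2:
        raise ValueError("F1 panel needs the two focal parents A and C")
    if not config.qtl_spec:
        raise ValueError("F1 panel simulation needs at least one QTL")
    if cross not in ("AxC", "CxC"):
        raise ValueError(f"unknown cross {cross!r}")

    rng = np.random.default_rng(config.seed)
    sites = _site_table(config, rng)
    n_sites = len(sites)
    founders = _founder_haplotypes(config, n_sites, rng)
    hap_a, hap_c = founders[0], founders[1]

    pos_key = {(f"chr{q.chrom + 1}", q.pos): q for q in config.qtl_spec}
    site_keys = list(zip(sites["chrom"], sites["pos"]))
    qtl_idx = np.array([i for i, k in enumerate(site_keys) if k in pos_key])
    effects = np.array([pos_key[site_keys[i]].effect for i in qtl_idx])
    _force_parent_qtl_genotypes(hap_a, hap_c, qtl_idx)

    rows, phen_rows = [], []
    clone_id, pedigree, expected = {}, [], {}
    for k in range(n_f1):
        line = f"F1_{k}"
        if cross == "AxC":
            g1 = _gamete(hap_a, sites, config.crossover_rate,
                         config.chromosome_length_bp, rng)
            mother, father, kind = "C", "A", "outcross"
        else:
            g1 = _gamete(hap_c, sites, config.crossover_rate,
                         config.chromosome_length_bp, rng)
            mother, father, kind = "C", "C", "self"
        g2 = _gamete(hap_c, sites, config.crossover_rate,
                     config.chromosome_length_bp, rng)
        geno = (g1 + g2).astype(np.int8)
        rows.append(geno)
        logit = config.baseline_male_logit + float(effects @ geno[qtl_idx])
        p_male = 1.0 / (1.0 + np.exp(-logit))
        males = int(rng.binomial(offspring_per_line, p_male))
        phen_rows.append((line, cross, males, offspring_per_line, p_male))
        clone_id[line] = line
        pedigree.append((line, mother, father, kind))
        expected[line] = float(p_male)

    # parents are included in the emitted matrix for segregation checks
    for name, hap in (("A", hap_a), ("C", hap_c)):
        rows.append(hap.sum(axis=0).astype(np.int8))
        phen_rows.append((name, "parent", 0, 0, np.nan))
        clone_id[name] = name

    dosages = np.vstack(rows)
    samples = pd.DataFrame(
        {
            "sample": [r[0] for r in phen_rows],
            "pond": "D8",
            "year": 2018,
            "source": ["lab"] * len(phen_rows),
            "median_depth": np.nan,
        }
    )
    sites = sites.copy()
    sites["depth"] = (dosages != -1).sum(axis=0) * 10
    gm = GenotypeMatrix(dosages, sites, samples)
    phenotypes = pd.DataFrame(
        phen_rows, columns=["line", "cross", "males", "total", "true_male_prob"]
    )
    truth = TruthSet(clone_id, pedigree, list(config.qtl_spec),
                     expected_male_prop=expected, seed=config.seed)
    return gm, phenotypes, truth


def simulate_pools(
    panel: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    pool_size_male: int = 35,
    pool_size_female: int = 50,
    raw_depth: int = 100,
    replace: bool = True,
    seed: int = 0,
):
    """Compose male and female bulks from an F1 panel and draw read counts.

    Lines enter the male bulk with probability proportional to their
    male-production probability and the female bulk proportional to its
    complement (a male is genetically identical to its parthenogenetic
    mother, so pooled males carry their mother line's genotype).  Read
    counts follow the double-binomial Pool-Seq model: allele sampling
    when individuals are drawn into the pool, then binomial read sampling
    at the raw depth.

    Returns a :class:`clonalmap.bsa.PoolCounts`.
    """
    from .bsa import PoolCounts

    rng = np.random.default_rng(seed)
    lines = phenotypes.loc[phenotypes["cross"] != "parent"]
    if lines.empty:
        raise ValueError("no F1 lines in phenotype table")
    idx = [panel.sample_index(s) for s in lines["line"]]
    dos = panel.dosages[idx, :].astype(float)
    p_male = lines["true_male_prob"].to_numpy(dtype=float)

    n_lines = len(lines)
    if not replace and max(pool_size_male, pool_size_female) > n_lines:
        raise ValueError(
            "pool size exceeds panel size; pass replace=True to sample "
            "lines with replacement"
        )

    def bulk_counts(weights: np.ndarray, pool_n: int) -> tuple[np.ndarray, np.ndarray]:
        w = weights / weights.sum()
        chosen = rng.choice(n_lines, size=pool_n, replace=replace, p=w)
        freq = dos[chosen].sum(axis=0) / (2.0 * pool_n)
        alt = rng.binomial(raw_depth, freq)
        ref = raw_depth - alt
        return ref, alt

    if not (p_male > 0).any():
        raise ValueError("all male-production probabilities are zero")
    ref_m, alt_m = bulk_counts(p_male, pool_size_male)
    ref_f, alt_f = bulk_counts(1.0 - p_male, pool_size_female)

    table = panel.sites[["chrom", "pos"]].copy()
    table["ref_high"] = ref_m
    table["alt_high"] = alt_m
    table["ref_low"] = ref_f
    table["alt_low"] = alt_f
    return PoolCounts(
        table=table,
        pool_n_high=pool_size_male,
        pool_n_low=pool_size_female,
        raw_depth=raw_depth,
    )
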