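"""End-to-end orchestration with a reproducibility manifest.

A single JSON config drives simulate -> filter -> clones -> pedigree ->
windows -> bsa -> f1scan; each stage writes into its own subdirectory of
the output directory and every emitted file is digested into the run
manifest, so a rerun with the same config and seed is checkable
byte-for-byte on the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import bsa, clonal, f1qtl, kinship, sim, vcfio, windows

log = logging.getLogger("clonalmap")

__all__ = ["RunManifest", "run_pipeline", "demo_config"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    digests: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, runtime_s: float, outputs: list[Path]) -> None:
        self.stages.append({"stage": stage, "runtime_s": round(runtime_s, 3)})
        for p in outputs:
            self.digests[str(p)] = _sha256(p)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "stages": self.stages,
                    "digests": self.digests,
                },
                fh, indent=1, sort_keys=True,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def demo_config(seed: int = 1) -> dict:
    """A small end-to-end scenario: two ponds, two years, four lineages,
    one selfed and one outcrossed offspring, an F1 panel with one QTL,
    and male/female pools."""
    return {
        "seed": seed,
        "simulate": {
            "n_sites": 10_000,
            "n_chromosomes": 6,
            "chromosome_length_bp": 1_000_000,
            "founder_divergence": 0.45,
            "n_founder_clones": 4,
            "clonal_mutation_rate": 4.0,
            "pond_year_design": [
                {"pond": "D8", "year": 2016, "sample_size": 8,
                 "clone_freqs": {"A": 0.5, "C": 0.5}},
                {"pond": "D8", "year": 2017, "sample_size": 8,
                 "clone_freqs": {"A": 0.4, "C": 0.4, "K2": 0.2}},
                {"pond": "DCat", "year": 2017, "sample_size": 6,
                 "clone_freqs": {"K3": 1.0}},
            ],
            "offspring": [
                {"child_id": "D8_self_1", "mother": "C", "father": None},
                {"child_id": "D8_f1_1", "mother": "A", "father": "C"},
            ],
            "qtl": [{"chrom": 0, "pos": 500_000, "effect": 1.5}],
        },
        "clones": {"ibs_threshold": 0.965},
        "windows": {"width": 250_000, "step": 250_000, "min_snps": 50},
        "f1": {"n_f1": 40, "n_perm": 25, "offspring_per_line": 200, "n_pool_cohort": 250},
        "pools": {"pool_size_male": 35, "pool_size_female": 50,
                  "raw_depth": 100},
        "bsa": {"maf_min": 0.15, "fdr": 0.05},
    }


def _sim_config(cfg: dict, seed: int) -> sim.SimConfig:
    s = cfg.get("simulate", {})
    return sim.SimConfig(
        n_chromosomes=s.get("n_chromosomes", 2),
        chromosome_length_bp=s.get("chromosome_length_bp", 2_000_000),
        n_sites=s.get("n_sites", 4000),
        n_founder_clones=s.get("n_founder_clones", 4),
        founder_divergence=s.get("founder_divergence", 0.0),
        clonal_mutation_rate=s.get("clonal_mutation_rate", 4.0),
        pond_year_design=[
            sim.PondYearBlock(b["pond"], b["year"], b["sample_size"],
                              b["clone_freqs"])
            for b in s.get("pond_year_design", [])
        ],
        offspring_design=[
            sim.OffspringSpec(o["child_id"], o["mother"], o.get("father"))
            for o in s.get("offspring", [])
        ],
        qtl_spec=[sim.QTL(q["chrom"], q["pos"], q["effect"])
                  for q in s.get("qtl", [])],
        seed=seed,
    )


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Run the configured stages in dependency order.

    A stage failure stops everything downstream; the manifest records
    per-stage runtimes and output digests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        seed=seed,
    )

    def stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    # -- simulate ------------------------------------------------------
    t0 = stage("simulate")
    scfg = _sim_config(config, seed)
    gm, truth = sim.simulate_population(scfg)
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    vcfio.write_vcf(gm, sim_dir / "population.vcf", seed=seed)
    gm.samples.to_csv(sim_dir / "samples.tsv", sep="\t", index=False)
    truth.to_json(sim_dir / "truth.json")
    manifest.record("simulate", time.perf_counter() - t0, [
        sim_dir / "population.vcf", sim_dir / "samples.tsv",
        sim_dir / "truth.json",
    ])
    if "clones" not in config:
        manifest.write(out / "manifest.json")
        return manifest

    # -- filter --------------------------------------------------------
    t0 = stage("filter")
    filt_dir = out / "filter"
    filt_dir.mkdir(exist_ok=True)
    filtered, report = vcfio.filter_cascade(gm)
    report.to_tsv(filt_dir / "filter_report.tsv")
    manifest.record("filter", time.perf_counter() - t0,
                    [filt_dir / "filter_report.tsv"])

    # -- clones --------------------------------------------------------
    t0 = stage("clones")
    clone_dir = out / "clones"
    clone_dir.mkdir(exist_ok=True)
    ibs = clonal.pairwise_ibs(filtered)
    clones = clonal.assign_clones(
        ibs, config["clones"].get("ibs_threshold", 0.965), filtered.samples
    )
    clones.to_frame().to_csv(clone_dir / "clones.tsv", sep="\t", index=False)
    if clones.composition is not None:
        div = (
            clones.composition.groupby(["pond", "year"])["count"]
            .apply(lambda c: clonal.shannon_diversity(c.to_numpy()))
            .rename("shannon_h")
            .reset_index()
        )
        div.to_csv(clone_dir / "diversity.tsv", sep="\t", index=False)
    manifest.record("clones", time.perf_counter() - t0,
                    [clone_dir / "clones.tsv"])

    # -- pedigree ------------------------------------------------------
    t0 = stage("pedigree")
    ped_dir = out / "pedigree"
    ped_dir.mkdir(exist_ok=True)
    pairs = kinship.classify_pairs(kinship.king_kinship(filtered))
    pairs.to_tsv(ped_dir / "pairs.tsv")
    ped = kinship.build_pedigree(clones, pairs, filtered.samples, gm=filtered)
    ped.edges_frame().to_csv(ped_dir / "pedigree.tsv", sep="\t", index=False)
    manifest.record("pedigree", time.perf_counter() - t0,
                    [ped_dir / "pairs.tsv", ped_dir / "pedigree.tsv"])

    # -- windows -------------------------------------------------------
    t0 = stage("windows")
    win_dir = out / "windows"
    win_dir.mkdir(exist_ok=True)
    wcfg = config.get("windows", {})
    wibs = windows.window_ibs(
        filtered, clones,
        width=wcfg.get("width", 250_000), step=wcfg.get("step", 10_000),
        min_snps=wcfg.get("min_snps", 1000),
    )
    wibs.to_csv(win_dir / "window_ibs.tsv", sep="\t", index=False)
    outputs = [win_dir / "window_ibs.tsv"]
    # focal pair: the two most abundant lineages (the dominant superclones)
    by_size = sorted(clones.members, key=lambda c: -len(clones.members[c]))
    if len(by_size) >= 2 and not wibs.empty:
        ratios = windows.divergence_ratio(wibs, (by_size[0], by_size[1]))
        ratios.to_csv(win_dir / "divergence_ratios.tsv", sep="\t", index=False)
        outputs.append(win_dir / "divergence_ratios.tsv")
    manifest.record("windows", time.perf_counter() - t0, outputs)

    # -- F1 panel, pools, BSA and F1 scan ------------------------------
    if "f1" in config and scfg.qtl_spec:
        t0 = stage("f1_panel")
        fcfg = config["f1"]
        panel_gm, phen, f1_truth = sim.simulate_f1_panel(
            scfg, fcfg.get("n_f1", 30),
            offspring_per_line=fcfg.get("offspring_per_line", 200),
        )
        f1_dir = out / "f1"
        f1_dir.mkdir(exist_ok=True)
        vcfio.write_vcf(panel_gm, f1_dir / "panel.vcf", seed=seed)
        phen.to_csv(f1_dir / "phenotypes.tsv", sep="\t", index=False)
        panel = f1qtl.F1Panel.from_simulation(panel_gm, phen)

        # pools draw from a larger wild F1 cohort than the phenotyped panel
        cohort_n = fcfg.get("n_pool_cohort", 0)
        if cohort_n > fcfg.get("n_f1", 30):
            # same seed -> same genome and parents; the cohort extends the
            # phenotyped panel with additional wild F1 lines
            cohort_gm, cohort_phen, _ = sim.simulate_f1_panel(
                scfg, cohort_n,
                offspring_per_line=fcfg.get("offspring_per_line", 200))
        else:
            cohort_gm, cohort_phen = panel_gm, phen
        # the field design has two replicate pool pairings; each is scanned
        # separately and reported separately, never averaged
        pcfg = config.get("pools", {})
        n_reps = pcfg.get("n_replicates", 2)
        pool_files = []
        pool_reps = []
        for rep in range(n_reps):
            pools = sim.simulate_pools(
                cohort_gm, cohort_phen,
                pool_size_male=pcfg.get("pool_size_male", 35),
                pool_size_female=pcfg.get("pool_size_female", 50),
                raw_depth=pcfg.get("raw_depth", 100),
                seed=seed * 10 + rep + 1,
            )
            path = f1_dir / f"pool_counts_rep{rep + 1}.tsv"
            pools.to_tsv(path)
            pool_files.append(path)
            pool_reps.append(pools)
        manifest.record("f1_panel", time.perf_counter() - t0, [
            f1_dir / "panel.vcf", f1_dir / "phenotypes.tsv", *pool_files,
        ])

        t0 = stage("bsa")
        bcfg = config.get("bsa", {})
        bsa_files = []
        for rep, pools in enumerate(pool_reps, start=1):
            gp = bsa.gprime_scan(pools, maf_min=bcfg.get("maf_min", 0.15),
                                 seed=seed)
            gp_path = f1_dir / f"gprime_rep{rep}.tsv"
            gp.table.to_csv(gp_path, sep="\t", index=False)
            regions = bsa.call_regions(gp, q_max=bcfg.get("fdr", 0.05),
                                       replicate=str(rep))
            reg_path = f1_dir / f"bsa_regions_rep{rep}.tsv"
            regions.regions.to_csv(reg_path, sep="\t", index=False)
            bsa_files += [gp_path, reg_path]
        manifest.record("bsa", time.perf_counter() - t0, bsa_files)

        t0 = stage("f1scan")
        tags = f1qtl.find_tags(panel)
        result = f1qtl.scan(panel, tags, n_perm=fcfg.get("n_perm", 25),
                            seed=seed)
        result.table.to_csv(f1_dir / "scan.tsv", sep="\t", index=False)
        boundaries = f1qtl.qtl_boundaries(result.significant())
        boundaries.regions.to_csv(f1_dir / "f1_qtl.tsv", sep="\t", index=False)
        manifest.record("f1scan", time.perf_counter() - t0, [
            f1_dir / "scan.tsv", f1_dir / "f1_qtl.tsv",
        ])

    manifest.write(out / "manifest.json")
    return manifest
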