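import numpy as np
import pandas as pd
import pytest

from clonalmap.genotypes import GenotypeMatrix
from clonalmap import sim


def make_gm(dosages, positions=None, chrom="chr1", ann=None, depth=None,
            sample_ids=None, **sample_cols):
    """Small GenotypeMatrix builder for hand-crafted examples."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = dosages.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if isinstance(chrom, str):
        chrom = [chrom] * n_sites
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": positions,
        "ref": "A",
        "alt": "T",
        "ann_class": ann if ann is not None else ["NONE"] * n_sites,
        "depth": depth if depth is not None else [30] * n_sites,
    })
    ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    samples = pd.DataFrame({"sample": ids})
    samples["pond"] = sample_cols.get("pond", "D8")
    samples["year"] = sample_cols.get("year", 2017)
    samples["source"] = sample_cols.get("source", "wild")
    samples["median_depth"] = sample_cols.get("median_depth", np.nan)
    return GenotypeMatrix(dosages, sites, samples)


@pytest.fixture(scope="session")
def small_population():
    """Four divergent clonal lineages sampled over two ponds and years."""
    cfg = sim.SimConfig(
        seed=2,
        n_sites=6000,
        n_founder_clones=4,
        clonal_mutation_rate=10.0,
        pond_year_design=[
            sim.PondYearBlock("D8", 2016, 8, {"A": 0.5, "C": 0.5}),
            sim.PondYearBlock("D8", 2017, 8,
                              {"A": 0.3, "C": 0.3, "K2": 0.2, "K3": 0.2}),
            sim.PondYearBlock("DCat", 2017, 6, {"K3": 1.0}),
        ],
    )
    return sim.simulate_population(cfg)


@pytest.fixture(scope="session")
def f1_panel_sim():
    """40-line AxC F1 panel with one planted male-production QTL."""
    cfg = sim.SimConfig(
        seed=7,
        n_sites=2000,
        n_chromosomes=2,
        chromosome_length_bp=5_000_000,
        qtl_spec=[sim.QTL(0, 2_500_000, 1.5)],
    )
    return sim.simulate_f1_panel(cfg, 40)
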