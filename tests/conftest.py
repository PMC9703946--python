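import numpy as np
import pandas as pd
import pytest

from xcrossqtl import (
    CrossPopulation,
    GeneticMap,
    conditional_genotype_probs,
    make_marker_map,
    simulate_backcross,
)
from xcrossqtl.synthetic_data import QtlSpec, TraitSpec


def make_cross(genotypes, cm, phenotypes=None, chrom="1", mbp=None):
    """Small hand-built cross: genotypes is a list of per-individual strings
    like "AH-" (one char per marker; '-' = missing)."""
    n_mark = len(cm)
    markers = [f"m{i}" for i in range(n_mark)]
    gmap = GeneticMap(
        pd.DataFrame(
            {
                "marker": markers,
                "chrom": chrom,
                "cm": cm,
                "mbp": mbp if mbp is not None else np.nan,
            }
        )
    )
    rows = []
    for s in genotypes:
        rows.append([np.nan if c == "-" else c for c in s])
    ids = pd.Index([f"i{k}" for k in range(len(genotypes))])
    geno = pd.DataFrame(rows, index=ids, columns=markers, dtype=object)
    pheno = pd.DataFrame(phenotypes or {}, index=ids, dtype=float)
    return CrossPopulation(gmap, geno, pheno)


@pytest.fixture
def informative_marker_cross():
    """One fully informative marker; helper to attach a trait."""

    def build(values_a, values_h):
        geno = ["A"] * len(values_a) + ["H"] * len(values_h)
        y = list(values_a) + list(values_h)
        cross = make_cross(geno, cm=[0.0], phenotypes={"y": y})
        probs = conditional_genotype_probs(cross, step_cm=0.0, error_prob=0.0)
        return cross, probs

    return build


@pytest.fixture(scope="session")
def planted_cross():
    """A moderate simulated cross with one planted QTL, reused across tests."""
    gmap = make_marker_map([100.0, 90.0], chrom_names=["1", "14"])
    qtl = QtlSpec("14", 30.0, {"bw": 1.0}, sigma_e=1.0)
    return simulate_backcross(
        gmap, 300, [qtl], seed=11, traits={"bw": TraitSpec(50.0, 1.0)}
    )
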