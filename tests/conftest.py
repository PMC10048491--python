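"""Shared fixtures: small simulated herds reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from herdgwas import simdata
from herdgwas.genotypes import GenotypeMatrix


def make_geno(dosage, chrom=None, pos=None, ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array with default metadata."""
    dosage = np.asarray(dosage, dtype=np.float32)
    n, m = dosage.shape
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "C",
        }
    )
    if ids is None:
        ids = np.array([f"ind{i}" for i in range(n)])
    return GenotypeMatrix(ids=np.asarray(ids), variants=variants, dosage=dosage)


@pytest.fixture(scope="session")
def small_sim():
    """Default structured herd: 600 cows, 25 sires, 2 chromosomes, 1 QTL."""
    cfg = simdata.SimConfig(
        n_individuals=600,
        n_sires=25,
        n_chromosomes=2,
        variants_per_chromosome=800,
        seed=3,
        qtl=(simdata.QTLSpec("1", 50_000_000, "milk_kg", 300.0, 0.3),),
    )
    geno = simdata.simulate_genotypes(cfg)
    records, truth = simdata.simulate_phenotypes(geno, cfg)
    return cfg, geno, records, truth
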