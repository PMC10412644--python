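import numpy as np
import pandas as pd
import pytest

from paleocline.genotype_store import (MISSING, GenotypeMatrix, SnpPanel,
                                       make_meta)
from paleocline.synthetic_data import make_panel


@pytest.fixture
def tiny_panel() -> SnpPanel:
    """Five transversion sites on two chromosomes, polarized (A ancestral)."""
    return SnpPanel(pd.DataFrame({
        "site_id": [f"s{i}" for i in range(5)],
        "chrom": ["1", "1", "1", "2", "2"],
        "pos": [100, 200, 300, 100, 200],
        "genetic_pos": [0.0, 0.001, 0.002, 0.0, 0.001],
        "allele1": ["A"] * 5,
        "allele2": ["C"] * 5,
        "ancestral": ["A"] * 5,
    }))


@pytest.fixture
def random_dataset():
    """50-site random mixed-ploidy dataset for round-trip style checks."""
    rng = np.random.default_rng(0)
    panel = make_panel(50, morgans=0.5)
    ploidy = np.array([2, 2, 1, 1, 2], dtype=np.int8)
    calls = np.empty((5, 50), dtype=np.int8)
    for i, p in enumerate(ploidy):
        calls[i] = rng.integers(0, p + 1, 50)
    calls[rng.random((5, 50)) < 0.1] = MISSING
    matrix = GenotypeMatrix([f"ind{i}" for i in range(5)], ploidy, calls)
    meta = make_meta([
        {"id": f"ind{i}", "group": g, "sex": s}
        for i, (g, s) in enumerate([("G1", "XX"), ("G1", "XY"),
                                    ("G2", "XY"), ("G2", "UNKNOWN"),
                                    ("G3", "XX")])])
    return panel, matrix, meta
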