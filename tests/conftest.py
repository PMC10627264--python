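import numpy as np
import pandas as pd
import pytest

from crossplan.data_model import GeneticMap, GenotypeMatrix
from crossplan.simulate import SimulationConfig, generate_founders, sample_architecture


@pytest.fixture(scope="session")
def small_panel():
    """60 inbred founders, 120 loci on 3 chromosomes, plus a 40-QTL
    architecture rescaled to TBV variance 14."""
    cfg = SimulationConfig(
        n_founders=60, n_loci=120, n_chromosomes=3, n_qtl=40, seed=1
    )
    founders, gmap = generate_founders(cfg)
    arch, effects = sample_architecture(founders, gmap, 40, 14.0, seed=2)
    return {"config": cfg, "founders": founders, "map": gmap,
            "architecture": arch, "effects": effects}


@pytest.fixture(scope="session")
def two_locus_map():
    """Two loci 0.2 M apart on one chromosome (r ~ 0.1648)."""
    return GeneticMap(pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "locus_id": ["a", "b"],
        "pos_morgans": [0.0, 0.2],
    }))


@pytest.fixture()
def tiny_genotypes():
    doses = np.array([[0, 2, 2, 0], [2, 0, 2, 0], [0, 0, 2, 2]], dtype=np.int8)
    return GenotypeMatrix(["A", "B", "C"], doses, ["l1", "l2", "l3", "l4"])
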