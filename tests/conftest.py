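import numpy as np
import pandas as pd
import pytest

from collangio.synthetic import (
    BulkSimConfig,
    SCSimConfig,
    SpatialSimConfig,
    gen_bulk_cohort,
    gen_sc_dataset,
    gen_spatial_sample,
)


@pytest.fixture(scope="session")
def small_bulk():
    """Small planted bulk cohort shared by scoring/subtyping/DEG tests."""
    cfg = BulkSimConfig(n_samples=80, n_genes=300, seed=11)
    expr, labels, blocks = gen_bulk_cohort(cfg)
    return expr, labels, blocks


@pytest.fixture(scope="session")
def null_bulk():
    """Zero-effect cohort: every gene is pure noise around its baseline."""
    cfg = BulkSimConfig(
        n_samples=60,
        n_genes=300,
        collagen_effect=0.0,
        immune_effect=0.0,
        angio_coupling=0.0,
        seed=12,
    )
    return gen_bulk_cohort(cfg)


@pytest.fixture(scope="session")
def two_type_sc():
    """Fibroblast/endothelial dataset with strongly planted LR pairs."""
    cfg = SCSimConfig(
        cells_per_type={"fibroblast": 120, "endothelial": 120, "immune": 120},
        planted_lr_pairs=[
            ("LIG_A", "REC_A", "fibroblast", "endothelial", 30.0),
            ("LIG_B", "REC_B", "fibroblast", "endothelial", 30.0),
            ("LIG_C", "REC_C", "fibroblast", "endothelial", 30.0),
        ],
        seed=21,
    )
    return gen_sc_dataset(cfg)


@pytest.fixture()
def coloc_spots():
    return gen_spatial_sample(
        SpatialSimConfig(n_fibro=50, n_endo=50, n_other=60, coloc_sd=1.0, seed=31)
    )


def toy_spots(rows):
    """Build a spot table from (cell_type, x, y) tuples."""
    return pd.DataFrame(
        {
            "sample_id": "t",
            "spot_id": [f"s{i}" for i in range(len(rows))],
            "x": [r[1] for r in rows],
            "y": [r[2] for r in rows],
            "cell_type": [r[0] for r in rows],
        }
    )
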