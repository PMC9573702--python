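import numpy as np
import pandas as pd
import pytest

import gelquant as gq


@pytest.fixture
def tiny_table() -> gq.SpotVolumeTable:
    """4 spots x 4 gels (2 groups x 2), one missing cell, one meta block."""
    vols = pd.DataFrame(
        {
            "A_1": [10.0, 5.0, np.nan, 0.0],
            "A_2": [11.0, 6.0, 2.0, 1.0],
            "B_1": [20.0, 5.5, 2.5, 0.5],
            "B_2": [21.0, 4.5, 3.0, 1.5],
        },
        index=["S1", "S2", "S3", "S4"],
    )
    meta = pd.DataFrame(
        {"pI_obs": [4.6, 5.2, 6.1, 6.5], "Mr_obs_kDa": [30.5, 39.3, 85.3, 24.2]},
        index=vols.index,
    )
    return gq.SpotVolumeTable(vols, meta)


@pytest.fixture
def tiny_design() -> gq.ExperimentDesign:
    return gq.ExperimentDesign.from_mapping(
        {"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B"}
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One study-shaped synthetic dataset (345 spots, 3 x 4 gels), seed 1."""
    cfg = gq.GeneratorConfig(seed=1)
    table, design, truth = gq.generate_dataset(cfg)
    return cfg, table, design, truth


@pytest.fixture(scope="session")
def default_run(default_dataset):
    """Full analysis of the seed-1 dataset at study settings (B=2000)."""
    _, table, design, truth = default_dataset
    normalized, presence = gq.preprocess(table, design)
    results = gq.pairwise_significance(
        normalized, design, presence, gq.BootstrapSettings(seed=1)
    )
    effects = gq.compute_effects(results)
    return {
        "table": table,
        "design": design,
        "truth": truth,
        "normalized": normalized,
        "presence": presence,
        "results": results,
        "effects": effects,
    }
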