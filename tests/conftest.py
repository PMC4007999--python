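import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from polylink import MarkerMatrix, SimulationConfig, generate_population

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def disomic_cross():
    """One octoploid HG under strict disomy: 8 homologues in 4 partner
    pairs, 10 SD markers per homologue, 227 progeny."""
    cfg = SimulationConfig(
        seed=9,
        n_homology_groups=1,
        homologues_per_hg=8,
        markers_per_homologue=10,
        dosage_mix=(1, 0, 0),
        anchor_families_per_hg=6,
        anchor_allele_range=(3, 5),
        cross_hg_anchor_rate=0.0,
        pairing_preference=1.0,
        distorted_homologue_fraction=0.0,
        missing_rate=0.02,
        subset_scored_fraction=0.0,
        n_progeny=227,
    )
    return generate_population(cfg)


@pytest.fixture(scope="session")
def polysomic_cross():
    """Same genome under fully polysomic (random) pairing."""
    cfg = SimulationConfig(
        seed=9,
        n_homology_groups=1,
        homologues_per_hg=8,
        markers_per_homologue=10,
        dosage_mix=(1, 0, 0),
        anchor_families_per_hg=6,
        anchor_allele_range=(3, 5),
        cross_hg_anchor_rate=0.0,
        pairing_preference=0.0,
        distorted_homologue_fraction=0.0,
        missing_rate=0.02,
        subset_scored_fraction=0.0,
        n_progeny=227,
    )
    return generate_population(cfg)


def make_matrix(calls: dict, progeny=None, metadata: dict | None = None) -> MarkerMatrix:
    """Small hand-built MarkerMatrix; calls maps marker -> list of 1/0/nan."""
    df = pd.DataFrame.from_dict(calls, orient="index", dtype=float)
    if progeny is not None:
        df.columns = progeny
    else:
        df.columns = [f"P{i + 1:03d}" for i in range(df.shape[1])]
    meta = None
    if metadata is not None:
        meta = pd.DataFrame.from_dict(metadata, orient="index")
    return MarkerMatrix(calls=df, metadata=meta)
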