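import numpy as np
import pandas as pd
import pytest

from mitonorm import (
    CohortConfig,
    MissingnessModel,
    NoiseModel,
    SampleDesign,
    best_normalise,
    generate_cohort,
)


def make_design(n_participants: int, timepoints=("BL", "PN", "PH", "PR"),
                layer: str = "proteomics", suffix: str = "") -> SampleDesign:
    rows = [
        (f"P{p + 1:02d}_{t}{suffix}", f"P{p + 1:02d}", t, layer)
        for p in range(n_participants)
        for t in timepoints
    ]
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample", "participant", "timepoint",
                                    "layer"]),
        tuple(timepoints),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (pure content change, delta = 0)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, missingness-free, jitter-free cohort: every deviation
    from baseline is the content multiplier alone."""
    cfg = CohortConfig(
        noise=NoiseModel(cv=0.0, sd_additive=0.0),
        missingness=None,
        enrichment_sd=0.0,
        participant_sd=0.0,
        seed=2,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def best_default(default_cohort):
    """BESt-normalised default cohort, shared across tests."""
    proteins, _, annotation, design, truth = default_cohort
    best = best_normalise(proteins, annotation, seed=11)
    return best, design.for_layer("proteomics"), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
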