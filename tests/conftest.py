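from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bronchoscore import (
    FeatureSim,
    RaterSpec,
    SimulationConfig,
    compose_all,
    counts_from_assignments,
    default_registry,
    simulate_ratings,
)
from bronchoscore.io import demo_ratings_path, read_ratings


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def demo_ratings(registry):
    return read_ratings(demo_ratings_path(), registry)


def single_feature_config(
    n_subjects: int,
    seed: int,
    noise_sd: float = 0.8,
    raters: int = 4,
) -> SimulationConfig:
    """One 0-2 threshold feature, equal-noise unbiased raters, cutpoints
    (0.5, 1.5): a moderate-agreement regime away from the coefficient
    boundary."""
    return SimulationConfig(
        n_subjects=n_subjects,
        raters=tuple(
            RaterSpec(f"r{j + 1}", bias=0.0, noise_sd=noise_sd)
            for j in range(raters)
        ),
        features=(FeatureSim("viscosity", 2, (0.5, 1.5)),),
        seed=seed,
        group_split=0.625,
        severity_sd=1.0,
        lobe_sd=0.5,
    )


def study_counts(config: SimulationConfig, q: int = 4) -> np.ndarray:
    """Simulate one study and reduce the (single-feature) composites to the
    per-subject category-count matrix."""
    ratings = simulate_ratings(config)
    comp = compose_all(ratings, default_registry())
    wide = comp.pivot_table(
        index="subject_id", columns="rater_id", values="composite",
        aggfunc="first",
    )
    return counts_from_assignments(wide.to_numpy(dtype=float), q)


@pytest.fixture(scope="session")
def default_study_ratings() -> pd.DataFrame:
    """One full-size synthetic study (80 subjects, 4 raters, 10 features)."""
    from bronchoscore import default_config

    return simulate_ratings(default_config(seed=20260929))
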