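import warnings

import numpy as np
import pandas as pd
import pytest

import ethoclass as ec

# SVC(probability=True) is the intended one-vs-one + Platt behaviour; the
# pending deprecation is noise for this suite
warnings.filterwarnings("ignore", message="The `probability` parameter")


@pytest.fixture(scope="session")
def random_trace():
    """Seeded 390-sample (30 epochs) tri-axial trace with varied structure."""
    rng = np.random.default_rng(42)
    n = 390
    t = np.arange(n) / 25.0
    xyz = np.column_stack([
        0.3 * np.sin(2 * np.pi * 1.5 * t) + rng.normal(0, 0.1, n),
        0.5 * np.sin(2 * np.pi * 2.5 * t + 1.0) + rng.normal(0, 0.15, n),
        1.0 + 0.2 * np.sin(2 * np.pi * 0.7 * t) + rng.normal(0, 0.05, n),
    ])
    place = np.array(["surface"] * (n // 2) + ["underwater"] * (n - n // 2), dtype=object)
    return ec.AccelerometerTrace(xyz=xyz, sampling_rate=25.0, place=place,
                                 subject_id="T01")


@pytest.fixture(scope="session")
def default_cohort_table():
    """12-subject default cohort, featurized and epoch-labelled."""
    cfg = ec.SimulationConfig(n_subjects=12, seed=7)
    profiles, table = ec.evaluation.build_labelled_features(cfg)
    return profiles, table


@pytest.fixture(scope="session")
def separable_protocol():
    """Full leave-two-out run on the 12-subject separable default cohort,
    with and without subject covariates (the most expensive fixture)."""
    cfg = ec.SimulationConfig(n_subjects=12, seed=7)
    return ec.run_protocol(cfg)


@pytest.fixture(scope="session")
def mass_protocol():
    """Leave-two-out run on the mass-scaled cohort, whose travelling and
    foraging signatures differ only in (mass-scaled) frequency."""
    cfg = ec.SimulationConfig(n_subjects=12, seed=7)
    return ec.run_protocol(cfg, specs=ec.mass_confounded_specs())


@pytest.fixture(scope="session")
def overlap_protocol():
    """Leave-two-out run on feeding-trial sessions whose travelling
    signatures wander across the foraging signature band."""
    cfg = ec.SimulationConfig(
        n_subjects=12, seed=7,
        transition_matrix=ec.synthetic_data.feeding_session_transition_matrix(),
    )
    return ec.run_protocol(
        cfg, specs=ec.overlapping_travel_forage_specs(),
        grids={"random_forest": ec.fast_grids()["random_forest"]},
        feature_flags=(True,),
    )


def make_feature_table(X: np.ndarray, y, columns=None) -> pd.DataFrame:
    """Minimal labelled feature table for model-suite tests."""
    X = np.asarray(X, dtype=float)
    columns = columns or [f"f{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=columns)
    df["category"] = np.asarray(y, dtype=object)
    df["subject_id"] = "S01"
    df["epoch_index"] = np.arange(len(df))
    df["epoch_start"] = np.arange(len(df)) * 13
    df["place"] = "surface"
    return df
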