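import numpy as np
import pandas as pd
import pytest

import ecmclock as ec


@pytest.fixture
def toy_annotation():
    """10 proteins: 4 matrisome (2 core, 2 associated), 6 non-matrisome."""
    return ec.make_annotation(
        [f"P{i}" for i in range(10)],
        ["collagens", "proteoglycans", "secreted_factors", "ecm_regulators"]
        + ["none"] * 6,
    )


@pytest.fixture(scope="session")
def recovery_setup():
    """Standard parameter-recovery conditions: n=500, noise_sd=0.2."""
    cfg = ec.SimulationConfig(
        seed=20260101, n_samples=500, n_proteins=300, matrisome_fraction=0.3,
        n_linear_aging=60, n_ushape=0, noise_sd=0.2,
    )
    annotation = ec.generate_annotation(cfg)
    cohort, truth = ec.generate_human_cohort(cfg, annotation)
    return cfg, annotation, cohort, truth


@pytest.fixture(scope="session")
def clock_setup():
    """Planted 5-protein ECM signal for clock-recovery tests."""
    cfg = ec.SimulationConfig(
        seed=20260105, n_samples=600, n_proteins=500, matrisome_fraction=0.3,
        n_linear_aging=5, aging_matrisome_fraction=1.0, n_ushape=0, noise_sd=0.1,
    )
    annotation = ec.generate_annotation(cfg)
    cohort, truth = ec.generate_human_cohort(cfg, annotation)
    return cfg, annotation, cohort, truth


def make_cohort(abundance: np.ndarray, ages, sex=None, **meta_cols) -> ec.Cohort:
    """Small helper to build cohorts from arrays in tests."""
    n = abundance.shape[0]
    index = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    ab = pd.DataFrame(
        abundance, index=index,
        columns=[f"P{j}" for j in range(abundance.shape[1])],
    )
    meta = pd.DataFrame(
        {"age": np.asarray(ages, dtype=float),
         "sex": sex if sex is not None else ["F", "M"] * (n // 2) + ["F"] * (n % 2),
         **meta_cols},
        index=index,
    )
    return ec.Cohort(ab, meta)
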