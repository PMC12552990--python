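import numpy as np
import pandas as pd
import pytest

from repeatmeth import (
    MethylationDataset,
    SimulationConfig,
    generate_cohort,
    implant_carrier_profile,
    load_locus_manifest,
)


@pytest.fixture(scope="session")
def locus_manifest():
    return load_locus_manifest()


@pytest.fixture(scope="session")
def small_cohort():
    """Implanted-effect cohort with a small probe background (fast)."""
    cfg = implant_carrier_profile(
        SimulationConfig(n_background_probes=300, seed=11)
    )
    ds, ann, truth = generate_cohort(cfg)
    return ds, ann, truth


@pytest.fixture(scope="session")
def locus_only_cohort():
    """Implanted-effect cohort restricted to the 23 locus probes."""
    cfg = implant_carrier_profile(SimulationConfig(n_background_probes=0, seed=5))
    ds, ann, truth = generate_cohort(cfg)
    return ds, ann, truth


@pytest.fixture(scope="session")
def null_cohort_20k():
    """No implanted effects, 20,000 background probes: the calibration null."""
    cfg = SimulationConfig(n_background_probes=20_000, seed=7)
    ds, ann, truth = generate_cohort(cfg)
    return ds, ann, truth


@pytest.fixture()
def tiny_dataset():
    """Hand-sized dataset: 8 samples, 3 probes, no covariates."""
    rng = np.random.default_rng(0)
    m = pd.DataFrame(
        rng.normal(size=(8, 3)),
        index=[f"s{i}" for i in range(8)],
        columns=["p1", "p2", "p3"],
    )
    carrier = pd.Series(
        ["carrier"] * 4 + ["non_carrier"] * 4, index=m.index
    )
    return MethylationDataset(m_values=m, carrier=carrier)
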