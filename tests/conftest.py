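"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

import rppasig as rs


@pytest.fixture(scope="session")
def small_cohort():
    """150-patient, 24-analyte, 2-array cohort with spots and harmonized matrix."""
    cfg = rs.SimulationConfig(n_patients=150, n_analytes=24, n_arrays=2, seed=9)
    clinical, truth = rs.simulate_cohort(cfg)
    spots = rs.simulate_spots(cfg, clinical, truth)
    matrices = rs.quantify(spots)
    harmonized, model = rs.harmonize(
        matrices, clinical, rs.PipelineConfig(n_subsamples=60, seed=9))
    return {
        "config": cfg, "clinical": clinical, "truth": truth, "spots": spots,
        "matrices": matrices, "harmonized": harmonized, "model": model,
    }


@pytest.fixture(scope="session")
def trial_scale_run():
    """Default trial-like conditions: 736 x 139 on 3 arrays, B = 5000."""
    cfg = rs.SimulationConfig(seed=1)
    clinical, truth = rs.simulate_cohort(cfg)
    spots = rs.simulate_spots(cfg, clinical, truth)
    matrices = rs.quantify(spots)
    raw = rs.combine_arrays([matrices[a] for a in sorted(matrices)])
    harmonized, model = rs.harmonize(
        matrices, clinical, rs.PipelineConfig(n_subsamples=5000, seed=1))
    return {
        "config": cfg, "clinical": clinical, "truth": truth,
        "matrices": matrices, "raw": raw, "harmonized": harmonized,
        "model": model,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
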