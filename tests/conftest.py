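import numpy as np
import pytest

import microdyn as md


@pytest.fixture(scope="session")
def montage64():
    return md.make_montage(64)


@pytest.fixture(scope="session")
def montage16():
    return md.make_montage(16)


@pytest.fixture(scope="session")
def cohort():
    """Small two-group cohort at the default noise level (snr 4).

    20 subjects, 40 s each: big enough for feature-recovery and
    equivalence checks, small enough to fit the suite's runtime.
    """
    cfg = md.SimulationConfig(n_per_group=10, duration=40.0, seed=11)
    recordings, truths, sheet = md.simulate_cohort(cfg)
    return cfg, recordings, truths, sheet


@pytest.fixture(scope="session")
def fitted_cohort(cohort):
    """The same cohort with the full pipeline (including stats) run once."""
    cfg, recordings, truths, sheet = cohort
    result = md.run_pipeline(recordings, sheet, seed=1, n_restarts=6,
                             n_perm=499)
    return cfg, recordings, truths, sheet, result


@pytest.fixture(scope="session")
def planted_templates(cohort):
    """The planted group-level templates of the session cohort."""
    cfg, recordings, _, _ = cohort
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    return md.make_templates(recordings[0].montage, cfg.n_classes, rng)
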