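import numpy as np
import pytest

from stabilometry import CoPTrial, RunConfig, run_pipeline
from stabilometry.synthetic import SyntheticConfig


def make_trial(
    ml,
    ap,
    rate=50.0,
    subject_id="S01",
    group="young",
    condition="FO",
    session=1,
) -> CoPTrial:
    return CoPTrial(
        subject_id=subject_id,
        group=group,
        condition=condition,
        session=session,
        sampling_rate_hz=rate,
        ml_cm=np.asarray(ml, dtype=float),
        ap_cm=np.asarray(ap, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def standard_trial():
    """A plausible 50 Hz x 60 s trial: bounded fractal sway, cm scale."""
    from stabilometry.synthetic import generate_trial

    cfg = SyntheticConfig(seed=0)
    return generate_trial(0.5, 0.6, cfg, 2024)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default synthetic-cohort pipeline run, shared across tests.

    26 young + 15 elderly subjects x 4 conditions x 2 sessions at the
    default designed ICC of 0.8; seed fixed so every test sees the same
    artifacts.
    """
    out = tmp_path_factory.mktemp("default_run")
    config = RunConfig(synthetic=SyntheticConfig(seed=1), out_dir=str(out), seed=1)
    return config, run_pipeline(config)
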