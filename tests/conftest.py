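import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_phantom_spec():
    from optquant.phantom import default_spec

    return default_spec()


@pytest.fixture(scope="session")
def quiet_phantom_spec():
    """Single-niche, blur- and noise-free phantom for exact recovery checks."""
    from optquant.phantom import NicheSpec, PhantomSpec

    niche = NicheSpec(
        name="anterior",
        ap_span_um=(60.0, 210.0),
        kind="midline_band",
        hemisphere=None,
        focus_rate_per_um3=3e-4,
        focus_peak=30000.0,
    )
    return PhantomSpec(
        niches=(niche,),
        parenchyma_amplitude={g: 0.0 for g in ("control", "1dpl", "3dpl", "7dpl")},
        blur_sigma_um=0.0,
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory, default_phantom_spec):
    """A small on-disk phantom cohort shared by I/O and CLI tests."""
    from optquant.phantom import generate_cohort

    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(
        default_phantom_spec,
        {"control": 2, "1dpl": 2, "3dpl": 2, "7dpl": 2},
        seed=99,
        out_dir=out,
    )
    return out
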