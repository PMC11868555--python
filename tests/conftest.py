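import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params():
    from maldiauxie import DEFAULT_PARAMS

    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def rendered_plate_files(tmp_path_factory):
    """One default sequential-mode plate rendered to CSV (seeded)."""
    from maldiauxie import CultureConfig, NoiseModel, make_mixture_design, simulate_plate

    layout = make_mixture_design([0.2, 0.4, 0.6, 0.8], [0.5], replicates=2, blanks=2)
    plate = simulate_plate(layout, CultureConfig(), NoiseModel(), seed=7)
    out = tmp_path_factory.mktemp("plate")
    paths = plate.write(out)
    return paths, plate


def random_valid_params(rng, n_choices=(2, 3, 4), margin=1.05):
    """A random parameter set in the bounded regime (ratio above threshold)."""
    from maldiauxie import RegulonParams

    b_T = float(10 ** rng.uniform(-3, np.log10(0.5)))
    u_T_max = float(rng.uniform(0.5, 5.0))
    d_T = float(rng.uniform(0.3, 3.0))
    v_T = float(10 ** rng.uniform(-0.5, 0.5))
    rmin = (b_T + u_T_max) / d_T
    ratio = float(rmin * 10 ** rng.uniform(np.log10(margin), 1.0))
    return RegulonParams(
        v_T=v_T,
        u_I_max=ratio * v_T,
        u_T_max=u_T_max,
        b_T=b_T,
        d_T=d_T,
        K_T=float(rng.uniform(1.05, 6.0)),
        K_M=float(rng.uniform(0.3, 3.0)),
        n=int(rng.choice(n_choices)),
    )
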