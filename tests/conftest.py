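import numpy as np
import pytest

import pmfkit as pk


@pytest.fixture(scope="session")
def dimer_surface_linear():
    return pk.make_dimer_surface(kind="linear")


@pytest.fixture(scope="session")
def dimer_surface_radial():
    return pk.make_dimer_surface(kind="radial")


@pytest.fixture(scope="session")
def small_experiment(dimer_surface_linear):
    """10 windows across the contact well: quick but non-trivial."""
    cfg = pk.GeneratorConfig(
        n_windows=10, spacing=0.1, samples_per_window=800, seed=42, xi_start=0.3
    )
    return pk.generate_experiment(dimer_surface_linear, cfg)


def make_profile(xi, w, temperature=310.0, plateau_region=(0.0, 100.0)):
    """Hand-constructed plateau-zeroed profile for feature tests."""
    return pk.PmfProfile(
        xi=np.asarray(xi, dtype=float),
        w=np.asarray(w, dtype=float),
        temperature=temperature,
        plateau_region=plateau_region,
    )
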