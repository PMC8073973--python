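import numpy as np
import pytest

import lignosim as ls


@pytest.fixture(scope="session")
def severe_spec():
    """Severely pretreated synthetic substrate, seed 1 (the reference
    fixture substrate)."""
    return ls.generate_synthetic_substrate(seed=1, archetype="severe")


@pytest.fixture(scope="session")
def severe_derived(severe_spec):
    return ls.derive_substrate(severe_spec)


@pytest.fixture(scope="session")
def reference_traj(severe_spec):
    """Reference run: severe substrate, e_l = 1, b_l = 0.02 g/cm^3, n = 50,
    24 h horizon, default tolerances."""
    return ls.simulate(severe_spec, e_l=1.0, b_l=0.02, n=50, t_end=1440.0)


@pytest.fixture(scope="session")
def understoich_traj(severe_spec):
    """Enzyme-starved run (e_l = 0.5) on a 200 um particle with dense
    linear output times, used for rate/coverage phasing checks."""
    import dataclasses

    spec = ls.generate_synthetic_substrate(seed=1, archetype="ds2_beech")
    times = np.concatenate([[0.0], np.geomspace(1.0, 1440.0, 160)])
    return ls.simulate(spec, e_l=0.5, b_l=0.07, n=24, output_times=times)
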