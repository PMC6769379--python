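import numpy as np
import pytest

import kgate


@pytest.fixture
def two_state_traces():
    """Small set of synthetic two-state binding traces with ground truth."""
    spec = kgate.RateSpec.two_state(kd_mm=8.0, k_off=0.1, concentration=1.0)
    return spec, kgate.gen_binding_traj(spec, duration=120.0, dt=0.002,
                                        n_monomers=6, seed=7)


def make_occupancy(states, site_order=("K1",), dt=1.0, concentration=1.0):
    """Build an OccupancyTrace directly from an encoded state array."""
    states = np.asarray(states, dtype=np.int64)
    bound = {s: ((states >> b) & 1).astype(bool)
             for b, s in enumerate(site_order)}
    return kgate.OccupancyTrace("manual", dt, tuple(site_order), bound,
                                states, {s: 3.5 for s in site_order},
                                concentration=concentration)
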