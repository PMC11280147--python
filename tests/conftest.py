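import numpy as np
import pytest

from glennpvr import (
    GlennLPCircuit,
    load_patient_table,
    synth_inlet_waveform,
)


@pytest.fixture(scope="session")
def bundled():
    return load_patient_table("bundled")


@pytest.fixture
def symmetric_circuit():
    return GlennLPCircuit(r_svc=0.0, r_lpa_outlet=6.0, r_rpa_outlet=6.0, p_dist_l=4.0, p_dist_r=4.0)


@pytest.fixture
def pulsatile_inlet():
    return synth_inlet_waveform(mean=2.0, pulsatility=0.3, cycle_length=0.8, dt=0.001)


def random_circuit(rng: np.random.Generator) -> GlennLPCircuit:
    """Valid random circuit spanning physiological and unphysiological corners."""
    return GlennLPCircuit(
        r_svc=float(rng.uniform(0.0, 2.0)),
        r_lpa_vessel=float(rng.uniform(0.0, 1.0)),
        r_rpa_vessel=float(rng.uniform(0.0, 1.0)),
        r_lpa_outlet=float(rng.uniform(0.5, 15.0)),
        r_rpa_outlet=float(rng.uniform(0.5, 15.0)),
        p_dist_l=float(rng.uniform(0.0, 10.0)),
        p_dist_r=float(rng.uniform(0.0, 10.0)),
    )
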