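"""Flow waveforms and synthetic patient generation.

A :class:`FlowWaveform` holds one cardiac cycle of flow samples on a uniform,
endpoint-exclusive grid t = 0, dt, ..., (n-1)*dt with n = l/dt, extended
periodically (the value at t = l is the value at t = 0). The endpoint-exclusive
convention makes a full sinusoidal period average exactly to its mean, which is
what anchors synthetic waveforms to a prescribed cycle-averaged flow.

Synthetic patients stand in for phase-contrast CMR measurements, which are not
publicly available for the clinical cohort: a ground-truth circuit is simulated
on a raised-sinusoid inlet and the branch flows are observed with optional
additive Gaussian noise, giving an inverse problem with a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import DomainError
from .patient_data import PatientRecord

if TYPE_CHECKING:  # pragma: no cover
    from .circuit import GlennLPCircuit


@dataclass(frozen=True)
class FlowWaveform:
    """One cardiac cycle of flow on a uniform endpoint-exclusive grid.

    Parameters
    ----------
    samples
        Flow values (L/min/m^2) at t = 0, dt, ..., (n-1)*dt.
    cycle_length
        Cycle length l in seconds; dt = l / n.
    """

    samples: np.ndarray
    cycle_length: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.cycle_length <= 0:
            raise DomainError(f"cycle length must be positive, got {self.cycle_length}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise DomainError("waveform needs at least 2 samples on a 1-D grid")
        if not np.all(np.isfinite(self.samples)):
            raise DomainError("waveform samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return self.cycle_length / self.n

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt


def time_average(w: FlowWaveform) -> float:
    """Cycle average: the arithmetic mean of the n samples."""
    return float(np.mean(w.samples))


def synth_inlet_waveform(
    mean: float,
    pulsatility: float,
    cycle_length: float = 0.8,
    dt: float = 0.001,
    phase: float = 0.0,
) -> FlowWaveform:
    """Raised-sinusoid inlet flow: mean * (1 + pulsatility * sin(2*pi*t/l + phase)).

    ``pulsatility`` is the peak excursion as a fraction of the mean; it must be
    < 1 so the inlet flow stays strictly positive (venous return to the lungs
    does not reverse in Glenn physiology).
    """
    if mean <= 0:
        raise DomainError(f"mean flow must be positive, got {mean}")
    if not (0 <= pulsatility < 1):
        raise DomainError(f"pulsatility must be in [0, 1), got {pulsatility}")
    n = int(round(cycle_length / dt))
    if n < 2:
        raise DomainError(f"dt = {dt} gives fewer than 2 samples per cycle")
    t = np.arange(n) * (cycle_length / n)
    samples = mean * (1.0 + pulsatility * np.sin(2.0 * np.pi * t / cycle_length + phase))
    return FlowWaveform(samples=samples, cycle_length=cycle_length)


def resample_linear(w: FlowWaveform, dt_new: float) -> FlowWaveform:
    """Resample by periodic linear interpolation onto a new uniform grid.

    Values at coincident grid points are preserved; between the last sample and
    t = l the interpolant wraps around to the t = 0 sample.
    """
    if dt_new <= 0:
        raise DomainError(f"dt_new must be positive, got {dt_new}")
    if dt_new > w.cycle_length / 2:
        raise DomainError("dt_new must leave at least 2 samples per cycle")
    n_new = int(round(w.cycle_length / dt_new))
    t_new = np.arange(n_new) * (w.cycle_length / n_new)
    samples = np.interp(t_new, w.times, w.samples, period=w.cycle_length)
    return FlowWaveform(samples=samples, cycle_length=w.cycle_length)


def read_waveform_csv(path: str | Path) -> FlowWaveform:
    """Read a one-cycle waveform CSV with columns ``time_s,flow_lpm_m2``."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-9, atol=1e-12):
        raise DomainError(f"{path}: time grid is not uniform")
    cycle_length = dt * len(t)
    return FlowWaveform(samples=df["flow_lpm_m2"].to_numpy(dtype=float), cycle_length=cycle_length)


def write_waveform_csv(w: FlowWaveform, path: str | Path) -> None:
    """Write a waveform CSV that round-trips at 12 significant digits."""
    pd.DataFrame({"time_s": w.times, "flow_lpm_m2": w.samples}).to_csv(
        path, index=False, float_format="%.12g"
    )


@dataclass(frozen=True)
class SyntheticPatientScenario:
    """Ground truth for one synthetic patient.

    ``noise`` is the SD of the additive Gaussian noise on each observed branch
    flow sample, as a fraction of that branch's cycle-averaged flow. The inlet
    is treated as exactly known (a Dirichlet inlet), so only branch flows are
    noisy.
    """

    circuit: "GlennLPCircuit"
    inlet_mean: float
    pulsatility: float = 0.3
    cycle_length: float = 0.8
    dt: float = 0.001
    phase: float = 0.0
    noise: float = 0.0
    seed: int = 0
    pid: str = "synthetic"
    bsa: float = 0.56
    sex: str = "M"
    age: float = 4.0

    def __post_init__(self) -> None:
        if self.inlet_mean <= 0:
            raise DomainError("inlet mean must be positive")
        if not (0 <= self.pulsatility < 1):
            raise DomainError("pulsatility must be in [0, 1)")
        if self.noise < 0:
            raise DomainError("noise level must be >= 0")


def synthetic_cohort(
    n: int,
    seed: int,
    noise: float = 0.0,
    pulsatility: float = 0.3,
    cycle_length: float = 0.8,
    dt: float = 0.001,
    r_svc: float = 0.0,
    r_lpa_vessel: float = 0.0,
    r_rpa_vessel: float = 0.0,
) -> list[SyntheticPatientScenario]:
    """Seeded scenarios spanning the clinical cohort's parameter ranges.

    Outlet resistances are drawn uniformly from 2-12 WU*m^2 (the computed
    per-lung PVR range of the bundled cohort), distal pressures from 3-7 mmHg
    (its left-atrial pressure range) with equal left/right values, and inlet
    means from 1.2-3.2 L/min/m^2 (its SVC flow range).
    """
    from .circuit import GlennLPCircuit

    rng = np.random.default_rng(seed)
    scenarios = []
    for i in range(n):
        p_la = float(rng.uniform(3.0, 7.0))
        circuit = GlennLPCircuit(
            r_svc=r_svc,
            r_lpa_vessel=r_lpa_vessel,
            r_rpa_vessel=r_rpa_vessel,
            r_lpa_outlet=float(rng.uniform(2.0, 12.0)),
            r_rpa_outlet=float(rng.uniform(2.0, 12.0)),
            p_dist_l=p_la,
            p_dist_r=p_la,
        )
        scenarios.append(
            SyntheticPatientScenario(
                circuit=circuit,
                inlet_mean=float(rng.uniform(1.2, 3.2)),
                pulsatility=pulsatility,
                cycle_length=cycle_length,
                dt=dt,
                noise=noise,
                seed=int(rng.integers(0, 2**31 - 1)),
                pid=f"synth{i + 1:02d}",
            )
        )
    return scenarios


def make_synthetic_patient(
    scenario: SyntheticPatientScenario,
) -> tuple[PatientRecord, FlowWaveform, tuple[FlowWaveform, FlowWaveform]]:
    """Simulate the ground-truth circuit and observe its branch flows.

    Returns the patient record built from the noise-free simulation's cycle
    averages, the (noise-free) inlet waveform, and the observed LPA/RPA flow
    waveforms with seeded Gaussian noise at the scenario's level. With zero
    noise the observed waveforms satisfy the circuit equations exactly, so the
    ground-truth resistances have zero calibration cost.
    """
    from .circuit import simulate  # deferred: circuit depends on this module
    from .direct import total_pvr

    inlet = synth_inlet_waveform(
        scenario.inlet_mean,
        scenario.pulsatility,
        scenario.cycle_length,
        scenario.dt,
        scenario.phase,
    )
    sim = simulate(scenario.circuit, inlet)
    rng = np.random.default_rng(scenario.seed)
    observed = []
    for clean in (sim.q_l, sim.q_r):
        sd = scenario.noise * time_average(clean)
        noisy = clean.samples + rng.normal(0.0, sd, clean.n) if sd > 0 else clean.samples.copy()
        observed.append(FlowWaveform(samples=noisy, cycle_length=clean.cycle_length))

    q_lpa = time_average(sim.q_l)
    q_rpa = time_average(sim.q_r)
    p_svc = time_average(sim.p_svc)
    p_junc = time_average(sim.p_junction)
    p_la = scenario.circuit.p_dist_l
    dp = p_svc - p_la
    record = PatientRecord(
        pid=scenario.pid,
        sex=scenario.sex,
        bsa=scenario.bsa,
        age=scenario.age,
        q_svc=time_average(inlet),
        q_lpa=q_lpa,
        q_rpa=q_rpa,
        pvr_cath=total_pvr(dp / q_lpa, dp / q_rpa) if dp > 0 else 0.0,
        qp_cath=q_lpa + q_rpa,
        p_svc=p_svc,
        p_lpa=p_junc,
        p_rpa=p_junc,
        p_la=p_la,
        p_ra=scenario.circuit.p_dist_r,
    )
    return record, inlet, (observed[0], observed[1])
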