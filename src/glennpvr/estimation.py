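"""Calibration of the two outlet resistances against clinical flow/pressure.

The calibration minimizes a discrepancy between simulated and clinically
measured hemodynamics over the pair (R_LPA_outlet, R_RPA_outlet):

    f = (1/n) * sum_t [ (Qc_LPA(t) - Qs_LPA(t))^2 / Qbar_c_LPA
                      + (Qc_RPA(t) - Qs_RPA(t))^2 / Qbar_c_RPA ]
      + (Pbar_c_SVC - Pbar_s_SVC)^2 / Pbar_c_SVC

where c/s denote clinical and simulated data and overbars are cycle averages.
The pressure term is constant over the cycle, so adding it once is identical
to carrying it under the time average; the denominators are the clinical cycle
averages as given, which leaves the flow and pressure terms in heterogeneous
units — deliberate, as the weighting is part of the method. Minimization uses
the Nelder-Mead simplex with absolute tolerance 1e-4 on both the parameter
simplex and the function values; non-positive candidate resistances receive a
large finite penalty instead of a simulation.

The simulation backend is a plain callable (r_lpa_outlet, r_rpa_outlet) ->
SimulationResult, so an external solver (e.g. a 3D CFD runner) could be
swapped in behind the same calibration loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .circuit import GlennLPCircuit, SimulationResult, simulate, simulate_nodal
from .direct import computed_pvr
from .errors import AlignmentError, DomainError
from .patient_data import PatientRecord
from .waveforms import FlowWaveform, synth_inlet_waveform, time_average

Backend = Callable[[float, float], SimulationResult]


@dataclass(frozen=True)
class ClinicalTarget:
    """Observed branch flow waveforms and mean SVC pressure to calibrate against."""

    q_lpa_obs: FlowWaveform
    q_rpa_obs: FlowWaveform
    p_svc_mean_obs: float

    def __post_init__(self) -> None:
        if self.p_svc_mean_obs <= 0:
            raise DomainError("mean SVC pressure target must be positive")
        if self.q_lpa_mean <= 0 or self.q_rpa_mean <= 0:
            raise DomainError("mean branch flow targets must be positive (cost denominators)")

    @property
    def q_lpa_mean(self) -> float:
        return time_average(self.q_lpa_obs)

    @property
    def q_rpa_mean(self) -> float:
        return time_average(self.q_rpa_obs)


@dataclass(frozen=True)
class PVRReport:
    """Reported per-lung PVR and its series decomposition (all WU*m^2).

    ``pvr_l``/``pvr_r`` follow the computed-PVR definition, mean pressure drop
    from SVC to the distal bed over mean branch flow; each decomposition maps
    resistor names to their Ohmic drops at mean flow expressed as resistances,
    plus the pulsatility-induced averaging ``residual``.
    """

    pvr_l: float
    pvr_r: float
    decomposition_l: dict[str, float]
    decomposition_r: dict[str, float]


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of one outlet-resistance calibration."""

    r_lpa_outlet: float
    r_rpa_outlet: float
    pvr_l: float
    pvr_r: float
    decomposition_l: dict[str, float]
    decomposition_r: dict[str, float]
    cost: float
    n_evaluations: int
    converged: bool
    simulation: SimulationResult


def cost(clinical: ClinicalTarget, simulated: SimulationResult) -> float:
    """Flow-and-pressure discrepancy; zero iff simulated matches clinical."""
    n = clinical.q_lpa_obs.n
    if simulated.q_l.n != n or simulated.q_r.n != n:
        raise AlignmentError(
            f"grid mismatch: clinical n = {n}, simulated n = ({simulated.q_l.n}, {simulated.q_r.n});"
            " resample first"
        )
    if abs(simulated.q_l.cycle_length - clinical.q_lpa_obs.cycle_length) > 1e-9:
        raise AlignmentError("cycle lengths differ between clinical and simulated waveforms")
    dl = clinical.q_lpa_obs.samples - simulated.q_l.samples
    dr = clinical.q_rpa_obs.samples - simulated.q_r.samples
    flow_term = float(
        np.mean(dl**2 / clinical.q_lpa_mean + dr**2 / clinical.q_rpa_mean)
    )
    dp = clinical.p_svc_mean_obs - simulated.mean_p_svc
    return flow_term + dp**2 / clinical.p_svc_mean_obs


def initial_guess(
    cohort: Sequence[PatientRecord],
    proximal_resistance: float = 0.0,
    floor: float = 0.1,
) -> tuple[float, float]:
    """Cohort-wide starting point: mean computed per-lung PVR, net of the
    configured proximal series resistance, floored at ``floor`` WU*m^2.

    Every patient's calibration starts from this same pair.
    """
    pairs = []
    for rec in cohort:
        try:
            pairs.append(computed_pvr(rec))
        except DomainError:
            import warnings

            warnings.warn(f"patient {rec.pid}: zero branch flow, excluded from initial guess",
                          stacklevel=2)
    if not pairs:
        raise DomainError("no usable patients for the cohort initial guess")
    arr = np.asarray(pairs)
    r0 = arr.mean(axis=0) - proximal_resistance
    return (max(float(r0[0]), floor), max(float(r0[1]), floor))


def report_pvr(sim: SimulationResult, circuit: GlennLPCircuit) -> PVRReport:
    """Per-lung PVR of a simulation, with its series decomposition.

    PVR per lung is (mean P_SVC - p_dist)/mean branch flow. The decomposition
    expresses each series element's Ohmic drop at the relevant mean flow as a
    resistance seen by that lung's mean flow; for a constant inlet the parts
    sum exactly to the PVR, and under pulsatile flow the averaging mismatch is
    reported as ``residual``.
    """
    q_l, q_r = sim.mean_q_l, sim.mean_q_r
    if q_l <= 0 or q_r <= 0:
        raise DomainError("mean branch flow must be positive to report PVR")
    q_in = q_l + q_r
    p_svc = sim.mean_p_svc
    reports = {}
    for side, q, r_vessel, r_outlet, p_dist in (
        ("l", q_l, circuit.r_lpa_vessel, circuit.r_lpa_outlet, circuit.p_dist_l),
        ("r", q_r, circuit.r_rpa_vessel, circuit.r_rpa_outlet, circuit.p_dist_r),
    ):
        pvr = (p_svc - p_dist) / q
        svc_share = circuit.r_svc * q_in / q  # inlet drop carried by this lung's flow
        residual = pvr - (svc_share + r_vessel + r_outlet)
        reports[side] = (
            pvr,
            {"svc": svc_share, "vessel": r_vessel, "outlet": r_outlet, "residual": residual},
        )
    return PVRReport(
        pvr_l=reports["l"][0],
        pvr_r=reports["r"][0],
        decomposition_l=reports["l"][1],
        decomposition_r=reports["r"][1],
    )


class GlennPVREstimator(BaseEstimator):
    """Nelder-Mead calibration of the two outlet resistances.

    Parameters
    ----------
    circuit_template
        Circuit carrying the fixed elements (inlet/junction resistance, vessel
        resistances, distal pressures); its outlet values are only used to
        build candidate circuits. Defaults to all resistance in the outlets
        and distal pressures of 4.5 mmHg.
    init
        Starting pair (r_lpa_outlet, r_rpa_outlet); see :func:`initial_guess`
        for the cohort-wide choice.
    tol
        Absolute Nelder-Mead tolerance applied to both the simplex spread and
        the function-value spread.
    max_evals
        Evaluation budget; exhausted -> best point returned, ``converged_``
        False.
    penalty
        Finite cost assigned to candidates with any resistance <= 0.
    backend
        ``"closed_form"`` (default), ``"nodal"`` (verification path), or a
        factory ``(circuit_template, inlet) -> Backend`` for an external
        simulator.

    Attributes (after :meth:`fit`)
    ------------------------------
    r_lpa_outlet_, r_rpa_outlet_ : calibrated outlet resistances (WU*m^2)
    pvr_l_, pvr_r_ : reported per-lung PVR (WU*m^2)
    decomposition_l_, decomposition_r_ : series decomposition per lung
    cost_, n_evaluations_, converged_, simulation_, result_
    """

    def __init__(
        self,
        circuit_template: GlennLPCircuit | None = None,
        init: tuple[float, float] = (6.0, 6.0),
        tol: float = 1e-4,
        max_evals: int = 2000,
        penalty: float = 1e6,
        backend="closed_form",
    ):
        self.circuit_template = circuit_template
        self.init = init
        self.tol = tol
        self.max_evals = max_evals
        self.penalty = penalty
        self.backend = backend

    def _make_backend(self, template: GlennLPCircuit, inlet: FlowWaveform) -> Backend:
        if callable(self.backend):
            return self.backend(template, inlet)
        run = {"closed_form": simulate, "nodal": simulate_nodal}.get(self.backend)
        if run is None:
            raise DomainError(f"unknown backend {self.backend!r}")

        def backend(r_l: float, r_r: float) -> SimulationResult:
            return run(replace(template, r_lpa_outlet=r_l, r_rpa_outlet=r_r), inlet)

        return backend

    def fit(self, inlet: FlowWaveform, clinical: ClinicalTarget) -> "GlennPVREstimator":
        """Calibrate the outlet resistances for one patient."""
        if self.tol <= 0:
            raise DomainError("tolerance must be positive")
        template = self.circuit_template or GlennLPCircuit()
        backend = self._make_backend(template, inlet)
        n_evals = 0

        def objective(x: np.ndarray) -> float:
            nonlocal n_evals
            n_evals += 1
            if x[0] <= 0 or x[1] <= 0:
                return self.penalty
            return cost(clinical, backend(x[0], x[1]))

        res = minimize(
            objective,
            x0=np.asarray(self.init, dtype=float),
            method="Nelder-Mead",
            options={
                "xatol": self.tol,
                "fatol": self.tol,
                "maxfev": self.max_evals,
                "disp": False,
            },
        )
        r_l, r_r = float(res.x[0]), float(res.x[1])
        if r_l <= 0 or r_r <= 0:
            # budget exhausted inside the penalty region: nothing to report
            raise DomainError(
                "calibration ended at a non-positive resistance "
                f"({r_l:.3g}, {r_r:.3g}); increase max_evals or fix the initial guess"
            )
        final_circuit = replace(template, r_lpa_outlet=r_l, r_rpa_outlet=r_r)
        sim = backend(r_l, r_r)
        report = report_pvr(sim, final_circuit)
        self.r_lpa_outlet_, self.r_rpa_outlet_ = r_l, r_r
        self.pvr_l_, self.pvr_r_ = report.pvr_l, report.pvr_r
        self.decomposition_l_ = report.decomposition_l
        self.decomposition_r_ = report.decomposition_r
        self.cost_ = float(res.fun)
        self.n_evaluations_ = n_evals
        self.converged_ = bool(res.success)
        self.simulation_ = sim
        self.result_ = OptimizationResult(
            r_lpa_outlet=r_l,
            r_rpa_outlet=r_r,
            pvr_l=report.pvr_l,
            pvr_r=report.pvr_r,
            decomposition_l=report.decomposition_l,
            decomposition_r=report.decomposition_r,
            cost=self.cost_,
            n_evaluations=n_evals,
            converged=self.converged_,
            simulation=sim,
        )
        return self


def optimize_pvr(
    circuit_template: GlennLPCircuit,
    inlet: FlowWaveform,
    clinical: ClinicalTarget,
    init: tuple[float, float],
    tol: float = 1e-4,
    max_evals: int = 2000,
    penalty: float = 1e6,
    backend="closed_form",
) -> OptimizationResult:
    """Functional wrapper over :class:`GlennPVREstimator`."""
    est = GlennPVREstimator(
        circuit_template=circuit_template,
        init=init,
        tol=tol,
        max_evals=max_evals,
        penalty=penalty,
        backend=backend,
    )
    return est.fit(inlet, clinical).result_


def make_consistent_target(
    record: PatientRecord,
    r_svc: float = 0.0,
    r_lpa_vessel: float = 0.0,
    r_rpa_vessel: float = 0.0,
    pulsatility: float = 0.3,
    cycle_length: float = 0.8,
    dt: float = 0.001,
) -> tuple[GlennLPCircuit, FlowWaveform, ClinicalTarget]:
    """Self-consistent calibration problem for one clinical record.

    Clinical tables generally violate mass conservation (the measured SVC
    inflow need not equal the summed branch flows), so a circuit cannot match
    every column at once. This stand-in builds the circuit whose outlet
    resistances equal the record's computed per-lung PVR (net of any proximal
    resistance), drives it with a synthetic inlet whose mean is the summed
    branch flows, and observes its own branch waveforms — the optimum of the
    resulting calibration problem is the computed PVR by construction.
    """
    r_l, r_r = computed_pvr(record)
    circuit = GlennLPCircuit(
        r_svc=r_svc,
        r_lpa_vessel=r_lpa_vessel,
        r_rpa_vessel=r_rpa_vessel,
        r_lpa_outlet=max(r_l - r_svc - r_lpa_vessel, 0.1),
        r_rpa_outlet=max(r_r - r_svc - r_rpa_vessel, 0.1),
        p_dist_l=record.p_la,
        p_dist_r=record.p_la,
    )
    inlet = synth_inlet_waveform(record.q_lpa + record.q_rpa, pulsatility, cycle_length, dt)
    sim = simulate(circuit, inlet)
    target = ClinicalTarget(
        q_lpa_obs=sim.q_l, q_rpa_obs=sim.q_r, p_svc_mean_obs=sim.mean_p_svc
    )
    return circuit, inlet, target
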