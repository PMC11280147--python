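"""The 0D resistive Glenn circuit and its solvers.

Topology: SVC inlet flow -> series resistor ``r_svc`` (the SVC and pulmonary
artery junction, folded into one resistor upstream of the split) -> junction
node -> two branches, each a vessel resistor in series with an outlet resistor
terminated by a constant distal pressure (the downstream pulmonary bed, taken
as left atrial pressure). Each element obeys the pressure-flow relation
``dP = R * Q``; there is no compliance, so the circuit is memoryless and a
single cycle reaches the periodic solution.

Two independent solution paths are provided: a closed-form per-timestep solver
(used by the pipeline) and a generic modified-nodal-analysis linear solve
(used only for verification).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SingularCircuitError
from .waveforms import FlowWaveform, time_average

#: dyn*s*cm^-5 per Wood unit (mmHg*min/L): 1333.22 dyn/cm^2 per mmHg, 60 s/min, 1000 cm^3/L
_CGS_PER_WU = 1333.22 * 60.0 / 1000.0


@dataclass(frozen=True)
class GlennLPCircuit:
    """Resistor network of the Glenn pathway, all resistances in WU*m^2.

    ``p_dist_l`` / ``p_dist_r`` are the constant distal pressures (mmHg)
    terminating each lung's outlet resistor.
    """

    r_svc: float = 0.0
    r_lpa_vessel: float = 0.0
    r_rpa_vessel: float = 0.0
    r_lpa_outlet: float = 6.0
    r_rpa_outlet: float = 6.0
    p_dist_l: float = 4.5
    p_dist_r: float = 4.5

    def __post_init__(self) -> None:
        for name in ("r_svc", "r_lpa_vessel", "r_rpa_vessel", "r_lpa_outlet", "r_rpa_outlet"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.branch_total_l == 0 and self.branch_total_r == 0:
            raise DomainError("at least one branch must have positive total resistance")

    @property
    def branch_total_l(self) -> float:
        return self.r_lpa_vessel + self.r_lpa_outlet

    @property
    def branch_total_r(self) -> float:
        return self.r_rpa_vessel + self.r_rpa_outlet


@dataclass(frozen=True)
class SimulationResult:
    """Branch flows and node pressures over one cycle, with cycle averages."""

    q_l: FlowWaveform
    q_r: FlowWaveform
    p_svc: FlowWaveform
    p_junction: FlowWaveform

    @property
    def mean_q_l(self) -> float:
        return time_average(self.q_l)

    @property
    def mean_q_r(self) -> float:
        return time_average(self.q_r)

    @property
    def mean_p_svc(self) -> float:
        return time_average(self.p_svc)

    @property
    def mean_p_junction(self) -> float:
        return time_average(self.p_junction)


def solve_timestep(circuit: GlennLPCircuit, q_in):
    """Closed-form solution for one inlet-flow value (or an array of them).

    Returns ``(q_l, q_r, p_junction, p_svc)``. The junction pressure follows
    from current conservation at the junction node:

        p_j = (q_in + p_dist_l / R_Lt + p_dist_r / R_Rt) / (1/R_Lt + 1/R_Rt)

    and each branch flow is its Ohmic drop over the branch total. A branch with
    zero total resistance pins the junction to its distal pressure (degenerate,
    warned); both branches at zero resistance is singular.
    """
    q_in = np.asarray(q_in, dtype=float)
    r_l, r_r = circuit.branch_total_l, circuit.branch_total_r
    if r_l == 0 and r_r == 0:
        raise SingularCircuitError("both branch totals are zero")
    if r_l == 0 or r_r == 0:
        warnings.warn("zero-resistance branch: junction pinned to its distal pressure",
                      stacklevel=2)
        if r_l == 0:
            p_j = np.full_like(q_in, circuit.p_dist_l)
            q_r = (p_j - circuit.p_dist_r) / r_r
            q_l = q_in - q_r
        else:
            p_j = np.full_like(q_in, circuit.p_dist_r)
            q_l = (p_j - circuit.p_dist_l) / r_l
            q_r = q_in - q_l
    else:
        g_l, g_r = 1.0 / r_l, 1.0 / r_r
        p_j = (q_in + circuit.p_dist_l * g_l + circuit.p_dist_r * g_r) / (g_l + g_r)
        q_l = (p_j - circuit.p_dist_l) * g_l
        q_r = (p_j - circuit.p_dist_r) * g_r
    p_svc = p_j + q_in * circuit.r_svc
    return q_l, q_r, p_j, p_svc


def simulate(circuit: GlennLPCircuit, inlet: FlowWaveform) -> SimulationResult:
    """Apply the closed-form solver at every timestep of one cycle.

    The circuit is memoryless, so the output at t depends only on the inlet
    flow at t and one cycle is the steady state.
    """
    q_l, q_r, p_j, p_svc = solve_timestep(circuit, inlet.samples)
    l = inlet.cycle_length
    return SimulationResult(
        q_l=FlowWaveform(q_l, l),
        q_r=FlowWaveform(q_r, l),
        p_svc=FlowWaveform(p_svc, l),
        p_junction=FlowWaveform(p_j, l),
    )


def nodal_oracle(circuit: GlennLPCircuit, q_in: float):
    """Independent solve by modified nodal analysis; no closed form used.

    Unknowns are the four node pressures (SVC, junction, and the two
    mid-branch nodes between vessel and outlet resistors) plus the five
    resistor currents. Equations: Kirchhoff's current law at each node and the
    pressure-flow relation across each resistor. Zero resistances are plain
    wires, so the system stays well posed unless both branches short the
    junction to conflicting distal pressures.
    """
    # x = [p_svc, p_j, p_ml, p_mr, i_svc, i_lv, i_lo, i_rv, i_ro]
    A = np.zeros((9, 9))
    b = np.zeros(9)
    # KCL: inlet node, junction, mid-left, mid-right
    A[0, 4] = 1.0
    b[0] = q_in
    A[1, 4], A[1, 5], A[1, 7] = 1.0, -1.0, -1.0
    A[2, 5], A[2, 6] = 1.0, -1.0
    A[3, 7], A[3, 8] = 1.0, -1.0
    # dP = R*Q across each resistor
    A[4, 0], A[4, 1], A[4, 4] = 1.0, -1.0, -circuit.r_svc
    A[5, 1], A[5, 2], A[5, 5] = 1.0, -1.0, -circuit.r_lpa_vessel
    A[6, 2], A[6, 6] = 1.0, -circuit.r_lpa_outlet
    b[6] = circuit.p_dist_l
    A[7, 1], A[7, 3], A[7, 7] = 1.0, -1.0, -circuit.r_rpa_vessel
    A[8, 3], A[8, 8] = 1.0, -circuit.r_rpa_outlet
    b[8] = circuit.p_dist_r
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise SingularCircuitError("nodal system is singular") from exc
    p_svc, p_j = x[0], x[1]
    q_l, q_r = x[5], x[7]
    return float(q_l), float(q_r), float(p_j), float(p_svc)


def simulate_nodal(circuit: GlennLPCircuit, inlet: FlowWaveform) -> SimulationResult:
    """Per-timestep nodal-analysis simulation (verification path; slower)."""
    out = np.array([nodal_oracle(circuit, q) for q in inlet.samples])
    l = inlet.cycle_length
    return SimulationResult(
        q_l=FlowWaveform(out[:, 0], l),
        q_r=FlowWaveform(out[:, 1], l),
        p_junction=FlowWaveform(out[:, 2], l),
        p_svc=FlowWaveform(out[:, 3], l),
    )


def poiseuille_resistance(mu: float, length: float, radius: float, bsa: float | None = None) -> float:
    """Hagen-Poiseuille resistance of a straight vessel, in Wood units.

    Parameters are in CGS units (mu in poise, length and radius in cm); the
    default blood viscosity used elsewhere in the package is 0.04 poise.
    R = 8*mu*L/(pi*r^4) in dyn*s*cm^-5 is converted to WU; if ``bsa`` (m^2) is
    given the result is BSA-indexed (WU*m^2).
    """
    if mu <= 0 or length <= 0 or radius <= 0:
        raise DomainError("viscosity, length and radius must all be positive")
    r_cgs = 8.0 * mu * length / (np.pi * radius**4)
    r_wu = r_cgs / _CGS_PER_WU
    if bsa is not None:
        if bsa <= 0:
            raise DomainError(f"BSA must be positive, got {bsa}")
        r_wu *= bsa
    return float(r_wu)
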