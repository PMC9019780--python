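"""Closed-loop lumped-parameter circulation coupled to the LV model.

Five-compartment left-heart circuit: LV (finite-element chamber, tabulated
response surface, or a time-varying elastance surrogate), arterial chamber
(compliance), right ventricle (elastance), pulmonary chamber (compliance) and
left atrium (elastance).  Valves are ideal diodes in series with resistances
(aortic, mitral); the systemic and pulmonic branches carry resistances with
check valves protecting the upstream chamber; a small pulmonary-venous
resistance closes the loop into the atrium.  Aortic stenosis is imposed by
raising the aortic valve resistance.

Volumes are the state variables; pressures follow from elastances and
compliances, so total blood volume is conserved exactly up to round-off.

Units: kPa, mL, s; resistances kPa*s/mL, compliances mL/kPa, elastances
kPa/mL.  1 mmHg = 0.133322 kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .fem import FemProblem, FemSolution, cavity_volume, solve_volume_constrained

__all__ = [
    "MMHG", "ElastanceWaveform", "CirculationParams", "CirculationState",
    "CycleSolution", "ElastanceLV", "ResponseSurfaceLV", "FemLV",
    "valve_flow", "step_circulation", "run_cycles", "detect_steady_state",
    "build_response_surface",
]

MMHG = 0.133322   # kPa per mmHg


def valve_flow(dp: float, R: float) -> float:
    """Ideal diode in series with a resistance: q = dp/R for dp > 0, else 0."""
    if R <= 0:
        raise ValueError("valve resistance must be > 0")
    return dp / R if dp > 0.0 else 0.0


@dataclass(frozen=True)
class ElastanceWaveform:
    """Periodic chamber elastance: E(t) = e_min + (e_max-e_min) * act(t).

    ``act`` is a raised-cosine pulse of duration ``duration`` starting at
    ``onset`` (s, within the cycle; wraps periodically).
    """

    e_min: float
    e_max: float
    onset: float
    duration: float
    period: float = 0.8

    def activation(self, t: float) -> float:
        tau = (t - self.onset) % self.period
        if tau < self.duration:
            return 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / self.duration))
        return 0.0

    def __call__(self, t: float) -> float:
        return self.e_min + (self.e_max - self.e_min) * self.activation(t)

    def scaled(self, amp: float) -> "ElastanceWaveform":
        return replace(self, e_max=self.e_min + amp * (self.e_max - self.e_min))


@dataclass(frozen=True)
class CirculationParams:
    """Lumped circuit constants (working values; calibration tunes a subset).

    The source model's printed constants are recorded in
    ``PRINTED_SOURCE_CONSTANTS`` for documentation; as typeset they are
    mutually inconsistent in magnitude, so the working defaults below are
    physiologic starting values on the package's unit system.
    """

    r_av: float = 0.008      # aortic valve, kPa*s/mL (raised -> stenosis)
    r_mv: float = 0.004      # mitral valve
    r_art: float = 0.14      # systemic arterial bed
    r_pul: float = 0.015     # pulmonic valve + pulmonary bed
    r_ven: float = 0.004     # pulmonary venous return into the LA
    c_art: float = 9.0       # arterial compliance mL/kPa (~1.2 mL/mmHg)
    c_pul: float = 30.0      # pulmonary compliance
    v0_art: float = 350.0    # unstressed volumes, mL
    v0_pul: float = 250.0
    v0_la: float = 20.0
    v0_rv: float = 40.0
    e_la: ElastanceWaveform = field(default_factory=lambda: ElastanceWaveform(
        e_min=0.020, e_max=0.050, onset=0.70, duration=0.14))
    e_rv: ElastanceWaveform = field(default_factory=lambda: ElastanceWaveform(
        e_min=0.008, e_max=0.070, onset=0.0, duration=0.40))
    total_blood_volume: float = 1200.0
    period: float = 0.8
    dt: float = 1e-3

    def validate(self) -> None:
        for n in ("r_av", "r_mv", "r_art", "r_pul", "r_ven", "c_art", "c_pul"):
            if getattr(self, n) <= 0:
                raise ValueError(f"{n} must be > 0")
        if self.total_blood_volume <= 0:
            raise ValueError("total_blood_volume must be > 0")


#: Source-model circulation constants exactly as printed (documentation only;
#: not used numerically -- the typeset magnitudes are mutually inconsistent).
PRINTED_SOURCE_CONSTANTS = {
    "aortic_valve_resistance": "5e-9 MPa*s/mm^3",
    "arterial_resistance": "1.35e+02 MPa*sec/mm^3",
    "pulmonary_vascular_resistance": "8e+0 MPa*sec/mm^3",
    "mitral_valve_resistance": "2e+0 MPa*sec/mm^3",
    "arterial_compliance": "1.0e+07 mm^3/MPa",
    "pulmonary_compliance": "7.99e+06 mm^3/MPa",
}


@dataclass
class CirculationState:
    """Instantaneous pressures (kPa), volumes (mL) and flows (mL/s)."""

    t: float
    p_lv: float
    p_la: float
    p_rv: float
    p_art: float
    p_pul: float
    v_lv: float
    v_la: float
    v_rv: float
    v_art: float
    v_pul: float
    q_av: float = 0.0
    q_mv: float = 0.0
    q_art: float = 0.0
    q_pul: float = 0.0
    q_ven: float = 0.0

    def total_volume(self) -> float:
        return self.v_lv + self.v_la + self.v_rv + self.v_art + self.v_pul


def _chamber_pressures(state: CirculationState, params: CirculationParams, t: float):
    p_art = (state.v_art - params.v0_art) / params.c_art
    p_pul = (state.v_pul - params.v0_pul) / params.c_pul
    p_la = params.e_la(t) * (state.v_la - params.v0_la)
    p_rv = params.e_rv(t) * (state.v_rv - params.v0_rv)
    return p_la, p_rv, p_art, p_pul


def step_circulation(state: CirculationState, p_lv: float, v_lv: float,
                     dt: float, params: CirculationParams) -> CirculationState:
    """One explicit step of the circuit given the LV pressure and volume.

    Updates every compartment volume from the branch flows (conserving total
    blood volume exactly) and refreshes pressures from the elastance and
    compliance laws at the new time.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = state.t
    p_la, p_rv, p_art, p_pul = _chamber_pressures(state, params, t)

    q_mv = valve_flow(p_la - p_lv, params.r_mv)
    q_av = valve_flow(p_lv - p_art, params.r_av)
    q_art = valve_flow(p_art - p_rv, params.r_art)   # check valve guards the RV inflow
    q_pul = valve_flow(p_rv - p_pul, params.r_pul)   # pulmonic valve
    q_ven = (p_pul - p_la) / params.r_ven            # venous return, no valve

    v_lv_new = v_lv + dt * (q_mv - q_av)
    v_art_new = state.v_art + dt * (q_av - q_art)
    v_rv_new = state.v_rv + dt * (q_art - q_pul)
    v_pul_new = state.v_pul + dt * (q_pul - q_ven)
    v_la_new = state.v_la + dt * (q_ven - q_mv)
    for name, v in (("v_la", v_la_new), ("v_rv", v_rv_new),
                    ("v_art", v_art_new), ("v_pul", v_pul_new), ("v_lv", v_lv_new)):
        if v < 0:
            raise RuntimeError(f"negative compartment volume in {name}: "
                               "non-physical circulation parameters")
    t_new = t + dt
    new = CirculationState(t=t_new, p_lv=p_lv, p_la=p_la, p_rv=p_rv,
                           p_art=p_art, p_pul=p_pul,
                           v_lv=v_lv_new, v_la=v_la_new, v_rv=v_rv_new,
                           v_art=v_art_new, v_pul=v_pul_new,
                           q_av=q_av, q_mv=q_mv, q_art=q_art, q_pul=q_pul,
                           q_ven=q_ven)
    return new


# --------------------------------------------------------------------------
# LV chamber models
# --------------------------------------------------------------------------

class ElastanceLV:
    """Time-varying elastance surrogate LV (textbook pump model).

    p(V, t) = E(t) (V - V0) with a raised-cosine elastance pulse; used for
    fast circuit verification and as the calibration self-consistency
    surrogate.
    """

    def __init__(self, waveform: Optional[ElastanceWaveform] = None,
                 v0: float = 20.0):
        self.waveform = waveform or ElastanceWaveform(
            e_min=0.012, e_max=0.25, onset=0.0, duration=0.45)
        self.v0 = v0

    def pressure(self, v: float, t: float) -> float:
        return max(self.waveform(t) * (v - self.v0), 0.0)

    def reference_volume(self) -> float:
        return 150.0


class ResponseSurfaceLV:
    """LV pressure from a (volume, time) table produced by the FEM chamber.

    ``p_table[i, j]`` is the cavity pressure at volume ``v_grid[i]`` and cycle
    time ``t_grid[j]``.  Queries interpolate bilinearly (linear extrapolation
    in volume) and split the tabulated pressure into its passive part (the
    fully relaxed column) and active excess, so the calibration scale factors
    for matrix stiffness (``a_scale``) and contractility (``tmax_scale``)
    apply multiplicatively to the right component.
    """

    def __init__(self, v_grid: np.ndarray, t_grid: np.ndarray,
                 p_table: np.ndarray, t_passive: float):
        self.v_grid = np.asarray(v_grid, dtype=float)
        self.t_grid = np.asarray(t_grid, dtype=float)
        self.p_table = np.asarray(p_table, dtype=float)
        jp = int(np.argmin(np.abs(self.t_grid - t_passive)))
        self.p_passive = self.p_table[:, jp]
        self.a_scale = 1.0
        self.tmax_scale = 1.0

    def with_scales(self, a_scale: float, tmax_scale: float) -> "ResponseSurfaceLV":
        out = ResponseSurfaceLV.__new__(ResponseSurfaceLV)
        out.v_grid, out.t_grid = self.v_grid, self.t_grid
        out.p_table, out.p_passive = self.p_table, self.p_passive
        out.a_scale, out.tmax_scale = a_scale, tmax_scale
        return out

    def _interp_v(self, col: np.ndarray, v: float) -> float:
        vg = self.v_grid
        if v <= vg[0]:
            s = (col[1] - col[0]) / (vg[1] - vg[0])
            return col[0] + s * (v - vg[0])
        if v >= vg[-1]:
            s = (col[-1] - col[-2]) / (vg[-1] - vg[-2])
            return col[-1] + s * (v - vg[-1])
        return float(np.interp(v, vg, col))

    def pressure(self, v: float, t: float) -> float:
        tg = self.t_grid
        tau = t % tg[-1] if tg[-1] > 0 else t
        j = int(np.searchsorted(tg, tau, side="right") - 1)
        j = min(max(j, 0), len(tg) - 2)
        w = (tau - tg[j]) / (tg[j + 1] - tg[j])
        p_tab = ((1 - w) * self._interp_v(self.p_table[:, j], v)
                 + w * self._interp_v(self.p_table[:, j + 1], v))
        p_pas = self._interp_v(self.p_passive, v)
        return self.a_scale * p_pas + self.tmax_scale * (p_tab - p_pas)

    def reference_volume(self) -> float:
        return float(0.5 * (self.v_grid[0] + self.v_grid[-1]))


def _predicted_warm(problem: FemProblem, s1: Optional[FemSolution],
                    s2: Optional[FemSolution], t: float) -> Optional[FemSolution]:
    """Secant extrapolation of the last two converged states to time ``t``.

    Returned as a pseudo-converged state at ``t`` itself, so the Newton solve
    starts from the prediction without a load path; callers fall back to the
    true previous equilibrium when the predicted start diverges.
    """
    if s1 is None:
        return None
    denom = s1.t - s2.t if s2 is not None else 0.0
    if s2 is None or abs(denom) < 1e-9:
        return s1
    a = float(np.clip((t - s1.t) / denom, 0.0, 1.5))
    u = s1.displacement + a * (s1.displacement - s2.displacement)
    p = s1.cavity_pressure + a * (s1.cavity_pressure - s2.cavity_pressure)
    return FemSolution(displacement=u, cavity_pressure=p, t=t, converged=True,
                       newton_iterations=0, residual_norm=0.0,
                       active_scale=problem.active_scale)


class FemLV:
    """Fully coupled FEM chamber: pressure from volume-constrained solves."""

    def __init__(self, problem: FemProblem):
        self.problem = problem
        self.solution: Optional[FemSolution] = None
        self._previous: Optional[FemSolution] = None
        self.solutions: List[FemSolution] = []

    def reference_volume(self) -> float:
        return cavity_volume(self.problem.mesh,
                             np.zeros_like(self.problem.mesh.nodes))

    def pressure_at_volume(self, v: float, t: float) -> float:
        from .fem import FemError
        warm = _predicted_warm(self.problem, self.solution, self._previous, t)
        try:
            sol = solve_volume_constrained(self.problem, v, t, warm_start=warm)
        except FemError:
            sol = solve_volume_constrained(self.problem, v, t,
                                           warm_start=self.solution)
        if self.solution is not None and t != self.solution.t:
            self._previous = self.solution
        self.solution = sol
        return sol.cavity_pressure


# --------------------------------------------------------------------------
# cycle orchestration
# --------------------------------------------------------------------------

@dataclass
class CycleSolution:
    """One cardiac cycle: uniform time grid plus state series.

    ``fields`` maps column name (p_lv, v_lv, q_av, ...) to an array over the
    cycle's time grid.  For coupled FEM runs, ``fem_solutions`` holds the
    converged wall states at the exchange times ``fem_times``.
    """

    time: np.ndarray
    fields: dict
    cycle_index: int
    fem_times: Optional[np.ndarray] = None
    fem_solutions: Optional[List[FemSolution]] = None
    final_state: Optional["CirculationState"] = None

    def series(self, name: str) -> np.ndarray:
        return self.fields[name]


_RECORD = ("p_lv", "p_la", "p_rv", "p_art", "p_pul",
           "v_lv", "v_la", "v_rv", "v_art", "v_pul",
           "q_av", "q_mv", "q_art", "q_pul", "q_ven")


def initial_state(params: CirculationParams, v_lv: float) -> CirculationState:
    """Distribute total blood volume over compartments at plausible pressures."""
    v_art = params.v0_art + params.c_art * (80.0 * MMHG)
    v_la = params.v0_la + 10.0 * MMHG / max(params.e_la.e_min, 1e-6)
    v_rv = params.v0_rv + 8.0 * MMHG / max(params.e_rv.e_min, 1e-6)
    v_pul = params.total_blood_volume - v_lv - v_art - v_la - v_rv
    if v_pul <= 0:
        raise RuntimeError("total_blood_volume too small to fill compartments")
    st = CirculationState(t=0.0, p_lv=0.0, p_la=0.0, p_rv=0.0, p_art=0.0,
                          p_pul=0.0, v_lv=v_lv, v_la=v_la, v_rv=v_rv,
                          v_art=v_art, v_pul=v_pul)
    return st


def run_cycles(lv, params: CirculationParams, n_max: int = 30,
               seed: int = 0, tol: float = 0.05,
               exchange_dt: float = 0.01,
               state: Optional[CirculationState] = None,
               record_fem: bool = True,
               verbose: bool = False) -> List[CycleSolution]:
    """Run cardiac cycles to steady state (or ``n_max``).

    ``lv`` is an LV chamber model.  Algebraic chambers (ElastanceLV,
    ResponseSurfaceLV) are evaluated every circulation step.  The FEM chamber
    is exchanged every ``exchange_dt`` with fixed-point sub-iteration: the
    circuit is integrated with a trial LV pressure, the FEM chamber is solved
    at the resulting volume, and the trial pressure is updated until
    consecutive trials agree within 0.5% of the chamber stiffness-equivalent
    volume tolerance.  Deterministic for fixed inputs and seed.
    """
    params.validate()
    del seed  # deterministic model; accepted for interface uniformity
    dt = params.dt
    n_steps = int(round(params.period / dt))
    algebraic = hasattr(lv, "pressure")

    if state is None:
        state = initial_state(params, v_lv=lv.reference_volume())
    cycles: List[CycleSolution] = []

    for ic in range(n_max):
        rec = {k: np.empty(n_steps) for k in _RECORD}
        time = np.empty(n_steps)
        fem_times, fem_sols = [], []
        if algebraic:
            for i in range(n_steps):
                tau = state.t % params.period
                p_lv = lv.pressure(state.v_lv, tau)
                state = step_circulation(state, p_lv, state.v_lv, dt, params)
                time[i] = state.t
                for k in _RECORD:
                    rec[k][i] = getattr(state, k)
                rec["p_lv"][i] = p_lv
        else:
            n_sub = max(1, int(round(exchange_dt / dt)))
            i = 0
            p_trial = state.p_lv
            p_start = state.p_lv          # LV pressure at the interval start
            while i < n_steps:
                m = min(n_sub, n_steps - i)
                tau_end = (state.t + m * dt) % params.period
                tau_end = params.period if tau_end == 0.0 else tau_end

                def _march(base, p_end):
                    # LV pressure interpolated linearly across the interval
                    st = base
                    for j in range(m):
                        p_j = p_start + (p_end - p_start) * (j + 1) / m
                        st = step_circulation(st, p_j, st.v_lv, dt, params)
                    return st

                # fixed-point sub-iteration on the end-of-interval pressure
                for _ in range(8):
                    trial = _march(state, p_trial)
                    p_new = lv.pressure_at_volume(trial.v_lv, tau_end)
                    dv_equiv = abs(p_new - p_trial) * _chamber_compliance(lv)
                    p_trial = p_new
                    if dv_equiv <= 0.005 * max(trial.v_lv, 1.0):
                        break
                else:
                    raise RuntimeError(
                        "FEM-circulation coupling failed to contract; "
                        f"last pressures {p_trial:.3f}/{p_new:.3f} kPa at t={state.t:.3f}")
                for j in range(m):
                    p_j = p_start + (p_trial - p_start) * (j + 1) / m
                    state = step_circulation(state, p_j, state.v_lv, dt, params)
                    time[i] = state.t
                    for k in _RECORD:
                        rec[k][i] = getattr(state, k)
                    rec["p_lv"][i] = p_j
                    i += 1
                p_start = p_trial
                if record_fem:
                    fem_times.append(state.t)
                    fem_sols.append(lv.solution)
                if verbose:
                    print(f"  t={state.t:6.3f}  p_lv={p_trial:7.3f} kPa  "
                          f"v_lv={state.v_lv:7.1f} mL")
        cycles.append(CycleSolution(
            time=time, fields=rec, cycle_index=ic,
            fem_times=np.asarray(fem_times) if fem_times else None,
            fem_solutions=fem_sols or None, final_state=state))
        if len(cycles) >= 2 and detect_steady_state(cycles, tol):
            break
    return cycles


def _chamber_compliance(lv) -> float:
    """Rough dV/dp (mL/kPa) used to convert pressure agreement to volume terms."""
    return 10.0


def detect_steady_state(cycles: List[CycleSolution], tol: float = 0.05) -> bool:
    """True when peak and trough chamber pressures repeat within ``tol``.

    Compares the last two cycles over every chamber pressure; the relative
    change of both the peak and the trough must fall below ``tol`` (default
    5%).
    """
    if len(cycles) < 2:
        raise ValueError("steady-state detection needs at least two cycles")
    a, b = cycles[-2], cycles[-1]
    for name in ("p_lv", "p_la", "p_rv", "p_art", "p_pul"):
        for stat in (np.max, np.min):
            va, vb = stat(a.fields[name]), stat(b.fields[name])
            ref = max(abs(va), 1e-2)
            if abs(vb - va) / ref >= tol:
                return False
    return True


# --------------------------------------------------------------------------
# FEM response surface
# --------------------------------------------------------------------------

def build_response_surface(problem: FemProblem,
                           v_span: tuple = (0.80, 1.30),
                           n_v: int = 7,
                           t_grid: Optional[np.ndarray] = None,
                           verbose: bool = False) -> ResponseSurfaceLV:
    """Tabulate the FEM chamber pressure over a (volume, time) grid.

    Sweeps activation time at each volume with warm-started volume-constrained
    solves (chained along time, seeded from the previous volume's states).
    The time grid must cover the twitch; the last entry is the cycle period
    and repeats the relaxed passive state.
    """
    from .fem import FemError
    ap = problem.active
    if t_grid is None:
        t_grid = np.array([0.0, 0.06, 0.12, 0.18, ap.t0, 0.31, 0.38, 0.46,
                           0.56, 0.70, ap.period])
    t_grid = np.asarray(t_grid, dtype=float)
    i_peak = int(np.argmin(np.abs(t_grid - ap.t0)))
    v_ref = cavity_volume(problem.mesh, np.zeros_like(problem.mesh.nodes))
    v_grid = v_ref * np.linspace(v_span[0], v_span[1], n_v)
    p_tab = np.full((n_v, len(t_grid)), np.nan)

    def _refine(ts, step):
        """March points covering ``ts`` (ordered) at spacing <= step."""
        out = [ts[0]]
        for a, b in zip(ts[:-1], ts[1:]):
            k = max(1, int(np.ceil(abs(b - a) / step)))
            out.extend(a + (b - a) * (np.arange(1, k + 1) / k))
        return np.round(out, 6)

    def _sweep(v, path, start, record, iv, min_step):
        """Chain volume-constrained solves along ``path``; record grid times."""
        sol, sol2 = start, None
        for t in path:
            warm = _predicted_warm(problem, sol, sol2, t) if sol else None
            try:
                try:
                    new = solve_volume_constrained(problem, v, t, warm_start=warm,
                                                   min_step=min_step)
                except FemError:
                    if warm is sol or sol is None:
                        raise
                    new = solve_volume_constrained(problem, v, t, warm_start=sol,
                                                   min_step=min_step)
            except FemError:
                continue          # unstable corner; filled by extrapolation
            sol2, sol = sol, new
            if t in record:
                j = int(np.argmin(np.abs(t_grid - t)))
                p_tab[iv, j] = new.cavity_pressure
                if verbose:
                    print(f"  surface V={v:6.1f} t={t:4.2f} "
                          f"p={new.cavity_pressure:7.3f} "
                          f"({new.newton_iterations} it)")
        return sol

    record = set(np.round(t_grid[:-1], 6))
    t_peak = t_grid[i_peak]
    # descend only to the first nonzero grid time: the passive states come
    # from their own (much better-conditioned) volume-descending chain below
    desc_path = _refine(t_grid[i_peak:0:-1], 0.03)[1:]
    asc_path = _refine(t_grid[i_peak:-1], 0.05)[1:]

    # passive column (t = 0) by a volume-descending chain
    passive_sols: List[Optional[FemSolution]] = [None] * n_v
    sol = None
    for iv in range(n_v - 1, -1, -1):
        sol = solve_volume_constrained(problem, v_grid[iv], 0.0, warm_start=sol)
        passive_sols[iv] = sol
        p_tab[iv, 0] = sol.cavity_pressure
        if verbose:
            print(f"  surface V={v_grid[iv]:6.1f} t=0.00 "
                  f"p={sol.cavity_pressure:7.3f} ({sol.newton_iterations} it)")

    top: Optional[FemSolution] = None
    for i, v in enumerate(v_grid[::-1]):          # large volume -> small
        iv = n_v - 1 - i
        if top is None:
            # first row: climb once from its passive state
            climb = _refine(t_grid[: i_peak + 1], 0.03)[1:]
            top = _sweep(v, climb, passive_sols[iv], record, iv,
                         min_step=1.0 / 256.0)
            if top is None or abs(top.t - t_peak) > 1e-9:
                raise FemError("response surface: could not reach peak "
                               f"activation at V={v:.1f}")
        else:
            # enter the row at peak activation (the most stable state), then
            # descend and ascend the twitch from there
            top = solve_volume_constrained(problem, v, t_peak, warm_start=top)
            p_tab[iv, i_peak] = top.cavity_pressure
            if verbose:
                print(f"  surface V={v:6.1f} t={t_peak:4.2f} "
                      f"p={top.cavity_pressure:7.3f} "
                      f"({top.newton_iterations} it)")
            _sweep(v, desc_path, top, record, iv, min_step=1.0 / 32.0)
        _sweep(v, asc_path, top, record, iv, min_step=1.0 / 32.0)

    # fill unstable corners by linear extrapolation down the volume axis
    for j in range(len(t_grid) - 1):
        for iv in range(n_v - 1, -1, -1):
            if np.isnan(p_tab[iv, j]):
                if iv + 2 < n_v and np.isfinite(p_tab[iv + 1, j]) \
                        and np.isfinite(p_tab[iv + 2, j]):
                    p_tab[iv, j] = 2 * p_tab[iv + 1, j] - p_tab[iv + 2, j]
                elif iv + 1 < n_v and np.isfinite(p_tab[iv + 1, j]):
                    p_tab[iv, j] = p_tab[iv + 1, j]
                else:
                    raise FemError("response surface infeasible at "
                                   f"V={v_grid[iv]:.1f}, t={t_grid[j]:.2f}")
    p_tab[:, -1] = p_tab[:, 0]                    # relaxed at end of cycle
    return ResponseSurfaceLV(v_grid=v_grid, t_grid=t_grid, p_table=p_tab,
                             t_passive=0.0)
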