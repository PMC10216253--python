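"""Two-compartment nicotine pharmacokinetics driven by infusion events.

The model has a central compartment (blood/plasma/CSF; volume ``vc``) and a
peripheral compartment (fat, muscle, other poorly perfused tissue).  Amounts
(μg) obey

    dA_c/dt = u(t) − (k_el + k_cp)·A_c + k_pc·A_p
    dA_p/dt = k_cp·A_c − k_pc·A_p

with first-order elimination ``k_el`` from the central compartment only, and
``u(t)`` the intravenous input: an instantaneous bolus at each infusion event
(default) or a 2-s zero-order pump infusion.  Concentration is reported as
C(t) = A_c/vc in ng/ml (μg/l).  All rate constants are in h⁻¹; the systemic
clearance k_el·vc (l/h) is a derived consistency quantity, not a second loss
term.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp


class PKParameterError(ValueError):
    """Non-positive or inconsistent pharmacokinetic parameters."""


class ScheduleError(ValueError):
    """Invalid infusion schedule (negative, unsorted times or bad dose)."""


class WindowError(ValueError):
    """Requested metrics window empty or outside the simulated grid."""


class DegenerateEigenvalueError(ArithmeticError):
    """Repeated disposition eigenvalues; biexponential form is singular."""


@dataclass(frozen=True)
class PKParameters:
    """Rate constants and volumes of the two-compartment model.

    vc_per_kg : central volume of distribution, l/kg
    k_el      : elimination rate constant from central, h⁻¹
    k_cp      : central→peripheral transfer rate, h⁻¹
    k_pc      : peripheral→central transfer rate, h⁻¹
    body_mass : kg
    clearance : configured systemic clearance, l/h (checked against k_el·vc)
    """

    vc_per_kg: float = 5.0
    k_el: float = 0.8
    k_cp: float = 1.5
    k_pc: float = 1.2
    body_mass: float = 0.35
    clearance: float | None = 1.4

    def __post_init__(self) -> None:
        for name in ("vc_per_kg", "k_el", "k_cp", "k_pc", "body_mass"):
            if not getattr(self, name) > 0:
                raise PKParameterError(f"{name} must be strictly positive")
        if self.clearance is not None and self.clearance <= 0:
            raise PKParameterError("clearance must be strictly positive")

    @property
    def vc(self) -> float:
        """Central volume of distribution, litres."""
        return self.vc_per_kg * self.body_mass

    def eigenvalues(self) -> tuple[float, float]:
        """Disposition eigenvalues λ1 > λ2 > 0 (h⁻¹).

        Roots of λ² − (k_el + k_cp + k_pc)λ + k_el·k_pc = 0.
        """
        tr = self.k_el + self.k_cp + self.k_pc
        det = self.k_el * self.k_pc
        disc = tr * tr - 4.0 * det
        if disc <= 0:
            raise DegenerateEigenvalueError(
                "repeated or complex disposition eigenvalues"
            )
        s = math.sqrt(disc)
        return (tr + s) / 2.0, (tr - s) / 2.0


def derive_clearance(params: PKParameters) -> float:
    """Systemic clearance k_el × vc in l/h.

    Warns if the derived value deviates from the configured ``clearance``
    by more than 1% — the two are redundant in this parameterization and a
    mismatch means the parameter set is internally inconsistent.
    """
    cl = params.k_el * params.vc
    if params.clearance is not None:
        if abs(cl - params.clearance) > 0.01 * params.clearance:
            warnings.warn(
                f"derived clearance {cl:.4g} l/h deviates >1% from configured "
                f"{params.clearance:.4g} l/h",
                stacklevel=2,
            )
    return cl


@dataclass(frozen=True)
class InfusionSchedule:
    """Timed intravenous infusion events within one session.

    event_times_min   : minutes from session start, sorted, non-negative
    dose_per_infusion : μg delivered per event
    infusion_duration_s : pump duration (s); used only in "infusion" mode
    infusion_volume_ml  : delivered volume (metadata only)
    """

    event_times_min: np.ndarray
    dose_per_infusion: float
    infusion_duration_s: float = 2.0
    infusion_volume_ml: float = 0.035

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times_min, dtype=float)
        object.__setattr__(self, "event_times_min", t)
        if t.ndim != 1:
            raise ScheduleError("event times must be a 1-d vector")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) < 0)):
            raise ScheduleError("event times must be non-negative and sorted")
        if not self.dose_per_infusion > 0:
            raise ScheduleError("dose_per_infusion must be strictly positive")
        if not self.infusion_duration_s > 0:
            raise ScheduleError("infusion_duration_s must be strictly positive")

    @classmethod
    def from_dose_per_kg(
        cls,
        event_times_min,
        dose_ug_per_kg: float,
        body_mass: float,
        **kw,
    ) -> "InfusionSchedule":
        return cls(
            np.asarray(event_times_min, dtype=float),
            dose_per_infusion=dose_ug_per_kg * body_mass,
            **kw,
        )

    @property
    def total_dose(self) -> float:
        return self.dose_per_infusion * self.event_times_min.size


@dataclass
class ConcentrationProfile:
    """Simulated concentration-versus-time profile.

    time_min : grid, minutes
    central_conc : ng/ml at each grid point
    central_amount / peripheral_amount / eliminated_amount : μg
    """

    time_min: np.ndarray
    central_conc: np.ndarray
    central_amount: np.ndarray
    peripheral_amount: np.ndarray
    eliminated_amount: np.ndarray

    def total_accounted(self) -> np.ndarray:
        return self.central_amount + self.peripheral_amount + self.eliminated_amount


@dataclass(frozen=True)
class PKMetrics:
    peak_conc: float  # ng/ml
    peak_time: float  # min
    auc: float  # ng·min/ml
    end_of_window_conc: float  # ng/ml


def analytic_bolus(dose: float, params: PKParameters, t) -> np.ndarray:
    """Closed-form central concentration after a single t=0 bolus.

    Biexponential disposition

        C(t) = (dose/vc)·[ (λ1−k_pc)/(λ1−λ2)·e^{−λ1 t}
                         + (k_pc−λ2)/(λ1−λ2)·e^{−λ2 t} ]

    with λ1 > λ2 the eigenvalues of the disposition matrix.  ``t`` is in
    hours; the return value in ng/ml.  Serves as an independent oracle for
    the numerical simulator.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    lam1, lam2 = params.eigenvalues()
    if math.isclose(lam1, lam2, rel_tol=0, abs_tol=1e-12):
        raise DegenerateEigenvalueError("λ1 == λ2")
    a1 = (lam1 - params.k_pc) / (lam1 - lam2)
    a2 = (params.k_pc - lam2) / (lam1 - lam2)
    return (dose / params.vc) * (a1 * np.exp(-lam1 * t) + a2 * np.exp(-lam2 * t))


def _rhs(params: PKParameters, rate_in_per_min: float, extra_loss_per_h: float):
    # amounts in μg, time in minutes; rates converted h⁻¹ → min⁻¹
    k_el = (params.k_el + extra_loss_per_h) / 60.0
    k_cp = params.k_cp / 60.0
    k_pc = params.k_pc / 60.0
    k_true_el = params.k_el / 60.0  # eliminated pool tracks all loss
    k_extra = extra_loss_per_h / 60.0

    def f(_t, y):
        a_c, a_p, _ = y
        return (
            rate_in_per_min - (k_el + k_cp) * a_c + k_pc * a_p,
            k_cp * a_c - k_pc * a_p,
            (k_true_el + k_extra) * a_c,
        )

    return f


def simulate_profile(
    schedule: InfusionSchedule,
    params: PKParameters,
    grid_resolution_s: float = 1.0,
    mode: str = "bolus",
    t_end_min: float | None = None,
    extra_loss_per_h: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcentrationProfile:
    """Integrate the two-compartment model over an infusion schedule.

    Between dosing events the linear system is integrated with an adaptive
    stiff-capable solver (LSODA); bolus events are handled as state jumps so
    no discontinuity is smeared across the grid.  ``mode="infusion"`` instead
    applies each dose as a zero-order input over ``infusion_duration_s``.

    The grid covers [0, last event + 10 min] at least, at ``grid_resolution_s``
    spacing.  Grid points that coincide with a bolus report the post-bolus
    concentration, so C(0⁺) = dose/vc for an event at t=0.
    """
    if mode not in ("bolus", "infusion"):
        raise ValueError("mode must be 'bolus' or 'infusion'")
    if grid_resolution_s <= 0:
        raise ValueError("grid_resolution_s must be positive")
    events = schedule.event_times_min
    last = float(events[-1]) if events.size else 0.0
    t_end = max(t_end_min if t_end_min is not None else 0.0, last + 10.0)
    res_min = grid_resolution_s / 60.0
    n = int(round(t_end / res_min))
    grid = np.linspace(0.0, n * res_min, n + 1)

    central = np.zeros_like(grid)
    peripheral = np.zeros_like(grid)
    eliminated = np.zeros_like(grid)

    if events.size == 0:
        conc = central / params.vc
        return ConcentrationProfile(grid, conc, central, peripheral, eliminated)

    # segment breakpoints: event onsets (+ pump offsets in infusion mode)
    dur_min = schedule.infusion_duration_s / 60.0
    breaks: list[tuple[float, float]] = []  # (time, input rate μg/min after it)
    if mode == "bolus":
        for te in events:
            breaks.append((float(te), 0.0))
    else:
        # overlapping pumps accumulate; build rate change-points
        deltas: dict[float, float] = {}
        rate = schedule.dose_per_infusion / dur_min
        for te in events:
            deltas[float(te)] = deltas.get(float(te), 0.0) + rate
            toff = float(te) + dur_min
            deltas[toff] = deltas.get(toff, 0.0) - rate
        acc = 0.0
        for tt in sorted(deltas):
            acc += deltas[tt]
            breaks.append((tt, max(acc, 0.0)))

    bounds = [b[0] for b in breaks] + [grid[-1]]
    y = np.zeros(3)
    rate_now = 0.0
    t_now = 0.0
    gi = 0  # next grid index to fill

    eps = res_min * 1e-9
    for tb, rate_after in breaks:
        # integrate up to the breakpoint, filling grid points in [t_now, tb)
        take = []
        while gi < grid.size and grid[gi] < tb - eps:
            take.append(gi)
            gi += 1
        t_eval = grid[take]
        if t_eval.size and abs(t_eval[0] - t_now) < eps:
            # grid point at current time: record current state directly
            central[take[0]], peripheral[take[0]], eliminated[take[0]] = y
            take = take[1:]
            t_eval = grid[take]
        if tb > t_now + 1e-15:
            if t_eval.size:
                sol = solve_ivp(
                    _rhs(params, rate_now, extra_loss_per_h),
                    (t_now, tb), y, method="LSODA",
                    t_eval=np.concatenate([t_eval, [tb]]),
                    rtol=rtol, atol=atol,
                )
                if not sol.success:  # pragma: no cover
                    raise RuntimeError(f"PK solver failed: {sol.message}")
                central[take] = sol.y[0, :-1]
                peripheral[take] = sol.y[1, :-1]
                eliminated[take] = sol.y[2, :-1]
                y = sol.y[:, -1].copy()
            else:
                sol = solve_ivp(
                    _rhs(params, rate_now, extra_loss_per_h),
                    (t_now, tb), y, method="LSODA", rtol=rtol, atol=atol,
                )
                if not sol.success:  # pragma: no cover
                    raise RuntimeError(f"PK solver failed: {sol.message}")
                y = sol.y[:, -1].copy()
        t_now = tb
        if mode == "bolus":
            y = y.copy()
            y[0] += schedule.dose_per_infusion
        else:
            rate_now = rate_after

    # final stretch after the last breakpoint
    take = list(range(gi, grid.size))
    t_eval = grid[take]
    if t_eval.size and abs(t_eval[0] - t_now) < eps:
        central[take[0]], peripheral[take[0]], eliminated[take[0]] = y
        take = take[1:]
        t_eval = grid[take]
    if t_eval.size:
        sol = solve_ivp(
            _rhs(params, rate_now, extra_loss_per_h),
            (t_now, grid[-1]), y, method="LSODA",
            t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"PK solver failed: {sol.message}")
        central[take] = sol.y[0]
        peripheral[take] = sol.y[1]
        eliminated[take] = sol.y[2]

    conc = central / params.vc
    return ConcentrationProfile(grid, conc, central, peripheral, eliminated)


def exposure_metrics(
    profile: ConcentrationProfile, window: tuple[float, float]
) -> PKMetrics:
    """Peak, peak time, trapezoidal AUC and end concentration over a window.

    ``window`` is (start_min, end_min) and must lie within the simulated grid.
    AUC is in ng·min/ml.
    """
    lo, hi = float(window[0]), float(window[1])
    t = profile.time_min
    if hi <= lo:
        raise WindowError("window must have positive length")
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise WindowError("window outside simulated grid")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not np.any(mask):
        raise WindowError("window contains no grid points")
    tw = t[mask]
    cw = profile.central_conc[mask]
    i = int(np.argmax(cw))
    auc = float(np.trapezoid(cw, tw))
    end_conc = float(np.interp(hi, t, profile.central_conc))
    return PKMetrics(
        peak_conc=float(cw[i]),
        peak_time=float(tw[i]),
        auc=auc,
        end_of_window_conc=end_conc,
    )


def window_average(profile: ConcentrationProfile, window: tuple[float, float]) -> float:
    """Time-averaged central concentration (ng/ml) over a window."""
    m = exposure_metrics(profile, window)
    return m.auc / (float(window[1]) - float(window[0]))


def window_minimum(profile: ConcentrationProfile, window: tuple[float, float]) -> float:
    """Minimum central concentration (ng/ml) over a window."""
    lo, hi = float(window[0]), float(window[1])
    t = profile.time_min
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not np.any(mask):
        raise WindowError("window contains no grid points")
    return float(np.min(profile.central_conc[mask]))
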