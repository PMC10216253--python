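"""Evoked dopamine release/uptake kinetics for fast-scan cyclic voltammetry.

Extracellular dopamine after electrical stimulation is modeled as
instantaneous per-pulse release increments [DA]p on top of Michaelis–Menten
reuptake by the dopamine transporter:

    d[DA]/dt = −Vmax·[DA] / (Km + [DA]),    pulse at t_i: [DA] += [DA]p

Between pulses the decay has an exact implicit solution
Km·ln([DA]₀/[DA]) + ([DA]₀ − [DA]) = Vmax·t, evaluated in closed form via
the Lambert-W function, so traces are computed without step-size error.
Fitting fixes Km (release transients constrain Vmax and [DA]p but not Km
jointly) and estimates Vmax and [DA]p by least squares against the trace.

Also here: stimulation-intensity and 4-pulse frequency-response curve
construction, electrode calibration by ordinary least squares on background-
current features, and nicotine concentration-response assembly feeding the
inhibition Hill fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares
from scipy.special import lambertw

from .hill import DoseResponseSeries, FitError, HillFit, fit_hill


class ResolutionError(ValueError):
    """Sampling interval too coarse to resolve the pulse train."""


class NoSignalError(ValueError):
    """Trace contains no stimulus-locked transient to fit."""


class CollinearityError(ValueError):
    """Calibration design matrix is rank deficient."""


class ReferenceError_(ValueError):
    """Missing single-pulse reference trace for normalization."""


@dataclass(frozen=True)
class MMParams:
    """Michaelis–Menten uptake and per-pulse release parameters.

    vmax : μM/s, maximal uptake rate
    km   : μM, half-saturation constant (fixed during fitting; 0.16 μM is a
           standard striatal value)
    da_per_pulse : μM released per stimulus pulse
    """

    vmax: float
    da_per_pulse: float
    km: float = 0.16

    def __post_init__(self) -> None:
        if not (self.vmax > 0 and self.da_per_pulse > 0 and self.km > 0):
            raise ValueError("all MM parameters must be strictly positive")


@dataclass(frozen=True)
class StimPattern:
    """Electrical stimulation protocol: single pulse or fixed-frequency train."""

    pulse_times: np.ndarray  # s
    frequency: float | None = None  # Hz, trains only
    intensity_v: float | None = None
    intensity_ua: float | None = None
    pulse_width_ms: float = 4.0

    def __post_init__(self) -> None:
        t = np.asarray(self.pulse_times, dtype=float)
        object.__setattr__(self, "pulse_times", t)
        if t.size == 0:
            raise ValueError("at least one pulse required")
        if np.any(np.diff(t) < 0):
            raise ValueError("pulse times must be sorted")
        if self.frequency is not None and t.size > 1:
            gaps = np.diff(t)
            if not np.allclose(gaps, 1.0 / self.frequency, rtol=1e-6):
                raise ValueError("train spacing must equal 1/frequency")

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_times.size)

    @classmethod
    def single_pulse(cls, t0: float = 0.5, intensity_v: float = 7.5,
                     intensity_ua: float = 350.0) -> "StimPattern":
        return cls(np.array([t0]), intensity_v=intensity_v, intensity_ua=intensity_ua)

    @classmethod
    def train(cls, n_pulses: int, frequency: float, t0: float = 0.5,
              intensity_v: float = 7.5) -> "StimPattern":
        t = t0 + np.arange(n_pulses) / frequency
        return cls(t, frequency=frequency, intensity_v=intensity_v)


@dataclass
class FSCVTrace:
    time: np.ndarray  # s, uniform grid
    da_conc: np.ndarray  # μM
    stim: StimPattern | None = None
    raw_current: np.ndarray | None = None  # nA

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.da_conc, dtype=float)
        if t.shape != c.shape:
            raise ValueError("time and da_conc must align")
        if t.size > 2 and not np.allclose(np.diff(t), t[1] - t[0], rtol=1e-6, atol=1e-12):
            raise ValueError("grid must be uniform")
        self.time, self.da_conc = t, c

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def mm_decay(c0, t, vmax: float, km: float):
    """Exact Michaelis–Menten decay from concentration ``c0`` after time ``t``.

    Solves Km·ln(c0/c) + (c0 − c) = Vmax·t for c.  Uses the principal
    Lambert-W branch, switching to its asymptotic expansion when the
    argument would overflow (deep zero-order regime, c ≫ Km).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if c0 <= 0:
        out = np.zeros_like(t)
        return float(out[0]) if scalar else out
    z = np.log(c0 / km) + (c0 - vmax * t) / km  # W argument is e^z
    c = np.empty_like(z)
    small = z < 500.0
    c[small] = km * np.real(lambertw(np.exp(z[small])))
    if np.any(~small):
        zz = z[~small]  # W(e^z) ≈ z − ln z + ln z / z for large z
        w = zz - np.log(zz) + np.log(zz) / zz
        c[~small] = km * w
    c = np.maximum(c, 0.0)
    return float(c[0]) if scalar else c


def simulate_trace(
    params: MMParams,
    stim: StimPattern,
    duration: float = 5.0,
    dt: float = 0.1,
) -> FSCVTrace:
    """Closed-form trace of release-plus-uptake over a uniform grid.

    Grid points at a pulse time report the post-release concentration.
    ``dt`` must resolve the train: dt ≤ 1/(2·frequency).
    """
    if stim.frequency is not None and dt > 1.0 / (2.0 * stim.frequency) + 1e-12:
        raise ResolutionError(
            f"dt={dt} s cannot resolve a {stim.frequency} Hz train"
        )
    n = int(round(duration / dt))
    grid = np.arange(n + 1) * dt
    conc = np.zeros_like(grid)
    # march pulse to pulse, carrying the exact state; a grid point that
    # coincides with a pulse is filled after the release jump (post-pulse value)
    state = 0.0
    t_state = 0.0
    gi = 0
    for pulse in stim.pulse_times:
        while gi < grid.size and grid[gi] < pulse - 1e-12:
            conc[gi] = mm_decay(state, grid[gi] - t_state, params.vmax, params.km)
            gi += 1
        state = float(mm_decay(state, max(pulse - t_state, 0.0), params.vmax, params.km))
        state += params.da_per_pulse
        t_state = pulse
    while gi < grid.size:
        conc[gi] = mm_decay(state, max(grid[gi] - t_state, 0.0), params.vmax, params.km)
        gi += 1
    return FSCVTrace(grid, conc, stim=stim)


def peak_da(trace: FSCVTrace, window: tuple[float, float] | None = None) -> tuple[float, float]:
    """(peak concentration μM, time s) in a post-stimulus window (default:
    from the first pulse onward, or the whole trace if no stim attached)."""
    t, c = trace.time, trace.da_conc
    if window is None:
        start = trace.stim.pulse_times[0] if trace.stim is not None else t[0]
        window = (start, t[-1])
    mask = (t >= window[0] - 1e-12) & (t <= window[1] + 1e-12)
    tw, cw = t[mask], c[mask]
    i = int(np.argmax(cw))
    return float(cw[i]), float(tw[i])


def fit_mm(
    trace: FSCVTrace,
    stim: StimPattern | None = None,
    km_fixed: float = 0.16,
    signal_floor: float = 1e-9,
) -> tuple[MMParams, dict]:
    """Estimate Vmax and [DA]p from a trace, Km fixed.

    Simulates candidate traces on the same grid and minimizes the squared
    residual.  Returns the parameters plus diagnostics (peak, residual RMS,
    optimizer cost).  Flat traces raise :class:`NoSignalError`.
    """
    stim = stim or trace.stim
    if stim is None:
        raise ValueError("a stimulation pattern is required")
    peak = float(np.max(trace.da_conc))
    if peak <= signal_floor:
        raise NoSignalError("trace has no transient above the signal floor")
    duration = float(trace.time[-1])
    dt = trace.dt

    def model(theta):
        vmax, dap = np.exp(theta)
        p = MMParams(vmax=vmax, da_per_pulse=dap, km=km_fixed)
        return simulate_trace(p, stim, duration=duration, dt=dt).da_conc

    def residuals(theta):
        return model(theta) - trace.da_conc

    dap0 = max(peak / stim.n_pulses, signal_floor * 10)
    best = None
    for v0 in (0.3, 1.0, 3.0):
        sol = least_squares(
            residuals, [np.log(v0), np.log(dap0)], method="lm",
            xtol=1e-12, ftol=1e-12, max_nfev=500,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16 * max(peak, 1.0) ** 2 * trace.time.size:
            break
    if best is None or not np.all(np.isfinite(best.x)):  # pragma: no cover
        raise FitError("MM fit did not converge", best)
    vmax, dap = np.exp(best.x)
    params = MMParams(vmax=float(vmax), da_per_pulse=float(dap), km=km_fixed)
    diag = {
        "peak_um": peak,
        "residual_rms": float(np.sqrt(2 * best.cost / trace.time.size)),
        "cost": float(best.cost),
    }
    return params, diag


# ------------------------------------------------------------- curves


@dataclass
class IntensityCurve:
    intensities_v: np.ndarray
    peaks_um: np.ndarray
    normalized: np.ndarray  # peak / max peak

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"intensity_v": self.intensities_v, "peak_um": self.peaks_um,
             "normalized": self.normalized}
        )


@dataclass
class FrequencyCurve:
    frequencies_hz: np.ndarray
    peaks_um: np.ndarray
    percent_of_single_pulse: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frequency_hz": self.frequencies_hz, "peak_um": self.peaks_um,
             "percent_single_pulse": self.percent_of_single_pulse}
        )


def intensity_curve(traces) -> IntensityCurve:
    """Peak dopamine per stimulation intensity, plus a max-normalized curve.

    ``traces`` maps intensity (V) → trace, or is an iterable of
    (intensity, trace) pairs; duplicate intensities are an input error.
    """
    pairs = list(traces.items()) if isinstance(traces, dict) else list(traces)
    levels_raw = [v for v, _ in pairs]
    if len(set(levels_raw)) != len(levels_raw):
        raise ValueError("duplicate intensities")
    pairs.sort(key=lambda p: p[0])
    levels = np.array([v for v, _ in pairs])
    peaks = np.array([peak_da(tr)[0] for _, tr in pairs])
    m = peaks.max()
    if m <= 0:
        raise NoSignalError("all traces flat; cannot normalize")
    return IntensityCurve(levels, peaks, peaks / m)


def frequency_response(
    single_pulse_trace: FSCVTrace | None,
    train_traces: dict[float, FSCVTrace],
) -> FrequencyCurve:
    """Peak dopamine per train frequency as percent of single-pulse release."""
    if single_pulse_trace is None:
        raise ReferenceError_("single-pulse reference trace is required")
    ref = peak_da(single_pulse_trace)[0]
    if ref <= 0:
        raise NoSignalError("single-pulse reference is flat")
    freqs = np.array(sorted(train_traces))
    peaks = np.array([peak_da(train_traces[f])[0] for f in freqs])
    return FrequencyCurve(freqs, peaks, 100.0 * peaks / ref)


# ---------------------------------------------------------- calibration


@dataclass
class CalibrationModel:
    """OLS map from electrode background-current features to dopamine
    sensitivity (nA per μM)."""

    feature_names: list[str]
    coefficients: np.ndarray  # intercept first
    r_squared: float
    stderr: np.ndarray

    def predict_sensitivity(self, features: pd.DataFrame | dict) -> np.ndarray:
        if isinstance(features, dict):
            features = pd.DataFrame([features])
        X = sm.add_constant(
            features[self.feature_names].to_numpy(dtype=float), has_constant="add"
        )
        return X @ self.coefficients


def calibrate_electrode(table: pd.DataFrame,
                        sensitivity_col: str = "sensitivity_na_per_um") -> CalibrationModel:
    """Fit the calibration regression: sensitivity ~ background-current features.

    All columns other than ``sensitivity_col`` are regressors.  Requires at
    least p+2 rows for p features and a full-rank design.
    """
    features = [c for c in table.columns if c != sensitivity_col]
    if not features:
        raise ValueError("no feature columns")
    if len(table) < len(features) + 2:
        raise ValueError(f"need >= {len(features) + 2} rows for {len(features)} features")
    X = sm.add_constant(table[features].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("rank-deficient calibration design")
    res = sm.OLS(table[sensitivity_col].to_numpy(dtype=float), X).fit()
    return CalibrationModel(
        feature_names=features,
        coefficients=np.asarray(res.params),
        r_squared=float(res.rsquared) if len(table) > X.shape[1] else 1.0,
        stderr=np.asarray(res.bse),
    )


def apply_calibration(
    time: np.ndarray, raw_current_na: np.ndarray, model: CalibrationModel,
    features: dict, stim: StimPattern | None = None,
) -> FSCVTrace:
    """Convert a raw current trace (nA) to concentration (μM) with the
    electrode's predicted sensitivity."""
    sens = float(model.predict_sensitivity(features)[0])
    if sens <= 0:
        raise ValueError("predicted sensitivity must be positive")
    return FSCVTrace(
        np.asarray(time, float),
        np.asarray(raw_current_na, float) / sens,
        stim=stim,
        raw_current=np.asarray(raw_current_na, float),
    )


# ------------------------------------------- nicotine modulation curves


@dataclass
class ModulationCurve:
    series: DoseResponseSeries | None
    fit: HillFit | None
    flat: bool


def nicotine_modulation_curve(
    baseline_release_um: float,
    doses_molar: np.ndarray,
    releases_um: np.ndarray,
    replicate_id: str = "slice",
    flat_tol: float = 1e-9,
) -> ModulationCurve:
    """Baseline-normalize evoked release across bath nicotine doses and fit
    an inhibition Hill curve (IC50 per slice).

    A curve where every dose equals baseline is flagged flat and not fitted.
    """
    if not baseline_release_um > 0:
        raise ValueError("baseline release must be positive")
    doses = np.asarray(doses_molar, dtype=float)
    rel = np.asarray(releases_um, dtype=float) / baseline_release_um
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be positive and strictly increasing")
    if np.max(np.abs(rel - 1.0)) < flat_tol:
        return ModulationCurve(series=None, fit=None, flat=True)
    series = DoseResponseSeries(doses, rel, np.full(doses.size, replicate_id))
    fit = fit_hill(series, direction="inhibition")
    return ModulationCurve(series=series, fit=fit, flat=False)
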