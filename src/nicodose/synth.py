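"""Synthetic cohorts, dose-response replicates and FSCV traces.

Real recordings from the study are not deposited, so the analyses are
exercised on generated data with the same statistical structure:

* operant sessions — a loading phase of closely spaced infusions in the
  first part of the session followed by maintenance infusions with
  log-normal inter-infusion intervals (heavy right tail matching
  post-infusion pausing), Poisson inactive pokes, and optional
  non-consequential pokes during timeouts; every generated log satisfies
  the FR/timeout contingency by construction;
* cohort scenarios mirroring the study's group structure: standard-dose
  acquirers (15–25 infusions/day), low-dose acquirers vs non-acquirers
  around the 11.1-infusion benchmark, an escalating TH-Cre-style cohort
  with sparse controls, and a saline-substitution arm with extinction;
* Hill-shaped dose-response replicates with additive Gaussian noise;
* FSCV traces from the Michaelis–Menten forward model with per-slice
  log-normal parameter jitter and additive Gaussian noise.

Every generator takes a seed and is byte-reproducible; ground-truth
parameters are returned in manifests for recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .fscv import FSCVTrace, MMParams, StimPattern, simulate_trace
from .hill import hill_response
from .sessions import SessionLog, SubjectHistory

INTENSITY_SERIES_V = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0,
                      6.0, 7.0, 8.0, 9.0, 10.0)
FREQUENCY_SERIES_HZ = (3.0, 10.0, 30.0, 100.0)

SCENARIOS = (
    "cre_pos_lowdose",
    "cre_neg_lowdose",
    "naive_lowdose",
    "standard_dose",
    "thcre",
    "saline_substitution",
)


class ConfigError(ValueError):
    """Generator configuration cannot produce a schedule-consistent session."""


@dataclass
class BehavioralModelConfig:
    """Generating process for one group's sessions.

    loading_count / loading_window_min : infusions placed early in the session
    maint_interval_logmean / _logsd    : log-normal inter-infusion interval
                                         parameters (minutes) for maintenance
    day_multiplier : per-day multiplier on the maintenance rate (>1 escalation,
                     <1 extinction), applied as multiplier**(day−1)
    inactive_rate_per_min : homogeneous Poisson rate of inactive pokes
    timeout_poke_rate_per_min : rate of extra (non-counted) actives in timeouts
    """

    group: str = "default"
    loading_count: int = 5
    loading_window_min: float = 20.0
    maint_interval_logmean: float = math.log(8.0)
    maint_interval_logsd: float = 0.4
    day_multiplier: float = 1.0
    inactive_rate_per_min: float = 0.05
    timeout_poke_rate_per_min: float = 0.5
    fr_value: int = 1
    timeout_s: float = 20.0
    session_min: float = 120.0
    dose_ug_per_kg: float = 30.0

    def __post_init__(self) -> None:
        if self.inactive_rate_per_min < 0 or self.timeout_poke_rate_per_min < 0:
            raise ConfigError("rates must be non-negative")
        if self.day_multiplier <= 0:
            raise ConfigError("day_multiplier must be positive")
        if self.fr_value < 1:
            raise ConfigError("fr_value must be >= 1")
        # an infusion needs fr actives outside timeout plus the timeout itself
        min_gap_min = (self.timeout_s + self.fr_value + 1.0) / 60.0
        if self.loading_count > 1:
            if self.loading_window_min / (self.loading_count - 1) < min_gap_min:
                raise ConfigError("loading spacing shorter than timeout + FR run")


def _infusion_times_min(config: BehavioralModelConfig, day: int,
                        rng: np.random.Generator) -> np.ndarray:
    times: list[float] = []
    min_gap = (config.timeout_s + config.fr_value + 1.0) / 60.0
    if config.loading_count > 0:
        if config.loading_count == 1:
            times.append(float(rng.uniform(0.5, config.loading_window_min)))
        else:
            base = np.linspace(0.5, config.loading_window_min, config.loading_count)
            jitter = rng.uniform(-0.2, 0.2, size=config.loading_count)
            t = np.maximum.accumulate(base + jitter)
            times.extend(t.tolist())
    scale = config.day_multiplier ** (day - 1)
    t = times[-1] if times else 0.0
    while True:
        gap = rng.lognormal(config.maint_interval_logmean, config.maint_interval_logsd)
        gap = max(gap / scale, min_gap)
        t += gap
        if t >= config.session_min - 0.5:
            break
        times.append(t)
    out = np.asarray(times)
    for i in range(1, out.size):  # guarantee the FR/timeout contingency
        out[i] = max(out[i], out[i - 1] + min_gap)
    return out[out < config.session_min - 0.25]


def generate_session(config: BehavioralModelConfig, day: int,
                     rng: np.random.Generator | int | None = None,
                     subject_id: str = "S0") -> SessionLog:
    """One session log obeying the FR/timeout contingency exactly.

    Each scheduled infusion is preceded by exactly ``fr_value`` counted
    active pokes in the preceding second; extra actives are sprinkled into
    timeout windows (recorded, never counted); inactive pokes arrive as a
    homogeneous Poisson process over the whole session.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    inf_min = _infusion_times_min(config, day, rng)
    events: list[tuple[float, str]] = []
    session_s = config.session_min * 60.0
    for tm in inf_min:
        ts = tm * 60.0
        for k in range(config.fr_value):
            events.append((ts - (config.fr_value - k - 1) * 0.5, "active"))
        events.append((ts, "infusion"))
        if config.timeout_poke_rate_per_min > 0:
            n_extra = rng.poisson(config.timeout_poke_rate_per_min * config.timeout_s / 60.0)
            for te in rng.uniform(ts + 0.5, ts + config.timeout_s - 0.5, size=n_extra):
                events.append((float(te), "active"))
    n_inactive = rng.poisson(config.inactive_rate_per_min * config.session_min)
    for ti in rng.uniform(0.0, session_s, size=n_inactive):
        events.append((float(ti), "inactive"))
    events.sort(key=lambda e: e[0])
    return SessionLog(
        subject_id=subject_id,
        day_index=day,
        events=events,
        dose_ug_per_kg=config.dose_ug_per_kg,
        fr_value=config.fr_value,
        timeout_s=config.timeout_s,
        session_min=config.session_min,
        group=config.group,
    )


def _scenario_configs(scenario: str) -> tuple[BehavioralModelConfig, int, dict]:
    """(base config, n_days, extras) for each cohort scenario."""
    if scenario == "standard_dose":
        # acquirers at 30 μg/kg: loading burst then ~8-min spaced maintenance,
        # 15-25 infusions/day
        return (
            BehavioralModelConfig(
                group=scenario, loading_count=8, loading_window_min=18.0,
                maint_interval_logmean=math.log(8.0), maint_interval_logsd=0.35,
                inactive_rate_per_min=0.05, dose_ug_per_kg=30.0,
            ),
            10,
            {},
        )
    if scenario == "cre_pos_lowdose":
        # low-dose acquirers: ~16-20 infusions/day, comfortably above 11.1
        return (
            BehavioralModelConfig(
                group=scenario, loading_count=4, loading_window_min=25.0,
                maint_interval_logmean=math.log(7.5), maint_interval_logsd=0.4,
                inactive_rate_per_min=0.05, dose_ug_per_kg=1.5,
            ),
            10,
            {},
        )
    if scenario in ("cre_neg_lowdose", "naive_lowdose"):
        # non-acquirers: sparse responding, ~4-6 infusions/day (saline-like)
        return (
            BehavioralModelConfig(
                group=scenario, loading_count=1, loading_window_min=20.0,
                maint_interval_logmean=math.log(28.0), maint_interval_logsd=0.35,
                inactive_rate_per_min=0.08, dose_ug_per_kg=1.5,
            ),
            10,
            {},
        )
    if scenario == "thcre":
        # escalation: 15-20/day early, rising toward ~40 by day 17
        return (
            BehavioralModelConfig(
                group=scenario, loading_count=4, loading_window_min=25.0,
                maint_interval_logmean=math.log(8.0), maint_interval_logsd=0.4,
                day_multiplier=1.06, inactive_rate_per_min=0.05,
                dose_ug_per_kg=1.5,
            ),
            17,
            {"control": BehavioralModelConfig(
                group="non_tg", loading_count=1, loading_window_min=30.0,
                maint_interval_logmean=math.log(32.0), maint_interval_logsd=0.35,
                inactive_rate_per_min=0.08, dose_ug_per_kg=1.5,
            )},
        )
    if scenario == "saline_substitution":
        # 17 nicotine days then 7 saline days with extinction
        nic, _, _ = _scenario_configs("thcre")
        nic = BehavioralModelConfig(**{**asdict(nic), "group": scenario})
        sal = BehavioralModelConfig(
            group=scenario, loading_count=2, loading_window_min=20.0,
            maint_interval_logmean=math.log(20.0), maint_interval_logsd=0.4,
            day_multiplier=0.75, inactive_rate_per_min=0.08, dose_ug_per_kg=0.0,
        )
        return nic, 24, {"saline": sal, "switch_day": 18}
    raise ConfigError(f"unknown scenario {scenario!r}")


def generate_cohort(
    scenario: str, n_subjects: int, seed: int | None = None
) -> tuple[list[SubjectHistory], dict]:
    """A cohort of subject histories plus a ground-truth manifest.

    For the ``thcre`` scenario the manifest also carries six control
    (non-transgenic) histories under ``controls``.
    """
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}")
    base, n_days, extras = _scenario_configs(scenario)
    rng = np.random.default_rng(seed)
    histories: list[SubjectHistory] = []
    manifest: dict = {"scenario": scenario, "seed": seed, "subjects": {}}

    def build_subject(sid: str, cfg: BehavioralModelConfig, days: int,
                      switch: tuple[int, BehavioralModelConfig] | None = None):
        # per-subject rate jitter (log-normal, ±~10%)
        jitter = float(rng.lognormal(0.0, 0.1))
        c = BehavioralModelConfig(**{
            **asdict(cfg),
            "maint_interval_logmean": cfg.maint_interval_logmean - math.log(jitter),
        })
        sessions = []
        for day in range(1, days + 1):
            active_cfg = c
            eff_day = day
            if switch is not None and day >= switch[0]:
                active_cfg = switch[1]
                eff_day = day - switch[0] + 1
            sessions.append(generate_session(active_cfg, eff_day, rng, subject_id=sid))
            sessions[-1].day_index = day
        hist = SubjectHistory(subject_id=sid, group=cfg.group, sessions=sessions)
        manifest["subjects"][sid] = {
            "group": cfg.group, "rate_jitter": jitter, "n_days": days,
        }
        return hist

    switch = None
    if scenario == "saline_substitution":
        switch = (extras["switch_day"], extras["saline"])
    for i in range(n_subjects):
        histories.append(build_subject(f"{scenario}_{i:02d}", base, n_days, switch))
    if scenario == "thcre":
        manifest["controls"] = [
            build_subject(f"non_tg_{i:02d}", extras["control"], n_days)
            for i in range(6)
        ]
    return histories, manifest


def generate_dose_response(
    ec50: float, hill_n: float, top: float, doses: np.ndarray,
    reps: int = 3, noise_sd: float = 0.05, seed: int | None = None,
    direction: str = "activation",
) -> tuple[pd.DataFrame, dict]:
    """Replicate Hill responses with additive Gaussian noise, truncated at 0."""
    if ec50 <= 0 or hill_n <= 0 or top <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    rows = []
    for r in range(reps):
        clean = hill_response(doses, ec50, hill_n, top, direction=direction)
        noisy = np.maximum(clean + rng.normal(0.0, noise_sd, size=doses.size), 0.0)
        for c, v in zip(doses, noisy):
            rows.append((r, c, v))
    df = pd.DataFrame(rows, columns=["replicate_id", "concentration_molar", "response"])
    manifest = {"ec50": ec50, "hill_n": hill_n, "top": top, "noise_sd": noise_sd,
                "reps": reps, "seed": seed, "direction": direction}
    return df, manifest


def default_dose_ladder(n_doses: int = 12, lowest: float = 1e-9) -> np.ndarray:
    """~3-fold concentration steps spanning several orders of magnitude."""
    return lowest * 3.0 ** np.arange(n_doses)


def intensity_release_coupling(
    intensity_v: float, dap_max: float, v50: float = 3.0, steepness: float = 2.0
) -> float:
    """Saturating (Hill-shaped) map from stimulation voltage to per-pulse
    release; the analysis layer is agnostic to this form."""
    return dap_max * intensity_v**steepness / (intensity_v**steepness + v50**steepness)


def generate_fscv_dataset(
    group_params: MMParams,
    n_slices: int = 5,
    noise_sd: float = 0.02,
    param_jitter_sd: float = 0.15,
    duration: float = 3.0,
    dt: float = 0.1,
    seed: int | None = None,
) -> tuple[dict, dict]:
    """Per-slice FSCV recordings: single pulse, the full 15-level intensity
    series, and 4-pulse trains at 3/10/30/100 Hz.

    Slice parameters are log-normal jitters around the group means; traces
    get additive Gaussian noise (μM).  Returns (dataset, manifest) where
    dataset maps slice id → {"single": trace, "intensity": {V: trace},
    "frequency": {Hz: trace}} and the manifest records true parameters.
    """
    rng = np.random.default_rng(seed)
    dataset: dict = {}
    manifest: dict = {"seed": seed, "noise_sd": noise_sd, "slices": {}}

    def noisy(trace: FSCVTrace) -> FSCVTrace:
        if noise_sd == 0:
            return trace
        da = np.maximum(trace.da_conc + rng.normal(0, noise_sd, trace.da_conc.size), 0.0)
        return FSCVTrace(trace.time, da, stim=trace.stim)

    for i in range(n_slices):
        sid = f"slice_{i:02d}"
        vmax = group_params.vmax * float(rng.lognormal(0, param_jitter_sd))
        dap = group_params.da_per_pulse * float(rng.lognormal(0, param_jitter_sd))
        p = MMParams(vmax=vmax, da_per_pulse=dap, km=group_params.km)
        single = noisy(simulate_trace(p, StimPattern.single_pulse(), duration, dt))
        intensity = {}
        for v in INTENSITY_SERIES_V:
            dv = intensity_release_coupling(v, dap)
            pv = MMParams(vmax=vmax, da_per_pulse=dv, km=p.km)
            intensity[v] = noisy(
                simulate_trace(pv, StimPattern.single_pulse(intensity_v=v), duration, dt)
            )
        freq = {}
        for f in FREQUENCY_SERIES_HZ:
            freq[f] = noisy(
                simulate_trace(p, StimPattern.train(4, f), duration, min(dt, 1 / (2 * f)))
            )
        dataset[sid] = {"single": single, "intensity": intensity, "frequency": freq}
        manifest["slices"][sid] = {"vmax": vmax, "da_per_pulse": dap, "km": p.km}
    return dataset, manifest
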