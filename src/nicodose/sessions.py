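"""Operant self-administration session logs and acquisition classifiers.

Sessions follow a fixed-ratio (FR) schedule with a post-infusion timeout:
``fr_value`` active nose pokes earn one infusion, after which pokes during
the ``timeout_s`` window are recorded but do not count toward the next
ratio.  Inactive-hole pokes never have consequences.

Three cohort-specific acquisition-failure rules are implemented:

* standard dose (30 μg/kg/inf): fail on (1) <10 infusions in ≥2 consecutive
  sessions, (2) active:inactive ratio <2.0 in ≥3 consecutive sessions, or
  (3) a ≥75% drop in active responding during sessions 6–10 relative to the
  mean of sessions 1–5;
* low dose (1.5 μg/kg/inf): fail iff mean infusions over days 6–10 < 11.1
  (the saline-level benchmark);
* control-referenced: fail iff the subject's window mean falls below the
  control cohort's mean + k·SD cutoff (k = 2 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

EVENT_KINDS = ("active", "inactive", "infusion")


class SessionParseError(ValueError):
    """Malformed session-log text; message carries the offending line."""


class CoverageError(ValueError):
    """A required day range is not fully covered by the history."""


class DegenerateSDError(ValueError):
    """Fewer than two control subjects: SD of window means undefined."""


@dataclass
class SessionLog:
    subject_id: str
    day_index: int
    events: list[tuple[float, str]] = field(default_factory=list)
    dose_ug_per_kg: float = 0.0
    fr_value: int = 1
    timeout_s: float = 20.0
    session_min: float = 120.0
    group: str = ""

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError("day_index must be >= 1")
        if self.fr_value < 1:
            raise ValueError("fr_value must be >= 1")
        for t, kind in self.events:
            if kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {kind!r}")
            if not (0.0 <= t <= self.session_min * 60.0):
                raise ValueError(f"event at {t} s outside session")

    def counts(self) -> dict[str, int]:
        c = {k: 0 for k in EVENT_KINDS}
        for _, kind in self.events:
            c[kind] += 1
        return c


@dataclass
class SubjectHistory:
    subject_id: str
    group: str
    sessions: list[SessionLog] = field(default_factory=list)
    phases: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        days = [s.day_index for s in self.sessions]
        if len(days) != len(set(days)):
            raise ValueError("at most one session per day")
        self.sessions.sort(key=lambda s: s.day_index)

    def session_for_day(self, day: int) -> SessionLog | None:
        for s in self.sessions:
            if s.day_index == day:
                return s
        return None

    @property
    def days(self) -> list[int]:
        return [s.day_index for s in self.sessions]


@dataclass(frozen=True)
class AcquisitionCriteria:
    min_infusions: int = 10
    min_consecutive_low_infusions: int = 2
    min_ratio: float = 2.0
    min_consecutive_low_ratio: int = 3
    drop_fraction: float = 0.75
    drop_baseline_days: tuple[int, int] = (1, 5)
    drop_eval_days: tuple[int, int] = (6, 10)
    lowdose_mean_cutoff: float = 11.1
    lowdose_days: tuple[int, int] = (6, 10)
    control_sd_multiplier: float = 2.0
    control_days: tuple[int, int] = (11, 17)
    acquisition_days: tuple[int, int] = (1, 10)

    def __post_init__(self) -> None:
        if self.min_infusions <= 0 or self.min_ratio <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.drop_fraction <= 1):
            raise ValueError("drop_fraction must be in (0, 1]")


@dataclass
class AcquisitionOutcome:
    subject_id: str
    verdict: str  # "acquired" | "failed"
    triggered_rule: str | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in ("acquired", "failed"):
            raise ValueError("verdict must be 'acquired' or 'failed'")
        if (self.verdict == "failed") != (self.triggered_rule is not None):
            raise ValueError("failed verdicts must carry a triggered rule")


# ---------------------------------------------------------------- I/O

_HEADER_KEYS = ("subject", "group", "day", "dose_ug_per_kg", "fr", "timeout_s", "session_min")


def write_session_log(log: SessionLog, target) -> None:
    """Write the documented CSV dialect: a ``# key=value`` header block, a
    ``t_sec,kind`` column line, then one event per row."""
    own = isinstance(target, (str, Path))
    fh = open(target, "w") if own else target
    try:
        fh.write(f"# subject={log.subject_id}\n")
        fh.write(f"# group={log.group}\n")
        fh.write(f"# day={log.day_index}\n")
        fh.write(f"# dose_ug_per_kg={log.dose_ug_per_kg:g}\n")
        fh.write(f"# fr={log.fr_value}\n")
        fh.write(f"# timeout_s={log.timeout_s:g}\n")
        fh.write(f"# session_min={log.session_min:g}\n")
        fh.write("t_sec,kind\n")
        for t, kind in log.events:
            fh.write(f"{t:.3f},{kind}\n")
    finally:
        if own:
            fh.close()


def parse_session_log(source) -> SessionLog:
    """Parse a session log written in the documented CSV dialect.

    Accepts a path, a file object, or a string of the file's content.
    Malformed rows raise :class:`SessionParseError` naming the line number.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    header: dict[str, str] = {}
    events: list[tuple[float, str]] = []
    saw_columns = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise SessionParseError(f"line {lineno}: malformed header {raw!r}")
            key, _, val = body.partition("=")
            key = key.strip()
            if key in header:
                raise SessionParseError(f"line {lineno}: duplicate header key {key!r}")
            header[key] = val.strip()
            continue
        if not saw_columns:
            if line.replace(" ", "") != "t_sec,kind":
                raise SessionParseError(f"line {lineno}: expected 't_sec,kind' column line")
            saw_columns = True
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise SessionParseError(f"line {lineno}: expected 't_sec,kind', got {raw!r}")
        try:
            t = float(parts[0])
        except ValueError:
            raise SessionParseError(f"line {lineno}: bad timestamp {parts[0]!r}") from None
        kind = parts[1]
        if kind not in EVENT_KINDS:
            raise SessionParseError(f"line {lineno}: unknown event kind {kind!r}")
        events.append((t, kind))
    missing = [k for k in ("subject", "day") if k not in header]
    if missing:
        raise SessionParseError(f"missing header keys: {missing}")
    session_min = float(header.get("session_min", 120))
    for t, _ in events:
        if not (0.0 <= t <= session_min * 60.0):
            raise SessionParseError(f"event at {t} s outside [0, {session_min} min] session")
    return SessionLog(
        subject_id=header["subject"],
        day_index=int(header["day"]),
        events=events,
        dose_ug_per_kg=float(header.get("dose_ug_per_kg", 0)),
        fr_value=int(header.get("fr", 1)),
        timeout_s=float(header.get("timeout_s", 20)),
        session_min=session_min,
        group=header.get("group", ""),
    )


# ---------------------------------------------------------- schedule checks


def validate_schedule_semantics(log: SessionLog) -> list[str]:
    """Replay the FR/timeout contingency over the event stream.

    Returns human-readable violation strings, one per infusion that is not
    justified by exactly ``fr_value`` counted active pokes since the last
    infusion's timeout expired.  Active pokes within ``timeout_s`` seconds
    after an infusion are recorded but never counted.  An empty list means
    the log is consistent with the stated schedule.
    """
    order = {"active": 0, "inactive": 1, "infusion": 2}
    events = sorted(log.events, key=lambda e: (e[0], order[e[1]]))
    violations: list[str] = []
    counted = 0
    last_infusion: float | None = None
    for t, kind in events:
        in_timeout = last_infusion is not None and t < last_infusion + log.timeout_s
        if kind == "active":
            if not in_timeout:
                counted += 1
        elif kind == "infusion":
            if in_timeout:
                violations.append(
                    f"infusion at {t:.1f} s within the {log.timeout_s:g}-s timeout "
                    f"of the infusion at {last_infusion:.1f} s"
                )
            elif counted != log.fr_value:
                violations.append(
                    f"infusion at {t:.1f} s after {counted} counted active pokes "
                    f"(FR{log.fr_value} requires exactly {log.fr_value})"
                )
            counted = 0
            last_infusion = t
    return violations


@dataclass(frozen=True)
class SessionSummary:
    infusions: int
    active: int
    inactive: int
    ratio: float  # +inf when inactive == 0 and active > 0; nan when both 0
    ratio_defined: bool


def session_summary(log: SessionLog) -> SessionSummary:
    c = log.counts()
    active, inactive = c["active"], c["inactive"]
    if active == 0 and inactive == 0:
        ratio, defined = math.nan, False
    elif inactive == 0:
        ratio, defined = math.inf, True
    else:
        ratio, defined = active / inactive, True
    return SessionSummary(c["infusion"], active, inactive, ratio, defined)


def infusion_times(log: SessionLog) -> np.ndarray:
    """Sorted infusion timestamps in minutes — the PK model's input vector."""
    t = sorted(t for t, kind in log.events if kind == "infusion")
    return np.asarray(t, dtype=float) / 60.0


# ------------------------------------------------------------ aggregation


def _window_sessions(history: SubjectHistory, day_range) -> list[SessionLog]:
    days = list(day_range) if not isinstance(day_range, tuple) else list(
        range(day_range[0], day_range[1] + 1)
    )
    out = []
    for d in days:
        s = history.session_for_day(d)
        if s is None:
            raise CoverageError(f"subject {history.subject_id}: no session for day {d}")
        out.append(s)
    return out


def phase_mean_infusions(history: SubjectHistory, day_range) -> float:
    """Arithmetic mean of per-session infusion counts over a day range.

    ``day_range`` is an inclusive (first, last) tuple or any iterable of days;
    every day must be present.
    """
    sessions = _window_sessions(history, day_range)
    return float(np.mean([session_summary(s).infusions for s in sessions]))


# ------------------------------------------------------------- classifiers


def _longest_run(flags: Sequence[bool]) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def classify_standard_dose(
    history: SubjectHistory, criteria: AcquisitionCriteria = AcquisitionCriteria()
) -> AcquisitionOutcome:
    """Apply the three standard-dose failure rules over the acquisition phase.

    Rules are checked in their stated order and the first triggered one is
    recorded.  A session with zero pokes on both holes counts as failing the
    ratio criterion (a non-responding animal is not discriminating).
    """
    first, last = criteria.acquisition_days
    sessions = _window_sessions(history, (first, last))
    if len(sessions) < last - first + 1:
        raise CoverageError("insufficient acquisition sessions")
    summaries = [session_summary(s) for s in sessions]
    infusions = [s.infusions for s in summaries]
    details: dict = {"infusions": infusions}

    low_inf = [n < criteria.min_infusions for n in infusions]
    ratios = [s.ratio for s in summaries]
    details["ratios"] = ratios
    low_ratio = [
        (not s.ratio_defined) or (s.ratio < criteria.min_ratio) for s in summaries
    ]

    b0, b1 = criteria.drop_baseline_days
    e0, e1 = criteria.drop_eval_days
    baseline = float(
        np.mean([session_summary(s).active for s in _window_sessions(history, (b0, b1))])
    )
    details["active_baseline"] = baseline
    eval_actives = [session_summary(s).active for s in _window_sessions(history, (e0, e1))]
    details["active_eval"] = eval_actives
    drop_threshold = (1.0 - criteria.drop_fraction) * baseline
    dropped = baseline > 0 and any(a <= drop_threshold for a in eval_actives)

    if _longest_run(low_inf) >= criteria.min_consecutive_low_infusions:
        return AcquisitionOutcome(history.subject_id, "failed", "rule1_low_infusions", details)
    if _longest_run(low_ratio) >= criteria.min_consecutive_low_ratio:
        return AcquisitionOutcome(history.subject_id, "failed", "rule2_low_ratio", details)
    if dropped:
        return AcquisitionOutcome(history.subject_id, "failed", "rule3_response_drop", details)
    return AcquisitionOutcome(history.subject_id, "acquired", None, details)


def classify_low_dose(
    history: SubjectHistory, criteria: AcquisitionCriteria = AcquisitionCriteria()
) -> AcquisitionOutcome:
    """Fail iff mean infusions over the low-dose window fall strictly below
    the saline-level benchmark (11.1 infusions across days 6–10)."""
    mean = phase_mean_infusions(history, criteria.lowdose_days)
    details = {"window_mean": mean, "cutoff": criteria.lowdose_mean_cutoff}
    if mean < criteria.lowdose_mean_cutoff:
        return AcquisitionOutcome(history.subject_id, "failed", "lowdose_mean", details)
    return AcquisitionOutcome(history.subject_id, "acquired", None, details)


def control_referenced_cutoff(
    control_histories: Iterable[SubjectHistory],
    day_range,
    sd_multiplier: float = 2.0,
) -> float:
    """Cutoff = mean + k·SD of the control subjects' window-mean infusions.

    SD is the sample (n−1) standard deviation across control subjects.
    """
    means = [phase_mean_infusions(h, day_range) for h in control_histories]
    if len(means) < 2:
        raise DegenerateSDError("need >= 2 control subjects for an SD")
    return float(np.mean(means) + sd_multiplier * np.std(means, ddof=1))


def classify_control_referenced(
    history: SubjectHistory,
    cutoff: float,
    day_range,
) -> AcquisitionOutcome:
    mean = phase_mean_infusions(history, day_range)
    details = {"window_mean": mean, "cutoff": cutoff}
    if mean < cutoff:
        return AcquisitionOutcome(history.subject_id, "failed", "below_control_cutoff", details)
    return AcquisitionOutcome(history.subject_id, "acquired", None, details)


def substitution_effect(history: SubjectHistory, pre_range, post_range) -> float:
    """Paired change in window-mean infusions (post − pre), e.g. across a
    switch from drug to saline.  Negative values mean responding extinguished."""
    return phase_mean_infusions(history, post_range) - phase_mean_infusions(
        history, pre_range
    )
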