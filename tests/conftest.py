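import numpy as np
import pytest

from nicodose.pk import InfusionSchedule, PKParameters
from nicodose.sessions import SessionLog, SubjectHistory


@pytest.fixture
def rat_params() -> PKParameters:
    """The published rat parameter set (Vc 5 l/kg, rates in h⁻¹, 350-g rat)."""
    return PKParameters()


@pytest.fixture
def single_bolus() -> InfusionSchedule:
    """One 30 μg/kg infusion into a 0.35-kg rat at t=0 (10.5 μg)."""
    return InfusionSchedule(np.array([0.0]), dose_per_infusion=10.5)


def make_history(
    infusions_per_day,
    actives_per_day=None,
    inactives_per_day=None,
    subject_id="S1",
    group="test",
    fr_value=1,
    dose_ug_per_kg=30.0,
):
    """Hand-construct a schedule-consistent history from per-day counts.

    Infusions are spaced 60 s apart (beyond the 20-s timeout); each is
    triggered by one active poke at the same timestamp.  ``actives_per_day``
    adds extra active pokes *inside* timeout windows (recorded, not counted)
    so total active counts can exceed infusion counts without breaking the
    FR1 contingency.  Inactive pokes land late in the session.
    """
    sessions = []
    for day, n_inf in enumerate(infusions_per_day, start=1):
        extra_active = 0
        if actives_per_day is not None:
            extra_active = max(actives_per_day[day - 1] - n_inf * fr_value, 0)
        n_inactive = 0 if inactives_per_day is None else inactives_per_day[day - 1]
        events = []
        for i in range(n_inf):
            t = 30.0 + 60.0 * i
            for k in range(fr_value):
                events.append((t - 0.5 * (fr_value - 1 - k), "active"))
            events.append((t, "infusion"))
        for j in range(extra_active):
            # inside the timeout window of infusion j % n_inf (non-counted)
            host = 30.0 + 60.0 * (j % max(n_inf, 1))
            events.append((host + 2.0 + 0.01 * (j // max(n_inf, 1)), "active"))
        for j in range(n_inactive):
            events.append((7000.0 + j, "inactive"))
        events.sort(key=lambda e: e[0])
        sessions.append(
            SessionLog(
                subject_id=subject_id,
                day_index=day,
                events=events,
                dose_ug_per_kg=dose_ug_per_kg,
                fr_value=fr_value,
            )
        )
    return SubjectHistory(subject_id=subject_id, group=group, sessions=sessions)
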