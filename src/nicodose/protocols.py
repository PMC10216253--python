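"""Reconstructed self-administration dosing schedules.

The study's raw infusion records are not published; these builders encode the
qualitative session structure it reports — a loading phase of rapid infusions
in the first ~20 min followed by spaced maintenance infusions at the standard
30 μg/kg dose, and a back-loaded pattern (weak loading, stronger boosting
late in the session) at the 1.5 μg/kg dose — at the reported session length
(2 h) and infusion counts.
"""

from __future__ import annotations

import numpy as np

from .pk import InfusionSchedule, PKParameters

RAT_BODY_MASS_KG = 0.35

STANDARD_DOSE_UG_PER_KG = 30.0
LOW_DOSE_UG_PER_KG = 1.5


def standard_dose_session(body_mass: float = RAT_BODY_MASS_KG) -> InfusionSchedule:
    """2-h, 22-infusion session at 30 μg/kg/infusion.

    Loading: 10 infusions evenly spaced over minutes 0–18.
    Maintenance: 12 infusions every 8 min from minute 26 to 114.
    """
    loading = np.linspace(0.0, 18.0, 10)
    maintenance = np.arange(26.0, 114.0 + 1e-9, 8.0)
    times = np.concatenate([loading, maintenance])
    return InfusionSchedule.from_dose_per_kg(
        times, STANDARD_DOSE_UG_PER_KG, body_mass
    )


def low_dose_backloaded_session(body_mass: float = RAT_BODY_MASS_KG) -> InfusionSchedule:
    """2-h, 40-infusion back-loaded session at 1.5 μg/kg/infusion.

    10 infusions evenly spaced over the first hour (endpoint-exclusive, so the
    minute-60 slot belongs to the late block) and 30 infusions evenly spaced
    over minutes 60–118.
    """
    early = np.linspace(0.0, 60.0, 10, endpoint=False)
    late = np.linspace(60.0, 118.0, 30)
    times = np.concatenate([early, late])
    return InfusionSchedule.from_dose_per_kg(times, LOW_DOSE_UG_PER_KG, body_mass)


def default_rat_parameters() -> PKParameters:
    """The published rat parameter set: Vc 5 l/kg, k_el 0.8 h⁻¹, k_cp 1.5 h⁻¹,
    k_pc 1.2 h⁻¹, clearance 1.4 l/h, 0.35-kg rat."""
    return PKParameters()
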