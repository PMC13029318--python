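#!/usr/bin/env python
"""Simulate reference-dog gentamicin profiles across renal-function stages.

A 10.5 kg beagle receives 4 mg/kg as a 5-min IV infusion q24h for three days.
Each renal stage scales the healthy GFR (3.3 mL/min/kg); since gentamicin is
cleared almost exclusively by glomerular filtration, AUC rises and troughs
climb steeply as GFR falls, while Cmax barely moves.  Writes the long-format
profile table and a per-stage exposure summary under results/.
"""

from pathlib import Path

import pandas as pd

from gentapbpk import (
    GENTAMICIN,
    DoseRegimen,
    apply_renal_stage,
    build_reference_dog,
    exposure_metrics,
    simulate_profile,
)
from gentapbpk.physiology import STAGE_ORDER

OUT = Path("results/reference_profiles")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    regimen = DoseRegimen(dose_per_kg=4.0)
    healthy = build_reference_dog()
    profiles, summary = [], []
    for stage in STAGE_ORDER:
        dog = apply_renal_stage(healthy, stage)
        prof = simulate_profile(dog, GENTAMICIN, regimen)
        m = exposure_metrics(prof, regimen)
        profiles.append(
            pd.DataFrame(
                {"stage": stage, "time_h": prof.times, "plasma_conc_ug_ml": prof.plasma_concentration}
            )
        )
        summary.append(
            {
                "stage": stage,
                "gfr_ml_min_kg": dog.gfr,
                "cmax_ug_ml": m.cmax,
                "auc24_day1_mg_h_l": m.auc24_day1,
                "auc24_final_mg_h_l": m.auc24_final,
                "cmin_final_ug_ml": m.cmin_final,
            }
        )
    pd.concat(profiles).to_csv(OUT / "profiles.csv", index=False, float_format="%.6g")
    summ = pd.DataFrame(summary)
    summ.to_csv(OUT / "exposure_summary.csv", index=False, float_format="%.6g")
    print(summ.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
    print(
        "\nFinding: day-1 AUC scales inversely with GFR "
        f"(x{summ['auc24_day1_mg_h_l'].iloc[-1] / summ['auc24_day1_mg_h_l'].iloc[0]:.1f} "
        "from healthy to sCr>=5) while Cmax varies by "
        f"{100 * (summ['cmax_ug_ml'].max() / summ['cmax_ug_ml'].min() - 1):.0f}%; "
        "trough accumulation appears below ~30% of healthy GFR."
    )


if __name__ == "__main__":
    main()
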