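"""Headline dosing-analysis outcomes, recomputed from scratch.

Eight benchmark quantities summarise the dosing analysis: nephrotoxicity
risk cells for the healthy and most-severe renal populations, and minimal
effective doses under the three PK/PD efficacy indices.  Each is computed by
sampling a fresh virtual population, simulating the regimen grid and
measuring the outcome — nothing is tabulated.
"""

from __future__ import annotations

import numpy as np

from .montecarlo import population_exposure_by_dose
from .pbpk import GENTAMICIN
from .physiology import RENAL_STAGES, PopulationSpec, population_frame
from .pkpd import EfficacyTarget, compute_pta, toxicity_risk

__all__ = ["benchmark_outcomes", "DOSES"]

DOSES = (2.0, 4.0, 6.0, 8.0, 10.0)


def _sub_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), tag]).generate_state(1)[0] % (2**31))


def _stage_metrics(stage: str, seed: int, n: int):
    spec = PopulationSpec(n=n, stage=RENAL_STAGES[stage], seed=seed)
    pop = population_frame(spec)
    return population_exposure_by_dose(pop, GENTAMICIN, DOSES)


def _minimal_dose(metrics, index: str, threshold: float, mic: float) -> float:
    """Smallest dose with PTA >= 90% for one target at one MIC; NaN if none."""
    target = EfficacyTarget(index, threshold)
    for dose in DOSES:
        grp = metrics[metrics["dose_mg_kg"] == dose]
        pta = compute_pta(grp, target, [mic])["pta_pct"].iloc[0]
        if pta >= 90.0:
            return dose
    return float("nan")


def benchmark_outcomes(seed: int, n: int = 2000) -> dict[str, dict[str, float]]:
    """Compute the eight benchmark outcomes at population size ``n``.

    Returns ``{id: {"value": ..., "n": n}}`` with doses in mg/kg and risks as
    percentages.  The q24h x3 5-min-infusion regimen shape is used
    throughout; populations are seeded deterministically from ``seed``.
    """
    healthy = _stage_metrics("healthy", _sub_seed(seed, 0), n)
    micro = _stage_metrics("microalbuminuria", _sub_seed(seed, 1), n)
    severe = _stage_metrics("scr_ge_5", _sub_seed(seed, 2), n)

    h10 = healthy[healthy["dose_mg_kg"] == 10.0]
    h2 = healthy[healthy["dose_mg_kg"] == 2.0]
    s10 = severe[severe["dose_mg_kg"] == 10.0]

    values = {
        # risk cells (final dosing interval, inclusive thresholds)
        "t1": toxicity_risk(h10, "auc24_ge_700"),
        "t2": toxicity_risk(h2, "cmin_ge_0_5"),
        "t7": toxicity_risk(s10, "cmin_ge_0_5"),
        # minimal effective doses
        "t3": _minimal_dose(healthy, "cmax_over_mic", 10.0, mic=0.5),
        "t4": _minimal_dose(healthy, "cmax_over_mic", 10.0, mic=2.0),
        "t5": _minimal_dose(healthy, "auc24_over_mic", 50.0, mic=0.5),
        "t6": _minimal_dose(healthy, "auc24_over_mic", 110.0, mic=0.25),
        "t8": _minimal_dose(micro, "auc24_over_mic", 50.0, mic=1.0),
    }
    return {k: {"value": float(v), "n": n} for k, v in sorted(values.items())}
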