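import numpy as np
import pandas as pd
import pytest

from gentapbpk import (
    GENTAMICIN,
    DoseRegimen,
    build_reference_dog,
)
from gentapbpk.montecarlo import population_exposure_by_dose
from gentapbpk.physiology import RENAL_STAGES, PopulationSpec, population_frame


@pytest.fixture(scope="session")
def reference_dog():
    return build_reference_dog()


@pytest.fixture(scope="session")
def q24_regimen():
    """Default study regimen shape: 5-min infusion q24h x3 at 1 mg/kg."""
    return DoseRegimen(dose_per_kg=1.0)


@pytest.fixture(scope="session")
def healthy_population_2000():
    spec = PopulationSpec(n=2000, stage=RENAL_STAGES["healthy"], seed=20260918)
    return population_frame(spec)


@pytest.fixture(scope="session")
def healthy_metrics_2000(healthy_population_2000):
    """Exposure metrics for the healthy n=2000 population, doses 2-10 q24h."""
    return population_exposure_by_dose(
        healthy_population_2000, GENTAMICIN, doses=(2, 4, 6, 8, 10)
    )
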