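import numpy as np
import pandas as pd
import pytest

from bcrisk.absolute_risk import RateTable
from bcrisk.cohort import ALL_COLUMNS, PV_GENES, Cohort
from bcrisk.relative_risk import default_coefficients


def make_cohort_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a cohort DataFrame from sparse row dicts; unspecified = missing."""
    df = pd.DataFrame(rows)
    for col in ALL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[list(ALL_COLUMNS)]


def complete_row(id, status, age, **overrides) -> dict:
    """A fully observed reference-ish row, overridable per field."""
    row = {
        "id": id,
        "status": status,
        "age": age,
        "age_menarche": 15.0,
        "parity": 0.0,
        "breastfeeding_months": 0.0,
        "benign_breast_disease": 0.0,
        "family_history": 0.0,
        "height_cm": 160.0,
        "bmi": 22.0,
        "alcohol": 0.0,
        "prs": 0.0,
    }
    row.update({f"pv_{g}": 0.0 for g in PV_GENES})
    row.update(overrides)
    return row


@pytest.fixture
def coeffs():
    return default_coefficients()


@pytest.fixture
def small_cohort():
    rows = [
        complete_row("c1", 0, 40.0),
        complete_row("c2", 0, 35.0, parity=2, height_cm=150.0),
        complete_row("c3", 0, 50.0, bmi=31.0, alcohol=1.0),
        complete_row("k1", 1, 45.0, family_history=1.0, prs=0.5),
        complete_row("k2", 1, 55.0, pv_BRCA1=1.0),
        complete_row("k3", 1, 60.0, parity=5, breastfeeding_months=80.0),
    ]
    return Cohort(make_cohort_frame(rows), imputed=True)


@pytest.fixture
def flat_rates():
    """One band [18, 80) with incidence 1e-3 and mortality 2e-3 per year."""
    return RateTable.from_bands([(18, 80, 1e-3, 2e-3)])


@pytest.fixture
def two_band_rates():
    return RateTable.from_bands([(18, 50, 1e-3, 1e-3), (50, 80, 2e-3, 5e-3)])
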