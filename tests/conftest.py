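import numpy as np
import pandas as pd
import pytest

from fairdea.panel import PanelDataset, REQUIRED_COLUMNS


_DEFAULTS = {
    "X1": 1.0, "X2": 1.0, "X3": 1.0, "X4": 1.0, "X5": 1.0, "X6": 1.0,
    "Y1": 1.0, "Y2": 1.0, "Y3": 1.0,
    "population": 1.0,
    "gdp_per_capita": 1.0,
    "population_density": 1.0,
    "urbanization_rate": 0.5,
}


def make_panel(records):
    """Build a PanelDataset from partial row dicts; unspecified numeric
    columns default to benign positive values."""
    rows = []
    for rec in records:
        row = dict(_DEFAULTS)
        row.update(rec)
        rows.append(row)
    return PanelDataset(pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)))


def random_panel(rng, n_east=3, n_west=3, years=(2014, 2015)):
    """Random positive balanced two-region panel."""
    records = []
    units = [("eastern", f"E{i}") for i in range(n_east)] + [
        ("western", f"W{i}") for i in range(n_west)
    ]
    for region, uid in units:
        pop = rng.uniform(0.5, 5.0)
        for year in years:
            rec = {"unit_id": uid, "region": region, "year": year, "population": pop}
            for col in ("X1", "X2", "X3", "X4", "X5", "X6", "Y1", "Y2", "Y3"):
                rec[col] = rng.uniform(0.5, 5.0)
            rec["gdp_per_capita"] = rng.uniform(1.0, 10.0)
            rec["population_density"] = rng.uniform(1.0, 10.0)
            rec["urbanization_rate"] = rng.uniform(0.2, 0.9)
            records.append(rec)
    return make_panel(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
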