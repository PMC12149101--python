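"""Panel data model: a balanced province-by-year table of healthcare
resource indicators, service outputs, population weights and context
covariates.

The canonical on-disk form is a tidy long CSV with one row per
(unit, year).  All analysis stages read a single validated
:class:`PanelDataset`; unit and year orderings are normalised so that
downstream matrix layouts are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "REGIONS",
    "INPUT_COLUMNS",
    "OUTPUT_COLUMNS",
    "COVARIATE_COLUMNS",
    "REQUIRED_COLUMNS",
    "SchemaError",
    "ValidationError",
    "AnalysisConfig",
    "PanelDataset",
    "read_panel",
    "write_panel",
    "write_report_table",
    "round_half_up",
]

#: The three macro-regions used in the regional decomposition.
REGIONS = ("eastern", "central", "western")

#: Resource (input) indicators.  X1 health technical personnel [persons],
#: X2 practicing (assistant) physicians [persons], X3 registered nurses
#: [persons], X4 beds [beds], X5 total assets [10^4 yuan], X6 total
#: health expenses [10^8 yuan].
INPUT_COLUMNS = ("X1", "X2", "X3", "X4", "X5", "X6")

#: Service (output) indicators.  Y1 bed utilization rate [%],
#: Y2 outpatient/emergency visits [persons], Y3 discharges [persons].
OUTPUT_COLUMNS = ("Y1", "Y2", "Y3")

#: Context covariates for the efficiency-determinants regression.
COVARIATE_COLUMNS = ("gdp_per_capita", "population_density", "urbanization_rate")

REQUIRED_COLUMNS = (
    ("unit_id", "region", "year")
    + INPUT_COLUMNS
    + OUTPUT_COLUMNS
    + ("population",)
    + COVARIATE_COLUMNS
)

_POSITIVE_COLUMNS = INPUT_COLUMNS + OUTPUT_COLUMNS + (
    "population",
    "gdp_per_capita",
    "population_density",
)


class SchemaError(ValueError):
    """A table is structurally incompatible with the panel schema."""


class ValidationError(ValueError):
    """A table matches the schema but violates a panel invariant."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration shared by all analysis stages.

    Parameters
    ----------
    dea_inputs, dea_outputs
        Indicator columns used as DEA inputs/outputs.  The default input
        set is personnel, physicians, nurses, beds and total health
        expenses (X1-X4, X6); total assets (X5) is kept for the fairness
        indices but not in the production technology.
    theil_indicators
        Indicators whose allocation fairness is measured (X1-X5).
    lp_tolerance
        Numerical tolerance for LP-derived quantities (slack zeroing,
        lambda-sum returns-to-scale classification).
    effective_threshold
        A unit with efficiency >= 1 - effective_threshold counts as
        frontier-efficient.
    digits
        Half-up rounding precision for report tables.
    theil_covariate_rule
        How province-level Theil covariates for the Tobit stage are
        assigned: ``"region"`` uses the within-region index of the
        unit's own region, ``"national"`` uses the overall index.
    """

    dea_inputs: tuple[str, ...] = ("X1", "X2", "X3", "X4", "X6")
    dea_outputs: tuple[str, ...] = OUTPUT_COLUMNS
    theil_indicators: tuple[str, ...] = ("X1", "X2", "X3", "X4", "X5")
    lp_tolerance: float = 1e-6
    effective_threshold: float = 1e-6
    digits: int = 3
    theil_covariate_rule: str = "region"

    def __post_init__(self) -> None:
        if self.lp_tolerance <= 0 or self.effective_threshold <= 0:
            raise ValueError("tolerances must be strictly positive")
        known = set(REQUIRED_COLUMNS)
        for name in (*self.dea_inputs, *self.dea_outputs, *self.theil_indicators):
            if name not in known:
                raise SchemaError(f"unknown indicator column: {name!r}")
        if self.theil_covariate_rule not in ("region", "national"):
            raise ValueError("theil_covariate_rule must be 'region' or 'national'")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        for key in ("dea_inputs", "dea_outputs", "theil_indicators"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class PanelDataset:
    """A validated balanced panel.

    ``frame`` holds one row per (unit, year), sorted by unit then year.
    """

    frame: pd.DataFrame
    units: tuple[str, ...] = field(init=False)
    years: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["unit_id"] = df["unit_id"].astype(str)
        df["region"] = df["region"].astype(str)
        df["year"] = df["year"].astype(int)

        bad_region = sorted(set(df["region"]) - set(REGIONS))
        if bad_region:
            raise ValidationError(
                f"unknown region label(s): {bad_region}; expected one of {REGIONS}"
            )

        for col in _POSITIVE_COLUMNS:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[~(vals > 0)]
            if len(bad):
                row = df.loc[bad[0]]
                raise ValidationError(
                    f"non-positive or missing value in column {col!r} for "
                    f"unit {row['unit_id']!r}, year {row['year']}"
                )
            df[col] = vals.astype(float)
        ur = pd.to_numeric(df["urbanization_rate"], errors="coerce")
        bad = df.index[~((ur > 0) & (ur <= 1))]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValidationError(
                "urbanization_rate must lie in (0, 1] for "
                f"unit {row['unit_id']!r}, year {row['year']} (got {ur[bad[0]]!r})"
            )
        df["urbanization_rate"] = ur.astype(float)

        dup = df.duplicated(subset=["unit_id", "year"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate record for unit {row['unit_id']!r}, year {row['year']}"
            )
        units = tuple(sorted(df["unit_id"].unique()))
        years = tuple(sorted(df["year"].unique()))
        have = set(zip(df["unit_id"], df["year"]))
        absent = [(u, y) for u in units for y in years if (u, y) not in have]
        if absent:
            raise ValidationError(f"unbalanced panel; missing (unit, year) pairs: {absent}")

        regions = df.drop_duplicates("unit_id").set_index("unit_id")["region"]
        if df.groupby("unit_id")["region"].nunique().max() > 1:
            raise ValidationError("a unit's region label must not change across years")

        df = df.sort_values(["unit_id", "year"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "frame", df)
        self.units = units
        self.years = years
        self._region_of = dict(regions)

    def __len__(self) -> int:
        return len(self.frame)

    def region_of(self, unit: str) -> str:
        return self._region_of[unit]

    @property
    def regions(self) -> tuple[str, ...]:
        present = {self._region_of[u] for u in self.units}
        return tuple(r for r in REGIONS if r in present)

    def year_slice(self, year: int) -> pd.DataFrame:
        """Rows of one year, ordered by unit."""
        if year not in self.years:
            raise KeyError(f"year {year} not in panel (years: {self.years})")
        return self.frame[self.frame["year"] == year].reset_index(drop=True)

    def matrices(self, year: int, inputs: Sequence[str], outputs: Sequence[str]):
        """(units, X, Y) for one year: X is n_inputs x n_units, Y likewise."""
        sl = self.year_slice(year)
        X = sl.loc[:, list(inputs)].to_numpy(float).T
        Y = sl.loc[:, list(outputs)].to_numpy(float).T
        return list(sl["unit_id"]), X, Y


def read_panel(path: str | Path, config: AnalysisConfig | None = None) -> PanelDataset:
    """Read and validate a tidy long panel CSV.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for invariant violations (non-positive
    indicators, bad region labels, unbalanced panels).
    """
    df = pd.read_csv(path)
    return PanelDataset(df)


def write_panel(dataset: PanelDataset, path: str | Path) -> None:
    dataset.frame.to_csv(path, index=False)


def round_half_up(value: float, digits: int) -> float:
    """Decimal half-up rounding (0.0005 -> 0.001 at 3 digits)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def write_report_table(rows: pd.DataFrame, path: str | Path, digits: int = 3) -> None:
    """Write a result table as CSV with numeric cells rounded half-up.

    Re-reading the file yields the same rounded values.  Raises
    ``ValueError`` on an empty table.
    """
    if rows is None or len(rows) == 0:
        raise ValueError("refusing to write an empty report table")
    out = rows.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: round_half_up(v, digits) if pd.notna(v) else v
            )
    out.to_csv(path, index=False)
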