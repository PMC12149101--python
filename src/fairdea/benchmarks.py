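"""Published benchmark tables and the arithmetic checks they support.

Three small CSVs transcribe the printed provincial results this
package's report layouts follow: the 2014-2019 comprehensive-efficiency
panel, the 2019 TE/PTE/SE/returns-to-scale decomposition, and the
per-province Malmquist TFP decomposition.  Their summary rows (means,
frontier counts, index products) are recomputable from the per-province
values, which makes them useful end-to-end arithmetic fixtures even
though the underlying yearbook inputs are not public.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .panel import round_half_up

__all__ = [
    "load_efficiency_panel",
    "load_decomposition_2019",
    "load_tfp_decomposition",
    "BenchmarkCheck",
    "run_benchmark_checks",
]

_FILES = {
    "efficiency": "benchmark_efficiency_2014_2019.csv",
    "decomposition": "benchmark_decomposition_2019.csv",
    "tfp": "benchmark_tfp_decomposition.csv",
}

#: Printed summary rows of the efficiency panel (per year):
#: arithmetic mean efficiency and number of frontier-efficient provinces.
PUBLISHED_MEANS = {2014: 0.908, 2015: 0.915, 2016: 0.93, 2017: 0.929, 2018: 0.934, 2019: 0.932}
PUBLISHED_EFFECTIVE = {2014: 11, 2019: 15}

#: Printed 2019 decomposition summary: mean TE/PTE/SE and the counts
#: reported alongside (frontier-efficient, doubly inefficient, drs).
PUBLISHED_2019 = {
    "mean_te": 0.932,
    "mean_pte": 0.936,
    "mean_se": 0.996,
    "effective_count": 15,
    "doubly_inefficient_count": 11,
    "drs_count": 8,
}

#: Printed per-province TFP row used as a product-identity fixture.
PUBLISHED_BEIJING_TFPCH = 1.002


def _read(name: str, data_dir: str | Path | None = None) -> pd.DataFrame:
    fname = _FILES[name]
    if data_dir is not None:
        return pd.read_csv(Path(data_dir) / fname, comment="#")
    with resources.files("fairdea.data").joinpath(fname).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")


def load_efficiency_panel(data_dir: str | Path | None = None) -> pd.DataFrame:
    """31 provinces x 6 years of comprehensive efficiency."""
    return _read("efficiency", data_dir)


def load_decomposition_2019(data_dir: str | Path | None = None) -> pd.DataFrame:
    """2019 TE/PTE/SE and returns-to-scale labels."""
    return _read("decomposition", data_dir)


def load_tfp_decomposition(data_dir: str | Path | None = None) -> pd.DataFrame:
    """Per-province Malmquist decomposition (period geometric means)."""
    return _read("tfp", data_dir)


@dataclass(frozen=True)
class BenchmarkCheck:
    name: str
    computed: float
    expected: float
    passed: bool


def run_benchmark_checks(data_dir: str | Path | None = None) -> list[BenchmarkCheck]:
    """Recompute every published-arithmetic check from the benchmark
    tables: yearly means, the 2014/2019 frontier counts, the 2019
    decomposition summary and counts, and Beijing's TFP product
    identity.  Raises ``FileNotFoundError`` if a table is missing."""
    eff = load_efficiency_panel(data_dir)
    dec = load_decomposition_2019(data_dir)
    tfp = load_tfp_decomposition(data_dir)
    for df, n in ((eff, "efficiency"), (dec, "decomposition"), (tfp, "tfp")):
        if len(df) != 31:
            raise ValueError(f"benchmark table {n!r} should have 31 provinces, found {len(df)}")

    checks: list[BenchmarkCheck] = []

    def add(name: str, computed: float, expected: float) -> None:
        checks.append(
            BenchmarkCheck(name, computed, expected, passed=bool(computed == expected))
        )

    for year, mean in PUBLISHED_MEANS.items():
        col = eff[f"y{year}"]
        add(f"mean_efficiency_{year}", round_half_up(col.mean(), 3), mean)
    for year, count in PUBLISHED_EFFECTIVE.items():
        add(f"effective_count_{year}", int((eff[f"y{year}"] >= 1.0).sum()), count)

    add("mean_te_2019", round_half_up(dec["te"].mean(), 3), PUBLISHED_2019["mean_te"])
    add("mean_pte_2019", round_half_up(dec["pte"].mean(), 3), PUBLISHED_2019["mean_pte"])
    add("mean_se_2019", round_half_up(dec["se"].mean(), 3), PUBLISHED_2019["mean_se"])
    add(
        "effective_count_2019_decomposition",
        int((dec["te"] >= 1.0).sum()),
        PUBLISHED_2019["effective_count"],
    )
    add(
        "doubly_inefficient_count_2019",
        int(((dec["pte"] < 1.0) & (dec["se"] < 1.0)).sum()),
        PUBLISHED_2019["doubly_inefficient_count"],
    )
    add("drs_count_2019", int((dec["rts"] == "drs").sum()), PUBLISHED_2019["drs_count"])

    beijing = tfp.loc[tfp["province"] == "Beijing"].iloc[0]
    add(
        "beijing_tfpch_product",
        round_half_up(beijing["effch"] * beijing["techch"], 3),
        PUBLISHED_BEIJING_TFPCH,
    )
    return checks
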