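"""End-to-end orchestration: simulate or load a panel, measure
allocation fairness (Theil), static efficiency (CCR/BCC), dynamic
productivity (Malmquist), and the efficiency-determinants Tobit, and
write all report tables plus a run manifest.

A single JSON config drives a run::

    {
      "seed": 1,
      "simulate": { ... SyntheticConfig fields ... },   # or "panel": "panel.csv"
      "analysis": { ... AnalysisConfig fields ... }
    }

Reruns with identical inputs reproduce byte-identical report tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .benchmarks import run_benchmark_checks
from .dea import projection_table, score_year, summarize_scores
from .malmquist import malmquist_panel, malmquist_summary
from .panel import AnalysisConfig, PanelDataset, read_panel, write_panel, write_report_table
from .synthetic import SyntheticConfig, generate_panel
from .theil import theil_table
from .tobit import build_regression_table, fit_tobit, tobit_report

__all__ = ["RunManifest", "run_all", "verify_fixtures"]


@dataclass
class RunManifest:
    config: dict
    seed: int | None
    input_digests: dict[str, str]
    outputs: dict[str, str]
    timings: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: dict | str | Path, outdir: str | Path) -> RunManifest:
    """Run every stage and write report tables under ``outdir``.

    Emits theil.csv, dea_scores.csv, dea_summary.csv, projections.csv,
    malmquist.csv, malmquist_summary.csv, tobit.csv and manifest.json.
    A single-year panel skips the Malmquist stage with a warning.  Any
    stage failure is recorded in the manifest (which is still written)
    and re-raised with the stage name.
    """
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = json.load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = AnalysisConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in config.get("analysis", {}).items()
    })
    manifest = RunManifest(
        config=config,
        seed=config.get("seed"),
        input_digests={},
        outputs={},
        timings={},
    )
    try:
        _run_stages(config, analysis, manifest, outdir)
    except Exception as exc:
        manifest.warnings.append(f"run aborted: {exc}")
        raise
    finally:
        manifest.to_json(outdir / "manifest.json")
    return manifest


def _run_stages(
    config: dict, analysis: AnalysisConfig, manifest: RunManifest, outdir: Path
) -> None:
    timings = manifest.timings
    warnings = manifest.warnings

    def _emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        write_report_table(frame, path, digits=analysis.digits)
        manifest.outputs[name] = str(path)

    def _run(stage: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        finally:
            timings[stage] = round(time.perf_counter() - t0, 4)

    state: dict[str, object] = {}

    def stage_input() -> None:
        if "panel" in config:
            panel_path = Path(config["panel"])
            state["dataset"] = read_panel(panel_path, analysis)
            manifest.input_digests["panel"] = _sha256(panel_path)
        elif "simulate" in config:
            sim_kwargs = dict(config["simulate"])
            for key in ("region_sizes", "region_multipliers"):
                if key in sim_kwargs:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            if manifest.seed is not None:
                sim_kwargs.setdefault("seed", manifest.seed)
            sim = SyntheticConfig(**sim_kwargs)
            dataset, _truth = generate_panel(sim)
            sim_panel = outdir / "panel.csv"
            write_panel(dataset, sim_panel)
            manifest.outputs["panel.csv"] = str(sim_panel)
            manifest.input_digests["panel"] = _sha256(sim_panel)
            manifest.seed = sim.seed
            state["dataset"] = dataset
        else:
            raise ValueError("config needs a 'panel' path or a 'simulate' block")

    def stage_theil() -> None:
        dataset: PanelDataset = state["dataset"]
        theil = theil_table(dataset, analysis.theil_indicators, dataset.years)
        state["theil"] = theil
        _emit("theil.csv", theil)

    def stage_dea() -> None:
        dataset: PanelDataset = state["dataset"]
        all_scores = []
        summaries = []
        for year in dataset.years:
            scores = score_year(dataset, year, analysis)
            all_scores.extend(scores)
            _table, summary = summarize_scores(scores, analysis)
            summaries.append({"year": year, **summary})
        score_table = pd.DataFrame(
            {
                "unit": [s.unit for s in all_scores],
                "year": [s.year for s in all_scores],
                "te": [s.te for s in all_scores],
                "pte": [s.pte for s in all_scores],
                "se": [s.se for s in all_scores],
                "rts": [s.rts_label for s in all_scores],
            }
        )
        state["scores"] = all_scores
        state["score_table"] = score_table
        _emit("dea_scores.csv", score_table)
        _emit("dea_summary.csv", pd.DataFrame(summaries))

    def stage_projection() -> None:
        dataset: PanelDataset = state["dataset"]
        last = dataset.years[-1]
        proj = projection_table(
            [s for s in state["scores"] if s.year == last], analysis
        )
        if len(proj):
            _emit("projections.csv", proj)
        else:
            warnings.append(
                f"no inefficient units in {last}; projections.csv not written"
            )

    def stage_malmquist() -> None:
        dataset: PanelDataset = state["dataset"]
        records = malmquist_panel(dataset, analysis)
        by_year, _by_unit = malmquist_summary(records)
        _emit("malmquist.csv", records)
        _emit("malmquist_summary.csv", by_year)

    def stage_tobit() -> None:
        dataset: PanelDataset = state["dataset"]
        reg = build_regression_table(
            dataset, state["score_table"], state["theil"], analysis
        )
        fit = fit_tobit(reg)
        _emit("tobit.csv", tobit_report(fit, analysis.digits))
        if not fit.n_censored:
            warnings.append("tobit: no censored observations (no unit on the frontier)")

    _run("input", stage_input)
    _run("theil", stage_theil)
    _run("dea", stage_dea)
    _run("projection", stage_projection)
    if len(state["dataset"].years) >= 2:
        _run("malmquist", stage_malmquist)
        _run("tobit", stage_tobit)
    else:
        # One period gives no adjacent-year pairs, and the fairness
        # covariates (one Theil value per region) are collinear with
        # the intercept, so neither stage is identified.
        warnings.append("single-year panel: Malmquist stage skipped")
        warnings.append(
            "single-year panel: Tobit stage skipped (region-level fairness "
            "covariates need temporal variation to be identified)"
        )


def verify_fixtures(data_dir: str | Path | None = None) -> pd.DataFrame:
    """Recompute every published-arithmetic check from the packaged
    benchmark tables.  Returns a table with columns (check, computed,
    expected, passed); raises if a fixture file is absent."""
    checks = run_benchmark_checks(data_dir)
    return pd.DataFrame(
        {
            "check": [c.name for c in checks],
            "computed": [c.computed for c in checks],
            "expected": [c.expected for c in checks],
            "passed": [c.passed for c in checks],
        }
    )
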