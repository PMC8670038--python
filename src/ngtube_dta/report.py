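"""Single-entry report pipeline.

Regenerates every in-scope output — the sensitivity table, lung
specificities, funnel series, and both decision-model scenarios — from
one input source (a CSV, the marginal-count fixture, or a synthetic
cohort), writing CSV/JSON artefacts plus a Markdown summary with a
provenance header.  All numbers in the summary are display-rounded
copies of values computed by the analysis modules; no arithmetic happens
at this layer.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .accuracy import lung_specificity, mean_reading, paired_t_test, sensitivity_table
from .cohort import CohortParams, generate_cohort, trial_fixture
from .decision import DecisionModelParams, run_recheck_scenario, run_standard_scenario, sweep
from .records import PatientDataset, TubeLocation, read_patient_table
from .sites import funnel_limits, per_site_estimates

__all__ = ["RunConfig", "run_full_report"]

DEFAULT_CUTOFFS = (4.0, 5.0, 5.5, 6.0)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one report run.

    Exactly one of ``input_path``, ``cohort_params`` or ``use_fixture``
    selects the data source.
    """

    input_path: Optional[str] = None
    cohort_params: Optional[CohortParams] = None
    use_fixture: bool = False
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    level: float = 0.95
    primary_cutoff: float = 5.5
    decision: Optional[DecisionModelParams] = None  # sensitivities filled from data
    seed: Optional[int] = None
    output_dir: str = "report_out"

    def __post_init__(self) -> None:
        sources = sum(
            [self.input_path is not None, self.cohort_params is not None, self.use_fixture]
        )
        if sources != 1:
            raise ValueError(
                "exactly one of input_path, cohort_params, use_fixture must be set"
            )
        if self.primary_cutoff not in self.cutoffs:
            raise ValueError("primary_cutoff must be one of the analysis cutoffs")

    def config_hash(self) -> str:
        payload = {
            "input_path": self.input_path,
            "cohort_params": self.cohort_params.to_dict() if self.cohort_params else None,
            "use_fixture": self.use_fixture,
            "cutoffs": list(self.cutoffs),
            "level": self.level,
            "primary_cutoff": self.primary_cutoff,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _load(config: RunConfig) -> tuple[PatientDataset, dict]:
    if config.input_path is not None:
        dataset, log = read_patient_table(config.input_path)
        return dataset, {
            "source": config.input_path,
            "excluded_one_test_only": log.one_test_only,
            "excluded_no_aspirate": log.no_aspirate,
        }
    if config.use_fixture:
        return trial_fixture(), {"source": "fixture"}
    dataset = generate_cohort(config.cohort_params, seed=config.seed)
    return dataset, {"source": "synthetic", "params": config.cohort_params.to_dict()}


def run_full_report(config: RunConfig) -> dict:
    """Run the full pipeline; returns a manifest of written artefacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        dataset, provenance = _load(config)
    except Exception as exc:
        raise RuntimeError(f"report stage 'load' failed: {exc}") from exc

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "provenance": provenance,
        "files": [],
    }

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        manifest["files"].append(name)

    # --- sensitivity table -------------------------------------------------
    try:
        table = sensitivity_table(dataset, config.cutoffs, config.level)
    except Exception as exc:
        raise RuntimeError(f"report stage 'accuracy' failed: {exc}") from exc
    _write(table.to_dataframe(display_rounding=False), "sensitivity_full.csv")
    _write(table.to_dataframe(display_rounding=True), "sensitivity_table.csv")

    # --- lung specificity --------------------------------------------------
    lung_rows = []
    if dataset.lung:
        for cutoff in config.cutoffs:
            est = lung_specificity(dataset, cutoff, level=config.level)
            lung_rows.append(
                {
                    "cutoff": cutoff,
                    "k": est.numerator,
                    "n": est.denominator,
                    "specificity": est.point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
        _write(pd.DataFrame(lung_rows), "lung_specificity.csv")

    # --- sites and funnel --------------------------------------------------
    try:
        sites = per_site_estimates(dataset, config.primary_cutoff, config.level)
    except Exception as exc:
        raise RuntimeError(f"report stage 'sites' failed: {exc}") from exc
    site_frame = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "n": [s.n for s in sites],
            "sens_standard": [s.sens_standard.point for s in sites],
            "sens_novel": [s.sens_novel.point for s in sites],
            "margin": [s.margin for s in sites],
        }
    )
    _write(site_frame, "site_estimates.csv")
    n_grid = tuple(range(5, max(max(s.n for s in sites) + 10, 60)))
    primary_row = next(r for r in table.rows if r.cutoff == config.primary_cutoff)
    for strip, pooled in (
        ("standard", primary_row.standard.point),
        ("novel", primary_row.novel.point),
    ):
        series = funnel_limits(pooled, n_grid, config.level)
        _write(series.to_dataframe(), f"funnel_{strip}.csv")

    # --- decision model ----------------------------------------------------
    base = config.decision or DecisionModelParams(
        sens_standard=primary_row.standard.point,
        sens_novel=primary_row.novel.point,
        cutoff=config.primary_cutoff,
    )
    scenarios = {
        "standard": run_standard_scenario(base),
        "recheck": run_recheck_scenario(base),
    }
    cutoff_sens = {
        r.cutoff: (r.standard.point, r.novel.point) for r in table.rows
    }
    margins = sorted(s.margin for s in sites)
    swept = sweep(base, cutoff_sensitivities=cutoff_sens, margins=margins)
    decision_payload = {
        "params": {
            k: getattr(base, k)
            for k in (
                "cohort_size",
                "gastric_rate",
                "aspiration_success",
                "sens_standard",
                "sens_novel",
                "cutoff",
                "cxr_unit_cost",
                "inflation_rate",
                "inflation_years",
            )
        },
        "scenarios": {k: v.to_dict() for k, v in scenarios.items()},
        "sweep": [r.to_dict() for r in swept],
    }
    (outdir / "decision_model.json").write_text(
        json.dumps(decision_payload, indent=2, sort_keys=True)
    )
    manifest["files"].append("decision_model.json")

    # --- markdown summary --------------------------------------------------
    manifest["files"].append("report.md")
    (outdir / "report.md").write_text(_render_markdown(config, manifest, dataset, table, lung_rows, scenarios))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _render_markdown(config, manifest, dataset, table, lung_rows, scenarios) -> str:
    lines = [
        "# NG-tube pH strip diagnostic accuracy report",
        "",
        f"- version: {manifest['version']}",
        f"- seed: {manifest['seed']}",
        f"- config hash: {manifest['config_hash']}",
        f"- source: {manifest['provenance']['source']}",
        f"- gastric n = {len(dataset.gastric)}, lung n = {len(dataset.lung)}",
        "",
        "## Sensitivity by cut-off",
        "",
        "| cut-off | standard | novel | difference | McNemar p |",
        "|---|---|---|---|---|",
    ]
    for r in table.rows:
        lines.append(
            f"| {r.cutoff:g} | {r.standard.display()} | {r.novel.display()} "
            f"| {r.comparison.difference * 100:.1f}% "
            f"({r.comparison.diff_ci_low * 100:.1f}%, {r.comparison.diff_ci_high * 100:.1f}%) "
            f"| {r.comparison.mcnemar_p:.2g} |"
        )
    if lung_rows:
        lines += ["", "## Lung specificity (novel strip)", ""]
        for row in lung_rows:
            lines.append(
                f"- cut-off {row['cutoff']:g}: {row['specificity'] * 100:.1f}% "
                f"({row['k']}/{row['n']})"
            )
    lines += ["", "## Decision model (per 1000 eligible patient checks)", ""]
    for name, res in scenarios.items():
        lines.append(
            f"- {name}: CXRs {res.cxr_standard:.0f} (standard) vs {res.cxr_novel:.0f} "
            f"(novel); {res.cxr_saved:.0f} avoided; "
            f"£{res.cost_saved_nominal:.0f} nominal, £{res.cost_saved_inflated:.0f} inflated"
        )
    lines.append("")
    return "\n".join(lines)
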