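"""End-to-end study pipeline: simulate → metrics → mechanics → stats.

A run is fully determined by a :class:`RunConfig` and a master seed; the
run directory contains every stage's CSV outputs, a log, and a manifest
recording the package version, the config hash and the seed, so any output
is regenerable from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import (
    DEFAULT_CUTOFF_MM,
    DEFAULT_THRESHOLD_FRACTION,
    compute_msv,
    compute_xv_metrics,
)
from .stats import correlate_with_tumor_count, fit_group_model, boxplot_summary
from .synth import CohortConfig, SimulatedAnimal, analyze_maneuver_battery, iter_cohort

__all__ = [
    "RunConfig",
    "build_study_table",
    "run_pipeline",
    "XV_PARAMETERS",
    "MECHANICS_PARAMETERS",
]

logger = logging.getLogger("xvlung")

XV_PARAMETERS = ["msv", "vt_ml", "vdp_pct", "nvdp_pct", "vh", "vh_ss", "vh_ls", "mean_ct_gray"]
MECHANICS_PARAMETERS = [
    "ic", "rrs", "crs", "rn", "g", "h", "cst", "k_curvature", "pv_area",
    "fev005", "fvc", "fef005",
]


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    cutoff_mm: float = DEFAULT_CUTOFF_MM
    reference_policy: str = "control_mean"   # or "own"
    adjustment: str = "tukey"
    zero_count_policy: str = "exclude"
    run_metrics: bool = True
    run_mechanics: bool = True
    run_stats: bool = True

    def __post_init__(self) -> None:
        if self.reference_policy not in ("control_mean", "own"):
            raise ValueError("reference_policy must be 'control_mean' or 'own'")
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.cutoff_mm <= 0:
            raise ValueError("cutoff_mm must be > 0")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True, indent=2)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def build_study_table(
    config: RunConfig,
    seed: int = 0,
    animals: list[SimulatedAnimal] | None = None,
) -> pd.DataFrame:
    """Simulate (or accept) a cohort and compute all per-animal parameters.

    Returns one row per animal joining ground truth, the XV metric panel
    and the CoD-gated mechanics aggregate. nVDP uses the mean MSV of the
    control group as reference when ``reference_policy == 'control_mean'``.
    """
    if animals is None:
        animals = list(iter_cohort(config.cohort, seed))

    reference_msv = None
    if config.run_metrics and config.reference_policy == "control_mean":
        control_msvs = [
            compute_msv(a.series, a.series.mask) for a in animals if a.group == "control"
        ]
        if control_msvs:
            reference_msv = float(np.mean(control_msvs))

    rows = []
    for animal in animals:
        row = animal.truth_row()
        if config.run_metrics:
            xv = compute_xv_metrics(
                animal.series,
                animal.ct,
                threshold_fraction=config.threshold_fraction,
                cutoff_mm=config.cutoff_mm,
                reference_msv=reference_msv,
            )
            row.update(xv.as_dict())
        if config.run_mechanics:
            if animal.replicates is not None:
                row.update(analyze_maneuver_battery(animal.replicates).as_dict())
            else:
                row.update({p: math.nan for p in MECHANICS_PARAMETERS})
        rows.append(row)
    return pd.DataFrame(rows)


def _stats_outputs(table: pd.DataFrame, config: RunConfig):
    parameters = [
        p
        for p in XV_PARAMETERS + MECHANICS_PARAMETERS
        if p in table.columns and table[p].notna().any()
    ]
    comparison_rows, correlation_rows, summary_rows = [], [], []
    for p in parameters:
        try:
            comp = fit_group_model(table, p, adjustment=config.adjustment)
            comparison_rows.extend(comp.to_rows())
        except ValueError as exc:
            logger.warning("group model skipped for %s: %s", p, exc)
        try:
            corr = correlate_with_tumor_count(
                table, p, zero_count_policy=config.zero_count_policy
            )
            correlation_rows.append(
                {"parameter": p, "r": corr.pearson_r, "p": corr.p_value, "n": corr.n_pairs}
            )
        except (ValueError, KeyError) as exc:
            logger.warning("correlation skipped for %s: %s", p, exc)
        for group, sub in table.groupby("group", observed=True):
            vals = pd.to_numeric(sub[p], errors="coerce").dropna()
            if len(vals):
                s = boxplot_summary(vals.to_numpy())
                summary_rows.append(
                    {
                        "parameter": p,
                        "group": group,
                        "median": s["median"],
                        "q1": s["q1"],
                        "q3": s["q3"],
                        "whisker_lo": s["whisker_lo"],
                        "whisker_hi": s["whisker_hi"],
                        "n_outliers": len(s["outliers"]),
                    }
                )
    return (
        pd.DataFrame(
            comparison_rows,
            columns=["parameter", "kind", "group", "estimate", "ci_lo", "ci_hi", "p_adj", "method"],
        ),
        pd.DataFrame(correlation_rows, columns=["parameter", "r", "p", "n"]),
        pd.DataFrame(
            summary_rows,
            columns=["parameter", "group", "median", "q1", "q3", "whisker_lo", "whisker_hi", "n_outliers"],
        ),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    seed: int,
    out_dir: str | Path,
    overwrite: bool = False,
    write_volumes: bool = False,
) -> dict[str, object]:
    """Execute the full study and write all outputs under ``out_dir``.

    Re-running with the same (config, seed) reproduces identical tables. A
    partially populated output directory is refused unless
    ``overwrite=True``. ``write_volumes`` additionally exports every
    animal's NIfTI volumes and trace CSVs (slower, larger).
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out_dir} is not empty; pass overwrite=True to replace it"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("run start: seed=%d config_hash=%s", seed, config.config_hash())
        animals = list(iter_cohort(config.cohort, seed))
        truth = pd.DataFrame([a.truth_row() for a in animals])
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
        if write_volumes:
            from .synth import _write_animal

            for animal in animals:
                _write_animal(animal, out_dir / "animals" / animal.animal_id)
        table = build_study_table(config, seed, animals=animals)
        table.to_csv(out_dir / "study_table.csv", index=False)
        logger.info("study table: %d animals, %d columns", *table.shape)

        outputs = {"ground_truth.csv": truth, "study_table.csv": table}
        if config.run_stats:
            comparisons, correlations, summaries = _stats_outputs(table, config)
            comparisons.to_csv(out_dir / "comparisons.csv", index=False)
            correlations.to_csv(out_dir / "correlations.csv", index=False)
            summaries.to_csv(out_dir / "summaries.csv", index=False)
            outputs.update(
                {
                    "comparisons.csv": comparisons,
                    "correlations.csv": correlations,
                    "summaries.csv": summaries,
                }
            )

        manifest = {
            "package": "xvlung",
            "version": __version__,
            "seed": int(seed),
            "config_hash": config.config_hash(),
            "config": json.loads(config.to_json()),
            "outputs": {
                name: _sha256(out_dir / name) for name in outputs if (out_dir / name).exists()
            },
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        logger.info("run complete: %s", ", ".join(outputs))
        return {"out_dir": out_dir, "manifest": manifest, **outputs}
    finally:
        logger.removeHandler(handler)
        handler.close()
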