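"""End-to-end pipeline: simulate -> preprocess/fit -> label -> correlate ->
aggregate -> report, with a manifest for reproducibility.

Every stage writes its CSV output into the run directory; the manifest
records the configuration, seed, per-file row counts and SHA-256 checksums,
so a rerun with the same configuration and seed can be verified byte for
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aggregation, correlation, cosinor, productivity, synthetic
from .series import HourlySeries, read_streams, write_streams

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable analysis constants in one place.

    survey_weeks, periods, the productivity threshold (weekly mean >= 2 is a
    high week), the <20% missing-data retention rule, the >28-observation
    cell filter, the cell significance level alpha and the significance-score
    cap are each configurable here and nowhere else.
    """

    survey_weeks: tuple[int, ...] = (1, 6, 15)
    periods: tuple[float, ...] = (8.0, 12.0, 24.0)
    productivity_threshold: float = 2.0
    max_missing: float = 0.20
    min_n: int = 28
    alpha: float = 0.05
    s_cap: float = 16.0
    top_k: int = 10
    aggregation_method: str = "hierarchical"
    window_radius: int = 1
    seed: int = 0
    simulation: synthetic.SimulationConfig | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0 < self.max_missing <= 1:
            raise ValueError("max_missing must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_n < 2:
            raise ValueError("min_n must be >= 2")

    def with_simulation(self, **overrides) -> "PipelineConfig":
        sim = synthetic.SimulationConfig(
            survey_weeks=self.survey_weeks, seed=self.seed, **overrides
        )
        return dataclasses.replace(self, simulation=sim)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            out["simulation"] = _jsonable(dataclasses.asdict(self.simulation))
        return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path, manifest: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    manifest["files"][path.name] = {"rows": int(len(frame)), "sha256": _sha256(path)}


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    streams: list[HourlySeries] | None = None,
    scores: pd.DataFrame | None = None,
    make_plots: bool = False,
) -> dict:
    """Run every stage and return the manifest.

    Either pass preloaded ``streams`` and daily ``scores`` or set
    ``config.simulation`` to generate a synthetic cohort.  Failures abort
    with the failing stage named; output written so far is retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _jsonable(config.to_dict()),
        "seed": config.seed,
        "files": {},
        "stages": {},
    }

    stage = "simulate"
    try:
        if streams is None or scores is None:
            if config.simulation is None:
                raise ValueError("no input data and no simulation configured")
            cohort = synthetic.simulate_cohort(config.simulation)
            streams = cohort.streams
            scores = cohort.productivity
            cohort.write(out / "simulate")
            for name in ("streams.csv", "productivity.csv"):
                path = out / "simulate" / name
                manifest["files"][name] = {"sha256": _sha256(path)}
        manifest["stages"]["simulate"] = {
            "n_streams": len(streams),
            "n_score_records": int(len(scores)),
        }

        stage = "label"
        labels = productivity.label_table(
            scores, config.survey_weeks, config.productivity_threshold
        )
        groups = productivity.group_table(labels, config.survey_weeks)
        _write(labels, out / "week_labels.csv", manifest)
        _write(groups, out / "groups.csv", manifest)
        manifest["stages"]["label"] = {
            "n_week_labels": int(len(labels)),
            "n_high_group": int((groups["group"] == "high").sum()) if len(groups) else 0,
        }

        stage = "fit"
        fits, discard_log = cosinor.window_fits(
            streams,
            survey_weeks=config.survey_weeks,
            periods=config.periods,
            window_radius=config.window_radius,
            max_missing=config.max_missing,
        )
        rhythms = cosinor.fits_to_frame(fits)
        _write(rhythms, out / "rhythms.csv", manifest)
        _write(discard_log, out / "discard_log.csv", manifest)
        manifest["stages"]["fit"] = {
            "n_fits": len(fits),
            "n_discarded": int((discard_log["decision"] != "fitted").sum()),
        }

        stage = "correlate"
        cells, excluded = correlation.correlation_table(rhythms, labels, config.min_n)
        cells_frame = correlation.cells_to_frame(cells)
        _write(cells_frame, out / "cells.csv", manifest)
        _write(excluded, out / "excluded_cells.csv", manifest)
        manifest["stages"]["correlate"] = {
            "n_cells": len(cells),
            "n_excluded": int(len(excluded)),
        }

        stage = "aggregate"
        agg = aggregation.aggregate_all(
            cells_frame,
            alpha=config.alpha,
            s_cap=config.s_cap,
            method=config.aggregation_method,
        )
        _write(agg, out / "scores.csv", manifest)
        for axis in ("feature", "parameter"):
            for value in ("C", "S"):
                matrix = aggregation.score_matrix(agg, axis, value)
                matrix.to_csv(out / f"{axis}_{value}_matrix.csv")
                manifest["files"][f"{axis}_{value}_matrix.csv"] = {
                    "rows": int(len(matrix)),
                    "sha256": _sha256(out / f"{axis}_{value}_matrix.csv"),
                }
                if make_plots:
                    _save_heatmap(matrix, out / f"{axis}_{value}_matrix.png", value)

        stage = "report"
        rankings = aggregation.rank_report(agg, top_k=config.top_k)
        for name, table in rankings.items():
            _write(table, out / f"top_{name}.csv", manifest)
        manifest["stages"]["aggregate"] = {"n_scores": int(len(agg))}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _save_heatmap(matrix: pd.DataFrame, path: Path, value: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * matrix.shape[1], 1 + 0.3 * matrix.shape[0])
    )
    cmap = "coolwarm_r" if value == "C" else "Greens"
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap=cmap)
    ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns])
    ax.set_yticks(range(matrix.shape[0]), [str(i) for i in matrix.index])
    fig.colorbar(im, ax=ax, label=value)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def load_inputs(stream_csv, productivity_csv):
    """Read the stream and productivity CSV schemas written by the simulator."""
    return read_streams(stream_csv), pd.read_csv(productivity_csv)
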