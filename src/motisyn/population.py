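"""Condition-level aggregation and pipeline orchestration.

Aggregates per-track classifications into walk-type fractions and motility
distributions, produces origin-aligned (windrose) coordinates, and runs the
full read -> filter -> stats -> MSD -> classify -> summarize pipeline.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, PipelineError
from .msd_models import (
    SELECTION_MODELS,
    classify_track,
    compute_msd,
    derive_motility,
    fit_power_law,
    truncate_for_fit,
)
from .track_io import (
    TrackCollection,
    TrackFilterConfig,
    apply_track_filters,
    read_trackmate_xml,
    read_tracks_csv,
    write_tracks_csv,
)
from .track_stats import stats_table, summarize_track

logger = logging.getLogger(__name__)

MODEL_CATEGORIES = ("constrained", "brownian", "prw", "unclassified")


@dataclass
class PopulationSummary:
    """Walk-type fractions and motility statistic distributions for one
    condition."""

    condition: str
    n_tracks: int
    model_fractions: dict
    stat_distributions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_tracks": self.n_tracks,
            "model_fractions": dict(self.model_fractions),
            "stat_distributions": {
                k: dict(v) for k, v in self.stat_distributions.items()
            },
        }


@dataclass
class WindroseData:
    """Origin-aligned track coordinates grouped by condition."""

    entries: list  # (condition, track_id, times, positions)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for condition, track_id, times, positions in self.entries:
            for t, (x, y) in zip(times, positions):
                rows.append(
                    {
                        "condition": condition,
                        "track_id": track_id,
                        "t_min": t,
                        "x_um": x,
                        "y_um": y,
                    }
                )
        return pd.DataFrame(
            rows, columns=["condition", "track_id", "t_min", "x_um", "y_um"]
        )


def _quartile_summary(values) -> dict:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)])
    if len(arr) == 0:
        return {"n": 0, "median": None, "q1": None, "q3": None}
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {"n": int(len(arr)), "median": float(med), "q1": float(q1), "q3": float(q3)}


def model_fractions(
    classifications, condition: str = "all", step_stats=None
) -> PopulationSummary:
    """Fraction of tracks per walk type, plus median/IQR motility summaries.

    ``step_stats`` (optional list of StepStats) adds a speed distribution.
    Fractions sum to 1 over {constrained, brownian, prw, unclassified}.
    """
    classifications = list(classifications)
    if not classifications:
        raise DegenerateInputError("no classifications to summarize")
    n = len(classifications)
    counts = {c: 0 for c in MODEL_CATEGORIES}
    for cls in classifications:
        counts[cls.best_model if cls.best_model in counts else "unclassified"] += 1
    if counts["unclassified"] == n:
        logger.warning("condition %s: every track is unclassified", condition)
    fractions = {c: counts[c] / n for c in MODEL_CATEGORIES}

    motility = [derive_motility(c) for c in classifications]
    distributions = {
        "rmc": _quartile_summary(m.rmc for m in motility),
        "effective_coefficient": _quartile_summary(
            m.effective_coefficient for m in motility
        ),
        "persistence_speed": _quartile_summary(
            c.persistence_speed for c in classifications
        ),
        "persistence_time": _quartile_summary(
            c.persistence_time for c in classifications
        ),
    }
    if step_stats is not None:
        distributions["median_speed"] = _quartile_summary(
            s.median_speed for s in step_stats
        )
    return PopulationSummary(
        condition=condition,
        n_tracks=n,
        model_fractions=fractions,
        stat_distributions=distributions,
    )


def windrose(collection: TrackCollection) -> WindroseData:
    """Translate every track so it starts at the origin (no rotation)."""
    entries = []
    for track in collection:
        entries.append(
            (
                track.condition,
                track.track_id,
                track.times.copy(),
                track.positions - track.positions[0],
            )
        )
    return WindroseData(entries=entries)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG = {
    "input": None,  # path to tracks CSV or TrackMate XML
    "format": "csv",  # "csv" | "trackmate"
    "frame_interval": None,
    "condition": None,  # override per-track condition label
    "filters": {},  # TrackFilterConfig keyword overrides
    "msd_max_lag_fraction": 1.0,
    "fit_fraction": 0.4,
    "powerlaw": True,
    "outdir": None,
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        import tomllib

        with open(config, "rb") as fh:
            config = tomllib.load(fh)
    merged = {**DEFAULT_PIPELINE_CONFIG, **dict(config)}
    if merged["input"] is None or merged["outdir"] is None:
        raise PipelineError("config", "config must set 'input' and 'outdir'")
    return merged


def run_motility_pipeline(config) -> dict:
    """Run the full track-motility pipeline from a config dict or TOML path.

    Writes per-track CSVs, a condition-level summary JSON, windrose
    coordinates, and a run log (config hash, package versions, filter
    report).  Any stage failure removes partial outputs and raises a
    stage-tagged :class:`PipelineError`.  Deterministic: identical inputs and
    config yield byte-identical summaries.
    """
    cfg = _load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    try:
        # --- read ---------------------------------------------------------
        stage = "read"
        if cfg["format"] == "trackmate":
            collection = read_trackmate_xml(
                cfg["input"], frame_interval=cfg["frame_interval"]
            )
        elif cfg["format"] == "csv":
            collection = read_tracks_csv(
                cfg["input"], frame_interval=cfg["frame_interval"]
            )
        else:
            raise PipelineError("read", f"unknown input format {cfg['format']!r}")
        if cfg["condition"]:
            from dataclasses import replace

            collection = TrackCollection(
                tracks=[replace(t, condition=cfg["condition"]) for t in collection],
                metadata=dict(collection.metadata),
            )

        # --- filter -------------------------------------------------------
        stage = "filter"
        filter_config = TrackFilterConfig(**cfg["filters"])
        result = apply_track_filters(collection, filter_config)
        filtered = result.collection
        _emit("tracks_filtered.csv", lambda p: write_tracks_csv(filtered, p))

        # --- stats --------------------------------------------------------
        stage = "stats"
        stats = stats_table(filtered)
        _emit("step_stats.csv", lambda p: stats.to_csv(p, index=False))

        # --- msd ----------------------------------------------------------
        stage = "msd"
        curves = [
            truncate_for_fit(
                compute_msd(t, max_lag_fraction=cfg["msd_max_lag_fraction"]),
                fraction=cfg["fit_fraction"],
            )
            for t in filtered
        ]
        msd_rows = []
        for c in curves:
            for lag, m, np_ in zip(c.lags, c.msd, c.n_pairs):
                msd_rows.append(
                    {"track_id": c.track_id, "lag_min": lag, "msd_um2": m, "n_pairs": np_}
                )
        msd_df = pd.DataFrame(
            msd_rows, columns=["track_id", "lag_min", "msd_um2", "n_pairs"]
        )
        _emit("msd_curves.csv", lambda p: msd_df.to_csv(p, index=False))

        # --- classify -----------------------------------------------------
        stage = "classify"
        classifications = [classify_track(c) for c in curves]
        power_fits = (
            {c.track_id: fit_power_law(c) for c in curves} if cfg["powerlaw"] else {}
        )
        cls_rows = []
        for cls in classifications:
            motility = derive_motility(cls)
            row = {
                "track_id": cls.track_id,
                "best_model": cls.best_model,
                "rmc": motility.rmc,
                "effective_coefficient": motility.effective_coefficient,
                "persistence_speed": cls.persistence_speed,
                "persistence_time": cls.persistence_time,
            }
            for name in SELECTION_MODELS:
                fit = cls.fits.get(name)
                row[f"aicc_{name}"] = fit.aicc if fit else math.nan
                if fit:
                    for pname, pval in fit.params.items():
                        row[f"{name}_{pname}"] = pval
            pw = power_fits.get(cls.track_id)
            if pw is not None and pw.converged:
                row["powerlaw_A"] = pw.params.get("A")
                row["powerlaw_alpha"] = pw.params.get("alpha")
            cls_rows.append(row)
        cls_df = pd.DataFrame(cls_rows)
        _emit("classifications.csv", lambda p: cls_df.to_csv(p, index=False))

        # --- summarize ----------------------------------------------------
        stage = "summarize"
        by_condition: dict[str, list] = {}
        track_condition = {t.track_id: t.condition or "all" for t in filtered}
        for cls in classifications:
            by_condition.setdefault(track_condition.get(cls.track_id, "all"), []).append(
                cls
            )
        step_by_condition: dict[str, list] = {}
        for t in filtered:
            step_by_condition.setdefault(t.condition or "all", []).append(
                summarize_track(t)
            )
        summary = {
            cond: model_fractions(
                cls_list, condition=cond, step_stats=step_by_condition.get(cond)
            ).to_dict()
            for cond, cls_list in sorted(by_condition.items())
        }
        _emit(
            "summary.json",
            lambda p: p.write_text(json.dumps(summary, indent=2, sort_keys=True)),
        )
        wind_df = windrose(filtered).to_dataframe()
        _emit("windrose.csv", lambda p: wind_df.to_csv(p, index=False))

        # --- log ----------------------------------------------------------
        stage = "log"
        import scipy

        from . import __version__

        log = {
            "config": {k: v for k, v in cfg.items()},
            "config_sha256": hashlib.sha256(
                json.dumps(
                    {k: str(v) for k, v in cfg.items()}, sort_keys=True
                ).encode()
            ).hexdigest(),
            "versions": {
                "motisyn": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
            "filter_report": result.report,
        }
        _emit(
            "run_log.json",
            lambda p: p.write_text(json.dumps(log, indent=2, sort_keys=True, default=str)),
        )
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as exc:
        _cleanup(written)
        raise PipelineError(stage, str(exc)) from exc

    return {
        "outdir": str(outdir),
        "n_tracks": len(filtered),
        "summary": summary,
        "filter_report": result.report,
    }


def _cleanup(paths) -> None:
    for p in paths:
        try:
            Path(p).unlink(missing_ok=True)
        except OSError:  # pragma: no cover
            pass
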