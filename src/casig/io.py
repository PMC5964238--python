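"""Readers/writers, run configuration and the end-to-end pipeline.

Track tables are comma-separated UTF-8 CSV with a header row; times in
seconds, positions in um, frames 0-based. Column aliases cover MTrackJ
exports (``TID``/``PID``/pixel coordinates, converted via a pixel size).
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierParams, classify_signature_rule, signature_frequencies
from .features import (compute_baseline, features_table, filter_tracks,
                       match_controls)
from .multivariate import run_lda, run_pca, scale_features
from .ratio import compute_ratio_stack, extract_trace, read_stack, render_display
from .sim import SimConfig, render_timelapse, simulate_tracks, write_channel_tiff

__all__ = ["read_tracks", "write_tracks", "RunConfig", "PipelineError",
           "run_pipeline", "MTRACKJ_ALIASES"]

REQUIRED_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]

#: Column aliases accepted on read (MTrackJ-style exports included).
MTRACKJ_ALIASES = {
    "TID": "track_id", "tid": "track_id",
    "PID": "frame", "pid": "frame", "frame_idx": "frame",
    "t [sec]": "t_s", "t_sec": "t_s", "time_s": "t_s",
    "x [um]": "x_um", "y [um]": "y_um",
    "x [pixel]": "x_px", "y [pixel]": "y_px",
    "x_pixel": "x_px", "y_pixel": "y_px",
}


def read_tracks(path, pixel_size_um: float | None = None,
                aliases: dict | None = None) -> pd.DataFrame:
    """Read a track CSV, normalising column names.

    Pixel-coordinate exports (``x_px``/``y_px`` after aliasing) are
    converted to um with ``pixel_size_um``. Missing required columns raise
    a schema error naming the first offender.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    amap = dict(MTRACKJ_ALIASES)
    if aliases:
        amap.update(aliases)
    df = df.rename(columns={c: amap[c] for c in df.columns if c in amap})
    if "x_um" not in df.columns and "x_px" in df.columns:
        if pixel_size_um is None:
            raise ValueError("pixel coordinates need pixel_size_um to convert to um")
        df["x_um"] = df["x_px"] * pixel_size_um
        df["y_um"] = df["y_px"] * pixel_size_um
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"track table is missing required column {col!r}")
    return df


def write_tracks(tracks: pd.DataFrame, path) -> None:
    """Write a track table as CSV at full float precision (round-trip exact)."""
    tracks.to_csv(path, index=False)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """End-to-end run configuration.

    Either ``simulate`` is on (the generator produces tracks and movies) or
    ``tracks_path``/``ch340_path``/``ch380_path`` point to existing inputs.
    """

    output_dir: str = "casig_run"
    seed: int = 0
    simulate: bool = True
    render_movie: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    tracks_path: str | None = None
    ch340_path: str | None = None
    ch380_path: str | None = None
    roi_diameter_px: float = 20.0
    bg_threshold: float = 0.0
    clip_lo: float = 0.5
    clip_hi: float = 2.0
    min_duration_s: float = 300.0
    condition: str = "+sAgs"

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("sim", "classifier")}
        d["sim"] = self.sim.to_dict()
        d["classifier"] = self.classifier.__dict__.copy()
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "classifier" in d:
            d["classifier"] = ClassifierParams(**d["classifier"])
        return cls(**d)

    def parameter_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(manifest: dict, name: str, outputs: list) -> None:
    manifest["stages"].append({"name": name, "outputs": [str(p) for p in outputs]})


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate (optional) -> ratio -> extract -> features -> classify
    -> match -> mva, writing every stage output plus a JSON manifest.

    Returns the manifest dict. A stage failure raises
    :class:`PipelineError`; outputs written by the failed stage are renamed
    with a ``.partial`` suffix.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "casig", "version": __version__,
                "python": sys.version.split()[0], "seed": config.seed,
                "parameter_hash": config.parameter_hash(), "stages": []}
    stage_files: list = []

    def run_stage(name, fn):
        stage_files.clear()
        try:
            result = fn()
        except Exception as exc:
            for f in stage_files:
                f = Path(f)
                if f.exists():
                    f.rename(f.with_name(f.name + ".partial"))
            raise PipelineError(name, exc) from exc
        _stage(manifest, name, stage_files)
        return result

    # -- inputs --------------------------------------------------------
    if config.simulate:
        def do_sim():
            cfg = config.sim
            cfg.seed = config.seed
            tracks, gt = simulate_tracks(cfg)
            stage_files.append(out / "tracks.csv")
            write_tracks(tracks, out / "tracks.csv")
            stage_files.append(out / "ground_truth_cells.csv")
            gt.cells.to_csv(out / "ground_truth_cells.csv", index=False)
            cfg.to_yaml(out / "sim_config.yaml")
            stage_files.append(out / "sim_config.yaml")
            if config.render_movie:
                ch340, ch380 = render_timelapse(gt, cfg)
                for name, arr in (("ch340.tif", ch340), ("ch380.tif", ch380)):
                    stage_files.append(out / name)
                    write_channel_tiff(arr, out / name)
            return tracks, gt
        tracks, gt = run_stage("simulate", do_sim)
        ch340_path = out / "ch340.tif" if config.render_movie else None
        ch380_path = out / "ch380.tif" if config.render_movie else None
        pixel_size = config.sim.pixel_size_um
        frame_interval = config.sim.frame_interval_s
    else:
        tracks = read_tracks(config.tracks_path)
        ch340_path, ch380_path = config.ch340_path, config.ch380_path
        pixel_size = config.sim.pixel_size_um
        frame_interval = config.sim.frame_interval_s

    # -- ratio + extraction -------------------------------------------
    if ch340_path is not None:
        def do_ratio():
            stack = compute_ratio_stack(read_stack(ch340_path), read_stack(ch380_path),
                                        clip_lo=config.clip_lo, clip_hi=config.clip_hi,
                                        bg_threshold=config.bg_threshold,
                                        pixel_size_um=pixel_size,
                                        frame_interval_s=frame_interval)
            display, _ = render_display(stack, lut_name=None)
            stage_files.append(out / "ratio_display.tif")
            write_channel_tiff(display, out / "ratio_display.tif")
            return stack
        stack = run_stage("ratio", do_ratio)

        def do_extract():
            pieces = []
            for tid, g in tracks.groupby("track_id"):
                tr = extract_trace(stack, g, roi_diameter_px=config.roi_diameter_px)
                pieces.append(tr)
            traces = pd.concat(pieces, ignore_index=True)
            traces = traces.dropna(subset=["ratio"])
            stage_files.append(out / "traces.csv")
            write_tracks(traces, out / "traces.csv")
            return traces
        measured = run_stage("extract", do_extract)
    else:
        def do_passthrough():
            if "ratio" not in tracks.columns:
                raise ValueError("no movie and no ratio column in the track table")
            stage_files.append(out / "traces.csv")
            write_tracks(tracks, out / "traces.csv")
            return tracks
        measured = run_stage("extract", do_passthrough)

    # -- features ------------------------------------------------------
    def do_features():
        kept, _ = filter_tracks(measured, min_duration_s=config.min_duration_s)
        baseline = compute_baseline(kept)
        feats = features_table(kept, baseline)
        stage_files.append(out / "features.csv")
        feats.to_csv(out / "features.csv", index=False)
        return kept, baseline, feats
    kept, baseline, feats = run_stage("features", do_features)

    # -- classification ------------------------------------------------
    def do_classify():
        rows = []
        for tid, g in kept.sort_values(["track_id", "frame"]).groupby("track_id"):
            label, rule = classify_signature_rule(g["ratio"].to_numpy(),
                                                  baseline.value, config.classifier)
            rows.append({"track_id": tid, "label": label, "rule_fired": rule})
        labels = pd.DataFrame(rows)
        stage_files.append(out / "labels.csv")
        labels.to_csv(out / "labels.csv", index=False)
        freq = signature_frequencies(labels["label"],
                                     [config.condition] * len(labels))
        stage_files.append(out / "frequencies.csv")
        freq.to_csv(out / "frequencies.csv")
        return labels
    labels = run_stage("classify", do_classify)

    # -- matching ------------------------------------------------------
    def do_match():
        thr = config.classifier.responder_threshold
        acute = feats[feats["max_ratio"] >= thr]
        basal = feats[feats["max_ratio"] <= thr]
        if acute.empty or basal.empty:
            pairing = pd.DataFrame(columns=["acute_id", "basal_id",
                                            "delta_t_max_s", "matched"])
        else:
            pairing = match_controls(acute, basal)
        stage_files.append(out / "matches.csv")
        pairing.to_csv(out / "matches.csv", index=False)
        return pairing
    run_stage("match", do_match)

    # -- multivariate --------------------------------------------------
    def do_mva():
        from .features import MEASURE_COLUMNS
        merged = feats.merge(labels, on="track_id")
        complete = merged.dropna(subset=MEASURE_COLUMNS)
        scaled = scale_features(complete[MEASURE_COLUMNS])
        pca = run_pca(scaled)
        files = {"mva_scores.csv": pca.scores, "mva_loadings.csv": pca.loadings}
        summary = {"pca_variance_explained_pct": pca.variance_explained_pct.tolist()}
        if complete["label"].nunique() >= 2 and complete["label"].value_counts().min() >= 2:
            lda = run_lda(scaled, complete["label"])
            files["mva_scalings.csv"] = lda.scalings
            files["mva_confusion.csv"] = lda.confusion
            summary["lda_overall_accuracy_pct"] = lda.overall_accuracy_pct
            summary["lda_class_accuracy_pct"] = lda.class_accuracy_pct.to_dict()
        for name, df in files.items():
            stage_files.append(out / name)
            df.to_csv(out / name)
        stage_files.append(out / "mva_summary.json")
        with open(out / "mva_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
    run_stage("mva", do_mva)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
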