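"""End-to-end pipeline orchestration with a config file and manifest.

Runs preprocess -> envelope -> annotate -> demodulate on a raw recording,
writing one CSV artifact per stage plus a JSON manifest with content
hashes, stage parameters and counts.  All stages are deterministic, so a
rerun with the same config produces byte-identical artifacts; stages can
be resumed from existing intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import demodulation as demod_mod
from . import envelope_features as env_mod
from . import preprocess as pre_mod
from .optics import OpticalConfig
from .preprocess import PreprocessConfig

__all__ = ["EnvelopeParams", "AnnotationParams", "PipelineConfig", "run_pipeline"]

STAGES = ("preprocess", "envelope", "annotate", "demodulate")


@dataclass(frozen=True)
class EnvelopeParams:
    trim_s: float = 0.5
    band_low_hz: float = 0.5
    band_high_hz: float = 10.0
    min_height: float = 0.3
    min_distance_s: float = 0.5
    epoch_pre_s: float = -0.2
    epoch_post_s: float = 1.0
    mean_smooth_cutoff_hz: float = 20.0
    drop_first: int = 0
    drop_last: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if self.min_distance_s <= 0:
            raise ValueError("min_distance_s must be > 0")
        if self.epoch_post_s <= self.epoch_pre_s:
            raise ValueError("epoch window must have post > pre")


@dataclass(frozen=True)
class AnnotationParams:
    prominence: float = 0.05
    search_radius_s: float = 0.15
    shallow_fraction: float = 0.1
    start_s: float | None = None
    end_s: float | None = None
    edits_json: str | None = None

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise ValueError("prominence must be > 0")
        if self.search_radius_s < 0:
            raise ValueError("search_radius_s must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    input_csv: str = "recording.csv"
    outdir: str = "."
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    envelope: EnvelopeParams = field(default_factory=EnvelopeParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("preprocess", PreprocessConfig),
            ("envelope", EnvelopeParams),
            ("annotation", AnnotationParams),
            ("optics", OpticalConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig, resume_from: str | None = None
) -> dict:
    """Run all stages, write artifacts, and return the manifest dict.

    ``resume_from`` names the first stage to recompute; earlier stages
    must have left their artifacts in ``outdir`` and are loaded from
    there.  Stage failures abort with the failing stage named; artifacts
    written before the failure are kept.
    """
    if resume_from is not None and resume_from not in STAGES:
        raise ValueError(f"resume_from must be one of {STAGES}")
    in_path = Path(config.input_csv)
    if resume_from is None and not in_path.is_file():
        raise FileNotFoundError(f"input file not found: {in_path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "preprocessed": outdir / "preprocessed.csv",
        "minima": outdir / "minima.csv",
        "annotations": outdir / "annotations.csv",
        "displacement": outdir / "displacement.csv",
    }
    resume_idx = STAGES.index(resume_from) if resume_from else 0
    manifest: dict = {"config": asdict(config), "stages": {}}

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # -- preprocess --------------------------------------------------------
    if resume_idx <= 0:
        try:
            pre = pre_mod.run_preprocess(
                pd.read_csv(in_path, float_precision="round_trip"), config.preprocess, out_path=paths["preprocessed"]
            )
        except Exception as exc:
            fail("preprocess", exc)
    else:
        pre = pre_mod.PreprocessedTrace.from_frame(
            pd.read_csv(paths["preprocessed"], float_precision="round_trip"), config.preprocess
        )
    manifest["stages"]["preprocess"] = {
        "n_samples": int(pre.time_s.size),
        "sampling_rate_hz": pre.sampling_rate_hz,
        "n_outliers_repaired": int(pre.outlier_indices.size),
    }

    # -- envelope ----------------------------------------------------------
    ep = config.envelope
    try:
        env = env_mod.compute_envelope(
            pre.time_s, pre.processed, trim_s=ep.trim_s,
            band=(ep.band_low_hz, ep.band_high_hz),
        )
        peaks = env_mod.detect_envelope_peaks(
            env, min_height=ep.min_height, min_distance_s=ep.min_distance_s
        )
        if resume_idx <= 1:
            avg = env_mod.epoch_average(
                env.time_s, env.envelope, peaks,
                window=(ep.epoch_pre_s, ep.epoch_post_s),
            )
            minima = env_mod.detect_epoch_minima(
                avg, peaks, smooth_cutoff_hz=ep.mean_smooth_cutoff_hz,
                drop_first=ep.drop_first, drop_last=ep.drop_last,
                out_path=paths["minima"],
            )
        else:
            minima = env_mod.MinimaCatalog.from_frame(pd.read_csv(paths["minima"], float_precision="round_trip"))
    except Exception as exc:
        fail("envelope", exc)
    manifest["stages"]["envelope"] = {
        "n_peaks": int(peaks.size),
        "n_minima": len(minima),
    }

    # -- annotate ----------------------------------------------------------
    ap = config.annotation
    try:
        if resume_idx <= 2:
            window = (
                ap.start_s if ap.start_s is not None else float(env.time_s[0]),
                ap.end_s if ap.end_s is not None else float(env.time_s[-1]),
            )
            annotations, warnings = ann_mod.build_annotations(
                pre.time_s, pre.processed, minima, window=window,
                prominence=ap.prominence, search_radius_s=ap.search_radius_s,
                shallow_fraction=ap.shallow_fraction, cycle_anchor_times=peaks,
            )
            if ap.edits_json:
                edits = ann_mod.load_edits(ap.edits_json)
                annotations = ann_mod.apply_edits(
                    annotations, edits, pre.time_s, pre.processed
                )
            annotations.write_csv(paths["annotations"])
        else:
            annotations = ann_mod.read_annotations_csv(paths["annotations"])
            warnings = []
    except Exception as exc:
        fail("annotate", exc)
    st = annotations.statuses()
    manifest["stages"]["annotate"] = {
        "n_points": len(st),
        "n_breakpoints": st.count("BP"),
        "warnings": list(warnings),
    }

    # -- demodulate --------------------------------------------------------
    try:
        displacement = demod_mod.demodulate(
            pre, annotations, config.optics, out_path=paths["displacement"]
        )
    except Exception as exc:
        fail("demodulate", exc)
    manifest["stages"]["demodulate"] = {
        "n_anchors": int(displacement.anchor_times_s.size),
        "span_s": [float(displacement.time_s[0]), float(displacement.time_s[-1])],
        "peak_delta_z_nm": float(np.max(displacement.delta_z_nm)),
    }

    manifest["artifacts"] = {
        name: {"path": str(p), "sha256": _sha256(p)} for name, p in paths.items()
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["manifest_path"] = str(manifest_path)
    return manifest
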