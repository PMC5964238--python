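"""Configuration for the synthetic time-lapse generator.

The defaults emulate the perfusion-chamber assay the package analyses:
10 s frame interval, ~20 min recordings, 470 x 470 um fields, ~107 T cells
over ~198 macrophages, and the four calcium-signature archetypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["TraceParams", "SimConfig", "DEFAULT_MIXTURE", "DEFAULT_MIXTURE_NO_SAG"]

#: Class mixture with superantigen: the majority of cells never signal
#: (63% flat); high-amplitude sustained signatures appear only here.
DEFAULT_MIXTURE = {"flat": 0.63, "transient": 0.15, "low": 0.12, "high": 0.10}

#: Class mixture without superantigen: more flat cells (72%), transients
#: predominate among responders, and no 'high' signatures at all.
DEFAULT_MIXTURE_NO_SAG = {"flat": 0.72, "transient": 0.20, "low": 0.08, "high": 0.0}


@dataclass
class TraceParams:
    """Per-class calcium trace templates (340:380 ratio units, seconds).

    A trace starts at ``baseline`` and, except for 'flat', rises at a random
    onset time. 'transient' peaks and decays back to baseline; 'low' rises to
    a sustained plateau below the 'high' criteria; 'high' peaks above 2 and
    settles to a sustained level well above 1.
    """

    baseline: float = 0.8
    baseline_jitter: float = 0.03
    noise_sd: float = 0.03
    level_jitter: float = 0.1
    onset_window_s: tuple = (60.0, 600.0)
    rise_time_s: float = 30.0
    transient_peak: float = 1.3
    transient_hold_s: float = 60.0
    transient_fall_s: float = 120.0
    low_level: float = 1.3
    high_peak: float = 2.2
    high_sustain_level: float = 1.6
    high_decay_s: float = 120.0


@dataclass
class SimConfig:
    """Assay-scale parameters for the synthetic generator.

    Lengths are um, times are seconds, speeds um/min. Cells are seeded on a
    jittered grid and each performs a persistent random walk confined near
    its seed point; this keeps measurement ROIs of different cells disjoint
    so rendered movies have unambiguous per-cell ground truth. On calcium
    onset, arresting cells keep their step speed but their confinement
    radius collapses to ``arrest_confine_um`` ("corralling": Euclidean
    displacement drops while path length and speed are preserved).
    """

    field_size_um: tuple = (470.0, 470.0)
    frame_interval_s: float = 10.0
    n_frames: int = 121
    n_tcells: int = 107
    n_mdms: int = 198
    class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    basal_speed_um_min: float = 10.0
    arrest_speed_um_min: float = 10.0
    persistence_kappa: float = 4.0
    pause_prob: float = 0.1
    pause_speed_max_um_min: float = 2.0
    enter_trim_max_s: float = 120.0
    exit_trim_max_s: float = 240.0
    dropout_prob: float = 0.05
    confine_um: float = 12.0
    arrest_confine_um: float = 2.5
    arrest_low_fraction: float = 0.5
    trace: TraceParams = field(default_factory=TraceParams)
    pixel_size_um: float = 1.0
    cell_sigma_um: float = 2.5
    blob_cutoff: float = 0.2
    peak_counts: float = 30000.0  # keeps E340 = B*2c/(1+c) under 16-bit full scale
    poisson_noise: bool = False
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture must sum to 1, got {total}")
        if any(p < 0 for p in self.class_mixture.values()):
            raise ValueError("mixture proportions must be non-negative")
        if self.n_tcells < 0 or self.n_mdms < 0 or self.n_frames < 0:
            raise ValueError("counts must be non-negative")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_size_um"] = list(self.field_size_um)
        d["trace"]["onset_window_s"] = list(self.trace.onset_window_s)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "trace" in d and isinstance(d["trace"], dict):
            tp = dict(d["trace"])
            if "onset_window_s" in tp:
                tp["onset_window_s"] = tuple(tp["onset_window_s"])
            d["trace"] = TraceParams(**tp)
        if "field_size_um" in d:
            d["field_size_um"] = tuple(d["field_size_um"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
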