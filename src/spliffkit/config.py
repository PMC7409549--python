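"""Configuration objects for the cleavage-reporter and FRAP simulators.

All time units are minutes for reporter kinetics and seconds for FRAP,
matching the acquisition conventions of the assay (time-lapse frames every
2/3/5 min; FRAP frames every 0.9 s). Intensity units are arbitrary
"mean gray value" units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

PHASES = ("PCDI", "PCDII", "PCDIII")
ALLOWED_SAMPLING_INTERVALS = (2.0, 3.0, 5.0)


class ValidationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class ReporterKineticsConfig:
    """Kinetic and measurement parameters of the mCherry-Cub-GFP reporter.

    The intact reporter U carries both fluorophores. Interaction-triggered
    cleavage converts U into a red-bearing fragment R_c (mCherry-Cub) and a
    free GFP moiety G_c that is rapidly degraded. Red signal is proportional
    to U + R_c, green to U + G_c.

    Parameters
    ----------
    synthesis_rate : float
        New intact reporter per minute after fusion. The default 0 models a
        promoter that is shut off during the measurement; continuing
        synthesis is supported by setting it > 0.
    cleavage_rate_on, cleavage_rate_off : float
        Per-minute cleavage rate constants while an interaction window is
        active / inactive (basal).
    gfp_degradation_rate : float
        Per-minute decay of the cleaved GFP moiety ("cleaved off and rapidly
        degraded"); 0.7/min gives a ~1 min half-life.
    reporter_degradation_rate : float
        Per-minute decay of both the intact reporter and the cleaved
        red-bearing fragment (mCherry is long-lived; default 0).
    initial_reporter : float
        Pre-fusion steady-state amount of intact reporter, in intensity
        units. Needed explicitly because the steady state synthesis/decay is
        undefined when the decay rate is 0.
    bleach_per_exposure_red, bleach_per_exposure_green : float
        Fractional signal loss per acquisition, applied as a cumulative
        multiplicative factor per channel.
    background_level : float
        Additive extracellular background, intensity units.
    noise_sd : float
        SD of additive Gaussian noise on each measured ROI mean (ROI,
        cytosol, background are each means over many pixels, so this is
        small relative to the signal).
    roi_fraction : float
        Fraction of the cell's total signal inside the polarity-site ROI;
        the remainder is cytosolic.
    """

    synthesis_rate: float = 0.0
    cleavage_rate_on: float = 0.03
    cleavage_rate_off: float = 0.0
    gfp_degradation_rate: float = 0.7
    reporter_degradation_rate: float = 0.0
    initial_reporter: float = 100.0
    bleach_per_exposure_red: float = 0.002
    bleach_per_exposure_green: float = 0.002
    background_level: float = 20.0
    noise_sd: float = 0.5
    roi_fraction: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "synthesis_rate",
            "cleavage_rate_on",
            "cleavage_rate_off",
            "gfp_degradation_rate",
            "reporter_degradation_rate",
            "initial_reporter",
            "background_level",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("bleach_per_exposure_red", "bleach_per_exposure_green"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if not 0.0 < self.roi_fraction <= 1.0:
            raise ValidationError(
                f"roi_fraction must be in (0, 1], got {self.roi_fraction}"
            )


@dataclass
class InteractionSchedule:
    """When the bait-prey interaction is active, relative to cell fusion.

    ``windows`` is a list of ``(start_min, end_min, phase_label)`` tuples
    (half-open intervals, sorted, non-overlapping, inside
    ``[0, total_duration]``) during which ``cleavage_rate_on`` applies.
    ``fusion_time`` is the pre-fusion observation span (minutes before
    t = 0 at which frames are already acquired).
    """

    windows: Sequence[tuple[float, float, str]] = field(default_factory=list)
    total_duration: float = 115.0
    sampling_interval: float = 2.0
    fusion_time: float = 6.0

    def __post_init__(self) -> None:
        if self.sampling_interval not in ALLOWED_SAMPLING_INTERVALS:
            raise ValidationError(
                f"sampling_interval must be one of {ALLOWED_SAMPLING_INTERVALS} min, "
                f"got {self.sampling_interval}"
            )
        if self.total_duration <= 0:
            raise ValidationError("total_duration must be > 0")
        if self.fusion_time < 0:
            raise ValidationError("fusion_time must be >= 0")
        self.windows = [tuple(w) for w in self.windows]
        prev_end = 0.0
        for start, end, phase in self.windows:
            if phase not in PHASES:
                raise ValidationError(f"unknown phase label {phase!r}")
            if start < prev_end or end <= start or end > self.total_duration:
                raise ValidationError(
                    "windows must be sorted, non-overlapping and within "
                    f"[0, total_duration]; offending window ({start}, {end})"
                )
            prev_end = end

    @property
    def n_prefusion_frames(self) -> int:
        return int(self.fusion_time // self.sampling_interval)

    def frame_times(self):
        """Acquisition times in minutes relative to fusion (t=0 is the first
        post-fusion frame); pre-fusion frames have negative times."""
        import numpy as np

        n_pre = self.n_prefusion_frames
        n_post = int(np.floor(self.total_duration / self.sampling_interval + 1e-9)) + 1
        return np.arange(-n_pre, n_post) * self.sampling_interval

    def cleavage_active(self, t: float) -> bool:
        return any(start <= t < end for start, end, _ in self.windows)

    def shifted(self, delta: float) -> "InteractionSchedule":
        """Schedule with all window boundaries shifted by ``delta`` minutes
        (clipped to the trace) — models cell-to-cell timing variability."""
        new = []
        for start, end, phase in self.windows:
            s = min(max(start + delta, 0.0), self.total_duration)
            e = min(max(end + delta, 0.0), self.total_duration)
            if e > s:
                new.append((s, e, phase))
        return InteractionSchedule(
            windows=new,
            total_duration=self.total_duration,
            sampling_interval=self.sampling_interval,
            fusion_time=self.fusion_time,
        )


@dataclass
class FrapSimConfig:
    """Parameters of a simulated FRAP experiment.

    Recovery follows a one-phase association: after an instantaneous bleach
    removing ``bleach_depth`` of the pre-bleach signal (0.9 by default — a
    full-laser-power bleach), the ROI recovers toward a plateau set by
    ``mobile_fraction`` with rate ``rate_k`` per second. Acquisition
    bleaching decays the reference (and ROI) signal by a constant fraction
    per frame; the double-normalization step corrects it.

    Measurement noise is shot-like: Gaussian with SD
    ``noise_sd * sqrt(signal / prebleach level)``, so nearly-dark
    post-bleach frames carry proportionally less absolute noise, as photon
    statistics dictate. The whole-cell reference averages a much larger
    region than the bleach spot; ``reference_noise_factor`` (default 0.1,
    i.e. a ~100x area ratio) scales its noise accordingly.
    """

    rate_k: float = 0.0786  # ln 2 / 8.82 s — cortex-exchange scale
    mobile_fraction: float = 0.85
    prebleach_frames: int = 4
    bleach_depth: float = 0.9
    frame_interval: float = 0.9
    n_frames: int = 120
    acquisition_bleach: float = 0.003
    noise_sd: float = 0.0
    reference_noise_factor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_k <= 0:
            raise ValidationError("rate_k must be > 0")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValidationError("bleach_depth must be in (0, 1]")
        if not 0.0 < self.mobile_fraction <= 1.0:
            raise ValidationError("mobile_fraction must be in (0, 1]")
        if self.prebleach_frames < 1:
            raise ValidationError("prebleach_frames must be >= 1")
        if self.frame_interval <= 0 or self.n_frames <= self.prebleach_frames:
            raise ValidationError("need positive frame_interval and post-bleach frames")
        if not 0.0 <= self.acquisition_bleach < 1.0:
            raise ValidationError("acquisition_bleach must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.reference_noise_factor < 0:
            raise ValidationError("reference_noise_factor must be >= 0")


def to_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"type": type(obj).__name__, "params": asdict(obj)}, fh)


def from_yaml(path):
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    cls = {
        "ReporterKineticsConfig": ReporterKineticsConfig,
        "InteractionSchedule": InteractionSchedule,
        "FrapSimConfig": FrapSimConfig,
    }[payload["type"]]
    params = payload["params"]
    if cls is InteractionSchedule:
        params["windows"] = [tuple(w) for w in params.get("windows", [])]
    return cls(**params)
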