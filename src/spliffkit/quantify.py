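"""From raw ROI intensities to the FD(t) conversion statistic.

Two background-handling conventions are exposed:

* ``relative_intensity`` — the comparative-localization ratio
  (I_fluorescence − I_background) / (I_cytosol − I_background), used when
  comparing a protein's enrichment across strains;
* ``localized_intensity`` — the SPLIFF path: the intracellular (cytosolic)
  background is subtracted from the localized signal, FI = I_fluorescence −
  I_cytosol, per channel.

The SPLIFF pipeline then normalizes FI per channel to the last pre-fusion
timepoint (RFI) and computes the conversion

    FD(t) = 100 · (RFI_red − RFI_green) / RFI_red   [percent]

which is 0 at the reference frame by construction, gain-invariant under any
common rescaling of both channels, and offset-invariant in the ratio path.
Values ≥ 80% carry an interpretability-caveat flag: once most reporter is
converted there is little uncleaved substrate left to report further
interaction.
"""

from __future__ import annotations

import numbers
from typing import Mapping

import numpy as np
import pandas as pd

from .config import PHASES, ValidationError

#: schema of the long-format measurement table
MEASUREMENT_COLUMNS = [
    "cell_id",
    "time_min",
    "channel",
    "roi",
    "cytosol",
    "background",
    "prefusion_flag",
]

CONVERSION_COLUMNS = [
    "cell_id",
    "time_min",
    "rfi_red",
    "rfi_green",
    "fd_percent",
    "phase",
    "flag_negative",
    "flag_caveat",
    "flag_invalid",
]

DEFAULT_CAVEAT_THRESHOLD = 80.0
DEFAULT_DENOMINATOR_FLOOR = 1e-9


def relative_intensity(i_fluorescence, i_cytosol, i_background,
                       floor: float = DEFAULT_DENOMINATOR_FLOOR):
    """(I_f − I_b) / (I_c − I_b); NaN (flagged invalid) where the
    denominator magnitude is below ``floor``. Accepts scalars or arrays."""
    f = np.asarray(i_fluorescence, dtype=float)
    c = np.asarray(i_cytosol, dtype=float)
    b = np.asarray(i_background, dtype=float)
    denom = c - b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(denom) >= floor, (f - b) / denom, np.nan)
    if all(isinstance(x, numbers.Number) for x in (i_fluorescence, i_cytosol, i_background)):
        return float(out)
    return out


def localized_intensity(i_fluorescence, i_cytosol):
    """FI = I_fluorescence − I_cytosol (intracellular-background subtraction).

    Negative values are retained (they are flagged downstream, not raised)."""
    f = np.asarray(i_fluorescence, dtype=float)
    c = np.asarray(i_cytosol, dtype=float)
    out = f - c
    if isinstance(i_fluorescence, numbers.Number) and isinstance(i_cytosol, numbers.Number):
        return float(out)
    return out


def conversion(rfi_red, rfi_green):
    """FD = 100 · (RFI_red − RFI_green)/RFI_red, percent.

    NaN where RFI_red ≤ 0 (invalid timepoint); out-of-range values are
    returned as-is so the caller can flag rather than clip them."""
    r = np.asarray(rfi_red, dtype=float)
    g = np.asarray(rfi_green, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(r > 0, 100.0 * (r - g) / r, np.nan)
    if isinstance(rfi_red, numbers.Number) and isinstance(rfi_green, numbers.Number):
        return float(out)
    return out


def normalize_to_prefusion(fi: pd.Series, prefusion_flag: pd.Series,
                           reference_frames: int = 1) -> pd.Series:
    """RFI(t) = FI(t) / FI(t_ref) for one cell and channel.

    The reference is the last pre-fusion frame (or the mean of the last
    ``reference_frames`` pre-fusion frames). Raises if no pre-fusion frame
    exists or the reference is ≤ 0 (such cells are excluded upstream)."""
    pre = fi[prefusion_flag.astype(bool).values]
    if pre.size == 0:
        raise ValidationError("no pre-fusion timepoint to normalize to")
    ref = float(pre.iloc[-reference_frames:].mean())
    if not np.isfinite(ref) or ref <= 0:
        raise ValidationError(f"non-positive pre-fusion reference ({ref!r})")
    return fi / ref


def annotate_phases(conv: pd.DataFrame,
                    boundaries: Mapping[str, tuple[float, float]]) -> pd.DataFrame:
    """Label each timepoint with its phase (half-open [start, end) intervals;
    a timepoint exactly on a boundary belongs to the later phase).

    ``boundaries`` maps PCDI/PCDII/PCDIII to (start_min, end_min); phases
    must be ordered and non-overlapping. Timepoints outside every phase are
    labeled 'unassigned'. Returns a copy with the ``phase`` column set."""
    items = [(p, boundaries[p]) for p in PHASES if p in boundaries]
    prev_end = -np.inf
    for phase, (start, end) in items:
        if end < start:
            raise ValidationError(f"phase {phase} has end < start")
        if start < prev_end:
            raise ValidationError("phase boundaries overlap or are out of order")
        prev_end = end
    out = conv.copy()
    t = out["time_min"].to_numpy(dtype=float)
    label = np.full(t.shape, "unassigned", dtype=object)
    for phase, (start, end) in items:
        label[(t >= start) & (t < end)] = phase
    out["phase"] = label
    return out


class ConversionQuantifier:
    """Stateless transformer: raw measurement table -> per-cell FD(t) traces.

    Parameters
    ----------
    reference_frames : int
        Number of trailing pre-fusion frames averaged into the RFI
        reference (1 = the single last pre-fusion frame).
    caveat_threshold : float
        FD (percent) at and above which the interpretability caveat flag is
        set (default 80).
    denominator_floor : float
        Minimum |I_cytosol − I_background| for ``relative_intensity``.
    drop_prefusion : bool
        If True (default) the output keeps only post-fusion timepoints
        (t ≥ 0); the pre-fusion frames exist solely to define the reference.
    """

    def __init__(self, reference_frames: int = 1,
                 caveat_threshold: float = DEFAULT_CAVEAT_THRESHOLD,
                 denominator_floor: float = DEFAULT_DENOMINATOR_FLOOR,
                 drop_prefusion: bool = True):
        self.reference_frames = reference_frames
        self.caveat_threshold = caveat_threshold
        self.denominator_floor = denominator_floor
        self.drop_prefusion = drop_prefusion

    # sklearn-style surface -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "reference_frames": self.reference_frames,
            "caveat_threshold": self.caveat_threshold,
            "denominator_floor": self.denominator_floor,
            "drop_prefusion": self.drop_prefusion,
        }

    def set_params(self, **params) -> "ConversionQuantifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "ConversionQuantifier":
        self._validate(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Compute per-cell RFI and FD traces from a measurement table."""
        self._validate(X)
        excluded: list[tuple[str, str]] = []
        out_rows = []
        for cell_id, cell in X.groupby("cell_id", sort=False):
            wide = self._to_wide(cell)
            try:
                rfi_red = normalize_to_prefusion(
                    wide["fi_red"], wide["prefusion_flag"], self.reference_frames
                )
                rfi_green = normalize_to_prefusion(
                    wide["fi_green"], wide["prefusion_flag"], self.reference_frames
                )
            except ValidationError as err:
                excluded.append((str(cell_id), str(err)))
                continue
            fd = conversion(rfi_red.to_numpy(), rfi_green.to_numpy())
            df = pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "time_min": wide["time_min"].to_numpy(),
                    "rfi_red": rfi_red.to_numpy(),
                    "rfi_green": rfi_green.to_numpy(),
                    "fd_percent": fd,
                    "phase": "unassigned",
                    "flag_negative": fd < 0,
                    "flag_caveat": fd >= self.caveat_threshold,
                    "flag_invalid": ~np.isfinite(fd),
                }
            )
            if self.drop_prefusion:
                df = df[df["time_min"] >= 0].reset_index(drop=True)
            out_rows.append(df)
        self.excluded_cells_ = excluded
        if not out_rows:
            return pd.DataFrame(columns=CONVERSION_COLUMNS)
        return pd.concat(out_rows, ignore_index=True)[CONVERSION_COLUMNS]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    # internals -------------------------------------------------------------
    @staticmethod
    def _validate(X: pd.DataFrame) -> None:
        missing = [c for c in MEASUREMENT_COLUMNS if c not in X.columns]
        if missing:
            raise ValidationError(f"measurement table missing columns {missing}")
        bad = set(X["channel"].unique()) - {"red", "green"}
        if bad:
            raise ValidationError(f"unknown channels {sorted(bad)}")

    @staticmethod
    def _to_wide(cell: pd.DataFrame) -> pd.DataFrame:
        fi = cell.assign(fi=localized_intensity(cell["roi"], cell["cytosol"]))
        wide = fi.pivot_table(
            index="time_min", columns="channel", values="fi", aggfunc="first"
        ).rename(columns={"red": "fi_red", "green": "fi_green"})
        if "fi_red" not in wide or "fi_green" not in wide:
            raise ValidationError("both channels required at every timepoint")
        wide = wide.dropna(subset=["fi_red", "fi_green"]).sort_index()
        flags = fi.groupby("time_min")["prefusion_flag"].first()
        wide["prefusion_flag"] = flags.reindex(wide.index).astype(bool)
        return wide.reset_index()


def quantify_traces(measurements: pd.DataFrame,
                    phase_boundaries: Mapping[str, tuple[float, float]] | None = None,
                    **params) -> pd.DataFrame:
    """Convenience wrapper: measurement table -> annotated conversion table."""
    conv = ConversionQuantifier(**params).fit_transform(measurements)
    if phase_boundaries:
        conv = annotate_phases(conv, phase_boundaries)
    return conv
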