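"""Timer fluorescence preprocessing: thresholding, normalization, Timer Angle.

The pipeline has three steps, all anchored on a gated Timer-negative control:

1. **Log transform** — every raw channel value x becomes log10(x + 1).
2. **Normalization / thresholding** — per channel, the negative control
   provides a reference location (by default the maximum of its log values;
   configurable quantile) and a scaled median absolute deviation (MAD).
   Each cell's normalized value is (log - reference) / MAD, clamped at 0.
   A cell with both normalized channels at 0 is Timer-negative.
3. **Trigonometric transform** — normalized Blue/Red are mapped to polar
   coordinates: Timer Intensity I = sqrt(Bnorm^2 + Rnorm^2) and Timer Angle
   theta = arccos(Bnorm / I) * 180 / pi, so that 0 deg is pure blue (new
   transcription), 90 deg pure red (arrested transcription), and sustained
   transcription accumulates near 45 deg.

Clamping sub-threshold channels to exactly 0 is what makes the 0 deg / 90 deg
anchor angles (hence the New and Arrested loci) attainable rather than
measure-zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tocky.io import Experiment, RawSample

logger = logging.getLogger(__name__)

#: Consistency constant making the MAD of a normal sample estimate its SD.
SCALED_MAD_CONSTANT = 1.4826

MIN_NEGATIVE_CONTROL_EVENTS = 10

__all__ = [
    "NegControlStats",
    "TransformedSample",
    "DegenerateControlError",
    "log_transform",
    "fit_negative_controls",
    "normalize_channel",
    "trig_transform",
    "preprocess_experiment",
    "transformed_to_frame",
]


class DegenerateControlError(ValueError):
    """Negative control has too few events or zero spread in a channel."""


@dataclass(frozen=True)
class NegControlStats:
    """Reference location and scaled MAD of the log negative control, per channel."""

    max_log_blue: float
    mad_log_blue: float
    max_log_red: float
    mad_log_red: float
    quantile_used: float = 1.0

    def __post_init__(self) -> None:
        if not (self.mad_log_blue > 0 and self.mad_log_red > 0):
            raise DegenerateControlError(
                "negative-control MAD must be positive in both channels"
            )


@dataclass
class TransformedSample:
    """Per-cell normalized fluorescence, Timer positivity, angle and intensity.

    ``data`` columns: ``b_norm``, ``r_norm``, ``timer_positive``, ``angle``
    (degrees in [0, 90], NaN for Timer-negative cells), ``intensity``, plus
    any marker columns carried through from the raw sample.
    """

    sample_id: str
    group_id: str
    data: pd.DataFrame
    stats: NegControlStats

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def n_timer_positive(self) -> int:
        return int(self.data["timer_positive"].sum())

    @property
    def timer_fraction(self) -> float:
        return self.n_timer_positive / self.n_events if self.n_events else 0.0

    def angles(self) -> np.ndarray:
        """Timer Angles of the Timer-positive cells, in degrees."""
        return self.data.loc[self.data["timer_positive"], "angle"].to_numpy()


def log_transform(raw):
    """log10(x + 1) of raw fluorescence; monotone, maps 0 to 0."""
    arr = np.asarray(raw, dtype=float)
    if np.any(arr < 0):
        raise ValueError("raw fluorescence must be >= 0 (floor negatives first)")
    out = np.log10(arr + 1.0)
    return out if arr.ndim else float(out)


def fit_negative_controls(
    neg: RawSample,
    quantile: float = 1.0,
    mad_constant: float = SCALED_MAD_CONSTANT,
    min_events: int = MIN_NEGATIVE_CONTROL_EVENTS,
) -> NegControlStats:
    """Fit per-channel threshold reference and scaled MAD from the control.

    ``quantile = 1.0`` reproduces the literal per-channel maximum of the
    log-transformed negative control; lower values (e.g. 0.995) discount
    outlier-contaminated controls.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    if neg.n_events < min_events:
        raise DegenerateControlError(
            f"negative control has {neg.n_events} events; need >= {min_events}"
        )
    refs, mads = {}, {}
    for channel in ("blue_raw", "red_raw"):
        logs = log_transform(neg.events[channel].to_numpy())
        ref = float(np.max(logs)) if quantile == 1.0 else float(np.quantile(logs, quantile))
        mad = mad_constant * float(np.median(np.abs(logs - np.median(logs))))
        if mad <= 0:
            raise DegenerateControlError(
                f"negative control is degenerate in {channel}: MAD = 0"
            )
        refs[channel], mads[channel] = ref, mad
    return NegControlStats(
        max_log_blue=refs["blue_raw"],
        mad_log_blue=mads["blue_raw"],
        max_log_red=refs["red_raw"],
        mad_log_red=mads["red_raw"],
        quantile_used=quantile,
    )


def normalize_channel(log_value, reference: float, mad: float):
    """(log - reference) / MAD, clamped at 0.

    Values at or below the negative-control reference map to exactly 0,
    declaring the channel negative for that cell.
    """
    if mad <= 0:
        raise ValueError("MAD must be positive")
    arr = np.asarray(log_value, dtype=float)
    out = np.maximum((arr - reference) / mad, 0.0)
    return out if arr.ndim else float(out)


def trig_transform(b_norm, r_norm):
    """Normalized Blue/Red -> (Timer Angle degrees, Timer Intensity).

    Timer-negative cells (both channels 0) get angle NaN and intensity 0.
    Single-positive cells land exactly at 0 deg (blue only) or 90 deg
    (red only); all other angles are clamped into [0, 90] against rounding.
    """
    b = np.asarray(b_norm, dtype=float)
    r = np.asarray(r_norm, dtype=float)
    if np.any(b < 0) or np.any(r < 0):
        raise ValueError("normalized fluorescence must be >= 0")
    b, r = np.atleast_1d(b), np.atleast_1d(r)
    intensity = np.hypot(b, r)
    angle = np.full(b.shape, np.nan)
    pos = intensity > 0
    with np.errstate(invalid="ignore"):
        ratio = np.clip(np.divide(b, intensity, where=pos, out=np.ones_like(b)), -1, 1)
    angle[pos] = np.degrees(np.arccos(ratio[pos]))
    # exact anchors for single-positive cells
    angle[(b > 0) & (r == 0)] = 0.0
    angle[(b == 0) & (r > 0)] = 90.0
    angle[pos] = np.clip(angle[pos], 0.0, 90.0)
    if np.isscalar(b_norm) or np.asarray(b_norm).ndim == 0:
        return float(angle[0]), float(intensity[0])
    return angle, intensity


def transform_sample(sample: RawSample, stats: NegControlStats) -> TransformedSample:
    """Apply normalization and the trigonometric transform to one sample."""
    blue_log = log_transform(sample.events["blue_raw"].to_numpy())
    red_log = log_transform(sample.events["red_raw"].to_numpy())
    b_norm = normalize_channel(blue_log, stats.max_log_blue, stats.mad_log_blue)
    r_norm = normalize_channel(red_log, stats.max_log_red, stats.mad_log_red)
    b_norm, r_norm = np.atleast_1d(b_norm), np.atleast_1d(r_norm)
    angle, intensity = trig_transform(b_norm, r_norm)
    data = pd.DataFrame(
        {
            "b_norm": b_norm,
            "r_norm": r_norm,
            "timer_positive": (b_norm > 0) | (r_norm > 0),
            "angle": angle,
            "intensity": intensity,
        }
    )
    for marker in sample.marker_names:
        data[marker] = sample.events[marker].to_numpy()
    return TransformedSample(
        sample_id=sample.sample_id,
        group_id=sample.group_id,
        data=data,
        stats=stats,
    )


def preprocess_experiment(
    exp: Experiment,
    quantile: float = 1.0,
    mad_constant: float = SCALED_MAD_CONSTANT,
) -> list[TransformedSample]:
    """Run the full preprocessing on every sample of an experiment.

    A single negative-control fit is shared across all samples, ensuring
    comparability of normalized values and angles between samples.
    """
    stats = fit_negative_controls(
        exp.negative_control, quantile=quantile, mad_constant=mad_constant
    )
    out = []
    for sample in exp.samples:
        ts = transform_sample(sample, stats)
        logger.info(
            "sample %r: %d/%d Timer-positive (%.1f%%)",
            ts.sample_id,
            ts.n_timer_positive,
            ts.n_events,
            100 * ts.timer_fraction,
        )
        out.append(ts)
    return out


def transformed_to_frame(samples: list[TransformedSample]) -> pd.DataFrame:
    """Concatenate transformed samples into one long table (CSV-ready)."""
    frames = []
    for ts in samples:
        frame = ts.data.copy()
        frame.insert(0, "sample_id", ts.sample_id)
        frame.insert(1, "group", ts.group_id)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "group", "b_norm", "r_norm", "timer_positive", "angle", "intensity"]
        )
    return pd.concat(frames, ignore_index=True)
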