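"""Synthetic Tocky-style fixture generator with known ground truth.

The generator produces raw two-channel fluorescence data by *inverting* the
preprocessing map rather than simulating Timer chemistry (mechanistic
populations come from :mod:`tocky.kinetics`): each Timer-positive cell is
given a true angle theta* and intensity d*, converted to target normalized
values b = d* cos(theta*), r = d* sin(theta*), and un-normalized into log
fluorescence against the spec's own negative-control parameters, then back
to raw scale via 10**log - 1.

Two constructions make the inversion recoverable by the pipeline:

* Negative-control log fluorescence is drawn from a normal *truncated at a
  hard upper bound* (mean + 3 sd by default).  The pipeline re-estimates the
  threshold as the control's sample maximum, which converges to that bound
  at O(1/n) — far faster than the unbounded normal maximum — so generated
  and recovered normalized values agree closely.
* The "off" channel of a single-positive cell (red for a 0-deg cell, blue
  for a 90-deg cell) is drawn from the negative cloud clipped half an sd
  below the bound, guaranteeing it falls below the re-estimated threshold
  and clamps to exactly 0.  This keeps the New and Arrested anchor angles
  exact after the round trip.

Every generated sample is accompanied by a ground-truth table
(cell_id, component, true_angle, true_intensity); tests must never
re-derive truth from pipeline outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from tocky.io import Experiment, RawSample

__all__ = [
    "TimerComponent",
    "PopulationSpec",
    "generate_sample",
    "generate_experiment",
]


@dataclass(frozen=True)
class TimerComponent:
    """One Timer-positive subpopulation.

    ``angle_kind``: ``point`` (all cells at ``angle_mean``), ``truncnorm``
    (normal with mean/sd truncated to [angle_low, angle_high]), or
    ``uniform`` on [angle_low, angle_high].  Intensities are log-uniform in
    MAD units above threshold between ``intensity_low`` and
    ``intensity_high``.
    """

    n: int
    angle_kind: str = "truncnorm"
    angle_mean: float = 45.0
    angle_sd: float = 8.0
    angle_low: float = 0.0
    angle_high: float = 90.0
    intensity_low: float = 3.0
    intensity_high: float = 30.0
    label: str = "component"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("component n must be >= 0")
        if self.angle_kind not in ("point", "truncnorm", "uniform"):
            raise ValueError(f"unknown angle_kind {self.angle_kind!r}")
        if not (0.0 <= self.angle_low <= self.angle_high <= 90.0):
            raise ValueError("angle bounds must satisfy 0 <= low <= high <= 90")
        if not (0.0 <= self.angle_mean <= 90.0):
            raise ValueError("angle_mean must lie in [0, 90]")
        if not 0 < self.intensity_low <= self.intensity_high:
            raise ValueError("intensity bounds must satisfy 0 < low <= high")

    def draw_angles(self, rng: np.random.Generator) -> np.ndarray:
        if self.angle_kind == "point":
            return np.full(self.n, float(self.angle_mean))
        if self.angle_kind == "uniform":
            return rng.uniform(self.angle_low, self.angle_high, size=self.n)
        a = (self.angle_low - self.angle_mean) / self.angle_sd
        b = (self.angle_high - self.angle_mean) / self.angle_sd
        return sps.truncnorm.rvs(
            a, b, loc=self.angle_mean, scale=self.angle_sd, size=self.n,
            random_state=rng,
        )

    def draw_intensities(self, rng: np.random.Generator) -> np.ndarray:
        return np.exp(
            rng.uniform(np.log(self.intensity_low), np.log(self.intensity_high), size=self.n)
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Full specification of one synthetic sample."""

    n_neg: int = 5000
    neg_log_mean_blue: float = 1.8
    neg_log_sd_blue: float = 0.15
    neg_log_mean_red: float = 1.8
    neg_log_sd_red: float = 0.15
    trunc_z: float = 3.0  # hard bound of the negative cloud, in sd units
    components: tuple[TimerComponent, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_neg < 0:
            raise ValueError("n_neg must be >= 0")
        object.__setattr__(self, "components", tuple(self.components))

    # generator-side normalization anchors (what the pipeline re-estimates)
    @property
    def ref_log_blue(self) -> float:
        return self.neg_log_mean_blue + self.trunc_z * self.neg_log_sd_blue

    @property
    def ref_log_red(self) -> float:
        return self.neg_log_mean_red + self.trunc_z * self.neg_log_sd_red


def _neg_logs(rng, n, mean, sd, z) -> np.ndarray:
    return sps.truncnorm.rvs(-z, z, loc=mean, scale=sd, size=n, random_state=rng)


def _off_channel_logs(rng, n, mean, sd, z) -> np.ndarray:
    # negative-cloud draw, clipped 0.5 sd under the bound so it always clamps
    return np.minimum(_neg_logs(rng, n, mean, sd, z), mean + (z - 0.5) * sd)


def _log_to_raw(logs: np.ndarray) -> np.ndarray:
    return np.maximum(10.0 ** logs - 1.0, 0.0)


def generate_sample(
    spec: PopulationSpec,
    sample_id: str = "synthetic",
    group_id: str = "synthetic",
    seed: int | np.random.Generator | None = None,
) -> tuple[RawSample, pd.DataFrame]:
    """Generate one raw sample plus its ground-truth table.

    Returns ``(RawSample, truth)`` where ``truth`` has one row per cell:
    ``cell_id, component, true_angle, true_intensity`` (angle/intensity NaN
    for autofluorescent negatives).
    """
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    blue_logs = [_neg_logs(rng, spec.n_neg, spec.neg_log_mean_blue,
                           spec.neg_log_sd_blue, spec.trunc_z)]
    red_logs = [_neg_logs(rng, spec.n_neg, spec.neg_log_mean_red,
                          spec.neg_log_sd_red, spec.trunc_z)]
    labels = [np.full(spec.n_neg, "neg", dtype=object)]
    angles = [np.full(spec.n_neg, np.nan)]
    intensities = [np.full(spec.n_neg, np.nan)]

    for comp in spec.components:
        theta = comp.draw_angles(rng)
        d = comp.draw_intensities(rng)
        b_norm = d * np.cos(np.radians(theta))
        r_norm = d * np.sin(np.radians(theta))
        # cos(90 deg) etc. are ~1e-16, not 0: snap so anchor cells stay single-positive
        b_norm[b_norm < 1e-9] = 0.0
        r_norm[r_norm < 1e-9] = 0.0
        blue = np.where(
            b_norm > 0,
            spec.ref_log_blue + b_norm * spec.neg_log_sd_blue,
            _off_channel_logs(rng, comp.n, spec.neg_log_mean_blue,
                              spec.neg_log_sd_blue, spec.trunc_z),
        )
        red = np.where(
            r_norm > 0,
            spec.ref_log_red + r_norm * spec.neg_log_sd_red,
            _off_channel_logs(rng, comp.n, spec.neg_log_mean_red,
                              spec.neg_log_sd_red, spec.trunc_z),
        )
        blue_logs.append(blue)
        red_logs.append(red)
        labels.append(np.full(comp.n, comp.label, dtype=object))
        angles.append(theta)
        intensities.append(d)

    events = pd.DataFrame(
        {
            "blue_raw": _log_to_raw(np.concatenate(blue_logs)),
            "red_raw": _log_to_raw(np.concatenate(red_logs)),
        }
    )
    truth = pd.DataFrame(
        {
            "cell_id": np.arange(len(events)),
            "component": np.concatenate(labels),
            "true_angle": np.concatenate(angles),
            "true_intensity": np.concatenate(intensities),
        }
    )
    sample = RawSample(sample_id=sample_id, group_id=group_id, events=events)
    return sample, truth


def _jitter_components(
    comps: Sequence[TimerComponent], rng: np.random.Generator, dirichlet_conc: float | None
) -> tuple[TimerComponent, ...]:
    """Resample component sizes around their spec'd proportions.

    ``dirichlet_conc`` scales a Dirichlet prior on component weights (larger
    = tighter replicates); ``None`` or 0 keeps sizes exact.
    """
    if not comps or not dirichlet_conc:
        return tuple(comps)
    n_total = sum(c.n for c in comps)
    base = np.array([c.n for c in comps], dtype=float) / n_total
    weights = rng.dirichlet(base * dirichlet_conc)
    sizes = rng.multinomial(n_total, weights)
    return tuple(replace(c, n=int(m)) for c, m in zip(comps, sizes))


def generate_experiment(
    group_specs: dict[str, PopulationSpec],
    n_samples: int = 3,
    seed: int | None = 0,
    dirichlet_conc: float | None = None,
    n_control: int = 20000,
) -> tuple[Experiment, dict[str, pd.DataFrame]]:
    """Build a multi-sample, multi-group experiment with a shared control.

    The negative control is generated once from the first group's
    autofluorescence parameters, with ``n_control`` events: gated
    Timer-negative populations are typically abundant, and a large control
    keeps the re-estimated threshold and MAD close to their population
    values.  Per-sample replicate variability is introduced by Dirichlet
    jitter on component proportions (off by default).  Returns the
    experiment and a mapping sample_id -> ground truth table.
    """
    if not group_specs:
        raise ValueError("need at least one group")
    rng = np.random.default_rng(seed)
    first = next(iter(group_specs.values()))
    for g, s in group_specs.items():
        if (s.neg_log_mean_blue, s.neg_log_sd_blue, s.neg_log_mean_red,
                s.neg_log_sd_red, s.trunc_z) != (
                first.neg_log_mean_blue, first.neg_log_sd_blue,
                first.neg_log_mean_red, first.neg_log_sd_red, first.trunc_z):
            raise ValueError(
                f"group {g!r}: autofluorescence parameters must match across groups "
                "(one shared negative control anchors the whole experiment)"
            )
    neg_spec = replace(first, components=(), n_neg=n_control)
    neg_control, _ = generate_sample(neg_spec, sample_id="neg_control",
                                     group_id="negative", seed=rng)

    samples, truths = [], {}
    for group_id, spec in group_specs.items():
        for i in range(1, n_samples + 1):
            jittered = replace(
                spec, components=_jitter_components(spec.components, rng, dirichlet_conc)
            )
            sid = f"{group_id}_s{i}"
            sample, truth = generate_sample(jittered, sample_id=sid,
                                            group_id=group_id, seed=rng)
            samples.append(sample)
            truths[sid] = truth
    exp = Experiment(samples=samples, negative_control=neg_control)
    return exp, truths
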