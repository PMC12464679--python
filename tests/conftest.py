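"""Shared fixtures: a minimal FCS writer and small synthetic experiments."""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd
import pytest

from tocky.io import Experiment, RawSample
from tocky.synthetic import (PopulationSpec, TimerComponent, generate_experiment,
                             generate_sample)


def write_minimal_fcs(path, channels: dict[str, np.ndarray], datatype: str = "F") -> None:
    """Write a minimal FCS 3.0 list-mode file (test fixture only).

    ``channels`` maps $PnN detector names to equal-length value arrays.
    """
    names = list(channels)
    matrix = np.column_stack([np.asarray(channels[n], dtype=float) for n in names])
    n_tot, n_par = matrix.shape
    if datatype == "F":
        payload = matrix.astype("<f4").tobytes()
        bits = 32
    elif datatype == "D":
        payload = matrix.astype("<f8").tobytes()
        bits = 64
    else:
        raise ValueError(datatype)

    kw = {
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$DATATYPE": datatype,
        "$BYTEORD": "1,2,3,4",
        "$MODE": "L",
    }
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = str(bits)

    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
    text_start = 58
    text_bytes = text.encode("latin-1")
    data_start = text_start + len(text_bytes)
    data_end = data_start + len(payload) - 1
    header = b"FCS3.0    " + b"".join(
        f"{v:>8d}".encode() for v in
        [text_start, text_start + len(text_bytes) - 1, data_start, data_end, 0, 0]
    )
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(payload)


@pytest.fixture
def fcs_writer():
    return write_minimal_fcs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_raw_sample(blue, red, sample_id="s1", group_id="g1", **markers) -> RawSample:
    events = pd.DataFrame({"blue_raw": np.asarray(blue, float),
                           "red_raw": np.asarray(red, float), **markers})
    return RawSample(sample_id=sample_id, group_id=group_id, events=events)


@pytest.fixture
def neg_control_sample():
    """A generated autofluorescence-only control (default spec parameters)."""
    sample, _ = generate_sample(PopulationSpec(n_neg=4000), sample_id="neg",
                                group_id="negative", seed=2024)
    return sample


@pytest.fixture
def sim_neg_control():
    """Autofluorescence control on the scale of ODE-simulated populations."""
    spec = PopulationSpec(n_neg=4000, neg_log_mean_blue=0.3, neg_log_sd_blue=0.1,
                          neg_log_mean_red=0.3, neg_log_sd_red=0.1)
    sample, _ = generate_sample(spec, sample_id="sim_neg", group_id="negative",
                                seed=5)
    return sample


@pytest.fixture
def two_group_experiment():
    """Small two-group experiment with a mid-angle component shift."""
    spec_a = PopulationSpec(n_neg=1000, components=(
        TimerComponent(n=300, angle_mean=25.0, angle_sd=6.0, label="low"),
        TimerComponent(n=300, angle_mean=50.0, angle_sd=6.0, label="mid"),
    ))
    spec_b = PopulationSpec(n_neg=1000, components=(
        TimerComponent(n=150, angle_mean=25.0, angle_sd=6.0, label="low"),
        TimerComponent(n=450, angle_mean=50.0, angle_sd=6.0, label="mid"),
    ))
    exp, truths = generate_experiment({"ctrl": spec_a, "treat": spec_b},
                                      n_samples=3, seed=11)
    return exp, truths
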