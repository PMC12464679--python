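"""Event-level I/O and the experiment data model.

A :class:`RawSample` holds one flow-cytometry sample as a table of per-cell
raw Timer-Blue / Timer-Red fluorescence values plus optional marker channels.
An :class:`Experiment` bundles the samples of one acquisition together with
the gated Timer-negative control that anchors normalization downstream.

Raw values are used exactly as stored in the file: no compensation, no
display transform.  Negative raw values (possible after acquisition-time
compensation) are floored at 0 so that the pipeline's log10(x+1) step stays
defined; the number of floored events is recorded on the sample.

Supported formats: FCS 3.0/3.1 (read-only, list mode) and a plain CSV schema
``sample_id,group,blue_raw,red_raw[,marker...]`` (read/write, the canonical
fixture format).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANDATORY_CSV_COLUMNS = ("sample_id", "group", "blue_raw", "red_raw")

__all__ = [
    "RawSample",
    "Experiment",
    "FCSFormatError",
    "ChannelError",
    "SchemaError",
    "read_fcs",
    "read_csv",
    "write_csv",
]


class FCSFormatError(ValueError):
    """File is not a parseable FCS 3.0/3.1 list-mode file."""


class ChannelError(KeyError):
    """A requested detector name is absent from the file."""


class SchemaError(ValueError):
    """CSV input is missing mandatory columns."""


@dataclass
class RawSample:
    """Per-cell raw fluorescence events for one sample.

    ``events`` holds one row per cell with at least ``blue_raw`` and
    ``red_raw`` columns (floats, >= 0 after flooring); extra columns are
    marker intensities carried through the pipeline untouched.
    """

    sample_id: str
    group_id: str
    events: pd.DataFrame
    n_floored: int = 0

    def __post_init__(self) -> None:
        for col in ("blue_raw", "red_raw"):
            if col not in self.events.columns:
                raise SchemaError(f"events table lacks mandatory column {col!r}")
        vals = self.events[["blue_raw", "red_raw"]].to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise ValueError(
                f"sample {self.sample_id!r}: non-finite blue/red fluorescence values"
            )
        if vals.size and (vals < 0).any():
            raise ValueError(
                f"sample {self.sample_id!r}: negative raw fluorescence; "
                "floor values before constructing RawSample"
            )
        if self.n_events == 0:
            logger.warning("sample %r contains no events", self.sample_id)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def marker_names(self) -> list[str]:
        return [c for c in self.events.columns if c not in ("blue_raw", "red_raw")]


@dataclass
class Experiment:
    """A set of samples sharing one gated Timer-negative control.

    ``channel_map`` maps logical channel names (``timer_blue``, ``timer_red``,
    marker names) to detector names in the source files; it is informational
    once events are loaded but mandatory when reading FCS.
    """

    samples: list[RawSample]
    negative_control: RawSample
    channel_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.negative_control.n_events == 0:
            raise ValueError("negative control sample is empty")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids in experiment: {ids}")

    @property
    def groups(self) -> pd.DataFrame:
        """Group-assignment table: one row per sample."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "group": [s.group_id for s in self.samples],
                "n_events": [s.n_events for s in self.samples],
            }
        )


def _floor_negatives(events: pd.DataFrame, sample_id: str) -> tuple[pd.DataFrame, int]:
    vals = events[["blue_raw", "red_raw"]].to_numpy(dtype=float)
    mask = vals < 0
    n = int(mask.sum())
    if n:
        logger.info("sample %r: floored %d negative raw values at 0", sample_id, n)
        events = events.copy()
        events[["blue_raw", "red_raw"]] = np.maximum(vals, 0.0)
    return events, n


# ---------------------------------------------------------------------------
# FCS reading (minimal FCS 3.0/3.1 list-mode parser)
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    tokens = body.split(delim)
    if len(tokens) % 2:
        # trailing stray token; drop it rather than fail on sloppy writers
        tokens = tokens[:-1]
    return {tokens[i].strip().upper(): tokens[i + 1] for i in range(0, len(tokens), 2)}


def read_fcs(
    path: str | Path,
    channel_map: Mapping[str, str],
    sample_id: str | None = None,
    group_id: str = "",
) -> RawSample:
    """Read one FCS 3.0/3.1 list-mode file into a :class:`RawSample`.

    ``channel_map`` maps logical names to the file's ``$PnN`` detector names
    and must resolve at least ``timer_blue`` and ``timer_red``.  Values are
    taken from the mapped detectors as stored, without compensation or
    display transformation; negative values are floored at 0.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 58:
        raise FCSFormatError(f"{path}: file too short to be FCS")
    version = data[:6].decode("latin-1")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"{path}: unsupported version {version!r}")

    def offset(a: int, b: int) -> int:
        txt = data[a:b].decode("latin-1").strip()
        return int(txt) if txt else 0

    text_start, text_end = offset(10, 18), offset(18, 26)
    data_start, data_end = offset(26, 34), offset(34, 42)
    kw = _parse_text_segment(data[text_start : text_end + 1])

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
        mode = kw.get("$MODE", "L").strip().upper()
    except KeyError as e:  # pragma: no cover - malformed files
        raise FCSFormatError(f"{path}: missing required keyword {e}") from e
    if mode != "L":
        raise FCSFormatError(f"{path}: only list mode ($MODE=L) is supported")
    if data_start == 0:
        data_start = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    if data_start == 0:
        raise FCSFormatError(f"{path}: cannot locate DATA segment")

    endian = "<" if byteord.startswith("1") else ">"
    names = [kw.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]
    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]

    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32):
            raise FCSFormatError(
                f"{path}: integer data with mixed/unsupported $PnB widths {bits}"
            )
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise FCSFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    n_values = n_par * n_tot
    raw = data[data_start : data_start + n_values * dtype.itemsize]
    if len(raw) < n_values * dtype.itemsize:
        raise FCSFormatError(f"{path}: DATA segment truncated")
    matrix = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(float)
    table = pd.DataFrame(matrix, columns=names)

    for logical in ("timer_blue", "timer_red"):
        if logical not in channel_map:
            raise ChannelError(f"channel_map must define {logical!r}")
    events = {}
    for logical, detector in channel_map.items():
        if detector not in table.columns:
            raise ChannelError(
                f"{path}: detector {detector!r} (for {logical!r}) not in file; "
                f"available channels: {sorted(table.columns)}"
            )
        col = {"timer_blue": "blue_raw", "timer_red": "red_raw"}.get(logical, logical)
        events[col] = table[detector].to_numpy()
    frame = pd.DataFrame(events)
    frame, n_floored = _floor_negatives(frame, sample_id or path.stem)
    return RawSample(
        sample_id=sample_id or path.stem,
        group_id=group_id,
        events=frame,
        n_floored=n_floored,
    )


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

def read_csv(path: str | Path) -> RawSample:
    """Read one sample from the canonical CSV schema.

    Mandatory header columns: ``sample_id, group, blue_raw, red_raw``;
    any further columns are marker intensities.  The file must contain a
    single sample (one unique ``sample_id``); an empty event section yields
    a valid zero-event sample (logged).
    """
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANDATORY_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    if len(table) == 0:
        logger.warning("%s: empty event section", path)
        return RawSample(
            sample_id=path.stem,
            group_id="",
            events=table.drop(columns=["sample_id", "group"]),
        )
    ids = table["sample_id"].unique()
    if len(ids) > 1:
        raise SchemaError(f"{path}: multiple sample ids in one file: {list(ids)}")
    groups = table["group"].unique()
    events = table.drop(columns=["sample_id", "group"]).astype(float)
    events, n_floored = _floor_negatives(events, str(ids[0]))
    return RawSample(
        sample_id=str(ids[0]),
        group_id=str(groups[0]),
        events=events.reset_index(drop=True),
        n_floored=n_floored,
    )


def write_csv(sample: RawSample, path: str | Path) -> None:
    """Write a sample in the canonical CSV schema, losslessly.

    Float values are written with ``repr`` precision so that
    ``read_csv(write_csv(x)) == x`` bitwise on all finite inputs.
    """
    path = Path(path)
    out = sample.events.copy()
    out.insert(0, "sample_id", sample.sample_id)
    out.insert(1, "group", sample.group_id)
    out.to_csv(path, index=False, float_format="%.17g")


def read_experiment_csvs(
    sample_paths: Sequence[str | Path],
    negative_control_path: str | Path,
    channel_map: Mapping[str, str] | None = None,
) -> Experiment:
    """Assemble an :class:`Experiment` from per-sample CSV files."""
    return Experiment(
        samples=[read_csv(p) for p in sample_paths],
        negative_control=read_csv(negative_control_path),
        channel_map=dict(channel_map or {}),
    )
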