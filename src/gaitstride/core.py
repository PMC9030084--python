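"""Core data model for foot-mounted IMU gait analysis.

The package works on uniformly sampled 6-channel IMU streams (3-axis
accelerometer + 3-axis gyroscope).  Physical axis names differ between
devices and mounting conventions, so every algorithm addresses channels
through anatomical *roles* -- ``coronal`` (left/right), ``sagittal``
(anterior/posterior) and ``vertical`` (gravity-aligned) -- resolved
through an explicit channel map.  Sample positions are addressed with
0-based, half-open ``[start, end)`` index intervals throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("coronal", "sagittal", "vertical")
PHASES = ("stance", "push_off", "swing", "heel_strike")

#: order in which the dynamic phases and the closing stance occur in a cycle
PHASE_ORDER = ("push_off", "swing", "heel_strike", "stance")


class FormatError(ValueError):
    """Malformed input file (missing columns, bad channel map, bad schema)."""


class DataError(ValueError):
    """Structurally valid file with physically invalid content."""


@dataclass(frozen=True, order=True)
class SampleInterval:
    """Half-open index range ``[start, end)`` on a recording."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {"start": int(self.start), "end": int(self.end)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SampleInterval":
        return cls(int(d["start"]), int(d["end"]))

    def contains(self, other: "SampleInterval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class GaitPhaseLabel:
    """One gait phase (stance / push_off / swing / heel_strike) interval."""

    phase: str
    interval: SampleInterval

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")

    def to_dict(self) -> dict:
        return {"phase": self.phase, **self.interval.to_dict()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "GaitPhaseLabel":
        return cls(str(d["phase"]), SampleInterval(int(d["start"]), int(d["end"])))


@dataclass
class ImuRecording:
    """Uniformly sampled multi-channel IMU stream with a role->column map.

    Parameters
    ----------
    sample_rate_hz:
        Nominal sampling rate; must agree with the timestamp spacing to 1%.
    timestamps:
        Monotone non-decreasing sample times in seconds, length ``n``.
    accel, gyro:
        ``n x 3`` arrays.  Units are carried in ``meta`` (keys
        ``accel_unit`` / ``gyro_unit``) and never assumed by algorithms.
    channel_map:
        ``{"accel": {role: column_index}, "gyro": {role: column_index}}``
        covering the three roles exactly once per sensor.
    """

    sample_rate_hz: float
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    channel_map: dict
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.sample_rate_hz <= 0:
            raise DataError("sample_rate_hz must be positive")
        n = self.timestamps.shape[0]
        if n < 2:
            raise DataError(f"recording needs at least 2 samples, got {n}")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise DataError(
                f"accel/gyro must be ({n}, 3); got {self.accel.shape} / {self.gyro.shape}"
            )
        dts = np.diff(self.timestamps)
        if np.any(dts < 0):
            row = int(np.argmax(dts < 0)) + 1
            raise DataError(f"timestamps decrease at row {row}")
        for sensor in ("accel", "gyro"):
            mapping = self.channel_map.get(sensor)
            if mapping is None or sorted(mapping) != sorted(ROLES):
                raise FormatError(
                    f"channel_map[{sensor!r}] must map exactly the roles {ROLES}"
                )
            if sorted(mapping.values()) != [0, 1, 2]:
                raise FormatError(
                    f"channel_map[{sensor!r}] must use columns 0..2 exactly once"
                )
        # sample-rate consistency: median dt within 1% of the nominal period
        med_dt = float(np.median(dts))
        if med_dt > 0 and abs(med_dt - 1.0 / self.sample_rate_hz) > 0.01 / self.sample_rate_hz:
            raise DataError(
                f"timestamp spacing {med_dt:.6g}s inconsistent with "
                f"sample_rate_hz={self.sample_rate_hz}"
            )

    def __len__(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self)

    def channel(self, sensor: str, role: str) -> np.ndarray:
        """Return one channel (1-D view) by sensor kind and anatomical role."""
        col = self.channel_map[sensor][role]
        arr = self.accel if sensor == "accel" else self.gyro
        return arr[:, col]

    def accel_magnitude(self) -> np.ndarray:
        """Per-sample Euclidean norm of the 3-axis acceleration."""
        return np.linalg.norm(self.accel, axis=1)


def slice_recording(rec: ImuRecording, iv: SampleInterval) -> ImuRecording:
    """Return the sub-recording covering ``iv``; channel map is preserved."""
    if iv.end > len(rec):
        raise IndexError(f"interval [{iv.start}, {iv.end}) out of range for n={len(rec)}")
    return replace(
        rec,
        timestamps=rec.timestamps[iv.start : iv.end].copy(),
        accel=rec.accel[iv.start : iv.end].copy(),
        gyro=rec.gyro[iv.start : iv.end].copy(),
        channel_map=rec.channel_map,
        meta=dict(rec.meta),
    )


# ---------------------------------------------------------------------------
# CSV recording I/O
# ---------------------------------------------------------------------------

_ACC_COLS = ("acc_x", "acc_y", "acc_z")
_GYR_COLS = ("gyr_x", "gyr_y", "gyr_z")


def load_recording(
    path,
    channel_map: Mapping[str, Mapping[str, str]] | Mapping[str, str],
    sample_rate_hz: float | None = None,
    meta: Mapping | None = None,
) -> ImuRecording:
    """Load a recording from CSV (columns ``t, acc_x..acc_z, gyr_x..gyr_z``).

    ``channel_map`` maps roles to *column names*, either flat (accel only,
    gyro inferred by the x/y/z suffix) or nested per sensor, e.g.
    ``{"accel": {"sagittal": "acc_y", ...}, "gyro": {...}}``.
    If ``sample_rate_hz`` is omitted it is inferred from the timestamps.
    """
    df = pd.read_csv(path)
    required = ("t",) + _ACC_COLS + _GYR_COLS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")

    if channel_map and "accel" not in channel_map:
        # flat role -> acc column form; mirror onto the gyro by axis suffix
        channel_map = {
            "accel": dict(channel_map),
            "gyro": {r: c.replace("acc", "gyr") for r, c in channel_map.items()},
        }
    cmap_idx: dict = {}
    for sensor, cols in (("accel", _ACC_COLS), ("gyro", _GYR_COLS)):
        mapping = dict(channel_map.get(sensor, {}))
        missing_roles = [r for r in ROLES if r not in mapping]
        if missing_roles:
            raise FormatError(f"channel_map[{sensor!r}] lacks role(s) {missing_roles}")
        try:
            cmap_idx[sensor] = {r: cols.index(mapping[r]) for r in ROLES}
        except ValueError as exc:
            raise FormatError(f"channel_map[{sensor!r}] names unknown column: {exc}")

    ts = df["t"].to_numpy(dtype=float)
    if ts.size < 2:
        raise DataError(f"{path}: recording needs at least 2 samples, got {ts.size}")
    if sample_rate_hz is None:
        dts = np.diff(ts)
        if np.any(dts <= 0):
            row = int(np.argmax(dts <= 0)) + 1
            raise DataError(f"{path}: timestamps non-increasing at row {row}")
        sample_rate_hz = 1.0 / float(np.median(dts))
    return ImuRecording(
        sample_rate_hz=float(sample_rate_hz),
        timestamps=ts,
        accel=df[list(_ACC_COLS)].to_numpy(dtype=float),
        gyro=df[list(_GYR_COLS)].to_numpy(dtype=float),
        channel_map=cmap_idx,
        meta=dict(meta or {}),
    )


def save_recording(rec: ImuRecording, path) -> None:
    """Write a recording as CSV with the canonical column layout."""
    df = pd.DataFrame(
        {
            "t": rec.timestamps,
            **{c: rec.accel[:, i] for i, c in enumerate(_ACC_COLS)},
            **{c: rec.gyro[:, i] for i, c in enumerate(_GYR_COLS)},
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Ground-truth or predicted strides, phases and per-stride lengths."""

    strides: list[SampleInterval] = field(default_factory=list)
    phases: list[GaitPhaseLabel] = field(default_factory=list)
    stride_lengths: list[float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for a, b in zip(self.strides, self.strides[1:]):
            if b.start < a.end:
                raise DataError(f"strides overlap or are unordered: {a} then {b}")
        for ph in self.phases:
            if not any(s.contains(ph.interval) for s in self.strides):
                raise DataError(f"phase {ph} lies outside every stride")
        if self.stride_lengths is not None and len(self.stride_lengths) != len(self.strides):
            raise DataError("stride_lengths must be one per stride")

    def phases_of(self, stride: SampleInterval) -> list[GaitPhaseLabel]:
        return [p for p in self.phases if stride.contains(p.interval)]

    def to_dict(self) -> dict:
        d: dict = {
            "strides": [s.to_dict() for s in self.strides],
            "phases": [p.to_dict() for p in self.phases],
            "meta": dict(self.meta),
        }
        if self.stride_lengths is not None:
            d["stride_lengths"] = [float(x) for x in self.stride_lengths]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnnotationSet":
        return cls(
            strides=[SampleInterval.from_dict(s) for s in d.get("strides", [])],
            phases=[GaitPhaseLabel.from_dict(p) for p in d.get("phases", [])],
            stride_lengths=(
                [float(x) for x in d["stride_lengths"]] if "stride_lengths" in d else None
            ),
            meta=dict(d.get("meta", {})),
        )


def write_annotations(ann: AnnotationSet, path) -> None:
    Path(path).write_text(json.dumps(ann.to_dict(), indent=1))


def read_annotations(path) -> AnnotationSet:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})")
    return AnnotationSet.from_dict(d)


def intervals_tile(intervals: Sequence[SampleInterval], span: SampleInterval) -> bool:
    """True iff sorted ``intervals`` exactly tile ``span`` (no gap/overlap)."""
    ivs = sorted(intervals)
    if not ivs:
        return False
    if ivs[0].start != span.start or ivs[-1].end != span.end:
        return False
    return all(a.end == b.start for a, b in zip(ivs, ivs[1:]))
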