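"""Marker-trajectory and stage-annotation I/O.

Recordings are uniform-rate (default 100 Hz) trajectories of 12 named
anatomical keypoints, stored internally in millimetres as a
``frames x keypoints x 3`` float array with NaN as the missing-value
sentinel.  The on-disk exchange format is long-format CSV
(``time,marker,x,y,z``) with empty fields for missing samples; a wide
format with per-marker ``_x/_y/_z`` columns is also accepted on read.

Stage annotations map half-open time intervals ``[start, end)`` in seconds
to the five experimental stages B1, B2, CR1, CR2 and DC (spontaneous
baseline, uncoupled reactive baseline, first minute of tethering, late
tethering, decoupled), integer-labelled 0-4.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SENTINEL",
    "STAGES",
    "LABEL_MAP",
    "DEFAULT_KEYPOINTS",
    "KeypointSchema",
    "MocapRecording",
    "StageAnnotation",
    "FormatError",
    "SchemaError",
    "DataError",
    "AnnotationError",
    "read_recording",
    "write_recording",
    "read_annotation",
    "write_annotation",
    "stage_of",
]

#: Missing-value sentinel used throughout the package.
SENTINEL = np.nan

#: The five experimental stages, in temporal order, and their integer labels.
STAGES = ("B1", "B2", "CR1", "CR2", "DC")
LABEL_MAP = {s: i for i, s in enumerate(STAGES)}

#: The 12 keypoints with complete data, in canonical column order.
DEFAULT_KEYPOINTS = (
    "Head", "CenterPelvis", "LHip", "RHip", "LShoulder", "RShoulder",
    "LHand", "RHand", "LKnee", "RKnee", "LFoot", "RFoot",
)


class FormatError(ValueError):
    """Malformed file header or layout."""


class SchemaError(ValueError):
    """Marker or stage token outside the declared schema."""


class DataError(ValueError):
    """Inconsistent data content (e.g. non-monotone time)."""


class AnnotationError(ValueError):
    """Invalid stage annotation (e.g. overlapping intervals)."""


@dataclass(frozen=True)
class KeypointSchema:
    """Ordered keypoint name list with anatomical-consistency checks."""

    names: tuple[str, ...] = DEFAULT_KEYPOINTS

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) != 12:
            raise SchemaError(f"expected 12 keypoints, got {len(names)}")
        if len(set(names)) != len(names):
            raise SchemaError("keypoint names must be unique")
        for side, other in (("L", "R"), ("R", "L")):
            for n in names:
                if n.startswith(side) and n not in ("Head", "CenterPelvis"):
                    partner = other + n[1:]
                    if partner not in names:
                        raise SchemaError(f"{n} lacks partner {partner}")
        for required in ("CenterPelvis", "LHip", "RHip"):
            if required not in names:
                raise SchemaError(f"required keypoint {required} missing")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown keypoint {name!r}") from None


@dataclass
class MocapRecording:
    """Uniform-rate 3D trajectories of the schema's keypoints.

    positions[i, k, :] is the (x, y, z) location in millimetres of keypoint
    ``schema.names[k]`` at time ``start_time + i / sample_rate`` seconds.
    NaN marks missing samples.
    """

    subject_id: str
    positions: np.ndarray
    sample_rate: float = 100.0
    start_time: float = 0.0
    schema: KeypointSchema = field(default_factory=KeypointSchema)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[1] != len(self.schema.names) or pos.shape[2] != 3:
            raise DataError(f"positions must be frames x {len(self.schema.names)} x 3, got {pos.shape}")
        if pos.shape[0] < 1:
            raise DataError("recording must contain at least one frame")
        if not self.sample_rate > 0:
            raise DataError("sample_rate must be positive")
        if np.isinf(pos).any():
            raise DataError("positions must be finite or NaN")
        self.positions = pos

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sample_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) / self.sample_rate

    def joint(self, name: str) -> np.ndarray:
        """Trajectory of one keypoint, shape (frames, 3)."""
        return self.positions[:, self.schema.index(name), :]

    def copy(self) -> "MocapRecording":
        return replace(self, positions=self.positions.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, MocapRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.sample_rate == other.sample_rate
            and self.start_time == other.start_time
            and self.schema.names == other.schema.names
            and self.positions.shape == other.positions.shape
            and bool(
                np.all(
                    (self.positions == other.positions)
                    | (np.isnan(self.positions) & np.isnan(other.positions))
                )
            )
        )


@dataclass(frozen=True)
class StageAnnotation:
    """Non-overlapping half-open intervals labelled with the five stages."""

    intervals: tuple[tuple[float, float, str], ...]

    label_map = LABEL_MAP

    def __post_init__(self):
        ivs = tuple((float(s), float(e), str(g)) for s, e, g in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for s, e, g in ivs:
            if g not in LABEL_MAP:
                raise SchemaError(f"unknown stage token {g!r}; must be one of {STAGES}")
            if not s < e:
                raise AnnotationError(f"interval start {s} must precede end {e}")
        by_start = sorted(ivs)
        for (s0, e0, g0), (s1, e1, g1) in zip(by_start, by_start[1:]):
            if s1 < e0:
                raise AnnotationError(f"intervals {g0} and {g1} overlap at t={s1}")

    def stage_of(self, t: float):
        """Stage label whose [start, end) interval contains ``t``, else None."""
        return stage_of(self, t)

    def label_of(self, t: float):
        """Integer label (0-4) at time ``t``, else None."""
        g = stage_of(self, t)
        return None if g is None else LABEL_MAP[g]

    def duration_of(self, stage: str) -> float:
        return sum(e - s for s, e, g in self.intervals if g == stage)


def stage_of(ann: StageAnnotation, t: float):
    """Stage containing instant ``t`` under the half-open convention."""
    if not np.isfinite(t):
        raise DataError("t must be finite")
    for s, e, g in ann.intervals:
        if s <= t < e:
            return g
    return None


# CSV serialization: full decimal precision via repr-exact %.17g, NaN as
# empty field, deterministic time-major row order.

def _fmt(v: float) -> str:
    if np.isnan(v):
        return ""
    return format(float(v), ".17g")


def write_recording(rec: MocapRecording, path) -> None:
    """Write a recording as long-format CSV (``time,marker,x,y,z``).

    Row order is time-major with markers in schema order; finite values
    survive a read/write round trip bit-exactly.
    """
    times = rec.times()
    buf = _io.StringIO()
    buf.write("time,marker,x,y,z\n")
    for i in range(rec.n_frames):
        t = _fmt(times[i])
        for k, name in enumerate(rec.schema.names):
            x, y, z = rec.positions[i, k]
            buf.write(f"{t},{name},{_fmt(x)},{_fmt(y)},{_fmt(z)}\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_recording(path, schema: KeypointSchema | None = None,
                   sample_rate: float = 100.0,
                   subject_id: str | None = None) -> MocapRecording:
    """Read a long- or wide-format trajectory CSV onto a uniform frame grid.

    Long format requires header ``time,marker,x,y,z``; wide format requires
    ``time`` plus ``<marker>_x/_y/_z`` columns.  Sample times are snapped to
    the nearest frame of a uniform grid at ``sample_rate``; grid frames with
    no sample become the NaN sentinel.
    """
    schema = schema or KeypointSchema()
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    if cols[:5] == ["time", "marker", "x", "y", "z"]:
        return _read_long(df, schema, sample_rate, subject_id)
    if cols and cols[0] == "time" and any(c.endswith("_x") for c in cols[1:]):
        return _read_wide(df, schema, sample_rate, subject_id)
    raise FormatError(
        "expected long header time,marker,x,y,z or wide header time,<marker>_x,..."
    )


def _grid(times: np.ndarray, sample_rate: float):
    t0 = float(times.min())
    idx = np.rint((times - t0) * sample_rate).astype(int)
    n = int(idx.max()) + 1
    return t0, idx, n


def _read_long(df, schema, sample_rate, subject_id) -> MocapRecording:
    unknown = set(df["marker"].unique()) - set(schema.names)
    if unknown:
        raise SchemaError(f"markers not in schema: {sorted(unknown)}")
    times = df["time"].to_numpy(dtype=float)
    if np.isnan(times).any():
        raise DataError("time column contains missing values")
    for name, g in df.groupby("marker", sort=False):
        t = g["time"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"non-monotone time for marker {name}")
    t0, idx, n = _grid(times, sample_rate)
    pos = np.full((n, len(schema.names), 3), SENTINEL)
    kidx = np.array([schema.index(m) for m in df["marker"]])
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    pos[idx, kidx, :] = xyz
    return MocapRecording(subject_id, pos, sample_rate, t0, schema)


def _read_wide(df, schema, sample_rate, subject_id) -> MocapRecording:
    markers = []
    for c in df.columns[1:]:
        if c.endswith("_x"):
            markers.append(c[:-2])
    unknown = set(markers) - set(schema.names)
    if unknown:
        raise SchemaError(f"markers not in schema: {sorted(unknown)}")
    for m in markers:
        for ax in ("_x", "_y", "_z"):
            if m + ax not in df.columns:
                raise FormatError(f"wide format missing column {m + ax}")
    times = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise DataError("non-monotone time")
    t0, idx, n = _grid(times, sample_rate)
    pos = np.full((n, len(schema.names), 3), SENTINEL)
    for m in markers:
        k = schema.index(m)
        for a, ax in enumerate(("_x", "_y", "_z")):
            pos[idx, k, a] = df[m + ax].to_numpy(dtype=float)
    return MocapRecording(subject_id, pos, sample_rate, t0, schema)


def read_annotation(path) -> StageAnnotation:
    """Read a stage annotation CSV with header ``start,end,stage``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:3]) != ["start", "end", "stage"]:
        raise FormatError("expected header start,end,stage")
    return StageAnnotation(
        tuple((float(r.start), float(r.end), str(r.stage)) for r in df.itertuples())
    )


def write_annotation(ann: StageAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("start,end,stage\n")
        for s, e, g in ann.intervals:
            fh.write(f"{_fmt(s)},{_fmt(e)},{g}\n")
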