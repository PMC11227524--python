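"""Histogram-of-Joint-Displacement (HJD) pose descriptors.

Every joint position is re-expressed as a displacement from the Center
Pelvis in a body-anchored orthonormal frame (lateral axis through the
hips, longitudinal axis toward the head, up axis their cross product).
The direction of that displacement is binned on an equal-angle
azimuth x elevation grid (default 8 x 8 = 64 bins), and an HJD is the
fraction of window frames a joint spends in each direction bin.  Because
the frame is built entirely from the markers, the descriptor is exactly
invariant to rigid motions of the capture volume, and, being
direction-only, to uniform scaling of the skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MocapRecording, SchemaError, StageAnnotation

__all__ = [
    "BodyFrame",
    "SphericalBinning",
    "WindowSpec",
    "HJDVector",
    "FusedFeature",
    "Window",
    "JOINT_SETS",
    "FrameError",
    "FusionError",
    "WindowError",
    "center_on_pelvis",
    "body_frame",
    "body_frames",
    "to_spherical",
    "from_spherical",
    "assign_bin",
    "bin_indices",
    "compute_hjd",
    "fuse",
    "make_windows",
    "displacement_rate",
    "extract_dataset",
]

#: Fixed fusion orders for the composite feature sets; single-joint sets
#: feed the 1D/classic models only (2D architectures need >= 2 joints).
JOINT_SETS = {
    "Hands": ("LHand", "RHand"),
    "Knees": ("LKnee", "RKnee"),
    "Feet": ("LFoot", "RFoot"),
    "FullBody": ("LHand", "RHand", "LKnee", "RKnee", "LFoot", "RFoot"),
    "LHand": ("LHand",),
    "RHand": ("RHand",),
    "LKnee": ("LKnee",),
    "RKnee": ("RKnee",),
    "LFoot": ("LFoot",),
    "RFoot": ("RFoot",),
}


class FrameError(ValueError):
    """Degenerate marker geometry: no well-defined body frame."""


class FusionError(ValueError):
    """HJDs incompatible for fusion (window/scheme/order mismatch)."""


class WindowError(ValueError):
    """Empty or out-of-range analysis window."""


@dataclass(frozen=True)
class BodyFrame:
    """Right-handed orthonormal basis anchored at the Center Pelvis."""

    origin: np.ndarray
    e_lat: np.ndarray   # LHip -> RHip
    e_long: np.ndarray  # toward the head, orthogonalized against e_lat
    e_up: np.ndarray    # e_lat x e_long

    def rotation(self) -> np.ndarray:
        """World->body rotation matrix with basis vectors as rows."""
        return np.stack([self.e_lat, self.e_long, self.e_up])


@dataclass(frozen=True)
class SphericalBinning:
    """Equal-angle partition of direction space.

    Azimuth covers ``[-pi, pi)`` in ``n_az`` sectors measured from the
    lateral axis within the lateral-longitudinal plane; elevation covers
    ``[-pi/2, pi/2]`` in ``n_el`` bands toward the up axis, with the top
    edge assigned to the last band.  Bin index = ``el_idx * n_az + az_idx``.
    """

    n_az: int = 8
    n_el: int = 8

    def __post_init__(self):
        if self.n_az < 1 or self.n_el < 1:
            raise ValueError("n_az and n_el must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.n_az * self.n_el


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds.

    The training default (width 5 s, stride 4 s) realises 5-second windows
    with 1 second of overlap between consecutive windows; temporal-analysis
    curves use a much finer stride (down to one frame).
    """

    width: float = 5.0
    stride: float = 4.0

    def __post_init__(self):
        if not (0 < self.stride <= self.width):
            raise ValueError("require 0 < stride <= width")


@dataclass(frozen=True)
class Window:
    start: float
    width: float
    label: int | None  # integer stage label, None when unannotated


@dataclass(frozen=True)
class HJDVector:
    joint: str
    window: tuple[float, float]
    hist: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.hist, dtype=float)
        object.__setattr__(self, "hist", h)


@dataclass(frozen=True)
class FusedFeature:
    joint_set: str
    window: tuple[float, float]
    vector_1d: np.ndarray
    matrix_2d: np.ndarray


def center_on_pelvis(rec: MocapRecording) -> np.ndarray:
    """Per-frame joint displacements from the Center Pelvis, (F, K, 3)."""
    if "CenterPelvis" not in rec.schema.names:
        raise SchemaError("recording schema lacks CenterPelvis")
    root = rec.joint("CenterPelvis")
    return rec.positions - root[:, None, :]


def _frames_from_markers(lhip, rhip, head, pelvis):
    """Vectorized body-frame construction; inputs (F, 3)."""
    lat = rhip - lhip
    lat_n = np.linalg.norm(lat, axis=-1, keepdims=True)
    if np.any(lat_n < 1e-9):
        raise FrameError("LHip and RHip coincide")
    e_lat = lat / lat_n
    long = head - pelvis
    long = long - np.sum(long * e_lat, axis=-1, keepdims=True) * e_lat
    long_n = np.linalg.norm(long, axis=-1, keepdims=True)
    if np.any(long_n < 1e-9):
        raise FrameError("head direction collinear with the hip axis")
    e_long = long / long_n
    e_up = np.cross(e_lat, e_long)
    return e_lat, e_long, e_up


def body_frame(rec: MocapRecording, t: int) -> BodyFrame:
    """Body frame at frame index ``t``."""
    one = slice(t, t + 1)
    e_lat, e_long, e_up = _frames_from_markers(
        rec.joint("LHip")[one], rec.joint("RHip")[one],
        rec.joint("Head")[one], rec.joint("CenterPelvis")[one],
    )
    return BodyFrame(rec.joint("CenterPelvis")[t].copy(), e_lat[0], e_long[0], e_up[0])


def body_frames(rec: MocapRecording) -> np.ndarray:
    """World->body rotation matrices for every frame, shape (F, 3, 3)."""
    e_lat, e_long, e_up = _frames_from_markers(
        rec.joint("LHip"), rec.joint("RHip"),
        rec.joint("Head"), rec.joint("CenterPelvis"),
    )
    return np.stack([e_lat, e_long, e_up], axis=1)


def to_spherical(displacement: np.ndarray, frame: BodyFrame):
    """Spherical coordinates (azimuth, elevation, radius) in a body frame.

    Azimuth is measured from the lateral axis within the
    lateral-longitudinal plane and lies in ``[-pi, pi)``; elevation in
    ``[-pi/2, pi/2]`` toward the up axis; radius is the Euclidean norm in mm.
    """
    d = np.asarray(displacement, dtype=float)
    rho = float(np.linalg.norm(d))
    if rho == 0.0:
        raise ValueError("zero displacement has no direction")
    x = float(d @ frame.e_lat)
    y = float(d @ frame.e_long)
    z = float(d @ frame.e_up)
    alpha = np.arctan2(y, x)
    if alpha >= np.pi:  # atan2 returns (-pi, pi]; fold the closed top edge
        alpha = -np.pi
    theta = np.arcsin(np.clip(z / rho, -1.0, 1.0))
    return float(alpha), float(theta), rho


def from_spherical(alpha: float, theta: float, rho: float, frame: BodyFrame) -> np.ndarray:
    """Inverse of :func:`to_spherical`."""
    x = rho * np.cos(theta) * np.cos(alpha)
    y = rho * np.cos(theta) * np.sin(alpha)
    z = rho * np.sin(theta)
    return x * frame.e_lat + y * frame.e_long + z * frame.e_up


def assign_bin(alpha, theta, scheme: SphericalBinning):
    """Map direction angles to a bin index in ``[0, n_bins)``.

    ``az_idx = floor((alpha + pi) / (2 pi / n_az))`` and
    ``el_idx = floor((theta + pi/2) / (pi / n_el))``, with the closed top
    elevation edge clamped into the last band.
    """
    alpha = np.asarray(alpha, dtype=float)
    theta = np.asarray(theta, dtype=float)
    az = np.floor((alpha + np.pi) / (2 * np.pi / scheme.n_az)).astype(int)
    az = np.clip(az, 0, scheme.n_az - 1)
    el = np.floor((theta + np.pi / 2) / (np.pi / scheme.n_el)).astype(int)
    el = np.clip(el, 0, scheme.n_el - 1)
    idx = el * scheme.n_az + az
    return idx if idx.ndim else int(idx)


def bin_indices(rec: MocapRecording, scheme: SphericalBinning) -> np.ndarray:
    """Per-frame direction-bin index of every joint, shape (F, K), int.

    A frame where a joint coincides with the pelvis (undefined direction)
    inherits the previous frame's bin, or bin 0 at the start of the
    recording; in practice this only affects the CenterPelvis row itself.
    """
    disp = center_on_pelvis(rec)
    R = body_frames(rec)  # (F, 3, 3), rows are basis vectors
    local = np.einsum("fab,fkb->fka", R, disp)
    x, y, z = local[..., 0], local[..., 1], local[..., 2]
    rho = np.linalg.norm(local, axis=-1)
    zero = rho == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.arctan2(y, x)
        alpha = np.where(alpha >= np.pi, -np.pi, alpha)
        theta = np.arcsin(np.clip(np.where(zero, 0.0, z / np.where(zero, 1.0, rho)), -1, 1))
    idx = assign_bin(alpha, theta, scheme)
    if np.any(zero):
        idx = idx.copy()
        for k in range(idx.shape[1]):
            col_zero = zero[:, k]
            if not col_zero.any():
                continue
            prev = 0
            for f in range(idx.shape[0]):
                if col_zero[f]:
                    idx[f, k] = prev
                else:
                    prev = idx[f, k]
    return idx


def _window_frames(rec: MocapRecording, start: float, width: float):
    i0 = int(round((start - rec.start_time) * rec.sample_rate))
    i1 = i0 + int(round(width * rec.sample_rate))
    i0c, i1c = max(i0, 0), min(i1, rec.n_frames)
    if i1c <= i0c:
        raise WindowError(f"window [{start}, {start + width}) contains no frames")
    return i0c, i1c


def compute_hjd(
    rec: MocapRecording,
    joint: str,
    window: tuple[float, float],
    scheme: SphericalBinning | None = None,
    _bins: np.ndarray | None = None,
) -> HJDVector:
    """Occupancy histogram of one joint's displacement directions.

    ``hist[b]`` is the fraction of the window's frames whose body-frame
    displacement direction falls in bin ``b``; entries sum to one.
    ``_bins`` accepts a precomputed :func:`bin_indices` array to avoid
    recomputation across windows.
    """
    scheme = scheme or SphericalBinning()
    start, width = window
    i0, i1 = _window_frames(rec, start, width)
    if np.isnan(rec.positions[i0:i1]).any():
        raise ValueError("window contains missing samples; preprocess first")
    bins = _bins if _bins is not None else bin_indices(rec, scheme)
    col = bins[i0:i1, rec.schema.index(joint)]
    hist = np.bincount(col, minlength=scheme.n_bins).astype(float)
    return HJDVector(joint, (start, width), hist / hist.sum())


def fuse(hjds: list[HJDVector], joint_set: str) -> FusedFeature:
    """Concatenate (1D) and stack (2D) per-joint HJDs in the fixed order."""
    if joint_set not in JOINT_SETS:
        raise FusionError(f"unknown joint set {joint_set!r}")
    expect = JOINT_SETS[joint_set]
    got = tuple(h.joint for h in hjds)
    if got != expect:
        raise FusionError(f"joint order {got} != required {expect}")
    windows = {h.window for h in hjds}
    if len(windows) != 1:
        raise FusionError("all HJDs must share one window")
    sizes = {h.hist.size for h in hjds}
    if len(sizes) != 1:
        raise FusionError("all HJDs must share one binning scheme")
    mat = np.stack([h.hist for h in hjds])
    return FusedFeature(joint_set, hjds[0].window, mat.reshape(-1).copy(), mat)


def make_windows(
    rec: MocapRecording, ann: StageAnnotation, spec: WindowSpec | None = None
) -> list[Window]:
    """Sliding windows with pure-stage labels.

    The stride grid restarts at the beginning of every annotated interval,
    so a stage of length L yields exactly ``floor((L - width)/stride) + 1``
    labelled windows; candidate windows that would straddle a stage
    boundary are dropped by construction.  Spans not covered by the
    annotation yield unlabelled windows on their own grids.
    """
    spec = spec or WindowSpec()
    eps = 0.5 / rec.sample_rate
    t_lo = rec.start_time
    t_hi = rec.start_time + rec.duration
    out = []

    def emit(lo, hi, label):
        t = lo
        while t + spec.width <= hi + eps:
            out.append(Window(t, spec.width, label))
            t += spec.stride

    intervals = sorted(ann.intervals)
    cursor = t_lo
    for s, e, g in intervals:
        if s > cursor:
            emit(cursor, min(s, t_hi), None)
        emit(max(s, t_lo), min(e, t_hi), ann.label_map[g])
        cursor = max(cursor, e)
    if cursor < t_hi:
        emit(cursor, t_hi, None)
    out.sort(key=lambda w: w.start)
    return out


def displacement_rate(rec: MocapRecording, joint: str, interval: tuple[float, float]) -> float:
    """Average world-frame path rate of a joint over an interval, in m/min.

    The summed frame-to-frame Euclidean path length (mm) is divided by the
    time those steps span, then converted to metres per minute (a steady
    1 mm per frame at 100 Hz is 6 m/min).
    """
    i0, i1 = _window_frames(rec, interval[0], interval[1] - interval[0])
    if i1 - i0 < 2:
        raise WindowError("interval must span at least 2 frames")
    traj = rec.joint(joint)[i0:i1]
    steps = np.linalg.norm(np.diff(traj, axis=0), axis=1)
    seconds = (i1 - i0 - 1) / rec.sample_rate
    return float(steps.sum() / seconds) * 60.0 / 1000.0


def extract_dataset(
    rec: MocapRecording,
    ann: StageAnnotation,
    joints: tuple[str, ...],
    scheme: SphericalBinning | None = None,
    spec: WindowSpec | None = None,
):
    """HJD features for every labelled window of a recording.

    Returns ``(X, y, starts)`` with ``X`` of shape
    ``(n_windows, len(joints), n_bins)`` (row order = ``joints``),
    integer labels ``y`` and window start times.
    """
    scheme = scheme or SphericalBinning()
    spec = spec or WindowSpec()
    bins = bin_indices(rec, scheme)
    windows = [w for w in make_windows(rec, ann, spec) if w.label is not None]
    X = np.empty((len(windows), len(joints), scheme.n_bins))
    y = np.empty(len(windows), dtype=int)
    starts = np.empty(len(windows))
    for i, w in enumerate(windows):
        for j, joint in enumerate(joints):
            X[i, j] = compute_hjd(rec, joint, (w.start, w.width), scheme, _bins=bins).hist
        y[i] = w.label
        starts[i] = w.start
    return X, y, starts
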