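"""Trajectory cleaning: spike-outlier elimination and spline gap filling.

Optical marker data contain two artifact families: isolated spikes from
reflections/mislabelling, and contiguous gaps from occlusion.  Cleaning is
applied independently to each (marker, axis) scalar series:

1. Values outside ``mean +/- k*sigma`` of the series (k = 3 by default,
   bounds inclusive, mean and population sigma computed once over the
   original series) are replaced by the NaN sentinel.
2. All sentinels are then filled with a not-a-knot cubic spline through the
   remaining samples; leading/trailing gaps hold the nearest valid value
   rather than extrapolating the cubic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import MocapRecording

__all__ = [
    "PreprocessConfig",
    "EmptySeriesError",
    "InsufficientSupportError",
    "eliminate_outliers",
    "interpolate_gaps",
    "preprocess_recording",
]


class EmptySeriesError(ValueError):
    """Series contains fewer than two valid samples."""


class InsufficientSupportError(ValueError):
    """Too few anchor points for cubic interpolation."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning parameters.

    k_sigma
        Half-width of the acceptance band in standard deviations (default 3).
    spline_boundary
        Boundary rule passed to the cubic spline (default ``not-a-knot``).
    edge_fill
        Rule for gaps before the first / after the last valid sample;
        ``hold`` repeats the nearest valid value.
    """

    k_sigma: float = 3.0
    spline_boundary: str = "not-a-knot"
    edge_fill: str = "hold"

    def __post_init__(self):
        if not self.k_sigma > 0:
            raise ValueError("k_sigma must be positive")
        if self.edge_fill != "hold":
            raise ValueError("only edge_fill='hold' is supported")


def eliminate_outliers(values: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Replace values outside ``mean +/- k*sigma`` with NaN.

    The mean and the population standard deviation (1/N) are computed in a
    single pass over the valid samples of the *input* series and are not
    re-estimated after removals; the acceptance band is inclusive at both
    ends, so a constant series (sigma = 0) passes through unchanged.
    """
    cfg = cfg or PreprocessConfig()
    v = np.asarray(values, dtype=float)
    valid = ~np.isnan(v)
    if valid.sum() == 0:
        raise EmptySeriesError("series has no valid samples")
    if valid.sum() < 2:
        raise EmptySeriesError("need at least 2 valid samples")
    mean = v[valid].mean()
    sigma = v[valid].std(ddof=0)
    lo, hi = mean - cfg.k_sigma * sigma, mean + cfg.k_sigma * sigma
    out = v.copy()
    out[valid & ((v < lo) | (v > hi))] = np.nan
    return out


def interpolate_gaps(values: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Fill NaN runs with a cubic spline through the valid samples.

    Interior gaps are filled by a cubic spline (boundary rule per config)
    evaluated at the missing frame indices; gaps touching either end of the
    series hold the nearest valid value.  Valid samples are returned
    bit-identical.
    """
    cfg = cfg or PreprocessConfig()
    v = np.asarray(values, dtype=float)
    valid = np.flatnonzero(~np.isnan(v))
    if valid.size < 4:
        raise InsufficientSupportError(
            f"cubic interpolation needs >=4 anchors, got {valid.size}"
        )
    out = v.copy()
    missing = np.flatnonzero(np.isnan(v))
    if missing.size == 0:
        return out
    first, last = valid[0], valid[-1]
    interior = missing[(missing > first) & (missing < last)]
    if interior.size:
        spline = CubicSpline(valid, v[valid], bc_type=cfg.spline_boundary)
        out[interior] = spline(interior)
    out[missing[missing < first]] = v[first]
    out[missing[missing > last]] = v[last]
    return out


def preprocess_recording(
    rec: MocapRecording,
    cfg: PreprocessConfig | None = None,
    return_report: bool = False,
):
    """Clean every (marker, axis) series of a recording.

    Applies :func:`eliminate_outliers` then :func:`interpolate_gaps` to each
    scalar series independently; the result is sentinel-free.  With
    ``return_report=True`` also returns a per-marker QC table with the
    number of removed and filled samples.

    Raises :class:`InsufficientSupportError` naming the marker when a series
    has too few valid samples to support the spline — the analogue of
    excluding a subject whose marker is absent for a whole phase.
    """
    cfg = cfg or PreprocessConfig()
    pos = rec.positions.copy()
    rows = []
    for k, name in enumerate(rec.schema.names):
        removed = filled = 0
        for a, ax in enumerate("xyz"):
            series = pos[:, k, a]
            try:
                flagged = eliminate_outliers(series, cfg)
                n_rm = int(np.isnan(flagged).sum() - np.isnan(series).sum())
                clean = interpolate_gaps(flagged, cfg)
            except (EmptySeriesError, InsufficientSupportError) as err:
                raise InsufficientSupportError(f"marker {name} axis {ax}: {err}") from err
            removed += n_rm
            filled += int(np.isnan(flagged).sum())
            pos[:, k, a] = clean
        rows.append({"marker": name, "n_removed": removed, "n_filled": filled})
    out = MocapRecording(rec.subject_id, pos, rec.sample_rate, rec.start_time, rec.schema)
    if return_report:
        return out, pd.DataFrame(rows)
    return out
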