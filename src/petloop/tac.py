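"""SUVmax time-activity curves and endpoint uptake/metabolism metrics.

A dynamic FDG-PET acquisition samples each region of interest (ROI) at 11
time points, 15 minutes apart, spanning 0-150 min.  The per-frame signal is
SUVmax — the hottest voxel inside the ROI — optionally standardized by the
ipsilateral cerebellum, which is treated as a metabolically stable reference
region.  Three summary metrics describe each curve:

* ``peak_value``      — the maximum SUVmax over the 11 frames,
* ``pre_peak_rate``   — (peak - value at t=0) / peak time,
* ``post_peak_rate``  — (peak - value at t=150) / (150 - peak time),

both rates in SUV/min.  Ties at the peak resolve to the earliest frame; a
peak at t=0 has pre-peak rate 0 and a peak at t=150 has post-peak rate 0, so
both rates are total functions of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Acquisition grid: 11 frames at 15-min spacing, 0-150 min.
TIME_GRID = np.arange(0, 151, 15, dtype=float)
N_FRAMES = len(TIME_GRID)
TOTAL_MINUTES = float(TIME_GRID[-1])


@dataclass(frozen=True)
class TimeActivityCurve:
    """SUVmax of one ROI of one subject over the 11-frame acquisition."""

    roi: str
    side: str
    values: np.ndarray
    times: np.ndarray = field(default_factory=lambda: TIME_GRID.copy())
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)
        if values.shape != (N_FRAMES,):
            raise ValueError(
                f"expected {N_FRAMES} samples, got shape {values.shape}"
            )
        steps = np.diff(times)
        if times.shape != (N_FRAMES,) or not np.allclose(steps, 15.0):
            raise ValueError("time grid must be 0,15,...,150 min (11 points)")


@dataclass(frozen=True)
class UptakeMetrics:
    """Endpoint summary of one time-activity curve (rates in SUV/min)."""

    peak_value: float
    peak_time: float
    pre_peak_rate: float
    post_peak_rate: float


def injection_dose(weight_kg: float) -> float:
    """Tracer activity to inject, in mCi: body weight (kg) x 0.1 mCi/kg."""
    if weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {weight_kg}")
    return weight_kg * 0.1


def extract_suvmax_curve(
    volume,
    labels,
    roi: str,
    *,
    repeats: int = 3,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TimeActivityCurve:
    """Measure the per-frame SUVmax of one ROI, repeated and averaged.

    Each of ``repeats`` measurements takes the maximum voxel value inside the
    ROI for every frame.  ``jitter`` emulates small manual re-delineation
    between repeat measurements by randomly dropping that fraction of ROI
    voxels per repeat (at least one voxel always survives); with
    ``jitter=0`` all repeats are identical and the average equals a single
    measurement.

    Parameters
    ----------
    volume : phantom.DynamicVolume
        4D (x, y, z, t) activity grid with 11 frames.
    labels : phantom.RoiLabelMap
        Integer label map naming the ROIs.
    roi : str
        ROI key, e.g. ``"prefrontal_left"`` or ``"cerebellum_left"``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    data = volume.data
    if data.ndim != 4 or data.shape[3] != N_FRAMES:
        raise ValueError(
            f"volume must have {N_FRAMES} frames, got shape {data.shape}"
        )
    mask = labels.mask(roi)
    if not mask.any():
        raise KeyError(f"ROI {roi!r} has no voxels in the label map")

    voxel_values = data[mask, :]  # (n_voxels, n_frames)
    n_vox = voxel_values.shape[0]

    if jitter > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        measurements = np.empty((repeats, N_FRAMES))
        for r in range(repeats):
            keep = rng.random(n_vox) >= jitter
            if not keep.any():
                keep[rng.integers(n_vox)] = True
            measurements[r] = voxel_values[keep].max(axis=0)
        values = measurements.mean(axis=0)
    else:
        # without jitter every repeat is identical; the average is the value
        values = voxel_values.max(axis=0)
    name, side = labels.split_key(roi)
    return TimeActivityCurve(
        roi=name, side=side, values=values, times=volume.times.copy(),
    )


def normalize_to_cerebellum(
    curve: TimeActivityCurve, cerebellum: TimeActivityCurve
) -> TimeActivityCurve:
    """Standardize a curve by the ipsilateral cerebellum, frame by frame.

    SUVmax(standardized) = SUVmax(ROI) / SUVmax(same-side cerebellum) at each
    of the 11 time points.
    """
    if curve.side != cerebellum.side:
        raise ValueError(
            f"sides differ: {curve.side!r} vs {cerebellum.side!r}"
        )
    if not np.array_equal(curve.times, cerebellum.times):
        raise ValueError("time grids differ")
    if np.any(cerebellum.values <= 0):
        raise ZeroDivisionError("cerebellar SUVmax must be positive")
    return replace(
        curve, values=curve.values / cerebellum.values, normalized=True
    )


def uptake_metrics(curve: TimeActivityCurve) -> UptakeMetrics:
    """Peak, pre-peak uptake rate and post-peak metabolic rate of a curve."""
    values, times = curve.values, curve.times
    i_peak = int(np.argmax(values))  # argmax takes the earliest tie
    peak = float(values[i_peak])
    t_peak = float(times[i_peak])
    pre = 0.0 if i_peak == 0 else (peak - float(values[0])) / t_peak
    post = (
        0.0
        if i_peak == len(values) - 1
        else (peak - float(values[-1])) / (times[-1] - t_peak)
    )
    return UptakeMetrics(
        peak_value=peak, peak_time=t_peak, pre_peak_rate=pre,
        post_peak_rate=post,
    )
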