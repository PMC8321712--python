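"""Synthetic dynamic-PET phantoms, cohorts and color scenes.

Real dynamic FDG-PET data for the emotional-control loop (bilateral
prefrontal cortex, striatum, hippocampus, thalamus) are not publicly
deposited, so this module generates:

* 3D label maps with the 8 loop ROIs plus left/right cerebellum,
* 4D dynamic volumes whose per-ROI time-activity curves (TACs) are known
  exactly — one designated "hottest voxel" per ROI carries a piecewise-linear
  TAC so that SUVmax extraction is exact,
* cohorts of per-subject TAC metrics drawn from published group summaries
  (mean, SD per ROI x metric x group), and
* 2D color scenes with ground-truth masks, the fixtures for the saliency and
  segmentation stages.

The TAC shape is piecewise linear — a rise from the start value to the peak
followed by a fall to the end value — the simplest curve for which the
endpoint rate formulas (see :mod:`petloop.tac`) are exact rather than
approximate.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2lab

from .tac import N_FRAMES, TIME_GRID, TOTAL_MINUTES, UptakeMetrics

#: Loop ROI base names, in a fixed order used everywhere.
LOOP_ROIS = ("prefrontal", "striatum", "hippocampus", "thalamus")
SIDES = ("left", "right")
#: All ROI keys carrying a TAC (loop ROIs), e.g. "prefrontal_left".
LOOP_ROI_KEYS = tuple(f"{r}_{s}" for r in LOOP_ROIS for s in SIDES)
#: Label-map keys: the loop ROIs plus the cerebellar reference regions.
ALL_ROI_KEYS = LOOP_ROI_KEYS + ("cerebellum_left", "cerebellum_right")
METRICS = ("peak", "pre_rate", "post_rate")
#: Canonical integer labels of :func:`make_label_map` (left 1-5, right 6-10).
DEFAULT_LABEL_NAMES = {
    f"{base}_{side}": i + 1
    for i, (side, base) in enumerate(
        (s, b) for s in SIDES for b in LOOP_ROIS + ("cerebellum",)
    )
}


class PhantomError(ValueError):
    """Invalid phantom specification (sizing, colors, missing ROIs)."""


# ---------------------------------------------------------------------------
# TAC parameters


@dataclass(frozen=True)
class TacParams:
    """Endpoints of one piecewise-linear time-activity curve.

    ``start_value``/``end_value`` are the SUVmax at t=0 and t=150 min,
    ``peak_value`` the maximum, reached at ``peak_time`` (minutes, on the
    15-min acquisition grid).
    """

    start_value: float
    peak_value: float
    peak_time: float
    end_value: float

    def __post_init__(self) -> None:
        if self.peak_value < self.start_value or self.peak_value < self.end_value:
            raise PhantomError(
                f"peak {self.peak_value} must dominate start "
                f"{self.start_value} and end {self.end_value}"
            )
        if self.peak_time not in TIME_GRID:
            raise PhantomError(
                f"peak_time {self.peak_time} not on the 15-min grid"
            )

    def curve(self, times: np.ndarray = TIME_GRID) -> np.ndarray:
        """Evaluate the piecewise-linear TAC (rise, then fall) on a grid."""
        t = np.asarray(times, dtype=float)
        return np.interp(
            t,
            np.unique([0.0, self.peak_time, TOTAL_MINUTES]),
            _breakpoint_values(self),
        )

    def implied_metrics(self) -> UptakeMetrics:
        """Metrics the tac module should recover from a noiseless render."""
        pre = (
            0.0
            if self.peak_time == 0
            else (self.peak_value - self.start_value) / self.peak_time
        )
        post = (
            0.0
            if self.peak_time == TOTAL_MINUTES
            else (self.peak_value - self.end_value)
            / (TOTAL_MINUTES - self.peak_time)
        )
        return UptakeMetrics(self.peak_value, self.peak_time, pre, post)


def _breakpoint_values(p: TacParams) -> np.ndarray:
    if p.peak_time == 0.0:
        return np.array([p.peak_value, p.end_value])
    if p.peak_time == TOTAL_MINUTES:
        return np.array([p.start_value, p.peak_value])
    return np.array([p.start_value, p.peak_value, p.end_value])


def params_from_metrics(
    peak: float,
    pre_rate: float,
    post_rate: float,
    peak_time: float = 60.0,
    *,
    clip: str = "clip",
) -> TacParams:
    """Invert the endpoint rate formulas into curve parameters.

    ``start = peak - pre_rate * peak_time`` and
    ``end = peak - post_rate * (150 - peak_time)``.  Published group rates can
    imply negative start/end values (the printed rates are larger than the
    peaks allow over a 150-min window); with ``clip="clip"`` (default) those
    are clipped to 0 with a warning, with ``clip="raise"`` a
    :class:`PhantomError` is raised.
    """
    start = peak - pre_rate * peak_time
    end = peak - post_rate * (TOTAL_MINUTES - peak_time)
    lo = min(start, end)
    if lo < 0:
        if clip == "raise":
            raise PhantomError(
                f"metric targets imply a negative SUV ({lo:.3g}); "
                "reduce the rates or the peak time"
            )
        warnings.warn(
            "derived start/end SUV below 0; clipping to 0 — the rendered "
            "curve will not reproduce the requested rates",
            stacklevel=2,
        )
        start, end = max(start, 0.0), max(end, 0.0)
    # drawn rates can be negative in the tails; keep the peak dominant
    start, end = min(start, peak), min(end, peak)
    return TacParams(start, peak, peak_time, end)


# ---------------------------------------------------------------------------
# Label map and dynamic volume


@dataclass(frozen=True)
class RoiLabelMap:
    """Integer-labeled 3D volume naming the 10 phantom regions."""

    data: np.ndarray
    names: dict  # key -> positive integer label

    def mask(self, key: str) -> np.ndarray:
        if key not in self.names:
            raise KeyError(f"unknown ROI {key!r}; have {sorted(self.names)}")
        return self.data == self.names[key]

    @staticmethod
    def split_key(key: str) -> tuple[str, str]:
        name, _, side = key.rpartition("_")
        return name, side


@dataclass(frozen=True)
class DynamicVolume:
    """4D (x, y, z, t) activity grid with an 11-frame time grid."""

    data: np.ndarray
    times: np.ndarray = field(default_factory=lambda: TIME_GRID.copy())
    spacing: tuple = (2.0, 2.0, 2.0)  # mm, isotropic PET-like default


def make_label_map(dims: tuple[int, int, int] = (64, 64, 64)) -> RoiLabelMap:
    """Place the 10 phantom regions as disjoint cubes in a 3D grid.

    Left-side regions lie entirely in the left half of the x axis (and right
    regions in the right half), mirroring the bilateral layout the analysis
    assumes.  Anatomical realism is out of scope — the map only has to give
    each ROI a well-defined, disjoint voxel set.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or min(dims) < 16:
        raise PhantomError(f"each dimension must be >= 16, got {dims}")
    nx, ny, nz = dims
    half = max(1, min(dims) // 16)  # cube half-width
    # five (y, z) slots per hemisphere: 4 loop ROIs + cerebellum
    slots = [(0.25, 0.25), (0.75, 0.25), (0.25, 0.75), (0.75, 0.75), (0.5, 0.5)]
    data = np.zeros(dims, dtype=np.int16)
    names: dict[str, int] = {}
    for side, xc in (("left", nx // 4), ("right", (3 * nx) // 4)):
        for base, (fy, fz) in zip(LOOP_ROIS + ("cerebellum",), slots):
            label = DEFAULT_LABEL_NAMES[f"{base}_{side}"]
            yc, zc = int(fy * ny), int(fz * nz)
            region = data[
                xc - half : xc + half + 1,
                yc - half : yc + half + 1,
                zc - half : zc + half + 1,
            ]
            if region.size == 0 or region.any():
                raise PhantomError(f"dims {dims} too small to place regions")
            region[...] = label
            names[f"{base}_{side}"] = label
    return RoiLabelMap(data=data, names=names)


def render_dynamic_volume(
    params: dict[str, TacParams],
    labels: RoiLabelMap,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    cerebellum_value: float = 1.0,
    secondary_fraction: float = 0.8,
) -> DynamicVolume:
    """Paint per-ROI TACs into a 4D volume.

    One designated voxel per ROI (the lexicographically first) carries the
    exact TAC value each frame; the remaining ROI voxels carry
    ``secondary_fraction`` of it, so the ROI maximum is the designated voxel
    and SUVmax extraction recovers the prescribed curve exactly.  The
    cerebellum is painted constant over time (``cerebellum_value``),
    reflecting its role as a stable reference region.  Gaussian noise of SD
    ``noise_sd`` is added everywhere except the designated voxels.
    """
    missing = [k for k in LOOP_ROI_KEYS if k not in params]
    if missing:
        raise PhantomError(f"missing TAC parameters for ROIs: {missing}")
    if not 0 < secondary_fraction < 1:
        raise PhantomError("secondary_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    data = np.zeros(labels.data.shape + (N_FRAMES,), dtype=float)
    hot: list[tuple] = []
    for key in ALL_ROI_KEYS:
        mask = labels.mask(key)
        if key.startswith("cerebellum"):
            tac = np.full(N_FRAMES, float(cerebellum_value))
        else:
            tac = params[key].curve()
        data[mask, :] = secondary_fraction * tac
        voxel = tuple(np.argwhere(mask)[0])
        data[voxel] = tac
        hot.append(voxel)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
        for voxel, key in zip(hot, ALL_ROI_KEYS):
            if key.startswith("cerebellum"):
                data[voxel] = float(cerebellum_value)
            else:
                data[voxel] = params[key].curve()
    return DynamicVolume(data=data)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Targets for a simulated subject group.

    ``targets`` is a DataFrame with columns roi, side, metric, mean, sd —
    one row per loop ROI x metric (metrics: peak, pre_rate, post_rate, with
    rates in SUV/min).
    """

    targets: pd.DataFrame
    n_subjects: int
    seed: int = 0
    peak_time: float = 60.0
    clip: str = "clip"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise PhantomError("n_subjects must be >= 1")
        t = self.targets
        needed = {"roi", "side", "metric", "mean", "sd"}
        if not needed.issubset(t.columns):
            raise PhantomError(f"targets must have columns {sorted(needed)}")
        if (t["sd"] < 0).any():
            raise PhantomError("target SDs must be non-negative")


@dataclass(frozen=True)
class CohortSample:
    """A drawn cohort: tidy per-subject metrics plus derived curve params."""

    metrics: pd.DataFrame  # subject, roi, side, metric, value
    params: dict  # (subject, roi_key) -> TacParams


def sample_cohort(spec: CohortSpec) -> CohortSample:
    """Draw a cohort of per-subject TAC metrics from the group targets.

    Peak, pre-peak rate and post-peak rate are drawn independently per
    subject and ROI from normal distributions with the target mean/SD (the
    three are summarized separately in the source tables, so no joint
    structure is imposed).  Curve start/end values are then derived by
    inverting the rate formulas at ``spec.peak_time``; negative derived SUVs
    are clipped (or raise) per ``spec.clip``.  The same seed reproduces the
    cohort bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    lookup = {
        (r.roi, r.side, r.metric): (float(r.mean), float(r.sd))
        for r in spec.targets.itertuples()
    }
    rows, params = [], {}
    n_clipped = 0
    for subject in range(spec.n_subjects):
        for roi in LOOP_ROIS:
            for side in SIDES:
                drawn = {}
                for metric in METRICS:
                    try:
                        mean, sd = lookup[(roi, side, metric)]
                    except KeyError:
                        raise PhantomError(
                            f"no target for {roi} {side} {metric}"
                        ) from None
                    drawn[metric] = rng.normal(mean, sd) if sd > 0 else mean
                    rows.append(
                        dict(subject=subject, roi=roi, side=side,
                             metric=metric, value=drawn[metric])
                    )
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    params[(subject, f"{roi}_{side}")] = params_from_metrics(
                        max(drawn["peak"], 0.0),
                        drawn["pre_rate"],
                        drawn["post_rate"],
                        spec.peak_time,
                        clip=spec.clip,
                    )
                n_clipped += len(caught)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} subject-ROI curves had negative derived start/end "
            "SUVs clipped to 0; drawn metric values are reported unclipped",
            stacklevel=2,
        )
    return CohortSample(metrics=pd.DataFrame(rows), params=params)


# ---------------------------------------------------------------------------
# Color scenes


@dataclass(frozen=True)
class SceneSpec:
    """A simple figure/ground color scene with known mask.

    The foreground is a disc of ``fg_color`` on a ``bg_color`` field with
    optional additive Gaussian pixel noise; the ground-truth mask is the disc
    support.  Used as a controllable fixture for the saliency and
    segmentation stages.
    """

    shape: tuple[int, int] = (64, 64)
    center: tuple[float, float] = (32.0, 32.0)
    radius: float = 12.0
    fg_color: tuple[float, float, float] = (0.85, 0.25, 0.2)
    bg_color: tuple[float, float, float] = (0.15, 0.35, 0.6)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        cy, cx = self.center
        r = self.radius
        if r <= 0:
            raise PhantomError("radius must be positive")
        if not (r <= cy <= h - 1 - r and r <= cx <= w - 1 - r):
            raise PhantomError("foreground disc must lie inside the image")
        if np.allclose(self.fg_color, self.bg_color):
            raise PhantomError("foreground and background colors coincide")


def make_color_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a scene; returns (H x W x 3 float image in [0,1], bool mask)."""
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = spec.center
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.radius**2
    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.bg_color
    img[mask] = spec.fg_color
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), mask


def scene_lab_contrast(spec: SceneSpec) -> float:
    """Mean LAB distance between the pure fg and bg colors of a scene."""
    fg = rgb2lab(np.array(spec.fg_color, dtype=float)[None, None, :])
    bg = rgb2lab(np.array(spec.bg_color, dtype=float)[None, None, :])
    return float(np.linalg.norm(fg - bg))
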