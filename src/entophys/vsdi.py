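"""Quantification of voltage-sensitive dye imaging movies.

The pipeline mirrors standard slice-VSDI practice: trials are averaged,
each pixel is converted to a fractional fluorescence change dF/F against
the mean of the pre-stimulus baseline frames (sign-flipped so that
depolarization is positive for an absorption dye whose emission dims on
depolarization), the stack is smoothed with a small spatial box kernel and
a cubic (order-3 Savitzky-Golay) temporal filter, and responses are
quantified as per-ROI integrals, activated-pixel counts above a fixed
dF/F threshold, paired-pulse ratios at a 25-ms interval, and stripe
profiles versus distance from the stimulation electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import savgol_filter

from .config import AnalysisConfig, DEFAULT_CONFIG
from .exceptions import (
    DimensionMismatchError,
    EmptyROIError,
    UndefinedPPRError,
)


@dataclass
class VSDIMovie:
    """Raw-fluorescence stack (height x width x frames) with metadata."""

    frames: np.ndarray
    frame_interval_ms: float
    stim_frame: int
    n_baseline_frames: int
    trial_id: str = "0"
    condition: str = "normal_ACSF"
    stimulus: str = "single_0.2mA"
    stim_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DimensionMismatchError("frames must be (h, w, t)")
        if self.n_baseline_frames >= self.frames.shape[2]:
            raise ValueError("baseline window exceeds the movie")
        if self.stim_frame < self.n_baseline_frames:
            raise ValueError("stimulus precedes the baseline window")
        if np.any(self.frames < 0):
            raise ValueError("raw intensities must be non-negative")
        if not self.stim_frames:
            self.stim_frames = (self.stim_frame,)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]


@dataclass
class DffMovie:
    """dF/F stack in %, depolarization-positive, with provenance."""

    values: np.ndarray
    frame_interval_ms: float
    stim_frame: int
    n_baseline_frames: int
    stim_frames: tuple[int, ...] = ()
    condition: str = "normal_ACSF"
    stimulus: str = "single_0.2mA"
    masked: Optional[np.ndarray] = None        # pixels with F0 <= 0
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class ROISpec:
    """Named pixel sets plus an optional ordered stripe.

    ``rois`` maps a name to an (n, 2) array of (row, col) indices; the
    stripe is an ordered voxel sequence anchored at the stimulation
    electrode with a per-voxel distance (pixels, or um when a scale is
    given).
    """

    rois: dict[str, np.ndarray] = field(default_factory=dict)
    stripe: Optional[np.ndarray] = None            # (n, 2) ordered
    stripe_distances: Optional[np.ndarray] = None  # same length
    um_per_pixel: Optional[float] = None

    def names(self) -> list[str]:
        return list(self.rois)

    def pixels(self, name: str) -> np.ndarray:
        return self.rois[name]

    def validate(self, shape: tuple[int, int]) -> None:
        for name, idx in self.rois.items():
            if len(idx) == 0:
                raise EmptyROIError(f"ROI {name!r} is empty")
            if idx[:, 0].max() >= shape[0] or idx[:, 1].max() >= shape[1] \
                    or idx.min() < 0:
                raise DimensionMismatchError(
                    f"ROI {name!r} exceeds frame bounds"
                )
        if self.stripe_distances is not None:
            if np.any(np.diff(self.stripe_distances) < 0):
                raise ValueError("stripe distances must be non-decreasing")

    @classmethod
    def from_discs(
        cls, discs: dict[str, tuple[tuple[int, int], int]],
        shape: tuple[int, int],
    ) -> "ROISpec":
        """Build ROIs as filled discs {name: ((row, col), radius)}."""
        rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
        rois = {}
        for name, ((r, c), rad) in discs.items():
            mask = (rows - r) ** 2 + (cols - c) ** 2 <= rad**2
            rois[name] = np.argwhere(mask)
        return cls(rois=rois)

    @classmethod
    def stripe_from_segment(
        cls, origin: tuple[float, float], end: tuple[float, float],
        shape: tuple[int, int], um_per_pixel: Optional[float] = None,
    ) -> "ROISpec":
        """Ordered single-pixel stripe from the electrode to ``end``.

        Voxels outside the frame are truncated (with the remaining stripe
        kept), matching analysis of electrodes near the slice edge.
        """
        n = int(np.hypot(end[0] - origin[0], end[1] - origin[1])) + 1
        rr = np.linspace(origin[0], end[0], n)
        cc = np.linspace(origin[1], end[1], n)
        pix = np.column_stack([np.round(rr), np.round(cc)]).astype(int)
        # drop consecutive duplicates, keep order
        keep = np.r_[True, np.any(np.diff(pix, axis=0) != 0, axis=1)]
        pix = pix[keep]
        inside = (
            (pix[:, 0] >= 0) & (pix[:, 0] < shape[0])
            & (pix[:, 1] >= 0) & (pix[:, 1] < shape[1])
        )
        pix = pix[inside]
        dist = np.hypot(pix[:, 0] - origin[0], pix[:, 1] - origin[1])
        if um_per_pixel is not None:
            dist = dist * um_per_pixel
        return cls(stripe=pix, stripe_distances=dist,
                   um_per_pixel=um_per_pixel)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def average_trials(movies: Sequence[VSDIMovie]) -> VSDIMovie:
    """Pixelwise mean across trials (metadata must agree)."""
    if not movies:
        raise ValueError("no movies to average")
    ref = movies[0]
    for m in movies[1:]:
        if m.frames.shape != ref.frames.shape:
            raise DimensionMismatchError("trial geometry differs")
        if (m.frame_interval_ms, m.stim_frame, m.n_baseline_frames,
                m.condition, m.stimulus, m.stim_frames) != (
                ref.frame_interval_ms, ref.stim_frame,
                ref.n_baseline_frames, ref.condition, ref.stimulus,
                ref.stim_frames):
            raise DimensionMismatchError("trial metadata differs")
    mean = np.mean([m.frames for m in movies], axis=0)
    return replace(ref, frames=mean, trial_id=f"avg[{len(movies)}]")


def compute_dff(
    movie: VSDIMovie, config: AnalysisConfig = DEFAULT_CONFIG
) -> DffMovie:
    """Per-pixel dF/F in %, baseline = mean of the first baseline frames.

    With the default sign flip a fluorescence *decrease* on depolarization
    maps to positive dF/F.  Pixels with non-positive baseline are masked
    and carried as NaN.
    """
    f = movie.frames.astype(np.float64)
    f0 = f[:, :, :movie.n_baseline_frames].mean(axis=2)
    bad = f0 <= 0
    f0_safe = np.where(bad, 1.0, f0)
    sign = -1.0 if config.vsdi.sign_flip else 1.0
    dff = sign * (f - f0_safe[:, :, None]) / f0_safe[:, :, None] * 100.0
    if bad.any():
        dff[bad] = np.nan
    return DffMovie(
        values=dff,
        frame_interval_ms=movie.frame_interval_ms,
        stim_frame=movie.stim_frame,
        n_baseline_frames=movie.n_baseline_frames,
        stim_frames=movie.stim_frames,
        condition=movie.condition,
        stimulus=movie.stimulus,
        masked=bad if bad.any() else None,
        provenance={"sign_flip": config.vsdi.sign_flip,
                    "n_baseline_frames": movie.n_baseline_frames},
    )


def filter_movie(
    dff: DffMovie, config: AnalysisConfig = DEFAULT_CONFIG
) -> DffMovie:
    """Spatial box smoothing then cubic temporal smoothing.

    The temporal filter is an order-3 local polynomial (Savitzky-Golay)
    which preserves cubic time courses exactly; edges are handled by
    reflection.  Kernel sizes must be odd and smaller than the movie.
    """
    k = config.vsdi.spatial_kernel
    w = config.vsdi.temporal_window
    if k % 2 == 0 or w % 2 == 0:
        raise ValueError("kernel sizes must be odd")
    h, wd, t = dff.shape
    if k > min(h, wd) or w > t:
        raise DimensionMismatchError("kernel larger than the movie")
    out = uniform_filter(dff.values, size=(k, k, 1), mode="reflect")
    out = savgol_filter(out, w, config.vsdi.temporal_order, axis=2,
                        mode="mirror")
    prov = dict(dff.provenance)
    prov.update({"spatial_kernel": k, "temporal_window": w,
                 "temporal_order": config.vsdi.temporal_order})
    return replace(dff, values=out, provenance=prov)


def roi_integral(
    dff: DffMovie, rois: ROISpec, name: str,
    window: Optional[tuple[int, int]] = None,
) -> float:
    """Mean over ROI voxels of the per-voxel trapezoidal area (% * ms).

    The default window runs from stimulus onset to the end of the movie.
    """
    rois.validate(dff.shape[:2])
    idx = rois.pixels(name)
    if len(idx) == 0:
        raise EmptyROIError(name)
    lo, hi = window if window is not None else (dff.stim_frame,
                                                dff.shape[2])
    if not (0 <= lo < hi <= dff.shape[2]):
        raise ValueError("window outside the movie")
    traces = dff.values[idx[:, 0], idx[:, 1], lo:hi]
    area = np.trapezoid(traces, dx=dff.frame_interval_ms, axis=1)
    return float(np.nanmean(area))


def activated_area(
    dff: DffMovie, threshold: Optional[float] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> int:
    """Pixels whose post-stimulus peak dF/F strictly exceeds the threshold."""
    thr = config.vsdi.threshold_pct if threshold is None else threshold
    post = dff.values[:, :, dff.stim_frame:]
    peak = np.nanmax(post, axis=2)
    return int(np.count_nonzero(peak > thr))


@dataclass
class PPRResult:
    per_roi: dict[str, float]
    mean: float


def paired_pulse_ratio(
    dff: DffMovie, rois: ROISpec,
    roi_names: Optional[Sequence[str]] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> PPRResult:
    """Second-pulse over first-pulse amplitude per ROI, plus the mean.

    The first amplitude is the peak dF/F after the first stimulus (up to
    the second stimulus); the second amplitude is the peak in the window
    after the second stimulus measured relative to the dF/F level
    immediately before it, which separates overlapping responses.
    """
    rois.validate(dff.shape[:2])
    if len(dff.stim_frames) < 2:
        raise ValueError("paired-pulse analysis needs two stimulus frames")
    s1, s2 = dff.stim_frames[0], dff.stim_frames[1]
    win = int(round(config.vsdi.ppr_window_ms / dff.frame_interval_ms))
    names = list(roi_names) if roi_names is not None else rois.names()
    per: dict[str, float] = {}
    for name in names:
        idx = rois.pixels(name)
        trace = np.nanmean(dff.values[idx[:, 0], idx[:, 1], :], axis=0)
        a1 = float(np.max(trace[s1:s2]))
        if a1 <= 0:
            raise UndefinedPPRError(f"first-pulse amplitude <= 0 in {name!r}")
        pre2 = float(trace[s2 - 1])
        a2 = float(np.max(trace[s2:min(len(trace), s2 + win)]) - pre2)
        per[name] = a2 / a1
    return PPRResult(per_roi=per, mean=float(np.mean(list(per.values()))))


def stripe_profile(
    dff: DffMovie, rois: ROISpec, metric: str = "peak",
    window: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    """(distance, value) per stripe voxel, ordered by distance.

    ``metric`` is "peak" (post-stimulus maximum) or "integral"
    (trapezoidal area over the window).
    """
    if rois.stripe is None or rois.stripe_distances is None:
        raise ValueError("ROI spec carries no stripe")
    pix = rois.stripe
    dist = rois.stripe_distances
    lo, hi = window if window is not None else (dff.stim_frame,
                                                dff.shape[2])
    traces = dff.values[pix[:, 0], pix[:, 1], lo:hi]
    if metric == "peak":
        vals = np.nanmax(traces, axis=1)
    elif metric == "integral":
        vals = np.trapezoid(traces, dx=dff.frame_interval_ms, axis=1)
    else:
        raise ValueError("metric must be 'peak' or 'integral'")
    return np.column_stack([dist, vals])


@dataclass
class BladeQuantification:
    """Summary row for one slice/condition."""

    integrals: dict[str, float]
    activated_pixels: int
    ppr: Optional[PPRResult] = None


def quantify_dg(
    movies: Sequence[VSDIMovie], rois: ROISpec,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> BladeQuantification:
    """Full DG quantification: average, dF/F, filter, integrate, count, PPR."""
    avg = average_trials(movies)
    dff = filter_movie(compute_dff(avg, config), config)
    integrals = {name: roi_integral(dff, rois, name)
                 for name in rois.names()}
    pixels = activated_area(dff, config=config)
    ppr = None
    if len(dff.stim_frames) >= 2:
        blade_names = [n for n in rois.names() if n.endswith("blade")]
        if blade_names:
            ppr = paired_pulse_ratio(dff, rois, blade_names, config)
    return BladeQuantification(integrals=integrals,
                               activated_pixels=pixels, ppr=ppr)
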