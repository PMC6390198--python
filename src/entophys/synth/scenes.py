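"""Synthetic VSDI movies of dentate-gyrus responses with known ground truth.

A scene is a set of spatial response footprints (anisotropic Gaussians)
with a shared difference-of-exponentials temporal kernel and per-pulse
amplitude scaling.  Raw-fluorescence movies are produced with the dye's
sign convention (fluorescence decreases on depolarization), a constant
optical baseline, and independent Gaussian noise per trial — mirroring an
acquisition of 100 x 100 pixels at 1.0 ms/frame for 512 frames with the
stimulus 50 ms in and the first 50 frames as baseline.

Because the generating kernels are analytic, the per-ROI peak, integral,
paired-pulse ratio and activated-pixel count are computed in closed form
and returned alongside the movies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..vsdi import ROISpec, VSDIMovie


@dataclass
class GaussianFootprint:
    """Elliptical Gaussian response footprint, amplitude in % dF/F."""

    name: str
    center: tuple[float, float]      # (row, col), pixels
    sigma: tuple[float, float]       # (along, across), pixels
    angle_deg: float = 0.0
    peak_dff: float = 0.3            # % dF/F at the center, first pulse

    def amplitude_map(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        dr = rows - self.center[0]
        dc = cols - self.center[1]
        th = np.deg2rad(self.angle_deg)
        u = np.cos(th) * dr + np.sin(th) * dc
        v = -np.sin(th) * dr + np.cos(th) * dc
        return self.peak_dff * np.exp(
            -0.5 * ((u / self.sigma[0]) ** 2 + (v / self.sigma[1]) ** 2)
        )


@dataclass
class VSDIScene:
    """Generating description of a DG (or MEC) VSDI experiment."""

    footprints: list[GaussianFootprint]
    shape: tuple[int, int] = (100, 100)
    n_frames: int = 512
    frame_interval_ms: float = 1.0
    stim_frame: int = 50
    n_baseline_frames: int = 50
    onset_latency_ms: float = 2.0
    rise_ms: float = 1.5
    decay_ms: float = 5.0
    pulse_scales: tuple[float, ...] = (1.0,)   # per-pulse amplitude scaling
    pulse_interval_ms: float = 25.0
    baseline_level: float = 1000.0             # raw fluorescence counts
    noise_sigma: float = 0.3                   # raw counts, per pixel/frame
    dye_sign: int = -1                         # fluorescence drop = depol.
    condition: str = "normal_ACSF"
    stimulus: str = "single_0.2mA"

    def temporal_kernel(self, t_ms: np.ndarray) -> np.ndarray:
        """Unit-peak difference of exponentials, zero before onset."""
        t = t_ms - self.onset_latency_ms
        k = np.where(
            t > 0,
            np.exp(-np.maximum(t, 0.0) / self.decay_ms)
            - np.exp(-np.maximum(t, 0.0) / self.rise_ms),
            0.0,
        )
        # normalize to unit peak (closed-form argmax of the difference)
        tr, td = self.rise_ms, self.decay_ms
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        return k / peak

    def dff_timecourse(self) -> np.ndarray:
        """Noise-free % dF/F time course at unit spatial amplitude."""
        t = (np.arange(self.n_frames) - self.stim_frame) \
            * self.frame_interval_ms
        out = np.zeros(self.n_frames)
        for p, scale in enumerate(self.pulse_scales):
            out += scale * self.temporal_kernel(
                t - p * self.pulse_interval_ms
            )
        return out

    def dff_stack(self) -> np.ndarray:
        """Noise-free % dF/F movie (h, w, t)."""
        amp = np.zeros(self.shape)
        for fp in self.footprints:
            amp += fp.amplitude_map(self.shape)
        return amp[:, :, None] * self.dff_timecourse()[None, None, :]

    # ------------------------------------------------------------------
    # closed-form ground truth
    # ------------------------------------------------------------------

    def ground_truth(self, threshold_pct: float = 0.05,
                     rois: Optional[ROISpec] = None) -> dict:
        """Analytic per-ROI integral/peak, PPR, and activated-pixel count.

        The integral of the single-pulse kernel is
        peak_dff * (decay - rise) / peak_factor per unit amplitude
        (difference of exponential integrals), reported in %*ms over the
        whole post-stimulus period; the activated count is the number of
        pixels whose noise-free peak dF/F strictly exceeds the threshold.
        """
        amp = np.zeros(self.shape)
        for fp in self.footprints:
            amp += fp.amplitude_map(self.shape)
        tc = self.dff_timecourse()
        peak_tc = float(np.max(tc))

        tr, td = self.rise_ms, self.decay_ms
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        peak_factor = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        kernel_integral = (td - tr) / peak_factor * float(
            np.sum(self.pulse_scales)
        )

        gt: dict = {
            "kernel_integral_per_unit_amplitude": kernel_integral,
            "activated_pixels": int(np.count_nonzero(
                amp * peak_tc > threshold_pct)),
            "ppr": (self.pulse_scales[1] / self.pulse_scales[0]
                    if len(self.pulse_scales) >= 2 else None),
            "footprint_peaks": {fp.name: fp.peak_dff
                                for fp in self.footprints},
        }
        if rois is not None:
            roi_integral = {}
            roi_peak = {}
            for name in rois.names():
                idx = rois.pixels(name)
                mean_amp = float(np.mean(amp[idx[:, 0], idx[:, 1]]))
                roi_integral[name] = mean_amp * kernel_integral
                roi_peak[name] = mean_amp * peak_tc
            gt["roi_integral"] = roi_integral
            gt["roi_peak"] = roi_peak
        return gt


def generate_vsdi_movie(
    scene: VSDIScene, n_trials: int = 8, seed: Optional[int] = 0
) -> list[VSDIMovie]:
    """Raw-fluorescence trial movies for a scene.

    Each trial is baseline * (1 + dye_sign * dff/100) plus independent
    Gaussian noise; eight trials mirror the averaging used during
    acquisition.
    """
    if scene.stim_frame < scene.n_baseline_frames:
        raise ValueError("stimulus must not precede the baseline window")
    rng = np.random.default_rng(seed)
    dff = scene.dff_stack()
    clean = scene.baseline_level * (1.0 + scene.dye_sign * dff / 100.0)
    movies = []
    for trial in range(n_trials):
        noise = rng.normal(0.0, scene.noise_sigma,
                           size=clean.shape).astype(np.float32)
        frames = clean.astype(np.float32) + noise
        movies.append(VSDIMovie(
            frames=frames,
            frame_interval_ms=scene.frame_interval_ms,
            stim_frame=scene.stim_frame,
            n_baseline_frames=scene.n_baseline_frames,
            trial_id=str(trial),
            condition=scene.condition,
            stimulus=scene.stimulus,
            stim_frames=tuple(
                scene.stim_frame
                + int(round(p * scene.pulse_interval_ms
                            / scene.frame_interval_ms))
                for p in range(len(scene.pulse_scales))
            ),
        ))
    return movies


def dg_scene(
    exposed_peak: float = 0.30,
    enclosed_peak: float = 0.18,
    ca3_peak: float = 0.08,
    pulse_scales: tuple[float, ...] = (1.0,),
    noise_sigma: float = 0.3,
    condition: str = "normal_ACSF",
    stimulus: str = "single_0.2mA",
) -> tuple[VSDIScene, ROISpec]:
    """Two-blade dentate-gyrus scene with a CA3 satellite.

    Defaults approximate a wild-type response: the exposed (infrapyramidal)
    blade responds more strongly than the enclosed blade, and footprint
    sizes are set so the single-pulse activated area at the standard
    0.05 % threshold is of order 1.5-2k pixels, as in 9-month control
    slices.  ROIs are centered discs inside each footprint.
    """
    footprints = [
        GaussianFootprint("exposed_blade", center=(28.0, 30.0),
                          sigma=(13.6, 6.9), angle_deg=30.0,
                          peak_dff=exposed_peak),
        GaussianFootprint("enclosed_blade", center=(70.0, 58.0),
                          sigma=(12.9, 6.0), angle_deg=-25.0,
                          peak_dff=enclosed_peak),
        GaussianFootprint("CA3", center=(40.0, 84.0), sigma=(5.0, 4.2),
                          peak_dff=ca3_peak),
    ]
    scene = VSDIScene(footprints=footprints, pulse_scales=pulse_scales,
                      noise_sigma=noise_sigma, condition=condition,
                      stimulus=stimulus)
    rois = ROISpec.from_discs(
        {
            "exposed_blade": ((28, 30), 5),
            "enclosed_blade": ((70, 58), 5),
            "CA3": ((40, 84), 4),
        },
        shape=scene.shape,
    )
    return scene, rois
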