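"""Synthetic perfusion stacks and vessel movies with known ground truth.

These generators make every pipeline stage testable without any recorded
data.  They emulate the study conditions the pipelines are built for:

* LSCI: three 60-s whisker stimulations separated by 120-s rest intervals,
  a spatially Gaussian response blob on a drifting baseline, multiplicative
  (speckle-like) noise, sampled at 4.4 Hz.
* Two-photon: a bright fluorescent tube (plasma-labelled vessel) on a dark
  background, one frame per 2 s, whose width dilates transiently; optional
  dark intraluminal blobs (passing erythrocytes), jittered frames (motion
  artifacts) and additive Gaussian noise.

Both generators are pure functions of their config (seed included) and
return a ground-truth record sufficient to score every pipeline output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "LSCISimConfig",
    "VesselSimConfig",
    "simulate_lsci",
    "simulate_vessel",
    "default_lsci_config",
    "default_vessel_config",
]


@dataclass
class LSCISimConfig:
    """Configuration of a synthetic LSCI perfusion stack.

    ``stimulations`` is a list of ``(onset_s, duration_s, amplitude_percent,
    ramp_s)``; onsets must be spaced by at least the duration plus 60 s so
    that each epoch keeps an undisturbed baseline window.  ``drift`` is
    ``(type, magnitude)`` with magnitude in percent of baseline per 10 min.
    ``blob`` is ``((row, col), sigma_px)`` for the Gaussian spatial response
    footprint.  Noise is multiplicative Gaussian (speckle-like), sigma in
    percent of the local signal.
    """

    shape: tuple[int, int, int] = (2640, 64, 64)
    sampling_rate_hz: float = 4.4
    baseline_level: float = 1000.0
    drift: tuple[str, float] = ("linear", 5.0)
    stimulations: Sequence[tuple[float, float, float, float]] = field(
        default_factory=lambda: [(60.0, 60.0, 10.0, 0.0), (240.0, 60.0, 10.0, 0.0), (420.0, 60.0, 10.0, 0.0)]
    )
    blob: tuple[tuple[float, float], float] = ((32.0, 32.0), 10.0)
    noise_sigma_percent: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        onsets = sorted(s[0] for s in self.stimulations)
        durs = {s[0]: s[1] for s in self.stimulations}
        for a, b in zip(onsets, onsets[1:]):
            if b - a < durs[a] + 60.0:
                raise ValueError("stimulation onsets must be spaced >= duration + 60 s")
        if any(s[2] < 0 for s in self.stimulations):
            raise ValueError("stimulation amplitudes must be >= 0")
        if self.drift[0] not in ("linear", "sinusoid"):
            raise ValueError(f"unknown drift type {self.drift[0]!r}")


@dataclass
class VesselSimConfig:
    """Configuration of a synthetic two-photon vessel movie.

    ``tube`` is ``(orientation_deg, width_voxels, intensity)``; the tube runs
    through the image centre, which sits on a voxel boundary so an
    even-width tube covers whole voxels exactly.  ``dilations`` is a list of
    ``(onset_frame, duration_frames, amplitude_percent, rise_frames)``.
    ``erythrocyte_rate`` is the expected number of dark intraluminal blobs
    per frame; ``jitter_frames`` are indices given a rigid translation;
    noise is additive Gaussian with ``noise_sigma`` in intensity units.
    """

    shape: tuple[int, int, int] = (240, 128, 128)
    frame_interval_s: float = 2.0
    tube: tuple[float, float, float] = (0.0, 40.0, 200.0)
    background_level: float = 10.0
    dilations: Sequence[tuple[int, int, float, int]] = field(
        default_factory=lambda: [(40, 30, 20.0, 5), (130, 30, 20.0, 5)]
    )
    erythrocyte_rate: float = 0.0
    jitter_frames: Sequence[int] = ()
    noise_sigma: float = 9.5
    pixel_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        width = self.tube[1]
        max_dil = max((d[2] for d in self.dilations), default=0.0)
        if width * (1 + max_dil / 100.0) >= min(self.shape[1:]) / 2:
            raise ValueError("tube width plus maximal dilation must stay below min(H, W)/2")


def _response_timecourse(
    t: np.ndarray, onset: float, duration: float, amplitude_pct: float, ramp: float
) -> np.ndarray:
    """Ramp to amplitude then boxcar, as a fraction of baseline."""
    resp = np.zeros_like(t)
    inside = (t >= onset) & (t < onset + duration)
    if ramp > 0:
        rise = np.clip((t - onset) / ramp, 0.0, 1.0)
    else:
        rise = 1.0
    resp[inside] = (amplitude_pct / 100.0) * (rise[inside] if ramp > 0 else 1.0)
    return resp


def simulate_lsci(config: LSCISimConfig) -> tuple[np.ndarray, dict]:
    """Generate a synthetic LSCI stack and its ground truth.

    Per pixel: ``baseline * (1 + drift(t) + blob(r, c) * response(t)) *
    (1 + eps)`` with ``eps ~ N(0, noise_sigma)``.  Deterministic per seed.
    """
    T, H, W = config.shape
    fs = config.sampling_rate_hz
    t = np.arange(T) / fs
    dtype_t = t[:, None, None]

    dkind, dmag = config.drift
    if dkind == "linear":
        drift = (dmag / 100.0) * (t / 600.0)
    else:  # sinusoid, one cycle per 10 min
        drift = (dmag / 100.0) * np.sin(2 * np.pi * t / 600.0)

    resp = np.zeros(T)
    for onset, dur, amp, ramp in config.stimulations:
        resp += _response_timecourse(t, onset, dur, amp, ramp)

    (br, bc), sigma = config.blob
    rr, cc = np.mgrid[0:H, 0:W]
    blob = np.exp(-((rr - br) ** 2 + (cc - bc) ** 2) / (2 * sigma**2))

    clean = config.baseline_level * (
        1.0 + drift[:, None, None] + blob[None] * resp[:, None, None]
    )
    rng = np.random.default_rng(config.seed)
    if config.noise_sigma_percent > 0:
        clean = clean * (1.0 + rng.normal(0.0, config.noise_sigma_percent / 100.0, clean.shape))
    stack = clean.astype(np.float32)

    truth = {
        "onsets_s": [s[0] for s in config.stimulations],
        "durations_s": [s[1] for s in config.stimulations],
        "amplitudes_percent": [s[2] for s in config.stimulations],
        "ramps_s": [s[3] for s in config.stimulations],
        "blob_center": list(config.blob[0]),
        "blob_sigma_px": config.blob[1],
        "baseline_level": config.baseline_level,
        "sampling_rate_hz": fs,
        "drift": list(config.drift),
        "config": asdict(config),
    }
    return stack, truth


def _dilation_timecourse(n_frames: int, dilations) -> np.ndarray:
    """Per-frame dilation in percent: linear rise, plateau, linear fall."""
    dil = np.zeros(n_frames)
    for onset, duration, amp, rise in dilations:
        for k in range(n_frames):
            rel = k - onset
            if rel < 0 or rel >= duration:
                continue
            if rise > 0 and rel < rise:
                frac = (rel + 1) / rise  # reaches full amplitude at frame onset+rise-1
            elif rise > 0 and rel >= duration - rise:
                frac = (duration - rel) / rise
            else:
                frac = 1.0
            dil[k] = max(dil[k], amp * min(frac, 1.0))
    return dil


def simulate_vessel(config: VesselSimConfig) -> tuple[np.ndarray, dict]:
    """Generate a synthetic vessel movie and its ground truth.

    The tube is rendered with linear anti-aliasing of the perpendicular
    distance to its axis; its width follows ``w(t) = w0 * (1 +
    dilation(t)/100)``.  Deterministic per seed.
    """
    T, H, W = config.shape
    theta, w0, intensity = config.tube
    bg = config.background_level
    rng = np.random.default_rng(config.seed)

    # perpendicular distance to the tube axis through the image centre
    # (centre on a voxel boundary: (H/2 - 0.5) is the last row of the top half)
    cr, cc_ = (H - 1) / 2.0, (W - 1) / 2.0
    rr, cc = np.mgrid[0:H, 0:W]
    th = np.deg2rad(theta)
    # 0 deg: tube along the column axis; distance is measured perpendicular
    # to the axis direction (sin th, cos th) in (row, col) coordinates
    dist = np.abs(np.cos(th) * (rr - cr) - np.sin(th) * (cc - cc_))

    dil = _dilation_timecourse(T, config.dilations)
    widths = w0 * (1.0 + dil / 100.0)

    movie = np.empty((T, H, W), dtype=float)
    for k in range(T):
        coverage = np.clip(widths[k] / 2.0 + 0.5 - dist, 0.0, 1.0)
        frame = bg + (intensity - bg) * coverage
        if config.erythrocyte_rate > 0:
            for _ in range(rng.poisson(config.erythrocyte_rate)):
                er = rng.uniform(0, H)
                ec = rng.uniform(0, W)
                if np.abs(np.cos(th) * (er - cr) - np.sin(th) * (ec - cc_)) < widths[k] / 2 - 1:
                    blob = np.exp(-(((rr - er) ** 2 + (cc - ec) ** 2) / (2 * 1.5**2)))
                    frame = frame - (intensity - bg) * 0.9 * blob * (coverage > 0)
        movie[k] = frame
    for k in config.jitter_frames:
        movie[k] = np.roll(np.roll(movie[k], 7, axis=0), 4, axis=1)
    if config.noise_sigma > 0:
        movie = movie + rng.normal(0.0, config.noise_sigma, movie.shape)

    truth = {
        "width_voxels_per_frame": widths.tolist(),
        "dilation_percent_per_frame": dil.tolist(),
        "dilations": [list(d) for d in config.dilations],
        "tube": list(config.tube),
        "jitter_frames": list(config.jitter_frames),
        "frame_interval_s": config.frame_interval_s,
        "pixel_size_um": config.pixel_size_um,
        "config": asdict(config),
    }
    return movie.astype(np.float32), truth


def default_lsci_config(**overrides) -> LSCISimConfig:
    """The standard synthetic whisker-stimulation cohort configuration."""
    return LSCISimConfig(**overrides)


def default_vessel_config(**overrides) -> VesselSimConfig:
    """The standard synthetic vessel-dilation movie configuration."""
    return VesselSimConfig(**overrides)
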