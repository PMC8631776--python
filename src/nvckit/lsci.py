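"""Stimulation-locked analysis of laser speckle contrast imaging (LSCI) stacks.

The pipeline turns a drifting, noisy perfusion movie into baseline-normalized
response maps and scalar metrics:

1. rigid integer-pixel re-alignment of frames (brain motion from heart beat
   and breathing);
2. zero-phase Chebyshev Type I high-pass filtering of the ROI-mean trace to
   remove slow signal drift (cut-off 0.004 Hz);
3. automatic stimulation-period detection by Otsu thresholding of the
   filtered trace;
4. per-pixel percent change: the response window (+10 to +30 s after onset,
   skipping the ramp-like initial rise) against the per-epoch baseline window
   (-40 to -10 s before onset);
5. crop around the circular ROI and resample to a fixed 120 x 120 grid so
   maps from different animals can be averaged into group heat maps.

Detection runs on the filtered ROI-mean trace; response amplitudes are
computed on raw per-pixel traces normalized to the per-epoch local baseline
(local normalization already cancels slow drift).  Missing pixels are NaN and
propagate through averaging as "mean over available values".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal
from skimage.transform import resize

from .otsu import otsu_threshold

__all__ = [
    "ROIMask",
    "FilterSpec",
    "StimulationEpoch",
    "ResponseWindows",
    "ResponseMap",
    "ScalarResponse",
    "STANDARD_MAP_SIZE",
    "align_frames",
    "design_drift_filter",
    "filter_trace",
    "roi_mean_trace",
    "otsu_threshold",
    "detect_stimulations",
    "epochs_from_markers",
    "compute_response_map",
    "standardize_map",
    "average_maps",
    "normalize_trace",
    "scalar_metrics",
]

#: Side length of the fixed grid every response map is resampled to, which
#: makes maps from different animals directly averageable.
STANDARD_MAP_SIZE = 120


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ROIMask:
    """Circular region of interest around the exposed cortex.

    ``mask`` is True exactly where the distance to ``center_px`` is at most
    ``radius_px``; at least 9 pixels must be inside.
    """

    center_px: tuple[float, float]
    radius_px: float
    mask: np.ndarray

    @classmethod
    def circular(
        cls, shape: tuple[int, int], center_px: tuple[float, float], radius_px: float
    ) -> "ROIMask":
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        dist2 = (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2
        mask = dist2 <= radius_px**2
        if mask.sum() < 9:
            raise ValueError(
                f"ROI of radius {radius_px} at {center_px} covers only {mask.sum()} pixels (<9)"
            )
        return cls(center_px=tuple(center_px), radius_px=float(radius_px), mask=mask)

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1), half-open, of the square box around the circle."""
        r0 = int(np.floor(self.center_px[0] - self.radius_px))
        r1 = int(np.ceil(self.center_px[0] + self.radius_px)) + 1
        c0 = int(np.floor(self.center_px[1] - self.radius_px))
        c1 = int(np.ceil(self.center_px[1] + self.radius_px)) + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1 = min(r1, self.mask.shape[0])
        c1 = min(c1, self.mask.shape[1])
        return r0, r1, c0, c1


@dataclass
class FilterSpec:
    """High-pass drift filter: Chebyshev Type I, order 2, 0.004 Hz edge."""

    cutoff_hz: float = 0.004
    order: int = 2
    passband_ripple_db: float = 0.5
    mode: str = "highpass"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not self.cutoff_hz > 0:
            raise ValueError("cutoff_hz must be > 0")
        if self.mode != "highpass":
            raise ValueError("only high-pass drift filtering is supported")


@dataclass
class StimulationEpoch:
    """One detected or marker-defined stimulation period, in seconds."""

    onset_s: float
    offset_s: float
    source: Literal["otsu", "marker"] = "otsu"

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(f"offset_s {self.offset_s} must be > onset_s {self.onset_s}")


@dataclass
class ResponseWindows:
    """Analysis windows relative to the detected stimulation onset (seconds).

    The response window starts at +10 s to skip the ramp-like initial rise of
    the perfusion signal; the baseline window ends 10 s before onset.
    """

    response_window_s: tuple[float, float] = (10.0, 30.0)
    baseline_window_s: tuple[float, float] = (-40.0, -10.0)

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window_s
        r0, r1 = self.response_window_s
        if not (b0 < b1 <= 0):
            raise ValueError("baseline window must lie entirely before onset")
        if not (0 <= r0 < r1):
            raise ValueError("response window must lie entirely after onset")


@dataclass
class ResponseMap:
    """Per-pixel percent perfusion change on the fixed 120 x 120 grid."""

    values: np.ndarray
    n_stimulations_averaged: int = 1
    n_animals_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (STANDARD_MAP_SIZE, STANDARD_MAP_SIZE):
            raise ValueError(
                f"standardized maps are {STANDARD_MAP_SIZE}x{STANDARD_MAP_SIZE}, "
                f"got {self.values.shape}"
            )


@dataclass
class ScalarResponse:
    """Scalar summary of one stimulation-locked normalized response trace."""

    peak_percent: float
    slope_percent_per_s: float
    auc_percent_s: float


# ---------------------------------------------------------------------------
# frame alignment
# ---------------------------------------------------------------------------

def _shift_with_nan(frame: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate a frame by integer pixels, exposing NaN at the border."""
    out = np.full_like(frame, np.nan, dtype=float)
    h, w = frame.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    dst_r = slice(max(0, dr), min(h, h + dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = frame[src_r, src_c]
    return out


def align_frames(
    stack: np.ndarray,
    reference: int | str = "median",
    search_radius_px: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly re-align every frame to a reference by integer-pixel translation.

    The shift maximizing the normalized cross-correlation with the reference
    (the pixelwise median frame by default) is searched within
    ``search_radius_px`` pixels.  Border pixels exposed by shifting are NaN.

    Returns ``(aligned_stack, shifts)`` with ``shifts[k] = (dr, dc)`` being the
    correction applied to frame ``k``.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (T, rows, cols) stack with at least 2 frames")
    ref = np.median(stack, axis=0) if reference == "median" else stack[int(reference)]
    ref0 = ref - ref.mean()
    ref_norm = np.linalg.norm(ref0)
    h, w = ref.shape
    r = int(search_radius_px)

    aligned = np.empty_like(stack)
    shifts = np.zeros((stack.shape[0], 2), dtype=int)
    for k, frame in enumerate(stack):
        f0 = frame - frame.mean()
        fnorm = np.linalg.norm(f0)
        if fnorm == 0 or ref_norm == 0:
            warnings.warn(f"frame {k}: zero variance, using zero shift")
            aligned[k] = frame
            continue
        # full cross-correlation; with mean-subtracted unit-scale frames the
        # argmax matches normalized cross-correlation for rigid translations
        corr = signal.fftconvolve(f0, ref0[::-1, ::-1], mode="full")
        cr, cc = h - 1, w - 1  # zero-shift position
        window = corr[
            max(0, cr - r) : cr + r + 1,
            max(0, cc - r) : cc + r + 1,
        ]
        ir, ic = np.unravel_index(np.argmax(window), window.shape)
        dr = (max(0, cr - r) + ir) - cr
        dc = (max(0, cc - r) + ic) - cc
        # corr peak at (dr, dc) means frame content sits at +(dr, dc) relative
        # to the reference; the correction applied is the negative
        shifts[k] = (-dr, -dc)
        aligned[k] = _shift_with_nan(frame, -dr, -dc)
    return aligned, shifts


# ---------------------------------------------------------------------------
# drift filtering
# ---------------------------------------------------------------------------

def design_drift_filter(
    spec: FilterSpec, sampling_rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Design the high-pass drift filter, returning ``(b, a)`` coefficients.

    The coefficients are meant for forward-backward (zero-phase) application;
    see :func:`filter_trace`.
    """
    nyquist = sampling_rate_hz / 2.0
    if not spec.cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {nyquist} Hz"
        )
    return signal.cheby1(
        spec.order,
        spec.passband_ripple_db,
        spec.cutoff_hz,
        btype="highpass",
        fs=sampling_rate_hz,
    )


def filter_trace(
    trace: np.ndarray, spec: FilterSpec, sampling_rate_hz: float
) -> np.ndarray:
    """Zero-phase high-pass filter a 1-D trace.

    The squared Chebyshev magnitude response — the transfer function of a
    forward-backward (filtfilt) pass — is applied in the frequency domain on
    an even (mirror) extension of the trace.  At a 0.004 Hz cutoff the
    impulse response spans hundreds of samples, and time-domain edge
    padding would leave visible asymmetric transients; the mirror-extension
    route is transient-free, exactly symmetric for symmetric inputs, and
    annihilates the DC component.
    """
    b, a = design_drift_filter(spec, sampling_rate_hz)
    x = np.asarray(trace, dtype=float)
    # subtract the straight line through the endpoints first: a mirror
    # extension folds a drift ramp into spurious end transients, while the
    # removed line is itself pure drift and is deliberately not re-added
    n = x.size
    line = x[0] + (x[-1] - x[0]) * np.arange(n) / max(n - 1, 1)
    resid = x - line
    ext = np.concatenate([resid, resid[::-1]])
    freqs = np.fft.rfftfreq(ext.size, d=1.0 / sampling_rate_hz)
    _, h = signal.freqz(b, a, worN=freqs, fs=sampling_rate_hz)
    out = np.fft.irfft(np.fft.rfft(ext) * np.abs(h) ** 2, n=ext.size)
    return out[:n]


def roi_mean_trace(stack: np.ndarray, roi: ROIMask) -> np.ndarray:
    """Mean perfusion inside the ROI per frame (NaN-aware)."""
    flat = np.asarray(stack, dtype=float)[:, roi.mask]
    return np.nanmean(flat, axis=1)


# ---------------------------------------------------------------------------
# stimulation detection
# ---------------------------------------------------------------------------

def detect_stimulations(
    trace: np.ndarray,
    sampling_rate_hz: float,
    min_duration_s: float = 5.0,
    merge_gap_s: float = 2.0,
    nbins: int = 256,
    time_origin_s: float = 0.0,
    plot_path=None,
) -> list[StimulationEpoch]:
    """Detect stimulation periods on a (filtered) ROI-mean trace.

    An Otsu threshold over a 256-bin histogram of the trace separates
    stimulated from resting perfusion.  Maximal supra-threshold runs are the
    candidate epochs; sub-threshold gaps shorter than ``merge_gap_s`` are
    bridged, and runs shorter than ``min_duration_s`` discarded.  The onset is
    the time of the first supra-threshold sample.

    A degenerate (near-constant) trace, where the between-class variance
    vanishes, yields an empty list with a warning.  When ``plot_path`` is
    given, a verification plot (trace, threshold, detected spans) is saved so
    the detection can be checked visually.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if n <= 2 * min_duration_s * sampling_rate_hz:
        raise ValueError("trace shorter than twice the minimum stimulation duration")
    rng_total = float(np.ptp(trace))
    scale = max(1.0, float(np.abs(trace).max(initial=0.0)))
    if rng_total <= 1e-12 * scale:
        warnings.warn("degenerate trace (no contrast): Otsu threshold undefined, no epochs")
        return []
    thr = otsu_threshold(trace, nbins=nbins)
    supra = trace > thr

    # bridge short sub-threshold gaps between supra runs
    max_gap = int(np.floor(merge_gap_s * sampling_rate_hz))
    if max_gap > 0:
        runs = _runs(~supra)
        for start, stop in runs:
            if start > 0 and stop < n and (stop - start) < max_gap:
                supra[start:stop] = True

    min_len = min_duration_s * sampling_rate_hz
    epochs = []
    times = time_origin_s + np.arange(n) / sampling_rate_hz
    for start, stop in _runs(supra):
        if (stop - start) >= min_len:
            epochs.append(
                StimulationEpoch(
                    onset_s=float(times[start]),
                    offset_s=float(times[stop - 1]),
                    source="otsu",
                )
            )
    if plot_path is not None:
        _plot_detection(times, trace, thr, epochs, plot_path)
    return epochs


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs in a boolean vector."""
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _plot_detection(times, trace, threshold, epochs, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3), dpi=120)
    ax.plot(times, trace, lw=0.8, label="filtered ROI mean")
    ax.axhline(threshold, color="crimson", ls="--", lw=1, label="Otsu threshold")
    for ep in epochs:
        ax.axvspan(ep.onset_s, ep.offset_s, color="orange", alpha=0.3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("perfusion (a.u.)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def epochs_from_markers(
    markers, label: str | None = None
) -> list[StimulationEpoch]:
    """Turn externally supplied event markers into stimulation epochs."""
    events = markers.events if label is None else [
        (l, s, e) for l, s, e in markers.events if l == label
    ]
    return [
        StimulationEpoch(onset_s=float(s), offset_s=float(e), source="marker")
        for _l, s, e in sorted(events, key=lambda ev: ev[1])
    ]


# ---------------------------------------------------------------------------
# response maps
# ---------------------------------------------------------------------------

def _window_indices(
    n: int, sampling_rate_hz: float, time_origin_s: float, t0: float, t1: float
) -> np.ndarray:
    times = time_origin_s + np.arange(n) / sampling_rate_hz
    eps = 1e-6 / sampling_rate_hz  # guard against float jitter at sample bounds
    idx = np.flatnonzero((times >= t0 - eps) & (times <= t1 + eps))
    if idx.size == 0:
        raise ValueError(f"window [{t0}, {t1}] s contains no samples")
    return idx


def compute_response_map(
    stack: np.ndarray,
    sampling_rate_hz: float,
    roi: ROIMask,
    epoch: StimulationEpoch,
    windows: ResponseWindows = ResponseWindows(),
    time_origin_s: float = 0.0,
) -> np.ndarray:
    """Per-pixel percent perfusion change for one stimulation, native resolution.

    For every ROI pixel: ``100 * (mean(response window) - mean(baseline
    window)) / mean(baseline window)``, windows taken relative to the epoch
    onset.  Pixels outside the ROI, and pixels whose baseline mean is not
    positive, are NaN (the latter counted in a warning).
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    end_t = time_origin_s + (n - 1) / sampling_rate_hz
    b0, b1 = (epoch.onset_s + w for w in windows.baseline_window_s)
    r0, r1 = (epoch.onset_s + w for w in windows.response_window_s)
    if b0 < time_origin_s or r1 > end_t:
        raise ValueError(
            f"windows [{b0:.1f}, {r1:.1f}] s fall outside the recording "
            f"[{time_origin_s:.1f}, {end_t:.1f}] s"
        )
    bidx = _window_indices(n, sampling_rate_hz, time_origin_s, b0, b1)
    ridx = _window_indices(n, sampling_rate_hz, time_origin_s, r0, r1)
    baseline = np.nanmean(stack[bidx], axis=0)
    response = np.nanmean(stack[ridx], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (response - baseline) / baseline
    out[~roi.mask] = np.nan
    bad = roi.mask & ~(baseline > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} ROI pixels with non-positive baseline dropped")
        out[bad] = np.nan
    return out


def standardize_map(
    native_map: np.ndarray, roi: ROIMask, size: int = STANDARD_MAP_SIZE
) -> ResponseMap:
    """Crop to the ROI's square bounding box and resample to the fixed grid.

    Bilinear resampling with the half-pixel-center convention.  Missing (NaN)
    pixels are propagated with normalized convolution: values and a validity
    weight are resampled separately and output pixels with less than half
    support stay missing.
    """
    r0, r1, c0, c1 = roi.bounding_box()
    crop = np.asarray(native_map, dtype=float)[r0:r1, c0:c1]
    if crop.shape[0] < 3 or crop.shape[1] < 3:
        raise ValueError(f"ROI bounding box {crop.shape} smaller than 3x3")
    valid = np.isfinite(crop)
    vals = np.where(valid, crop, 0.0)
    out_shape = (size, size)
    v = resize(vals, out_shape, order=1, mode="edge", anti_aliasing=False)
    w = resize(valid.astype(float), out_shape, order=1, mode="edge", anti_aliasing=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = v / w
    out[w < 0.5] = np.nan
    return ResponseMap(values=out, n_stimulations_averaged=1, n_animals_averaged=1)


def average_maps(
    maps: Sequence[ResponseMap],
    level: Literal["within_animal", "across_animals"] = "within_animal",
) -> ResponseMap:
    """Pixelwise mean of standardized maps, ignoring missing values.

    ``within_animal`` averages the stimulation repetitions of one animal;
    ``across_animals`` averages per-animal maps into the group map.  The
    result is order-invariant.
    """
    if len(maps) == 0:
        raise ValueError("cannot average an empty list of maps")
    # canonical summation order makes the result bit-identical under input
    # permutation (float addition is not associative)
    data = np.stack(sorted((m.values for m in maps), key=lambda v: v.tobytes()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(data, axis=0)
    n_stim = sum(m.n_stimulations_averaged for m in maps)
    if level == "within_animal":
        n_animals = 1
    elif level == "across_animals":
        n_animals = sum(m.n_animals_averaged for m in maps)
    else:
        raise ValueError(f"unknown level {level!r}")
    return ResponseMap(values=mean, n_stimulations_averaged=n_stim, n_animals_averaged=n_animals)


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def normalize_trace(
    trace: np.ndarray,
    sampling_rate_hz: float,
    epoch: StimulationEpoch,
    windows: ResponseWindows = ResponseWindows(),
    time_origin_s: float = 0.0,
    detrended: np.ndarray | None = None,
) -> np.ndarray:
    """Express a ROI-mean trace as percent change from the epoch baseline.

    The denominator is always the raw trace's baseline-window mean (the
    physical perfusion level).  When ``detrended`` is given (typically the
    drift-filtered trace, in the same units), the percent change is computed
    on it instead of the raw trace, so slow drift does not tilt the response.
    """
    trace = np.asarray(trace, dtype=float)
    b0, b1 = (epoch.onset_s + w for w in windows.baseline_window_s)
    bidx = _window_indices(trace.size, sampling_rate_hz, time_origin_s, b0, b1)
    baseline = np.nanmean(trace[bidx])
    if not baseline > 0:
        raise ValueError(f"baseline mean {baseline} is not positive")
    num = trace if detrended is None else np.asarray(detrended, dtype=float)
    return 100.0 * (num - np.nanmean(num[bidx])) / baseline


def scalar_metrics(
    trace_percent: np.ndarray,
    sampling_rate_hz: float,
    epoch: StimulationEpoch,
    windows: ResponseWindows = ResponseWindows(),
    auc_window_s: tuple[float, float] | None = None,
    recovery_s: float = 120.0,
    time_origin_s: float = 0.0,
) -> ScalarResponse:
    """Peak, slope and AUC of a baseline-normalized (%) response trace.

    * ``peak_percent``: maximum of the trace within [onset, offset] (first
      occurrence defines the peak time).
    * ``slope_percent_per_s``: ``(peak - baseline mean) / (t_peak -
      t_baseline_end)`` with the baseline mean over the baseline window and
      ``t_baseline_end`` the end of that window — the same construction as
      the vessel-dilation slope, on a trace whose baseline is ~0 %.
    * ``auc_percent_s``: trapezoidal integral of the trace over
      ``auc_window_s`` (default onset to offset + ``recovery_s``, clipped to
      the recording).

    A peak at or before the baseline end leaves the slope NaN with a warning.
    """
    trace = np.asarray(trace_percent, dtype=float)
    n = trace.size
    times = time_origin_s + np.arange(n) / sampling_rate_hz
    eps = 1e-6 / sampling_rate_hz
    in_epoch = np.flatnonzero((times >= epoch.onset_s - eps) & (times <= epoch.offset_s + eps))
    if in_epoch.size == 0:
        raise ValueError("epoch contains no samples")
    seg = trace[in_epoch]
    k = int(np.nanargmax(seg))
    peak = float(seg[k])
    t_peak = float(times[in_epoch[k]])

    b0, b1 = (epoch.onset_s + w for w in windows.baseline_window_s)
    bidx = _window_indices(n, sampling_rate_hz, time_origin_s, b0, b1)
    base_mean = float(np.nanmean(trace[bidx]))
    t_base_end = b1
    if t_peak <= t_base_end:
        warnings.warn("peak time precedes baseline end: slope undefined")
        slope = float("nan")
    else:
        slope = (peak - base_mean) / (t_peak - t_base_end)

    if auc_window_s is None:
        auc_window_s = (epoch.onset_s, epoch.offset_s + recovery_s)
    a0 = max(auc_window_s[0], times[0])
    a1 = min(auc_window_s[1], times[-1])
    aidx = _window_indices(n, sampling_rate_hz, time_origin_s, a0, a1)
    auc = float(np.trapezoid(trace[aidx], times[aidx]))
    return ScalarResponse(peak_percent=peak, slope_percent_per_s=slope, auc_percent_s=auc)
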