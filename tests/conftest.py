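"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (explicit Python loops, no reuse of
package internals) so they can serve as cross-checks for the vectorized
implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# Otsu oracle: exhaustive between-class-variance maximization on a histogram
# ---------------------------------------------------------------------------

def brute_force_otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustively search all histogram bin edges for the split maximizing
    the between-class variance w0*w1*(mu0-mu1)^2; returns the bin-edge
    threshold separating the two classes of the best split (first on ties)."""
    hist, edges = np.histogram(np.asarray(values, dtype=float), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = hist.sum()
    best_var = -1.0
    best_thr = edges[1]
    for split in range(1, nbins):
        w0 = int(hist[:split].sum())
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float((hist[:split] * centers[:split]).sum()) / w0
        mu1 = float((hist[split:] * centers[split:]).sum()) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_thr = edges[split]
    return float(best_thr)


@pytest.fixture
def otsu_oracle():
    return brute_force_otsu


# ---------------------------------------------------------------------------
# peak-detector oracle: plain frame-by-frame scan
# ---------------------------------------------------------------------------

def brute_force_peaks(diam, times, n_baseline, start_pct, end_pct, min_end):
    """Reference baseline-tracking scan, written as a flat per-frame loop.

    Returns a list of dicts with the same fields as ``vessel.Peak``.
    """
    d = [float(x) for x in diam]
    t = [float(x) for x in times]
    valid = [i for i in range(len(d)) if math.isfinite(d[i])]
    peaks = []
    pos = 0
    while pos + n_baseline <= len(valid):
        base = valid[pos : pos + n_baseline]
        d_base = sum(d[i] for i in base) / n_baseline
        t_base = t[base[-1]]
        pos += n_baseline
        if not d_base > 0:
            continue
        lo = d_base * (1 + start_pct / 100.0)
        hi = d_base * (1 + end_pct / 100.0)
        open_pos = None
        while pos < len(valid):
            if d[valid[pos]] > lo:
                open_pos = pos
                break
            pos += 1
        if open_pos is None:
            break
        run_start, run_len, close_pos = None, 0, None
        scan = open_pos
        while scan < len(valid):
            if d[valid[scan]] < hi:
                if run_len == 0:
                    run_start = scan
                run_len += 1
                if run_len >= min_end:
                    close_pos = run_start
                    break
            else:
                run_len, run_start = 0, None
            scan += 1
        if close_pos is None:
            end_pos, resume = len(valid) - 1, len(valid)
        else:
            end_pos, resume = close_pos, close_pos + min_end
        segment = valid[open_pos : end_pos + 1]
        d_max = max(d[i] for i in segment)
        kmax = next(i for i in segment if d[i] == d_max)
        t_max = t[kmax]
        slope = (
            float("nan")
            if t_max == t_base
            else ((d_max - d_base) / (t_max - t_base)) / d_base
        )
        peaks.append(
            {
                "t_start_s": t[valid[open_pos]],
                "t_end_s": t[valid[end_pos]],
                "diameter_baseline_um": d_base,
                "time_baseline_s": t_base,
                "diameter_max_um": d_max,
                "time_max_s": t_max,
                "slope_per_s": slope,
                "percent_change": 100.0 * (d_max - d_base) / d_base,
            }
        )
        pos = resume
    return peaks


@pytest.fixture
def peak_oracle():
    return brute_force_peaks


def random_diameter_trace(rng: np.random.Generator, n_frames: int) -> np.ndarray:
    """A plausible noisy diameter trace with occasional dilations and dropouts."""
    base = rng.uniform(8.0, 15.0)
    d = np.full(n_frames, base) + rng.normal(0, base * 0.01, n_frames)
    for _ in range(rng.integers(0, 4)):
        onset = int(rng.integers(5, max(6, n_frames - 10)))
        dur = int(rng.integers(3, 25))
        amp = rng.uniform(0.02, 0.4) * base
        d[onset : onset + dur] += amp
    # occasional missing frames
    for i in rng.choice(n_frames, size=rng.integers(0, n_frames // 20 + 1), replace=False):
        d[i] = np.nan
    return d


# ---------------------------------------------------------------------------
# small reusable synthetic inputs
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_lsci():
    """One-stimulation LSCI stack, small enough for fast unit tests."""
    from nvckit import synthetic

    cfg = synthetic.LSCISimConfig(
        shape=(880, 32, 32),
        stimulations=[(60.0, 60.0, 10.0, 0.0)],
        blob=((16.0, 16.0), 6.0),
        seed=11,
    )
    stack, truth = synthetic.simulate_lsci(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def small_vessel():
    """Default-condition vessel movie (two 20 % dilations)."""
    from nvckit import synthetic

    cfg = synthetic.VesselSimConfig(seed=7)
    movie, truth = synthetic.simulate_vessel(cfg)
    return cfg, movie, truth
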