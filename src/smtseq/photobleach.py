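"""Photobleaching-trace classification by step counting.

A surface site holding one fluorophore bleaches in a single abrupt step;
aggregated sites bleach through multiple steps.  Traces are segmented
with an exact penalized change-point program on piecewise-constant
means; the number of significant downward level changes labels the site
``single`` (1 step), ``aggregated`` (>= 2) or ``unclassified``
(irregular: an upward step, a poor piecewise-constant fit, too many
steps, or no step at all).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .imagesim import BleachMovie

LABEL_SINGLE = "single"
LABEL_AGGREGATED = "aggregated"
LABEL_UNCLASSIFIED = "unclassified"


@dataclass
class Trace:
    intensity: np.ndarray
    frame_interval: float = 0.1  # seconds
    centroid: Tuple[float, float] = (0.0, 0.0)
    clipped: bool = False

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or len(self.intensity) < 2:
            raise ValueError("a trace needs at least two frames")


@dataclass
class StepResult:
    n_steps: int
    step_frames: List[int]
    step_amplitudes: List[float]
    quality: float  # residual std over robust frame-noise estimate
    label: str


@dataclass
class StepParams:
    """Change-point segmentation knobs.

    ``penalty_factor`` scales the per-changepoint penalty
    (penalty = penalty_factor x sigma^2 x log n, a BIC-flavoured choice);
    a trace is irregular when any level change goes up by more than
    ``up_tolerance_sigmas`` noise sigmas, when the post-fit residual std
    exceeds ``max_residual_factor`` x the robust frame-noise estimate, or
    when more than ``max_steps`` steps are found.
    """

    penalty_factor: float = 4.0
    max_steps: int = 5
    max_residual_factor: float = 2.5
    up_tolerance_sigmas: float = 3.0
    min_step_sigmas: float = 3.0


@dataclass
class CompositionSummary:
    counts: Dict[str, int]
    fractions: Dict[str, float]
    n_total: int


# ---------------------------------------------------------------------------
# Trace extraction
# ---------------------------------------------------------------------------


def extract_trace(
    movie: BleachMovie,
    centroid: Tuple[float, float],
    aperture_radius: float = 2.0,
) -> Trace:
    """Background-subtracted aperture photometry around one centroid.

    Sums pixels within ``aperture_radius`` of the centroid in every frame
    after subtracting the frame median (a radius of 0 degenerates to the
    nearest single pixel).  The trace is flagged when the aperture is
    clipped by the image border.
    """
    x0, y0 = centroid
    n_frames, h, w = movie.frames.shape
    if not (0 <= x0 < w and 0 <= y0 < h):
        raise ValueError("centroid outside the movie frames")
    r = int(np.ceil(aperture_radius))
    ys = slice(max(int(round(y0)) - r, 0), min(int(round(y0)) + r + 1, h))
    xs = slice(max(int(round(x0)) - r, 0), min(int(round(x0)) + r + 1, w))
    yy, xx = np.mgrid[ys, xs]
    mask = (xx - x0) ** 2 + (yy - y0) ** 2 <= aperture_radius**2
    if not mask.any():  # degenerate aperture: nearest pixel
        mask = (yy == int(round(y0))) & (xx == int(round(x0)))
    clipped = (
        x0 - aperture_radius < -0.5
        or y0 - aperture_radius < -0.5
        or x0 + aperture_radius > w - 0.5
        or y0 + aperture_radius > h - 0.5
    )
    vals = np.empty(n_frames)
    for f in range(n_frames):
        frame = movie.frames[f]
        bg = float(np.median(frame))
        vals[f] = float((frame[ys, xs][mask] - bg).sum())
    return Trace(intensity=vals, centroid=(x0, y0), clipped=clipped)


# ---------------------------------------------------------------------------
# Change-point step counting
# ---------------------------------------------------------------------------


def _segment_costs(y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])
    return s1, s2


def _optimal_segmentation(y: np.ndarray, max_segments: int, penalty: float
                          ) -> Tuple[List[int], float]:
    """Exact penalized least-squares partition into piecewise-constant means.

    Minimizes RSS + penalty x (number of change points) over partitions
    with at most ``max_segments`` segments by dynamic programming; ties
    prefer fewer segments.  Returns the interior change-point indices
    (a change at t means a new segment starts at frame t) and the RSS.
    """
    n = len(y)
    s1, s2 = _segment_costs(y)
    K = min(max_segments, n)
    # dp[k][j]: best RSS of y[:j] split into exactly k segments
    dp = np.full((K + 1, n + 1), np.inf)
    back = np.zeros((K + 1, n + 1), dtype=np.int64)
    dp[0, 0] = 0.0
    for k in range(1, K + 1):
        prev = dp[k - 1]
        for j in range(k, n + 1):
            i = np.arange(k - 1, j)
            tot = s1[j] - s1[i]
            rss = (s2[j] - s2[i]) - tot * tot / (j - i)
            c = prev[i] + rss
            m = int(np.argmin(c))  # ties: earliest change point
            dp[k, j] = c[m]
            back[k, j] = i[m]
    best_k = 1
    best_cost = dp[1, n]
    for k in range(2, K + 1):
        cost = dp[k, n] + penalty * (k - 1)
        if cost < best_cost - 1e-9:
            best_cost = cost
            best_k = k
    # recover change points
    cps: List[int] = []
    j = n
    for k in range(best_k, 1, -1):
        i = int(back[k, j])
        cps.append(i)
        j = i
    cps.reverse()
    return cps, float(dp[best_k, n])


def frame_noise_sigma(y: np.ndarray) -> float:
    """Robust per-frame noise from first differences (MAD / sqrt(2))."""
    d = np.diff(y)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _trace_noise_sigma(y: np.ndarray) -> float:
    """Noise scale for step detection on a shot-noise-limited trace.

    Fluorescence shot noise scales with intensity, so post-bleach frames
    are much quieter than pre-bleach frames and a pooled estimate is
    dominated by the quiet tail.  The maximum of the whole-trace and
    early-window estimates tracks the noise of the bright (pre-bleach)
    level that the change-point penalty must beat.
    """
    sigma = frame_noise_sigma(y)
    head = y[: max(8, len(y) // 4)]
    if len(head) >= 6:
        sigma = max(sigma, frame_noise_sigma(head))
    return sigma


def count_steps(trace: Trace, params: StepParams = StepParams()) -> StepResult:
    """Count photobleaching steps in one intensity trace.

    Segments the trace into piecewise-constant levels and counts the
    significant downward level changes.  An upward change, residual noise
    well above the frame noise, more than ``max_steps`` steps, or no step
    at all leaves the trace unclassified.
    """
    y = trace.intensity
    if len(y) < 4:
        raise ValueError("count_steps needs a trace of length >= 4")
    sigma = _trace_noise_sigma(y)
    # floor keeps noiseless traces from tripping on round-off dust
    scale = max(sigma, 1e-6 * max(np.ptp(y), 1.0), 1e-300)
    penalty = params.penalty_factor * scale**2 * np.log(len(y))
    cps, rss = _optimal_segmentation(y, params.max_steps + 2, penalty)
    rss = max(rss, 0.0)  # guard numerical round-off on noiseless traces
    # segment means
    bounds = [0] + cps + [len(y)]
    means = [float(np.mean(y[bounds[i]: bounds[i + 1]])) for i in range(len(bounds) - 1)]
    amps = [means[i + 1] - means[i] for i in range(len(means) - 1)]
    resid_std = float(np.sqrt(rss / len(y)))
    quality = resid_std / scale

    min_step = params.min_step_sigmas * scale
    down = [i for i, a in enumerate(amps) if a < -min_step]
    up = [i for i, a in enumerate(amps) if a > params.up_tolerance_sigmas * scale]
    n_steps = len(down)
    step_frames = [cps[i] for i in down]
    step_amps = [amps[i] for i in down]

    irregular = (
        bool(up)
        or quality > params.max_residual_factor
        or n_steps > params.max_steps
        or n_steps == 0
    )
    if irregular:
        label = LABEL_UNCLASSIFIED
    elif n_steps == 1:
        label = LABEL_SINGLE
    else:
        label = LABEL_AGGREGATED
    return StepResult(
        n_steps=n_steps,
        step_frames=step_frames,
        step_amplitudes=step_amps,
        quality=quality,
        label=label,
    )


def summarize_composition(results: Sequence[StepResult]) -> CompositionSummary:
    """Counts and fractions of single / aggregated / unclassified sites."""
    if not results:
        raise ValueError("summarize_composition needs at least one result")
    counts = Counter(r.label for r in results)
    n = len(results)
    labels = (LABEL_SINGLE, LABEL_AGGREGATED, LABEL_UNCLASSIFIED)
    return CompositionSummary(
        counts={lab: counts.get(lab, 0) for lab in labels},
        fractions={lab: counts.get(lab, 0) / n for lab in labels},
        n_total=n,
    )


def field_composition(
    movie: BleachMovie,
    aperture_radius: float = 2.0,
    params: StepParams = StepParams(),
) -> Tuple[CompositionSummary, List[StepResult]]:
    """Classify every site of a bleaching movie and summarize the field."""
    results = []
    for x, y in movie.site_positions:
        trace = extract_trace(movie, (float(x), float(y)), aperture_radius)
        results.append(count_steps(trace, params))
    return summarize_composition(results), results
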