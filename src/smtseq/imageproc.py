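"""Spot localization: drift correction, detection, fitting, coincidence.

Implements the image half of the pipeline: phase-only correlation (POC)
drift estimation between cycles, Gaussian smoothing with a robust
noise-derived threshold, contiguous-pixel (8-connected) spot grouping,
least-squares 2-D Gaussian fitting with a cluster filter, and
two-channel coincidence calling that turns an incorporation-channel spot
near a template-channel anchor into a base-incorporation event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize

from .imagesim import ImageStack


@dataclass(frozen=True)
class Shift:
    dx: float
    dy: float

    def as_tuple(self) -> Tuple[float, float]:
        return (self.dx, self.dy)


@dataclass
class Spot:
    """A fitted candidate spot (0-based pixel coordinates, subpixel centroid)."""

    x: float
    y: float
    amplitude: float
    sigma: float
    background: float
    residual: float
    area: int  # pixels in the thresholded component
    ok: bool = True
    flag: str = ""


@dataclass
class IncorporationSpot:
    spot: Spot
    cycle: int  # 1-based
    anchor_id: int
    distance: float


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the detection stage.

    The threshold is median + threshold_k x robust noise scale (1.4826 x
    MAD) of the smoothed image; components larger than ``max_area``
    pixels or with fitted sigma above ``cluster_sigma_factor`` x
    ``psf_sigma`` are treated as 3+-molecule clusters and dropped.
    """

    smooth_sigma: float = 1.0
    threshold_k: float = 5.0
    psf_sigma: float = 1.0
    cluster_sigma_factor: float = 1.8
    max_area: int = 120
    min_area: int = 2
    fit_margin: int = 3


# ---------------------------------------------------------------------------
# Phase-only correlation registration
# ---------------------------------------------------------------------------


def _signed_index(idx: int, n: int) -> int:
    return idx - n if idx > n // 2 else idx


def estimate_shift_poc(
    image_a: np.ndarray, image_b: np.ndarray, subpixel: bool = False
) -> Shift:
    """Translation from ``image_a`` to ``image_b`` by phase-only correlation.

    Computes the inverse transform of the unit-normalised cross-power
    spectrum and returns the signed argmax, i.e. the (dx, dy) such that
    ``image_b(y, x) ~= image_a(y - dy, x - dx)`` (circular convention).
    Optional subpixel refinement fits a parabola through the peak and its
    neighbours along each axis.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must be 2-D and share dimensions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant image: phase spectrum is undefined")
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    poc = np.real(np.fft.ifft2(cross / mag))
    iy, ix = np.unravel_index(int(np.argmax(poc)), poc.shape)
    h, w = poc.shape
    dy = float(_signed_index(iy, h))
    dx = float(_signed_index(ix, w))
    if subpixel:
        def refine(center, minus, plus):
            denom = minus + plus - 2.0 * center
            if denom >= 0:
                return 0.0
            return float(np.clip(0.5 * (minus - plus) / denom, -0.5, 0.5))

        dy += refine(poc[iy, ix], poc[(iy - 1) % h, ix], poc[(iy + 1) % h, ix])
        dx += refine(poc[iy, ix], poc[iy, (ix - 1) % w], poc[iy, (ix + 1) % w])
    return Shift(dx=dx, dy=dy)


def translate_image(image: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Shift an image by (dx, dy); integer shifts roll exactly (circular)."""
    if float(dx).is_integer() and float(dy).is_integer():
        return np.roll(image, (int(dy), int(dx)), axis=(0, 1))
    return ndimage.shift(image, (dy, dx), order=1, mode="grid-wrap")


def register_stack(
    stack: ImageStack, reference_cycle: int = 1, subpixel: bool = False
) -> Tuple[ImageStack, List[Shift]]:
    """Align every cycle's channels to the reference cycle (default: first).

    Shifts are estimated on the template channel by POC; both channels of
    cycle c are translated by the negated estimated shift.
    """
    ref = stack.template[reference_cycle - 1]
    shifts: List[Shift] = []
    template = np.empty_like(stack.template)
    incorporation = np.empty_like(stack.incorporation)
    for c in range(stack.n_cycles):
        if np.ptp(ref) == 0 or np.ptp(stack.template[c]) == 0:
            s = Shift(0.0, 0.0)  # featureless frame: nothing to register
        else:
            s = estimate_shift_poc(ref, stack.template[c], subpixel=subpixel)
        shifts.append(s)
        template[c] = translate_image(stack.template[c], -s.dx, -s.dy)
        incorporation[c] = translate_image(stack.incorporation[c], -s.dx, -s.dy)
    registered = ImageStack(
        template=template,
        incorporation=incorporation,
        true_drift=stack.true_drift.copy(),
        pixel_size_um=stack.pixel_size_um,
    )
    return registered, shifts


# ---------------------------------------------------------------------------
# Spot detection and fitting
# ---------------------------------------------------------------------------

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


def robust_noise_scale(image: np.ndarray) -> float:
    """1.4826 x median absolute deviation about the median."""
    med = np.median(image)
    return 1.4826 * float(np.median(np.abs(image - med)))


def _gauss2d(coords, x0, y0, amp, sigma, bg):
    x, y = coords
    return bg + amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma**2))


def fit_spot(
    image: np.ndarray,
    region: Tuple[slice, slice],
    psf_sigma: float = 1.0,
    peak: Optional[Tuple[float, float]] = None,
) -> Spot:
    """Least-squares isotropic 2-D Gaussian plus constant background.

    ``region`` is a (row slice, column slice) window containing the
    candidate plus margin.  Non-convergent fits, non-positive amplitudes
    and centroids escaping the window are flagged ``ok=False``.
    """
    ys, xs = region
    sub = image[ys, xs].astype(float)
    if sub.size < 6 or np.ptp(sub) == 0:
        return Spot(0.0, 0.0, 0.0, 0.0, float(sub.mean()) if sub.size else 0.0,
                    0.0, sub.size, ok=False, flag="flat")
    yy, xx = np.mgrid[ys, xs]
    bg0 = float(sub.min())
    amp0 = float(sub.max() - bg0)
    if peak is None:
        w = np.clip(sub - bg0, 0, None) + 1e-12
        x0 = float((xx * w).sum() / w.sum())
        y0 = float((yy * w).sum() / w.sum())
    else:
        x0, y0 = peak
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            sub.ravel(),
            p0=(x0, y0, amp0, psf_sigma, bg0),
            maxfev=2000,
        )
    except (RuntimeError, optimize.OptimizeWarning):
        return Spot(x0, y0, 0.0, 0.0, bg0, 0.0, sub.size, ok=False, flag="no_convergence")
    fx, fy, amp, sigma, bg = popt
    sigma = abs(float(sigma))
    resid = float(np.sqrt(np.mean((sub.ravel() - _gauss2d((xx.ravel(), yy.ravel()), *popt)) ** 2)))
    ok = True
    flag = ""
    if amp <= 0:
        ok, flag = False, "nonpositive_amplitude"
    elif not (xs.start - 1 <= fx <= xs.stop and ys.start - 1 <= fy <= ys.stop):
        ok, flag = False, "centroid_escaped"
    return Spot(float(fx), float(fy), float(amp), sigma, float(bg), resid, sub.size,
                ok=ok, flag=flag)


def detect_spots(
    image: np.ndarray,
    params: DetectionParams = DetectionParams(),
    return_rejected: bool = False,
):
    """Detect and fit diffraction-limited spots in one image.

    The image is smoothed with a Gaussian kernel, thresholded at the
    smoothed median plus ``threshold_k`` robust noise scales, and
    8-connected above-threshold components become candidates; components
    holding several local maxima are split into one candidate per peak.
    Each candidate is Gaussian-fitted on the *unsmoothed* image; fits
    that fail, and 3+-molecule clusters (oversized components or inflated
    fitted sigma), are removed.  Invariant to adding a constant offset.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        return ([], []) if return_rejected else []
    smoothed = ndimage.gaussian_filter(img, params.smooth_sigma)
    med = float(np.median(smoothed))
    scale = robust_noise_scale(smoothed)
    ptp = float(np.ptp(smoothed))
    if ptp == 0:
        return ([], []) if return_rejected else []
    if scale <= 1e-9 * ptp:
        # noise-free render: fall back to a small fraction of the dynamic range
        scale = ptp / (100.0 * params.threshold_k)
    threshold = med + params.threshold_k * scale
    mask = smoothed > threshold
    labels, n_comp = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    h, w = img.shape
    spots: List[Spot] = []
    rejected: List[Spot] = []
    if n_comp:
        # local maxima of the smoothed image inside the mask, for splitting
        maxima = (smoothed == ndimage.maximum_filter(smoothed, size=3)) & mask
        objects = ndimage.find_objects(labels)
        for comp in range(1, n_comp + 1):
            sl = objects[comp - 1]
            area = int((labels[sl] == comp).sum())
            if area < params.min_area:
                continue
            if area > params.max_area:
                rejected.append(
                    Spot(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, area, ok=False, flag="cluster_area")
                )
                continue
            py, px = np.nonzero(maxima[sl] & (labels[sl] == comp))
            peaks = list(zip(px + sl[1].start, py + sl[0].start))
            if not peaks:
                continue
            m = params.fit_margin
            for cx, cy in peaks:
                ys = slice(max(int(cy) - m - 1, 0), min(int(cy) + m + 2, h))
                xs = slice(max(int(cx) - m - 1, 0), min(int(cx) + m + 2, w))
                spot = fit_spot(img, (ys, xs), params.psf_sigma, peak=(float(cx), float(cy)))
                spot = replace(spot, area=area)
                if not spot.ok:
                    rejected.append(spot)
                elif spot.sigma > params.cluster_sigma_factor * params.psf_sigma:
                    rejected.append(replace(spot, ok=False, flag="cluster_sigma"))
                else:
                    spots.append(spot)
    # deduplicate multi-peak refits that converged to the same centroid
    spots = _dedupe_spots(spots, min_dist=1.0)
    return (spots, rejected) if return_rejected else spots


def _dedupe_spots(spots: List[Spot], min_dist: float) -> List[Spot]:
    kept: List[Spot] = []
    for s in sorted(spots, key=lambda s: -s.amplitude):
        if all((s.x - k.x) ** 2 + (s.y - k.y) ** 2 >= min_dist**2 for k in kept):
            kept.append(s)
    kept.sort(key=lambda s: (s.y, s.x))
    return kept


# ---------------------------------------------------------------------------
# Two-channel coincidence
# ---------------------------------------------------------------------------

DEFAULT_COINCIDENCE_RADIUS = 1.6  # pixels


def coincidence_spots(
    template_spots: Sequence[Spot],
    incorporation_spots: Sequence[Spot],
    radius: float = DEFAULT_COINCIDENCE_RADIUS,
    cycle: int = 1,
) -> List[IncorporationSpot]:
    """Match incorporation-channel spots to template-channel anchors.

    An incorporation spot within ``radius`` of an anchor is matched to
    the nearest such anchor; each anchor accepts at most one spot per
    cycle (nearest wins, ties broken by lower spot index).  Unmatched
    spots are discarded.
    """
    if not template_spots or not incorporation_spots:
        return []
    ax = np.array([s.x for s in template_spots])
    ay = np.array([s.y for s in template_spots])
    claimed: Dict[int, Tuple[float, int]] = {}  # anchor -> (distance, spot index)
    for si, s in enumerate(incorporation_spots):
        d = np.hypot(ax - s.x, ay - s.y)
        ai = int(np.argmin(d))
        dist = float(d[ai])
        if dist > radius:
            continue
        prev = claimed.get(ai)
        if prev is None or (dist, si) < prev:
            claimed[ai] = (dist, si)
    out = [
        IncorporationSpot(
            spot=incorporation_spots[si], cycle=cycle, anchor_id=ai, distance=dist
        )
        for ai, (dist, si) in sorted(claimed.items())
    ]
    return out
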