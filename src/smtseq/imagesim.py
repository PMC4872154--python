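"""Two-channel TIRF-like image rendering for simulated fields.

Renders per-cycle template (anchor dye) and incorporation (terminator
dye) channel images from a molecule placement and its event table, with
cumulative per-cycle stage drift, a diffraction-limited Gaussian point
spread function, Poisson shot noise and Gaussian camera read noise; also
renders continuous-illumination photobleaching movies with stepwise
per-fluorophore bleaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .simcore import EventTable, FieldGeometry, MoleculeSet


@dataclass(frozen=True)
class OpticsConfig:
    """Camera and illumination model.

    Amplitudes are expected photons per fluorophore per (averaged)
    exposure; the camera records Poisson(signal + background) plus
    Gaussian read noise.  The default PSF sigma of 1 px is close to the
    diffraction-limited sigma for ~670 nm emission at the 54.6 um / 512 px
    scale.  ``exposure_frames`` exposures per field are averaged into one
    frame per channel per cycle (keep ``average_exposures=False`` to get
    all of them).  ``shot_noise=False`` disables all noise sources for
    ground-truth renders.
    """

    psf_sigma: float = 1.0  # pixels
    template_channel_amp: float = 300.0
    incorporation_channel_amp: float = 300.0
    background_level: float = 20.0  # photons / pixel
    read_noise_sigma: float = 3.0
    drift_per_cycle_sigma: float = 0.5  # pixels
    exposure_frames: int = 4
    average_exposures: bool = True
    shot_noise: bool = True

    def __post_init__(self):
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.template_channel_amp <= 0 or self.incorporation_channel_amp <= 0:
            raise ValueError("channel amplitudes must be positive")
        if self.drift_per_cycle_sigma < 0:
            raise ValueError("drift sigma must be >= 0")


@dataclass
class ImageStack:
    """Per-cycle two-channel images with ground-truth drift.

    ``template`` and ``incorporation`` are (n_cycles, H, W) float arrays;
    ``true_drift[c]`` is the cumulative (dx, dy) offset applied to every
    site at cycle index ``c`` (0 at the first cycle).
    """

    template: np.ndarray
    incorporation: np.ndarray
    true_drift: np.ndarray  # (n_cycles, 2)
    pixel_size_um: float = 54.6 / 512

    def __post_init__(self):
        if self.template.shape != self.incorporation.shape:
            raise ValueError("channel stacks must share dimensions")

    @property
    def n_cycles(self) -> int:
        return self.template.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.template.shape[1:]


@dataclass
class BleachMovie:
    """Continuous-illumination anchor-channel movie.

    ``true_bleach_frames[i]`` lists the bleach frame of every fluorophore
    at site ``i`` (a fluorophore alive through the whole movie is coded
    as ``n_frames``).
    """

    frames: np.ndarray  # (n_frames, H, W)
    site_positions: np.ndarray  # (n_sites, 2)
    site_occupancy: np.ndarray  # (n_sites,)
    true_bleach_frames: List[np.ndarray]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


_WINDOW_SIGMAS = 4.0  # spots are rendered out to +/- 4 sigma


def add_gaussian_spots(
    image: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    amps: np.ndarray,
    sigma: float,
) -> None:
    """Accumulate isotropic Gaussian spots into ``image`` in place.

    Pixel centres sit at integer coordinates; x indexes columns and y
    rows.  Each spot is truncated at +/- 4 sigma.
    """
    h, w = image.shape
    r = int(np.ceil(_WINDOW_SIGMAS * sigma))
    inv = 1.0 / (2.0 * sigma * sigma)
    for x, y, a in zip(xs, ys, amps):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.exp(-((np.arange(x0, x1) - x) ** 2) * inv)
        gy = np.exp(-((np.arange(y0, y1) - y) ** 2) * inv)
        image[y0:y1, x0:x1] += a * np.outer(gy, gx)


def _camera(
    signal: np.ndarray, optics: OpticsConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply background, shot noise, read noise and exposure averaging."""
    expected = signal + optics.background_level
    if not optics.shot_noise:
        return expected.copy()
    k = optics.exposure_frames if optics.average_exposures else 1
    # average of k Poisson exposures == Poisson(k * mean) / k
    img = rng.poisson(expected * k).astype(float) / k
    img += rng.normal(0.0, optics.read_noise_sigma / np.sqrt(k), size=img.shape)
    return img


def render_cycle_stack(
    molecules: MoleculeSet,
    events: EventTable,
    optics: OpticsConfig = OpticsConfig(),
    seed: int = 0,
    shape: Tuple[int, int] = (512, 512),
    drifts: Optional[Sequence[Tuple[float, float]]] = None,
) -> ImageStack:
    """Render the per-cycle two-channel image stack for one field.

    The template channel shows every molecule at every cycle; the
    incorporation channel at cycle c shows only molecules with a recorded
    event at c.  All positions at cycle c are shifted by that cycle's
    cumulative drift (random walk with ``drift_per_cycle_sigma`` per
    axis, or the injected ``drifts`` sequence).
    """
    if molecules.n_molecules != events.n_molecules:
        raise ValueError("molecule and event tables disagree on molecule count")
    rng = np.random.default_rng(seed)
    n_cyc = events.n_cycles
    if drifts is None:
        steps = rng.normal(0, optics.drift_per_cycle_sigma, size=(n_cyc, 2))
        steps[0] = 0.0
        true_drift = np.cumsum(steps, axis=0)
    else:
        true_drift = np.asarray(drifts, dtype=float)
        if true_drift.shape != (n_cyc, 2):
            raise ValueError("drifts must provide one (dx, dy) per cycle")
    h, w = shape
    template = np.zeros((n_cyc, h, w))
    incorporation = np.zeros((n_cyc, h, w))
    incorporated = events.incorporated()
    amps_t = np.full(molecules.n_molecules, optics.template_channel_amp)
    amps_i = np.full(molecules.n_molecules, optics.incorporation_channel_amp)
    for c in range(n_cyc):
        dx, dy = true_drift[c]
        tmpl = np.zeros((h, w))
        add_gaussian_spots(tmpl, molecules.x + dx, molecules.y + dy, amps_t, optics.psf_sigma)
        template[c] = _camera(tmpl, optics, rng)
        inc = np.zeros((h, w))
        on = incorporated[:, c]
        add_gaussian_spots(
            inc, molecules.x[on] + dx, molecules.y[on] + dy, amps_i[on], optics.psf_sigma
        )
        incorporation[c] = _camera(inc, optics, rng)
    return ImageStack(
        template=template,
        incorporation=incorporation,
        true_drift=true_drift,
        pixel_size_um=54.6 / shape[1],
    )


def render_bleach_movie(
    molecules: MoleculeSet,
    optics: OpticsConfig = OpticsConfig(),
    n_frames: int = 200,
    bleach_rate: float = 0.02,
    seed: int = 0,
    shape: Tuple[int, int] = (512, 512),
) -> BleachMovie:
    """Continuous-illumination movie with stepwise photobleaching.

    Every fluorophore bleaches independently at a geometric time with
    per-frame probability ``bleach_rate``, so a site of occupancy k shows
    k downward intensity steps (fewer if two fluorophores bleach in the
    same frame).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    n_mol = molecules.n_molecules
    if bleach_rate > 0:
        bleach = rng.geometric(bleach_rate, size=n_mol) - 1  # frame of bleaching
        bleach = np.minimum(bleach, n_frames)
    else:
        bleach = np.full(n_mol, n_frames)
    h, w = shape
    frames = np.zeros((n_frames, h, w))
    for f in range(n_frames):
        alive = bleach > f
        img = np.zeros((h, w))
        add_gaussian_spots(
            img,
            molecules.x[alive],
            molecules.y[alive],
            np.full(int(alive.sum()), optics.template_channel_amp),
            optics.psf_sigma,
        )
        frames[f] = _camera(img, optics, rng)
    site_pos = molecules.site_positions()
    occ = np.bincount(molecules.site_index, minlength=molecules.n_sites)
    true_bleach = [
        np.sort(bleach[molecules.site_index == s]) for s in range(molecules.n_sites)
    ]
    return BleachMovie(
        frames=frames,
        site_positions=site_pos,
        site_occupancy=occ,
        true_bleach_frames=true_bleach,
    )
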