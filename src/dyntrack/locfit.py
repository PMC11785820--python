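"""Shot-noise-limited localization: PSF rendering, 2-D Gaussian fitting, linking.

In background-free imaging the localization precision is set entirely by
photon shot noise, delta_x ~ (lambda / 2 NA) / sqrt(n_photons).  This module
renders diffraction-limited spots as Poisson realizations of a
pixel-integrated 2-D Gaussian, localizes them by least-squares Gaussian
fitting, and links per-frame detections into trajectories with a gated
nearest-neighbor rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf

from .trajsim import Trajectory

__all__ = ["PsfModel", "Detection", "render_psf_stack", "localize_frames", "link_tracks"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PsfModel:
    """Optical settings for spot rendering.

    The diffraction-limited spot FWHM is lambda_em / (2 NA); the Gaussian
    SD is FWHM / 2.355.  ``wavelength_nm`` defaults to 605 nm so that
    (lambda/2NA)/sqrt(1000) = 6.4 nm at NA 1.49; the erbium emission bands
    bracket this value and the exact detection wavelength is an instrument
    knob, so only photon-count *scaling* of the precision is physical.
    """

    wavelength_nm: float = 605.0
    na: float = 1.49
    pixel_size_nm: float = 160.0
    photons_per_frame: float = 1000.0
    background_per_pixel: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.na <= 1.49):
            raise ValueError("NA must lie in (0, 1.49]")
        if self.photons_per_frame <= 0:
            raise ValueError("photons_per_frame must be > 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be > 0")

    @property
    def diffraction_limit_nm(self) -> float:
        """lambda / (2 NA): the numerator of the precision formula."""
        return self.wavelength_nm / (2.0 * self.na)

    @property
    def psf_sd_nm(self) -> float:
        return self.diffraction_limit_nm / 2.355

    def precision_nm(self, n_photons: float | None = None) -> float:
        """Theoretical shot-noise localization precision (lambda/2NA)/sqrt(n)."""
        n = self.photons_per_frame if n_photons is None else n_photons
        return self.diffraction_limit_nm / np.sqrt(n)


@dataclass
class Detection:
    """One fitted spot in one frame."""

    frame: int
    x_nm: float
    y_nm: float
    width_nm: float
    amplitude: float
    photons: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("fitted width must be > 0")
        if self.photons < 0:
            raise ValueError("photon estimate must be >= 0")


def _pixel_gaussian(shape: tuple[int, int], x0: float, y0: float, sd: float,
                    pixel: float) -> np.ndarray:
    """Unit-integral 2-D Gaussian integrated over pixels (positions in nm,
    pixel centers at (i + 0.5) * pixel)."""
    edges_x = np.arange(shape[1] + 1) * pixel
    edges_y = np.arange(shape[0] + 1) * pixel
    cx = 0.5 * (erf((edges_x[1:] - x0) / (np.sqrt(2) * sd))
                - erf((edges_x[:-1] - x0) / (np.sqrt(2) * sd)))
    cy = 0.5 * (erf((edges_y[1:] - y0) / (np.sqrt(2) * sd))
                - erf((edges_y[:-1] - y0) / (np.sqrt(2) * sd)))
    return np.outer(cy, cx)


def render_psf_stack(
    true_positions_nm: np.ndarray,
    psf: PsfModel,
    shape: tuple[int, int] = (16, 16),
    seed: int = 0,
) -> np.ndarray:
    """Render one Poisson-noise frame per true position.

    Each frame is a Poisson realization of a pixel-integrated Gaussian spot
    of SD (lambda/2NA)/2.355 carrying ``psf.photons_per_frame`` expected
    photons, plus uniform background.  Positions are (x, y) in nm inside
    the field of view.
    """
    pos = np.atleast_2d(np.asarray(true_positions_nm, dtype=float))
    fov_x = shape[1] * psf.pixel_size_nm
    fov_y = shape[0] * psf.pixel_size_nm
    if np.any(pos[:, 0] < 0) or np.any(pos[:, 0] > fov_x) or np.any(
            pos[:, 1] < 0) or np.any(pos[:, 1] > fov_y):
        raise ValueError("positions must lie inside the field of view")
    if psf.diffraction_limit_nm < psf.pixel_size_nm:
        warnings.warn("PSF SD below one pixel: spot is undersampled", stacklevel=2)
    rng = np.random.default_rng(seed)
    stack = np.empty((len(pos), *shape))
    for i, (x0, y0) in enumerate(pos):
        lam = psf.photons_per_frame * _pixel_gaussian(shape, x0, y0, psf.psf_sd_nm,
                                                      psf.pixel_size_nm)
        lam = lam + psf.background_per_pixel
        stack[i] = rng.poisson(lam)
    return stack


def _fit_spot(frame: np.ndarray, seed_rc: tuple[int, int], pixel: float,
              sd0: float, window: int) -> Detection | None:
    r0, c0 = seed_rc
    half = window // 2
    r_lo, r_hi = max(0, r0 - half), min(frame.shape[0], r0 + half + 1)
    c_lo, c_hi = max(0, c0 - half), min(frame.shape[1], c0 + half + 1)
    patch = frame[r_lo:r_hi, c_lo:c_hi].astype(float)
    yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    xc = (xx + 0.5) * pixel
    yc = (yy + 0.5) * pixel

    def model(p):
        amp, x0, y0, sd, off = p
        return off + amp * np.exp(-((xc - x0) ** 2 + (yc - y0) ** 2) / (2 * sd**2))

    amp0 = float(patch.max() - patch.min())
    p0 = [amp0, (c0 + 0.5) * pixel, (r0 + 0.5) * pixel, sd0, float(patch.min())]
    try:
        res = least_squares(
            lambda p: (model(p) - patch).ravel(), p0,
            bounds=([0, xc.min(), yc.min(), 0.1 * pixel, -np.inf],
                    [np.inf, xc.max(), yc.max(), 10 * sd0, np.inf]),
        )
    except Exception:
        return None
    if not res.success:
        return None
    amp, x0, y0, sd, _off = res.x
    photons = 2.0 * np.pi * amp * sd**2 / pixel**2
    return Detection(frame=-1, x_nm=float(x0), y_nm=float(y0),
                     width_nm=float(sd), amplitude=float(amp),
                     photons=max(float(photons), 0.0))


def localize_frames(
    stack: np.ndarray,
    threshold: float | None = None,
    psf: PsfModel | None = None,
    window: int = 11,
) -> list[Detection]:
    """Least-squares 2-D Gaussian fits of every spot in every frame.

    Candidate spots are connected regions above ``threshold`` (default:
    mean + 4 SD of the frame); each is fit in a ``window`` x ``window``
    pixel patch.  Failed fits are dropped and counted in the log.
    """
    psf = psf or PsfModel()
    detections: list[Detection] = []
    n_failed = 0
    for f, frame in enumerate(np.atleast_3d(stack.reshape((-1, *stack.shape[-2:])))):
        if frame.max() <= 0:
            log.info("frame %d is empty: no detection", f)
            continue
        thr = threshold if threshold is not None else frame.mean() + 4.0 * frame.std()
        mask = frame > thr
        labels, n_obj = ndimage.label(mask)
        if n_obj == 0:
            continue
        maxima = ndimage.maximum_position(frame, labels, range(1, n_obj + 1))
        for rc in np.atleast_2d(maxima):
            det = _fit_spot(frame, tuple(rc), psf.pixel_size_nm, psf.psf_sd_nm, window)
            if det is None:
                n_failed += 1
                continue
            det.frame = f
            detections.append(det)
    if n_failed:
        log.warning("%d spot fits failed and were dropped", n_failed)
    return detections


def link_tracks(
    detections: list[Detection],
    max_jump_nm: float = 100.0,
    dt_s: float = 0.01,
) -> list[Trajectory]:
    """Greedy nearest-neighbor linking gated at ``max_jump_nm``.

    Detections are consumed frame by frame; each open track claims its
    nearest detection in the next frame if within the gate (closest pair
    first, so the result does not depend on detection order within a
    frame).  Tracks that find no continuation are closed; detections that
    extend no track open new ones.  Single-detection chains are discarded
    and counted.
    """
    if not detections:
        return []
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    frames = sorted(by_frame)
    open_tracks: list[list[Detection]] = [[d] for d in by_frame[frames[0]]]
    closed: list[list[Detection]] = []
    for prev_f, f in zip(frames[:-1], frames[1:]):
        cands = list(by_frame[f])
        if f != prev_f + 1:
            closed.extend(open_tracks)
            open_tracks = [[d] for d in cands]
            continue
        # all (track, candidate) pairs inside the gate, closest first
        pairs = []
        for ti, tr in enumerate(open_tracks):
            last = tr[-1]
            for ci, c in enumerate(cands):
                dist = np.hypot(c.x_nm - last.x_nm, c.y_nm - last.y_nm)
                if dist <= max_jump_nm:
                    pairs.append((dist, ti, ci))
        pairs.sort(key=lambda p: p[0])
        used_t: set[int] = set()
        used_c: set[int] = set()
        next_open: list[list[Detection]] = []
        for dist, ti, ci in pairs:
            if ti in used_t or ci in used_c:
                continue
            used_t.add(ti)
            used_c.add(ci)
            open_tracks[ti].append(cands[ci])
            next_open.append(open_tracks[ti])
        for ti, tr in enumerate(open_tracks):
            if ti not in used_t:
                closed.append(tr)
        for ci, c in enumerate(cands):
            if ci not in used_c:
                next_open.append([c])
        open_tracks = next_open
    closed.extend(open_tracks)

    trajectories = []
    n_dropped = 0
    for chain in closed:
        if len(chain) < 2:
            n_dropped += 1
            continue
        first = chain[0].frame
        trajectories.append(
            Trajectory(
                frame=np.array([d.frame - first for d in chain]),
                t_s=np.array([d.frame * dt_s for d in chain]),
                x_nm=np.array([d.x_nm for d in chain]),
                y_nm=np.array([d.y_nm for d in chain]),
                photons=np.array([d.photons for d in chain]),
                meta={"dt_s": dt_s, "first_frame": first},
            )
        )
    if n_dropped:
        log.info("%d unlinked single detections discarded", n_dropped)
    trajectories.sort(key=lambda tr: tr.meta["first_frame"])
    return trajectories
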