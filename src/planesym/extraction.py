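"""Reciprocal-lattice refinement and Fourier-coefficient extraction.

From a more-or-less 2D-periodic grayscale image this module recovers the
direct-space lattice (two basis vectors in pixel units) from the strong
peaks of the discrete Fourier transform, and then samples the
structure-bearing Fourier coefficients at the reciprocal-lattice nodes
under the selection settings of the classification workflow: a circular
area selection (outside filled with the mean intensity), a dynamic range
of the coefficient amplitudes (maximum fixed at 10000 on the file scale),
and an optional resolution radius in transform pixels of a 1024-wide
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .hka import CoefficientSet, FILE_SCALE

__all__ = [
    "PatternImage",
    "Lattice2D",
    "ExtractionSettings",
    "load_image",
    "refine_lattice",
    "extract_coefficients",
    "histogram",
    "NotPeriodicError",
    "ResolutionError",
]


class NotPeriodicError(ValueError):
    """No significant non-origin peaks: the image is not 2D periodic."""


class ResolutionError(ValueError):
    """Reciprocal nodes too closely spaced to be separated."""


@dataclass
class PatternImage:
    """A grayscale 2D-periodic image (row-major intensities)."""

    intensities: np.ndarray
    bit_depth: int = 8
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError("intensities must be a 2D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if min(arr.shape) < 128:
            raise ValueError("image must be at least 128x128")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class Lattice2D:
    """Direct-space basis vectors (x, y) in pixel units."""

    a: tuple[float, float]
    b: tuple[float, float]

    def __post_init__(self):
        m = self.matrix
        if abs(np.linalg.det(m)) < 1e-9:
            raise ValueError("basis vectors are linearly dependent")
        if min(self.length_a, self.length_b) <= 4.0:
            raise ValueError("lattice constants must exceed 4 px")

    @property
    def matrix(self) -> np.ndarray:
        """Rows are the basis vectors, so (u, v) @ matrix = (x, y)."""
        return np.array([self.a, self.b], dtype=float)

    @property
    def length_a(self) -> float:
        return float(np.hypot(*self.a))

    @property
    def length_b(self) -> float:
        return float(np.hypot(*self.b))

    @property
    def gamma(self) -> float:
        """Angle between the basis vectors in degrees."""
        a, b = np.asarray(self.a), np.asarray(self.b)
        cosg = float(a @ b) / (self.length_a * self.length_b)
        return float(np.degrees(np.arccos(np.clip(cosg, -1.0, 1.0))))

    @property
    def reciprocal(self) -> np.ndarray:
        """Rows are a*, b* in cycles/px: (h, k) @ reciprocal = spatial freq."""
        return np.linalg.inv(self.matrix).T

    def fractional(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) @ np.linalg.inv(self.matrix)

    def lattice_kind(self, rtol: float = 0.02, atol_deg: float = 1.5) -> str:
        """Pragmatic metric classification: square/hexagonal/rectangular/oblique."""
        eq = abs(self.length_a - self.length_b) <= rtol * max(
            self.length_a, self.length_b
        )
        g = self.gamma
        if eq and abs(g - 90.0) <= atol_deg:
            return "square"
        if eq and (abs(g - 120.0) <= atol_deg or abs(g - 60.0) <= atol_deg):
            return "hexagonal"
        if abs(g - 90.0) <= atol_deg:
            return "rectangular"
        return "oblique"


@dataclass
class ExtractionSettings:
    """Selection settings for the coefficient extraction.

    ``resolution_radius`` is measured in transform pixels of a 1024-wide
    window (maximum 512); it is rescaled automatically when the actual
    window is smaller.
    """

    mask_diameter: int = 1024
    dynamic_range: float = 200.0
    resolution_radius: float | None = None
    peak_window: int = 3

    def __post_init__(self):
        if self.dynamic_range < 1:
            raise ValueError("dynamic_range must be >= 1")
        if self.peak_window < 1:
            raise ValueError("peak_window must be >= 1")


def load_image(path) -> PatternImage:
    """Load a TIFF/PNG (8/16/32-bit gray; RGB reduced by luminance)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    bit_depth = 8 * arr.dtype.itemsize if arr.dtype.kind in "ui" else 32
    arr = arr.astype(float)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = (
            0.2126 * arr[..., 0] + 0.7152 * arr[..., 1] + 0.0722 * arr[..., 2]
        )
    return PatternImage(arr, bit_depth=bit_depth, metadata={"source": str(path)})


# --------------------------------------------------------------------------
# windowing


def _masked_window(image: PatternImage, settings: ExtractionSettings):
    """Central square window with circular mask, mean filled outside.

    Returns (window - mean, mean, (row_offset, col_offset), n).
    """
    arr = image.intensities
    n = min(settings.mask_diameter, min(arr.shape))
    # a near-central but deliberately generic area selection: a window
    # accidentally centered on a symmetry element would make the residuals
    # of the operations fixing it numerically exact while every other
    # operation keeps a selection-induced floor, biasing the model
    # comparisons; a generic position gives all models a comparable floor
    r0 = min((arr.shape[0] - n) // 2 + 23, arr.shape[0] - n)
    c0 = min((arr.shape[1] - n) // 2 + 37, arr.shape[1] - n)
    win = arr[r0 : r0 + n, c0 : c0 + n].astype(float)
    # center the mask on the same pixel the transform phases are referenced
    # to (n//2): the mask is then exactly symmetric under the grid's point
    # operations about that pixel, so it does not break pattern symmetry
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = n // 2
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= (n / 2.0 - 0.5) ** 2
    mean = float(win[mask].mean())
    out = np.where(mask, win - mean, 0.0)
    return out, mean, (r0, c0), n, int(mask.sum())


# --------------------------------------------------------------------------
# lattice refinement


def _find_peaks(
    mag: np.ndarray, n: int, min_radius: float, rel_threshold: float,
    window: int = 5,
):
    """Local maxima of the (unshifted) magnitude spectrum as wrapped freqs."""
    shifted = np.fft.fftshift(mag)
    local_max = shifted == ndimage.maximum_filter(
        shifted, size=max(3, window), mode="wrap"
    )
    yy, xx = np.mgrid[0:n, 0:n]
    fy = yy - n // 2
    fx = xx - n // 2
    radius = np.hypot(fx, fy)
    cand = local_max & (radius >= min_radius) & (radius < n // 2 - 1)
    if not cand.any():
        raise NotPeriodicError("no non-origin Fourier peaks found")
    strongest = shifted[cand].max()
    total = float(np.sqrt(np.sum(shifted**2)))
    if strongest <= 0 or strongest < 1e-9 * total:
        raise NotPeriodicError("no significant non-origin Fourier peaks")
    cand &= shifted >= rel_threshold * strongest
    ys, xs = np.nonzero(cand)
    peaks = np.stack([fx[ys, xs], fy[ys, xs]], axis=1).astype(float)
    heights = shifted[ys, xs]
    # parabolic sub-bin positions
    for i, (y, x) in enumerate(zip(ys, xs)):
        for axis, idx in ((1, x), (0, y)):
            lo = shifted[(y, idx - 1) if axis == 1 else (idx - 1, x)]
            hi = shifted[(y, (idx + 1) % n) if axis == 1 else ((idx + 1) % n, x)]
            c = shifted[y, x]
            denom = lo - 2 * c + hi
            if denom < 0:
                peaks[i, 0 if axis == 1 else 1] += 0.5 * (lo - hi) / denom
    return peaks, heights


def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _canonical_basis(g1: np.ndarray, g2: np.ndarray):
    """Right-handed, angle-ordered reciprocal basis (deterministic)."""
    if _cross2(g1, g2) < 0:
        g2 = -g2
    ang1 = np.arctan2(g1[1], g1[0]) % np.pi
    ang2 = np.arctan2(g2[1], g2[0]) % np.pi
    if ang2 < ang1:
        g1, g2 = g2, g1
        if _cross2(g1, g2) < 0:
            g2 = -g2
    if g1[0] < 0 or (g1[0] == 0 and g1[1] < 0):
        g1 = -g1
        g2 = -g2
        if _cross2(g1, g2) < 0:
            g2 = -g2
    return g1, g2


def _snap_metric(g1, g2, rtol=0.02, atol_deg=1.5):
    """Average the basis onto the detected Bravais metric (square,
    hexagonal or rectangular), preserving its orientation.  Metric
    symmetrization removes the spurious residual a refined-but-slightly-
    anisotropic basis would otherwise inject into symmetry-related orbits.
    """
    l1, l2 = np.linalg.norm(g1), np.linalg.norm(g2)
    ang = np.degrees(
        np.arccos(np.clip(g1 @ g2 / (l1 * l2), -1.0, 1.0))
    )
    eq = abs(l1 - l2) <= rtol * max(l1, l2)
    th1 = np.arctan2(g1[1], g1[0])
    if eq and abs(ang - 90.0) <= atol_deg:
        length = 0.5 * (l1 + l2)
        th = 0.5 * (th1 + np.arctan2(g2[1], g2[0]) - np.pi / 2)
        c, s = np.cos(th), np.sin(th)
        return length * np.array([c, s]), length * np.array([-s, c])
    if eq and abs(ang - 120.0) <= atol_deg:
        length = 0.5 * (l1 + l2)
        th = 0.5 * (th1 + np.arctan2(g2[1], g2[0]) - 2 * np.pi / 3)
        rot = 2 * np.pi / 3
        return (
            length * np.array([np.cos(th), np.sin(th)]),
            length * np.array([np.cos(th + rot), np.sin(th + rot)]),
        )
    if abs(ang - 90.0) <= atol_deg:
        th2 = th1 + np.pi / 2
        return (
            l1 * np.array([np.cos(th1), np.sin(th1)]),
            l2 * np.array([np.cos(th2), np.sin(th2)]),
        )
    return g1, g2


def refine_lattice(
    image: PatternImage, settings: ExtractionSettings | None = None
) -> Lattice2D:
    """Recover the direct-space lattice from the strong transform peaks.

    The two shortest independent strong peaks seed the reciprocal basis;
    all strong peaks that index to within half a transform pixel are then
    used in a least-squares refinement of the basis.
    """
    settings = settings or ExtractionSettings()
    win, _, _, n, _ = _masked_window(image, settings)
    mag = np.abs(np.fft.fft2(win))
    peaks, heights = _find_peaks(
        mag, n, min_radius=3.0, rel_threshold=0.05,
        window=2 * settings.peak_window - 1,
    )

    # seed from the strongest peaks (noise peaks rarely reach the top):
    # the two shortest independent vectors among them
    top = np.argsort(heights)[::-1][: min(24, len(heights))]
    order = top[np.argsort(np.hypot(peaks[top, 0], peaks[top, 1]))]
    g1 = None
    g2 = None
    for i in order:
        p = peaks[i]
        if g1 is None:
            g1 = p
            continue
        if abs(_cross2(g1, p)) > 1.0:
            g2 = p
            break
    if g1 is None or g2 is None:
        raise NotPeriodicError("fewer than two independent Fourier peaks")

    def _lsq_refine(basis, rounds=2):
        for _ in range(rounds):
            hk = peaks @ np.linalg.inv(basis)
            hk_round = np.round(hk)
            resid = np.linalg.norm((hk - hk_round) @ basis, axis=1)
            good = (resid < 0.5) & (np.abs(hk_round).max(axis=1) > 0)
            if good.sum() < 2 or np.linalg.matrix_rank(hk_round[good]) < 2:
                break
            w = np.sqrt(heights[good])[:, None]
            sol, *_ = np.linalg.lstsq(
                hk_round[good] * w, peaks[good] * w, rcond=None
            )
            if abs(np.linalg.det(sol)) > 1e-9:
                basis = sol
        return basis

    cov_idx = np.argsort(heights)[::-1][: min(48, len(heights))]

    def _coverage(basis):
        hk = peaks[cov_idx] @ np.linalg.inv(basis)
        resid = np.linalg.norm((hk - np.round(hk)) @ basis, axis=1)
        w = np.sqrt(heights[cov_idx])
        return float(np.sum(w * (resid < 0.35)) / np.sum(w))

    basis = _lsq_refine(np.stack([g1, g2]))
    # A strong translational pseudosymmetry (e.g. near-centering) can make
    # the seed basis a sublattice of the true reciprocal lattice: test the
    # centering-split and cell-doubling candidates and keep the coarsest
    # reciprocal basis that still indexes the strong peaks.
    splits = (
        np.array([[1.0, 0.0], [0.0, 1.0]]),
        np.array([[0.5, 0.5], [-0.5, 0.5]]),
        np.array([[0.5, 0.0], [0.0, 1.0]]),
        np.array([[1.0, 0.0], [0.0, 0.5]]),
    )
    best = None
    for s in splits:
        cand = _lsq_refine(s @ basis, rounds=1)
        cov = _coverage(cand)
        det = abs(np.linalg.det(cand))
        if cov >= 0.95:
            if best is None or det > best[0]:
                best = (det, cand)
    if best is None:
        cands = [(_coverage(s @ basis), s @ basis) for s in splits]
        best = (0.0, max(cands, key=lambda c: c[0])[1])
    basis = _lsq_refine(best[1])
    g1, g2 = _canonical_basis(basis[0], basis[1])
    g1, g2 = _snap_metric(g1, g2)
    m = np.stack([g1, g2]) / n            # rows in cycles/px
    direct = np.linalg.inv(m).T           # rows are a, b in px
    try:
        return Lattice2D(tuple(direct[0]), tuple(direct[1]))
    except ValueError as exc:
        raise NotPeriodicError(str(exc)) from None


# --------------------------------------------------------------------------
# coefficient extraction


def _airy_falloff(r_bins: float) -> float:
    """Normalized transform magnitude of the full circular mask at an
    off-bin radius (first zero at 1.22 bins); floored away from the zero."""
    from scipy.special import j1

    x = np.pi * r_bins
    if x < 1e-9:
        return 1.0
    return float(max(2.0 * j1(x) / x, 0.3))


def extract_coefficients(
    image: PatternImage,
    lattice: Lattice2D,
    settings: ExtractionSettings | None = None,
) -> CoefficientSet:
    """Sample amplitude/phase at every reciprocal node inside the selection.

    One Friedel representative is kept per node pair, the (0,0) term is
    excluded, amplitudes are rescaled to a maximum of 10000 and coefficients
    weaker than max/dynamic_range are dropped.  Phases are measured relative
    to the window origin (its top-left pixel); the phase-origin refinement
    of the symmetrization stage picks the symmetry origin.
    """
    settings = settings or ExtractionSettings()
    win, mean, offset, n, mask_area = _masked_window(image, settings)
    # reference phases to the window center: the circular mask's leakage
    # kernel is then real and even, so off-bin peaks carry no phase slope
    spec = np.fft.fft2(np.fft.ifftshift(win))

    recip_bins = lattice.reciprocal * n  # rows a*, b* in transform px
    gmin = min(np.linalg.norm(recip_bins[0]), np.linalg.norm(recip_bins[1]))
    if gmin < 2.0:
        raise ResolutionError(
            f"reciprocal nodes spaced {gmin:.2f} transform px apart "
            "cannot be separated"
        )
    rmax = n / 2.0 - 2.0
    if settings.resolution_radius is not None:
        rmax = min(rmax, settings.resolution_radius * n / 1024.0)

    hmax = int(np.ceil(rmax / gmin)) + 1
    hs, ks, amps, phases = [], [], [], []
    hk_all = np.array(
        [
            (h, k)
            for h in range(0, hmax + 1)
            for k in range(-hmax, hmax + 1)
            if (h > 0 or k > 0)
        ],
        dtype=int,
    )
    pos = hk_all @ recip_bins
    keep = np.hypot(pos[:, 0], pos[:, 1]) <= rmax
    hk_all, pos = hk_all[keep], pos[keep]

    absspec = np.abs(spec)
    for (h, k), (px, py) in zip(hk_all, pos):
        # sample at the bin nearest the predicted node (the refined lattice
        # localizes nodes to a small fraction of a transform pixel; chasing
        # local maxima would hop onto neighbors' leakage sidelobes and is
        # both a noise amplifier and a symmetry breaker for weak nodes)
        bx, by = int(round(px)), int(round(py))
        iy, ix = by % n, bx % n
        # the circular mask's leakage kernel is an Airy pattern; divide the
        # sampled magnitude by its falloff at the node's off-bin offset
        off_r = np.hypot(px - bx, py - by)
        amp = absspec[iy, ix] / _airy_falloff(off_r)
        hs.append(int(h))
        ks.append(int(k))
        amps.append(amp / mask_area)
        phases.append(np.degrees(np.angle(spec[iy, ix])))

    amps = np.asarray(amps)
    if len(amps) == 0 or amps.max() <= 0:
        raise NotPeriodicError("no reciprocal-node intensity found")
    pixel_scale = float(amps.max())
    scaled = amps / pixel_scale * FILE_SCALE
    keep = scaled >= FILE_SCALE / settings.dynamic_range
    cset = CoefficientSet(
        np.asarray(hs)[keep],
        np.asarray(ks)[keep],
        scaled[keep],
        np.asarray(phases)[keep],
        metadata={
            "mask_diameter": n,
            "dynamic_range": settings.dynamic_range,
            "resolution_radius": settings.resolution_radius,
            "window_offset": list(offset),
            "phase_origin_px": [n // 2, n // 2],
            "mean_intensity": mean,
            "pixel_scale": pixel_scale,
            "lattice_a": list(lattice.a),
            "lattice_b": list(lattice.b),
        },
    )
    return cset


def histogram(image: PatternImage, bins: int = 256) -> np.ndarray:
    """Intensity histogram; counts sum to the pixel count."""
    arr = image.intensities
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        counts = np.zeros(bins, dtype=int)
        counts[0] = arr.size
        return counts
    counts, _ = np.histogram(arr, bins=bins, range=(lo, hi))
    return counts
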