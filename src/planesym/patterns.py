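"""Synthetic crystal patterns with tunable Fedorov-type pseudosymmetry.

The generator emulates the statistical structure the classifier assumes:
a square-lattice p4 pattern whose motif feigns the higher symmetry p4gm
(and with it p2gg and c2mm, plus the glide and centered-mirror groups at
the k = 2 level).  The motif consists of five intensity levels: a
background, gray "right-angle ruler" frames and dark "curved diamonds"
around the fourfold sites at (0,0) and (1/2,1/2), small gray dots, and
bright "bow ties" at the twofold sites (1/2,0) and (0,1/2).  The bow-tie
tips extend along the cell diagonal; the ``delta`` parameter displaces the
tip anchor points so the distances defining the diagonal mirror differ by
the fraction ``delta`` (0.2 by default, i.e. a 20% difference), which
breaks every p4gm operation that is not in p4 while leaving p4 exact.

Rasterization samples the continuum motif at pixel corners ((j/c, i/c) in
fractional coordinates), so every integer-matrix plane-group operation
with translations of 0 or 1/2 maps the pixel grid onto itself exactly
(half-cell translations require an even ``cell_px``).  The p4 operations
are additionally enforced on the raster by index permutation, making the
generated pattern p4 symmetric to the bit.

Two noise models are provided: additive zero-mean Gaussian pixel noise
(clipped to the intensity range) and "spread" noise that replaces each
pixel by a randomly chosen pixel within a +/-s window, emulating the
GIMP spread filter; a strict-permutation variant preserves the histogram
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import PlaneGroup, get_group
from .extraction import PatternImage

__all__ = [
    "PatternSpec",
    "NoiseSpec",
    "generate",
    "add_gaussian_noise",
    "add_spread_noise",
    "apply_operation_to_raster",
    "raster_symmetry_residual",
]


@dataclass
class PatternSpec:
    cell_px: int = 97
    cells_per_side: int = 12
    group: str = "p4"
    delta: float = 0.2
    levels: tuple = (21.0, 80.0, 140.0, 190.0, 255.0)
    #: Gaussian softening of the motif edges (px).  Scanned/photographed
    #: artwork is band limited; a perfectly hard-edged raster would carry
    #: an unphysically flat spectrum out to the Nyquist frequency.
    blur_sigma: float = 1.2

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.cell_px < 24:
            raise ValueError("cell too small for the motif")
        if len(self.levels) != 5:
            raise ValueError("the motif uses exactly five intensity levels")


@dataclass
class NoiseSpec:
    gaussian_sigma: float = 0.0
    spread_radius: int = 0
    seed: int = 0


# --------------------------------------------------------------------------
# raster group action


def apply_operation_to_raster(img: np.ndarray, op, cell_px: int | None = None):
    """Image of a corner-sampled square raster under a plane-group operation.

    Pixel (i, j) holds the value at fractional coordinates (j/c, i/c); the
    operation (W, t) maps it to another grid point whenever t*c is integer.
    Returns ``out`` with ``out[g(p)] = img[p]``.
    """
    c = img.shape[0] if cell_px is None else cell_px
    if img.shape[0] != img.shape[1]:
        raise ValueError("raster must be square (one cell)")
    tvec = op.t * c
    if not np.allclose(tvec, np.round(tvec)):
        raise ValueError(
            f"translation {op.t} is not grid compatible with cell_px={c}"
        )
    tx, ty = (int(round(v)) for v in tvec)
    jj, ii = np.meshgrid(np.arange(c), np.arange(c))
    w = op.matrix
    xj = (w[0, 0] * jj + w[0, 1] * ii + tx) % c
    yi = (w[1, 0] * jj + w[1, 1] * ii + ty) % c
    out = np.empty_like(img)
    out[yi, xj] = img
    return out


def raster_symmetry_residual(cell: np.ndarray, group: PlaneGroup | str) -> float:
    """Maximal absolute pixel deviation of a cell raster from exact symmetry
    under every operation (and centering) of a group."""
    if isinstance(group, str):
        group = get_group(group)
    resid = 0.0
    for op in group.operations:
        resid = max(resid, float(np.abs(
            apply_operation_to_raster(cell, op) - cell
        ).max()))
    if group.is_centered:
        c = cell.shape[0]
        if c % 2:
            raise ValueError("centering check needs an even cell raster")
        shifted = np.roll(cell, (c // 2, c // 2), axis=(0, 1))
        resid = max(resid, float(np.abs(shifted - cell).max()))
    return resid


# --------------------------------------------------------------------------
# motif shapes (continuum predicates on wrapped fractional displacements)


def _wrap(d):
    return (d + 0.5) % 1.0 - 0.5


def _in_triangle(du, dv, a, b, cpt):
    """Barycentric point-in-triangle test on displacement grids."""
    ax, ay = a
    bx, by = b
    cx, cy = cpt
    d = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
    l1 = ((by - cy) * (du - cx) + (cx - bx) * (dv - cy)) / d
    l2 = ((cy - ay) * (du - cx) + (ax - cx) * (dv - cy)) / d
    l3 = 1.0 - l1 - l2
    eps = -1e-12
    return (l1 >= eps) & (l2 >= eps) & (l3 >= eps)


def _astroid(du, dv, radius, exponent=2.0 / 3.0):
    return (
        np.abs(du) ** exponent + np.abs(dv) ** exponent
    ) <= radius ** exponent


def _disc(du, dv, radius):
    return du * du + dv * dv <= radius * radius


def _bowtie_mask(du, dv, delta, tip=0.20, width=0.10, gap=0.045,
                 body=(0.155, 0.062)):
    """Bright bow tie: a smooth ellipse elongated along the cell diagonal
    with two triangular tips at its ends.

    The elongated body carries the site's twofold signature in strong
    low-order Fourier coefficients (the pattern's translational
    pseudosymmetry stays strong because that signature is concentrated in
    few reflections).  The tip anchor points approach (fixed) ruler edges
    across small gaps; ``delta`` makes the two gap distances differ by that
    fraction (one anchor retracts by delta*gap).  At delta = 0 the whole
    shape is symmetric under the diagonal swap (u, v) -> (v, u); delta > 0
    breaks every p4gm coset operation while the twofold site symmetry stays
    exact (the mate tip is the point reflection).  The breaking is a
    sub-pixel-to-few-pixel anchor displacement — a strong Fedorov-type
    pseudosymmetry, not a gross shape change.
    """
    e_par = (du + dv) / np.sqrt(2.0)
    e_perp = (du - dv) / np.sqrt(2.0)
    m = (e_par / body[0]) ** 2 + (e_perp / body[1]) ** 2 <= 1.0
    a = (tip - delta * gap, tip - width)
    b = (tip - width, tip)
    m |= _in_triangle(du, dv, a, b, (0.0, 0.0))
    m |= _in_triangle(-du, -dv, a, b, (0.0, 0.0))  # twofold mate
    return m


def _ruler_mask(du, dv, inner=0.17, outer=0.40, half_width=0.032, offset=0.095):
    """Gray right-angle 'ruler': two bars meeting at a right angle,
    symmetric under the diagonal swap."""
    bar1 = (
        (du >= inner) & (du <= outer)
        & (np.abs(dv - offset) <= half_width)
    )
    bar2 = (
        (dv >= inner) & (dv <= outer)
        & (np.abs(du - offset) <= half_width)
    )
    return bar1 | bar2


def _p4_raster_closure(mask: np.ndarray, group: PlaneGroup) -> np.ndarray:
    """Union of a boolean cell mask with its images under the group's
    rotations (index permutations, exact for corner sampling)."""
    out = mask.copy()
    for op in group.operations:
        out |= apply_operation_to_raster(mask, op)
    return out


def generate(spec: PatternSpec | None = None):
    """Rasterize the pattern; returns (PatternImage, ground-truth metadata).

    ``delta = 0`` (with an even ``cell_px``) produces an exactly p4gm
    symmetric raster; ``delta > 0`` is exactly p4 only.
    """
    spec = spec or PatternSpec()
    c = spec.cell_px
    group = get_group(spec.group)
    lvl_diamond, lvl_dot, lvl_ruler, lvl_background, lvl_bowtie = spec.levels

    jj, ii = np.meshgrid(np.arange(c), np.arange(c))
    u = jj / c
    v = ii / c

    def around(cx, cy):
        return _wrap(u - cx), _wrap(v - cy)

    cell = np.full((c, c), float(lvl_background))

    # gray rulers and their fourfold closure around both fourfold sites
    ruler = np.zeros((c, c), dtype=bool)
    for cx, cy in ((0.0, 0.0), (0.5, 0.5)):
        du, dv = around(cx, cy)
        ruler |= _ruler_mask(du, dv)
    cell[_p4_raster_closure(ruler, group)] = lvl_ruler

    # small gray dots on the diagonals around both fourfold sites
    dots = np.zeros((c, c), dtype=bool)
    for cx, cy in ((0.0, 0.0), (0.5, 0.5)):
        du, dv = around(cx, cy)
        dots |= _disc(du - 0.135, dv - 0.135, 0.030)
    cell[_p4_raster_closure(dots, group)] = lvl_dot

    # dark curved diamonds at the fourfold sites
    diamonds = np.zeros((c, c), dtype=bool)
    for cx, cy in ((0.0, 0.0), (0.5, 0.5)):
        du, dv = around(cx, cy)
        diamonds |= _astroid(du, dv, 0.115)
    cell[_p4_raster_closure(diamonds, group)] = lvl_diamond

    # bright bow ties at the twofold sites (fourfold closure maps the
    # (1/2,0) tie onto (0,1/2))
    du, dv = around(0.5, 0.0)
    bowtie = _bowtie_mask(du, dv, spec.delta)
    cell[_p4_raster_closure(bowtie, group)] = lvl_bowtie

    if spec.blur_sigma > 0:
        fy = np.fft.fftfreq(c)
        kern = np.exp(
            -2.0 * np.pi**2 * spec.blur_sigma**2
            * (fy[:, None] ** 2 + fy[None, :] ** 2)
        )
        cell = np.real(np.fft.ifft2(np.fft.fft2(cell) * kern))

    # Enforce the symmetry on the raster to the bit: the orbit minimum is
    # order independent, so the result is exactly invariant (a delta = 0
    # pattern is genuinely p4gm, so that full group is enforced when the
    # cell admits its half-cell translations).
    enforce = group
    if spec.delta == 0 and spec.group == "p4" and c % 2 == 0:
        enforce = get_group("p4gm")
    stack = [apply_operation_to_raster(cell, op) for op in enforce.operations]
    cell = np.min(stack, axis=0)

    tiles = np.tile(cell, (spec.cells_per_side, spec.cells_per_side))
    image = PatternImage(
        tiles,
        bit_depth=8,
        metadata={
            "generator": "planesym.patterns",
            "group": spec.group,
            "delta": spec.delta,
            "cell_px": c,
            "cells_per_side": spec.cells_per_side,
            "levels": [float(x) for x in spec.levels],
            "cell_vectors": [[float(c), 0.0], [0.0, float(c)]],
        },
    )
    return image, dict(image.metadata)


# --------------------------------------------------------------------------
# noise


def add_gaussian_noise(
    image: PatternImage, sigma: float, seed: int = 0,
    clip_range: tuple[float, float] | None = (0.0, 255.0),
) -> PatternImage:
    """Independent zero-mean Gaussian noise per pixel, clipped to range.

    ``clip_range=None`` disables clipping (pure Gaussian noise; clipping at
    the intensity ceiling otherwise biases the strong structure levels).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    arr = image.intensities
    if sigma == 0:
        noisy = arr.copy()
    else:
        rng = np.random.default_rng(seed)
        noisy = arr + rng.normal(0.0, sigma, arr.shape)
        if clip_range is not None:
            noisy = np.clip(noisy, *clip_range)
    meta = {**image.metadata, "gaussian_sigma": sigma, "noise_seed": seed}
    return PatternImage(noisy, bit_depth=image.bit_depth, metadata=meta)


def add_spread_noise(
    image: PatternImage, s: int, seed: int = 0, permute: bool = False
) -> PatternImage:
    """Spread noise: each pixel takes the value of a uniformly chosen pixel
    within +/-s of it along both axes (periodic boundaries).

    With ``permute=True`` a histogram-preserving variant is used instead:
    columns are locally shuffled within each row, then rows within each
    column, each displacement bounded by ~2s.
    """
    if s < 0 or int(s) != s:
        raise ValueError("spread radius must be a non-negative integer")
    arr = image.intensities
    rng = np.random.default_rng(seed)
    if s == 0:
        out = arr.copy()
    elif permute:
        out = arr.copy()
        n_r, n_c = out.shape
        keys = np.arange(n_c) + rng.uniform(-s, s, size=(n_r, n_c))
        out = np.take_along_axis(out, np.argsort(keys, axis=1), axis=1)
        keys = np.arange(n_r)[:, None] + rng.uniform(-s, s, size=(n_r, n_c))
        out = np.take_along_axis(out, np.argsort(keys, axis=0), axis=0)
    else:
        n_r, n_c = arr.shape
        dy = rng.integers(-s, s + 1, size=arr.shape)
        dx = rng.integers(-s, s + 1, size=arr.shape)
        yy, xx = np.mgrid[0:n_r, 0:n_c]
        out = arr[(yy + dy) % n_r, (xx + dx) % n_c]
    meta = {**image.metadata, "spread_radius": int(s), "noise_seed": seed,
            "spread_permute": bool(permute)}
    return PatternImage(out, bit_depth=image.bit_depth, metadata=meta)
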