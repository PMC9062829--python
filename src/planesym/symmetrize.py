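"""Fourier-space symmetrization: geometric models of a coefficient set.

A geometric model of the image data is the coefficient set averaged over
the symmetry-related index orbits of one plane group (complex values, after
phase-origin refinement) or one projected Laue class (amplitudes only).
The residual sums

* ``J_cFC`` — sum of squared complex-coefficient residuals of the
  symmetrized model against the translation-averaged (p1) set, and
* ``J_aFC`` — the analogous sum over real amplitudes,

are the quantities the geometric-AIC climbing tests compare.  Both the
reference and each model are normalized by their own maximal amplitude
before the residual sums are taken, and every model is re-thresholded at
max/dynamic_range, which defines the model's own coefficient count ``N``
(systematically absent reflections are zeroed by the symmetrization and
therefore drop out of the model, as in the CRISP ``.hka`` workflow; the
residual sums run over the index intersection of model and reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .catalog import LaueClassNode, PlaneGroup, get_group
from .hka import CoefficientSet, to_unit_scale, wrap_phase_deg

__all__ = [
    "SymmetrizedModel",
    "refine_origin",
    "symmetrize_plane_group",
    "symmetrize_laue",
    "residual_complex",
    "residual_amplitude",
]

DEFAULT_DYNAMIC_RANGE = 200.0


@dataclass
class SymmetrizedModel:
    """A coefficient set constrained to one symmetry target.

    ``coefficients`` are stored unit-scale in the symmetry frame (origin
    ramp applied, so the target's symmetry elements sit at (0,0)).
    """

    target: str
    origin: tuple[float, float]
    coefficients: CoefficientSet
    N: int
    k: int
    J_cFC: float | None
    J_aFC: float | None
    metadata: dict = field(default_factory=dict)

    def complex_in_image_frame(self) -> tuple[np.ndarray, np.ndarray]:
        """(indices, complex values) with the origin ramp undone."""
        hk = self.coefficients.indices
        vals = self.coefficients.complex_values()
        ramp = np.exp(-2j * np.pi * (hk @ np.asarray(self.origin)))
        return hk, vals * ramp

    def summary(self) -> dict:
        return {
            "target": self.target,
            "origin": [float(self.origin[0]), float(self.origin[1])],
            "N": int(self.N),
            "k": int(self.k),
            "J_cFC": None if self.J_cFC is None else float(self.J_cFC),
            "J_aFC": None if self.J_aFC is None else float(self.J_aFC),
        }


# --------------------------------------------------------------------------
# orbit machinery


def _friedel_full(cset: CoefficientSet):
    """Indices and complex values with Friedel mates made explicit."""
    hk = cset.indices
    vals = cset.complex_values()
    full_hk = np.concatenate([hk, -hk])
    full_vals = np.concatenate([vals, np.conj(vals)])
    return full_hk, full_vals


def _orbit_partition(full_hk: np.ndarray, group: PlaneGroup):
    """Partition indices into symmetry orbits with alignment phases.

    Returns (orbit_id, phi, absent_orbit) where ``phi`` are per-index phase
    increments in cycles relative to the orbit root (so an exactly
    symmetric set obeys ``F_i = F_root * exp(2 pi i phi_i)``), and
    ``absent_orbit`` marks orbits whose constraints force zero amplitude.
    """
    mats = [op.matrix for op in group.operations]
    trans = [op.t for op in group.operations]
    pos = {(int(h), int(k)): i for i, (h, k) in enumerate(full_hk)}
    n = len(full_hk)
    orbit_id = np.full(n, -1, dtype=int)
    phi = np.zeros(n)
    absent: list[bool] = []
    oid = 0
    for start in range(n):
        if orbit_id[start] >= 0:
            continue
        orbit_id[start] = oid
        phi[start] = 0.0
        bad = False
        if group.is_centered and (full_hk[start, 0] + full_hk[start, 1]) % 2 != 0:
            bad = True
        stack = [start]
        while stack:
            i = stack.pop()
            q = full_hk[i]
            for w, t in zip(mats, trans):
                qj = q @ w
                j = pos.get((int(qj[0]), int(qj[1])))
                if j is None:
                    continue
                ph = (phi[i] + float(q @ t)) % 1.0
                if orbit_id[j] == -1:
                    orbit_id[j] = oid
                    phi[j] = ph
                    stack.append(j)
                else:
                    d = (phi[j] - ph) % 1.0
                    if min(d, 1.0 - d) > 1e-9:
                        bad = True
        absent.append(bad)
        oid += 1
    return orbit_id, phi, np.asarray(absent, dtype=bool)


def _project(full_vals, orbit_id, phi, absent) -> np.ndarray:
    """Average aligned values within each orbit (the symmetry projection)."""
    aligned = full_vals * np.exp(-2j * np.pi * phi)
    n_orb = orbit_id.max() + 1
    sums = np.zeros(n_orb, dtype=complex)
    counts = np.zeros(n_orb)
    np.add.at(sums, orbit_id, aligned)
    np.add.at(counts, orbit_id, 1.0)
    means = sums / counts
    means[absent] = 0.0
    return means[orbit_id] * np.exp(2j * np.pi * phi)


# --------------------------------------------------------------------------
# phase-origin refinement


def _origin_objective_terms(cset: CoefficientSet, group: PlaneGroup, n_strongest):
    order = np.argsort(cset.amplitude)[::-1][: min(n_strongest, len(cset))]
    sub = CoefficientSet(
        cset.h[order], cset.k[order], cset.amplitude[order], cset.phase[order]
    )
    sub = to_unit_scale(sub)
    full_hk, full_vals = _friedel_full(sub)
    orbit_id, phi, absent = _orbit_partition(full_hk, group)
    keep = ~absent[orbit_id]
    const = float(np.sum(np.abs(full_vals) ** 2))
    hk = full_hk[keep]
    w = full_vals[keep] * np.exp(-2j * np.pi * phi[keep])
    oid = orbit_id[keep]
    # compact orbit ids and counts
    uniq, oid = np.unique(oid, return_inverse=True)
    counts = np.bincount(oid).astype(float)
    return const, hk, w, oid, counts


def _origin_residual(x0, hk, w, oid, counts, const):
    ramp = np.exp(2j * np.pi * (hk @ np.asarray(x0)))
    s = np.zeros(len(counts), dtype=complex)
    np.add.at(s, oid, w * ramp)
    return const - float(np.sum(np.abs(s) ** 2 / counts))


def refine_origin(
    cset: CoefficientSet,
    group: PlaneGroup | str,
    coarse_grid: int = 64,
    n_strongest: int = 256,
) -> tuple[float, float]:
    """Fractional origin shift minimizing the complex residual of Eq-style
    symmetrization, found by a coarse grid search (amplitude-squared
    weighting comes in naturally through the residual itself) followed by a
    local simplex refinement.
    """
    if isinstance(group, str):
        group = get_group(group)
    if group.k < 2:
        return (0.0, 0.0)
    if cset.max_amplitude <= 0:
        warnings.warn("degenerate coefficient set; origin ambiguous", stacklevel=2)
        return (0.0, 0.0)
    const, hk, w, oid, counts = _origin_objective_terms(cset, group, n_strongest)
    if const <= 0 or len(w) == 0:
        warnings.warn("degenerate coefficient set; origin ambiguous", stacklevel=2)
        return (0.0, 0.0)

    g = coarse_grid
    grid = np.arange(g) / g
    best_val = np.inf
    best_xy = (0.0, 0.0)
    # evaluate J on the grid in chunks of origin columns
    ey = np.exp(2j * np.pi * np.outer(hk[:, 1], grid))
    for ix, u in enumerate(grid):
        ex = np.exp(2j * np.pi * hk[:, 0] * u)
        phased = (w * ex)[:, None] * ey
        s = np.zeros((len(counts), g), dtype=complex)
        np.add.at(s, oid, phased)
        vals = const - np.sum(np.abs(s) ** 2 / counts[:, None], axis=0)
        j = int(np.argmin(vals))
        if vals[j] < best_val:
            best_val = float(vals[j])
            best_xy = (float(u), float(grid[j]))

    span = const - best_val
    if span <= 1e-12 * max(const, 1.0):
        warnings.warn("flat origin landscape; origin ambiguous", stacklevel=2)
        return (0.0, 0.0)

    res = optimize.minimize(
        _origin_residual,
        np.asarray(best_xy),
        args=(hk, w, oid, counts, const),
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 400},
    )
    x0 = np.mod(res.x, 1.0)
    return (float(x0[0]), float(x0[1]))


# --------------------------------------------------------------------------
# symmetrized models


def _apply_ramp(cset: CoefficientSet, origin) -> CoefficientSet:
    shift = np.asarray(origin, dtype=float)
    phase = cset.phase + 360.0 * (cset.indices @ shift)
    return CoefficientSet(
        cset.h.copy(), cset.k.copy(), cset.amplitude.copy(),
        wrap_phase_deg(phase), metadata=dict(cset.metadata),
    )


def symmetrize_plane_group(
    cset: CoefficientSet,
    group: PlaneGroup | str,
    origin: tuple[float, float] | None = None,
    dynamic_range: float | None = None,
) -> SymmetrizedModel:
    """Symmetrize a coefficient set to one plane group.

    The origin ramp is applied (refined when not given), each orbit is
    replaced by its phase-consistent average, systematically absent indices
    are zeroed, the model is renormalized to unit maximum and re-thresholded
    at max/dynamic_range, and the residual sums against the (ramped)
    translation-averaged reference are recorded.
    """
    if isinstance(group, str):
        group = get_group(group)
    ref = to_unit_scale(cset)
    if dynamic_range is None:
        dynamic_range = float(ref.metadata.get("dynamic_range") or DEFAULT_DYNAMIC_RANGE)
    if origin is None:
        origin = refine_origin(ref, group) if group.k >= 2 else (0.0, 0.0)
    ref = _apply_ramp(ref, origin)

    full_hk, full_vals = _friedel_full(ref)
    orbit_id, phi, absent = _orbit_partition(full_hk, group)
    model_full = _project(full_vals, orbit_id, phi, absent)
    n_reps = len(ref)
    model_vals = model_full[:n_reps]

    max_model = float(np.abs(model_vals).max())
    if max_model <= 0:
        raise ValueError(f"symmetrization to {group.symbol} annihilated the set")
    model_norm = model_vals / max_model
    keep = np.abs(model_norm) >= 1.0 / dynamic_range

    ref_vals = ref.complex_values()
    jc = float(np.sum(np.abs(ref_vals[keep] - model_norm[keep]) ** 2))
    ja = float(np.sum((np.abs(ref_vals[keep]) - np.abs(model_norm[keep])) ** 2))

    kept = CoefficientSet(
        ref.h[keep],
        ref.k[keep],
        np.abs(model_norm[keep]),
        np.degrees(np.angle(model_norm[keep])),
        metadata={**ref.metadata, "target": group.symbol},
    )
    return SymmetrizedModel(
        target=group.symbol,
        origin=(float(origin[0]), float(origin[1])),
        coefficients=kept,
        N=int(keep.sum()),
        k=group.k,
        J_cFC=jc,
        J_aFC=ja,
        metadata={"dynamic_range": dynamic_range,
                  "n_absent": int(absent[orbit_id][:n_reps].sum()),
                  "max_amplitude_prenorm": max_model},
    )


def symmetrize_laue(
    cset: CoefficientSet,
    laue: LaueClassNode,
    dynamic_range: float | None = None,
) -> SymmetrizedModel:
    """Average amplitudes over a point-group orbit; phases untouched.

    Amplitudes are origin invariant, so no phase-origin refinement is
    involved; the residual is the squared amplitude residual sum.
    """
    ref = to_unit_scale(cset)
    if dynamic_range is None:
        dynamic_range = float(ref.metadata.get("dynamic_range") or DEFAULT_DYNAMIC_RANGE)
    point_group = PlaneGroup(
        symbol=laue.symbol, centering="p",
        operations=laue.operations, lattice_constraint="oblique",
    )
    full_hk, _ = _friedel_full(ref)
    full_amp = np.concatenate([ref.amplitude, ref.amplitude])
    orbit_id, _, absent = _orbit_partition(full_hk, point_group)
    n_orb = orbit_id.max() + 1
    sums = np.zeros(n_orb)
    counts = np.zeros(n_orb)
    np.add.at(sums, orbit_id, full_amp)
    np.add.at(counts, orbit_id, 1.0)
    means = sums / counts
    means[absent] = 0.0
    model_amp = means[orbit_id][: len(ref)]

    max_model = float(model_amp.max())
    if max_model <= 0:
        raise ValueError(f"Laue averaging to {laue.symbol} annihilated the set")
    model_amp = model_amp / max_model
    keep = model_amp >= 1.0 / dynamic_range
    ja = float(np.sum((ref.amplitude[keep] - model_amp[keep]) ** 2))

    kept = CoefficientSet(
        ref.h[keep], ref.k[keep], model_amp[keep], ref.phase[keep],
        metadata={**ref.metadata, "target": laue.symbol},
    )
    return SymmetrizedModel(
        target=laue.symbol,
        origin=(0.0, 0.0),
        coefficients=kept,
        N=int(keep.sum()),
        k=laue.k,
        J_cFC=None,
        J_aFC=ja,
        metadata={"dynamic_range": dynamic_range, "laue": True},
    )


# --------------------------------------------------------------------------
# residual sums


def _intersect(model_set: CoefficientSet, reference: CoefficientSet):
    mi = model_set.index_map()
    ri = reference.index_map()
    common = [ix for ix in ri if ix in mi]
    if not common:
        raise ValueError("model and reference share no indices")
    a = np.array([ri[ix] for ix in common])
    b = np.array([mi[ix] for ix in common])
    return a, b


def residual_complex(model, reference: CoefficientSet) -> float:
    """Sum of squared complex residuals over matching Laue indices.

    Both sets must be on unit scale.  ``model`` may be a
    :class:`SymmetrizedModel` or a bare :class:`CoefficientSet`.
    """
    mset = model.coefficients if isinstance(model, SymmetrizedModel) else model
    ia, ib = _intersect(mset, reference)
    rv = reference.complex_values()[ia]
    mv = mset.complex_values()[ib]
    return float(np.sum(np.abs(rv - mv) ** 2))


def residual_amplitude(model, reference: CoefficientSet) -> float:
    """Sum of squared amplitude residuals over matching Laue indices."""
    mset = model.coefficients if isinstance(model, SymmetrizedModel) else model
    ia, ib = _intersect(mset, reference)
    return float(
        np.sum((reference.amplitude[ia] - mset.amplitude[ib]) ** 2)
    )
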