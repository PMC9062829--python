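import numpy as np
import pytest

from planesym import catalog as cat
from planesym.hka import CoefficientSet, to_unit_scale
from planesym.patterns import apply_operation_to_raster
from planesym.processing import reconstruct_cell
from planesym.symmetrize import (
    refine_origin,
    residual_amplitude,
    residual_complex,
    symmetrize_laue,
    symmetrize_plane_group,
)

from conftest import square_cell_coefficients


def hex_closed_coefficients(group, seed=0, band=10):
    """Coefficient universe closed under a (hexagonal) group's index maps."""
    rng = np.random.default_rng(seed)
    seed_vals = {}
    for h in range(0, band + 1):
        for k in range(-band, band + 1):
            if h == 0 and k <= 0:
                continue
            seed_vals[(h, k)] = rng.normal() + 1j * rng.normal()
    universe = set()
    for hk in seed_vals:
        for sign in (1, -1):
            stack = [(sign * hk[0], sign * hk[1])]
            while stack:
                p = stack.pop()
                if p in universe:
                    continue
                universe.add(p)
                for op in group.operations:
                    q = tuple(int(x) for x in (np.array(p) @ op.matrix))
                    if q not in universe:
                        stack.append(q)
    reps = sorted(
        {p if (p[0] > 0 or (p[0] == 0 and p[1] > 0)) else (-p[0], -p[1])
         for p in universe}
    )
    vals = [seed_vals.get(p, 0j) for p in reps]
    return CoefficientSet(
        np.array([p[0] for p in reps]), np.array([p[1] for p in reps]),
        np.abs(vals), np.degrees(np.angle(vals)),
        metadata={"dynamic_range": 1e12},
    )


def pixel_route(cell, group, n):
    acc = np.zeros_like(cell)
    for op in group.operations:
        acc += apply_operation_to_raster(cell, op)
    acc /= group.k
    if group.is_centered:
        acc = 0.5 * (acc + np.roll(acc, (n // 2, n // 2), axis=(0, 1)))
    return acc


@pytest.mark.parametrize("symbol", cat.PLANE_GROUP_SYMBOLS)
def test_fourier_route_equals_pixel_route(symbol):
    """Symmetrizing the coefficients and back-transforming equals averaging
    the group-transformed direct-space images, to 1e-6 relative."""
    group = cat.get_group(symbol)
    n = 64
    if group.lattice_constraint == "hexagonal":
        cset = hex_closed_coefficients(group)
    else:
        cset, n = square_cell_coefficients(n=n)
    ref = to_unit_scale(cset)
    scale = cset.max_amplitude
    cell0 = reconstruct_cell(ref, n=n) * scale
    model = symmetrize_plane_group(ref, group, origin=(0.0, 0.0),
                                   dynamic_range=1e12)
    fourier = (
        reconstruct_cell(model, n=n, frame="symmetric")
        * model.metadata["max_amplitude_prenorm"] * scale
    )
    pixel = pixel_route(cell0, group, n)
    err = np.abs(fourier - pixel).max() / np.abs(cell0).max()
    assert err < 1e-6


@pytest.mark.parametrize("symbol", ["p2", "p2gg", "c2mm", "p4", "p4gm", "p3m1"])
def test_symmetrization_idempotent(symbol):
    group = cat.get_group(symbol)
    cset, _ = square_cell_coefficients(seed=1)
    once = symmetrize_plane_group(cset, group, origin=(0.0, 0.0))
    twice = symmetrize_plane_group(
        once.coefficients, group, origin=(0.0, 0.0)
    )
    assert twice.J_cFC == pytest.approx(0.0, abs=1e-16)
    ia = once.coefficients.index_map()
    ib = twice.coefficients.index_map()
    assert set(ia) == set(ib)
    for ix, i in ia.items():
        assert twice.coefficients.amplitude[ib[ix]] == pytest.approx(
            once.coefficients.amplitude[i], abs=1e-9
        )


def test_p1_model_is_identity(toy_coefficient_set):
    model = symmetrize_plane_group(toy_coefficient_set, cat.get_group("p1"))
    assert model.J_cFC == 0.0
    assert model.N == len(toy_coefficient_set)
    assert model.k == 1


def test_laue2_identity_on_amplitudes(toy_coefficient_set):
    model = symmetrize_laue(toy_coefficient_set, cat.get_laue_class("2"))
    assert model.J_aFC == 0.0
    np.testing.assert_allclose(
        np.sort(model.coefficients.amplitude),
        np.sort(to_unit_scale(toy_coefficient_set).amplitude),
    )


def test_p4_model_amplitudes_invariant_under_laue4():
    cset, _ = square_cell_coefficients(seed=2)
    p4 = symmetrize_plane_group(cset, cat.get_group("p4"), origin=(0.0, 0.0))
    laue = symmetrize_laue(p4.coefficients, cat.get_laue_class("4"))
    assert laue.J_aFC == pytest.approx(0.0, abs=1e-18)


def test_glide_systematic_absences_removed():
    """An exactly glide-symmetric set has zero amplitude at the forbidden
    axial parity; the model drops them."""
    cset, n = square_cell_coefficients(seed=3)
    model = symmetrize_plane_group(
        cset, cat.get_group("p1g1"), origin=(0.0, 0.0), dynamic_range=1e6
    )
    forbidden = [(h, k) for h, k in model.coefficients.indices
                 if h == 0 and k % 2 == 1]
    assert forbidden == []
    cell = reconstruct_cell(model, n=n)
    resid = np.abs(
        apply_operation_to_raster(cell, cat.get_group("p1g1").operations[0])
        - cell
    ).max()
    # direct-space glide invariance of the enforced model
    for op in cat.get_group("p1g1").operations:
        assert np.abs(
            apply_operation_to_raster(cell, op) - cell
        ).max() <= 1e-6 * np.abs(cell).max()
    assert resid <= 1e-6 * np.abs(cell).max()


@pytest.mark.parametrize("symbol", ["p2", "p2gg", "p4", "p4gm", "c2mm"])
def test_reconstruction_invariance_under_enforced_group(symbol):
    group = cat.get_group(symbol)
    cset, n = square_cell_coefficients(seed=4)
    model = symmetrize_plane_group(cset, group, origin=(0.0, 0.0))
    cell = reconstruct_cell(model, n=n, frame="symmetric")
    for op in group.operations:
        resid = np.abs(apply_operation_to_raster(cell, op) - cell).max()
        assert resid <= 1e-6 * np.abs(cell).max()
    if group.is_centered:
        rolled = np.roll(cell, (n // 2, n // 2), axis=(0, 1))
        assert np.abs(rolled - cell).max() <= 1e-6 * np.abs(cell).max()


class TestOriginRefinement:
    def p2_symmetric_set(self):
        cset, _ = square_cell_coefficients(seed=5)
        return symmetrize_plane_group(
            cset, cat.get_group("p2"), origin=(0.0, 0.0)
        ).coefficients

    def test_already_on_origin(self):
        sym = self.p2_symmetric_set()
        x0 = np.asarray(refine_origin(sym, "p2"))
        allowed = np.array([[0, 0], [0.5, 0], [0, 0.5], [0.5, 0.5], [1, 0],
                            [0, 1], [1, 1], [1, 0.5], [0.5, 1]])
        assert np.min(np.abs(allowed - x0).sum(axis=1)) < 1e-4

    def test_ramp_then_recover(self):
        sym = self.p2_symmetric_set()
        shift = (0.137, 0.291)
        hk = sym.indices
        ramped = CoefficientSet(
            sym.h, sym.k, sym.amplitude,
            sym.phase + 360.0 * (hk @ np.asarray(shift)),
        )
        x0 = np.asarray(refine_origin(ramped, "p2"))
        # recovered origin is -shift modulo the p2 allowed-origin set
        diff = (x0 + np.asarray(shift)) % 0.5
        diff = np.minimum(diff, 0.5 - diff)
        assert np.all(diff < 1e-3)

    def test_allowed_origins_equivalent(self):
        """The complex residual is identical at every allowed origin."""
        from planesym.symmetrize import _apply_ramp

        sym = self.p2_symmetric_set()
        models = [
            symmetrize_plane_group(
                _apply_ramp(sym, t), cat.get_group("p2"), origin=(0.0, 0.0)
            ).J_cFC
            for t in [(0, 0), (0.5, 0), (0, 0.5), (0.5, 0.5)]
        ]
        assert max(models) - min(models) < 1e-9

    def test_degenerate_set_warns(self):
        zero = CoefficientSet(
            np.array([1]), np.array([0]), np.array([0.0]), np.array([0.0])
        )
        with pytest.warns(UserWarning):
            x0 = refine_origin(zero, "p4")
        assert x0 == (0.0, 0.0)
        # a set whose only orbits are systematically absent is flat too
        absent_only = CoefficientSet(
            np.array([0]), np.array([3]), np.array([1.0]), np.array([0.0])
        )
        with pytest.warns(UserWarning):
            assert refine_origin(absent_only, "p1g1") == (0.0, 0.0)


class TestResiduals:
    def test_identical_sets_zero(self, toy_coefficient_set):
        u = to_unit_scale(toy_coefficient_set)
        assert residual_complex(u, u) == 0.0
        assert residual_amplitude(u, u) == 0.0

    def test_zeroed_coefficient_costs_its_power(self):
        ref = CoefficientSet(np.array([1]), np.array([0]),
                             np.array([1.0]), np.array([0.0]))
        model = CoefficientSet(np.array([1]), np.array([0]),
                               np.array([0.0]), np.array([0.0]))
        assert residual_complex(model, ref) == pytest.approx(1.0)

    def test_phase_flip_costs_four(self):
        ref = CoefficientSet(np.array([1]), np.array([0]),
                             np.array([1.0]), np.array([0.0]))
        model = CoefficientSet(np.array([1]), np.array([0]),
                               np.array([1.0]), np.array([180.0]))
        assert residual_complex(model, ref) == pytest.approx(4.0)
        assert residual_amplitude(model, ref) == pytest.approx(0.0)

    def test_amplitude_difference(self):
        ref = CoefficientSet(np.array([1]), np.array([0]),
                             np.array([1.0]), np.array([0.0]))
        model = CoefficientSet(np.array([1]), np.array([0]),
                               np.array([0.5]), np.array([0.0]))
        assert residual_amplitude(model, ref) == pytest.approx(0.25)

    def test_amplitude_never_exceeds_complex(self):
        rng = np.random.default_rng(6)
        n = 40
        hs = np.arange(1, n + 1)
        ks = np.zeros(n, dtype=int)
        ref = CoefficientSet(hs, ks, rng.uniform(0.1, 1, n),
                             rng.uniform(-180, 180, n))
        model = CoefficientSet(hs, ks, rng.uniform(0.1, 1, n),
                               rng.uniform(-180, 180, n))
        assert residual_amplitude(model, ref) <= residual_complex(model, ref)

    def test_disjoint_sets_error(self):
        a = CoefficientSet(np.array([1]), np.array([0]),
                           np.array([1.0]), np.array([0.0]))
        b = CoefficientSet(np.array([2]), np.array([0]),
                           np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            residual_complex(a, b)
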