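import numpy as np
import pytest

from planesym.hka import CoefficientSet
from planesym.selection import (
    NotTestableError,
    anchoring_group,
    classify_laue,
    classify_plane_groups,
    climb_test,
    consistency_check,
    gaic_bound,
    noise_variance,
)
from planesym.symmetrize import SymmetrizedModel

from paperdata import (
    FINAL_VERDICTS,
    K,
    LAUE_COMPARISONS,
    MODEL_TABLES,
    PLANE_COMPARISONS,
    assert_printed,
)


def stub_model(symbol, j_c, j_a, n, k=None, laue=False):
    """A SymmetrizedModel carrying only the selection-relevant fields."""
    cset = CoefficientSet(
        np.array([1]), np.array([0]), np.array([1.0]), np.array([0.0])
    )
    return SymmetrizedModel(
        target=symbol, origin=(0.0, 0.0), coefficients=cset,
        N=n, k=k if k is not None else K[symbol],
        J_cFC=None if laue else j_c, J_aFC=j_a,
    )


def plane_models(condition):
    return {
        sym: stub_model(sym, j_c, j_a, n)
        for sym, (j_c, j_a, n) in MODEL_TABLES[condition].items()
    }


def laue_models(condition):
    """Laue models derived from the amplitude maps of the plane-group
    models: class 4 from the p4 model, 2mm from p2gg, 4mm from p4mm."""
    t = MODEL_TABLES[condition]
    return {
        "2": stub_model("2", None, 0.0, t["p2"][2], k=2, laue=True),
        "2mm": stub_model("2mm", None, t["p2gg"][1], t["p2gg"][2], k=4, laue=True),
        "4": stub_model("4", None, t["p4"][1], t["p4"][2], k=4, laue=True),
        "4mm": stub_model("4mm", None, t["p4mm"][1], t["p4mm"][2], k=8, laue=True),
    }


class TestGaicBound:
    @pytest.mark.parametrize(
        "args,expected",
        [((2, 4, 956, 948), 2.008368),
         ((2, 4, 956, 931), 2.0261506),
         ((4, 8, 948, 918), 1.3438819),
         ((2, 4, 665, 650), 2.0225564),
         ((4, 8, 276, 266), 1.3454106),
         ((2, 4, 275, 276), 1.9963636),
         ((2, 4, 275, 269), 2.0218182),
         ((4, 8, 276, 276), 1.3333333)],
    )
    def test_printed_bounds(self, args, expected):
        assert_printed(gaic_bound(*args), expected)

    @pytest.mark.parametrize("k_l,k_m", [(2, 4), (2, 3), (3, 6), (4, 8), (6, 12)])
    @pytest.mark.parametrize("n", [64, 500, 956])
    def test_equal_counts_reduce_to_closed_form(self, k_l, k_m, n):
        reduced = 1.0 + 2.0 * (k_m - k_l) / (k_m * (k_l - 1))
        assert gaic_bound(k_l, k_m, n, n) == pytest.approx(reduced, abs=1e-12)

    def test_monotone_decreasing_in_count_ratio(self):
        bounds = [gaic_bound(2, 4, 600, nm) for nm in (540, 570, 600, 630)]
        assert bounds == sorted(bounds, reverse=True)

    def test_k1_not_testable(self):
        with pytest.raises(NotTestableError):
            gaic_bound(1, 2, 100, 100)
        with pytest.raises(ValueError):
            gaic_bound(4, 4, 100, 100)


@pytest.mark.parametrize("condition", list(PLANE_COMPARISONS))
def test_climbing_tables_reproduced(condition):
    """LHS ratios, RHS bounds and verdicts of every plane-group climbing
    test reproduce the printed values from the model residuals and counts
    (rows whose printed RHS is internally inconsistent assert the verdict
    only)."""
    table = MODEL_TABLES[condition]
    for sub, sup, lhs, rhs, fulfilled in PLANE_COMPARISONS[condition]:
        j_l, _, n_l = table[sub]
        j_m, _, n_m = table[sup]
        result = climb_test(j_l, j_m, K[sub], K[sup], n_l, n_m,
                            sub=sub, super_=sup)
        assert_printed(result.lhs, lhs)
        if rhs is not None:
            assert_printed(result.rhs, rhs)
        assert result.fulfilled == fulfilled


@pytest.mark.parametrize("condition", list(LAUE_COMPARISONS))
def test_laue_tables_reproduced(condition):
    """Amplitude-residual climbing tests between the plane-group models'
    amplitude maps reproduce the printed Laue comparisons."""
    table = MODEL_TABLES[condition]
    for sub, sup, lhs, rhs, fulfilled in LAUE_COMPARISONS[condition]:
        _, ja_l, n_l = table[sub]
        _, ja_m, n_m = table[sup]
        k_l = 4  # amplitude maps of the k=4 settings
        result = climb_test(ja_l, ja_m, k_l, 8, n_l, n_m, sub=sub, super_=sup)
        assert_printed(result.lhs, lhs)
        if rhs is not None:
            assert_printed(result.rhs, rhs)
        assert result.fulfilled == fulfilled


def test_climb_test_zero_residual_not_testable():
    with pytest.raises(NotTestableError):
        climb_test(0.0, 0.1, 2, 4, 100, 100)


class TestAnchoring:
    @pytest.mark.parametrize("condition", ["noise_free", "moderate", "heavy"])
    def test_anchor_is_p2(self, condition):
        base = {s: m for s, m in plane_models(condition).items()
                if m.k in (2, 3)}
        assert anchoring_group(base) == "p2"

    def test_deterministic_tie_break(self):
        base = {
            "p1g1": stub_model("p1g1", 0.5, 0.1, 100),
            "p11g": stub_model("p11g", 0.5, 0.1, 100),
            "p3": stub_model("p3", 0.5, 0.1, 100),
        }
        # equal residuals: larger k wins, then lexicographic order
        assert anchoring_group(base) == "p3"
        base.pop("p3")
        assert anchoring_group(base) == min("p1g1", "p11g")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            anchoring_group({})


@pytest.mark.parametrize("condition", ["noise_free", "moderate", "heavy"])
def test_full_classification_from_model_tables(condition):
    """End-to-end selection logic on the published model residuals: the
    anchoring group, the final plane group after the consistency check,
    the Laue class and the pseudosymmetry list all match."""
    plane = classify_plane_groups(plane_models(condition))
    laue = classify_laue(laue_models(condition))
    report = consistency_check(plane, laue)
    expected = FINAL_VERDICTS[condition]
    assert report.anchoring_group == expected["anchor"]
    assert report.best_plane_group == expected["best"]
    assert report.best_laue == expected["laue"]
    assert report.consistent is expected["consistent"]
    assert set(report.pseudo_groups) == expected["pseudo"]
    # pseudosymmetry strength ranks by ascending complex residual
    js = [MODEL_TABLES[condition][g][0] for g in report.pseudo_groups]
    assert js == sorted(js)


def test_heavy_condition_ascends_then_demotes():
    """With heavy noise the formally best plane group is p4gm (every
    climbing test on its chain is fulfilled), but the Laue class stays 4;
    the consistency check must flag this and demote to p4."""
    plane = classify_plane_groups(plane_models("heavy"))
    assert "p4gm" in plane.genuine_groups
    laue = classify_laue(laue_models("heavy"))
    assert laue.best_laue == "4"
    report = consistency_check(plane, laue)
    assert report.consistent is False
    assert report.best_plane_group == "p4"
    assert "p4gm" in report.pseudo_groups


def test_moderate_condition_resolves_disjoint_candidates():
    """At the moderate noise level both p2gg and p4 pass every climbing
    test; the Laue anchor (class 4) resolves the tie toward p4 without
    raising the inconsistency flag."""
    plane = classify_plane_groups(plane_models("moderate"))
    assert {"p2gg", "p4"} <= set(plane.genuine_groups)
    laue = classify_laue(laue_models("moderate"))
    report = consistency_check(plane, laue)
    assert report.consistent is True
    assert report.best_plane_group == "p4"
    assert "p2gg" in report.pseudo_groups


def test_laue_anchor_beats_2mm_by_large_margin():
    t = MODEL_TABLES["moderate"]
    assert t["p2gg"][1] / t["p4"][1] > 2.7


class TestNoiseVariance:
    def test_zero_residual(self):
        assert noise_variance(stub_model("p2", 0.0, 0.0, 956)).epsilon_squared == 0.0

    def test_reference_value(self):
        est = noise_variance(stub_model("p2", 0.0042, 0.0, 956))
        assert est.epsilon_squared == pytest.approx(8.7866e-6, rel=1e-4)
        assert est.model == "p2"

    def test_linear_in_residual(self):
        a = noise_variance(stub_model("p4", 0.02, 0.0, 500)).epsilon_squared
        b = noise_variance(stub_model("p4", 0.04, 0.0, 500)).epsilon_squared
        assert b == pytest.approx(2 * a)

    def test_k1_undefined(self):
        with pytest.raises(NotTestableError):
            noise_variance(stub_model("p1", 0.1, 0.0, 100, k=1))


def test_report_serialization_roundtrip():
    import json

    plane = classify_plane_groups(plane_models("noise_free"))
    laue = classify_laue(laue_models("noise_free"))
    report = consistency_check(plane, laue)
    payload = json.loads(report.to_json())
    assert payload["best_plane_group"] == "p4"
    assert payload["models"]["p2"]["N"] == 956
    assert any(c["super"] == "p4" for c in payload["comparisons"])
    text = report.render_tables()
    assert "p4 over p2" in text and "Anchoring group: p2" in text
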