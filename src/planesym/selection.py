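"""Geometric-AIC model selection over symmetry hierarchies.

Kanatani's geometric AIC balances a model's residual against a selection
penalty proportional to its degrees of freedom times the noise variance.
For crystallographic models of 2D-periodic image data the model dimension
is zero (pixels are points, d = 0), the co-dimension is unity (r = 1) and
the degrees of freedom are n = N/k, with N the coefficient count and k the
number of non-translational symmetry operations.  Under these constants
the pairwise comparison of a more symmetric model (subscript m) against a
less symmetric one (subscript l) reduces to the climbing-up inequality

    J_m / J_l  <  1 + (2 / (k_l - 1)) * (1 - k_l * N_m / (k_m * N_l))

which for equal coefficient counts N_m = N_l collapses to
1 + 2 (k_m - k_l) / (k_m (k_l - 1)).  No noise-level estimate and no
interpretation threshold enter: ascent in the hierarchy tree is permitted
exactly when the inequality holds.

The classification procedure anchors at the least-broken disjoint model of
the lowest non-trivial level (k = 2, 3 for plane groups; k = 4, 6 for
projected Laue classes, since Friedel symmetry makes Laue class 2 residual
zero), climbs while permitted, labels fulfilled-but-unanchored comparisons
as Fedorov-type pseudosymmetries, and cross-checks the plane-group result
against the Laue result for crystallographic consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

from . import catalog
from .catalog import plane_group_laue_class
from .symmetrize import SymmetrizedModel

__all__ = [
    "ComparisonResult",
    "NoiseEstimate",
    "ClassificationReport",
    "gaic_bound",
    "climb_test",
    "anchoring_group",
    "classify_plane_groups",
    "classify_laue",
    "consistency_check",
    "noise_variance",
    "NotTestableError",
]

#: Dimension of the geometric models: image data are per-pixel intensities,
#: i.e. zero-dimensional points.
MODEL_DIMENSION = 0
#: Co-dimension of the models in Kanatani's framework.
CO_DIMENSION = 1

BASE_LEVEL_GROUPS = (
    "p2", "p1m1", "p11m", "p1g1", "p11g", "c1m1", "c11m", "p3",
)


class NotTestableError(ValueError):
    """Climb test undefined (J_l = 0 or k_l = 1)."""


@dataclass
class ComparisonResult:
    """One climbing-up test of a supergroup model over a subgroup model."""

    sub: str
    super_: str
    lhs: float
    rhs: float
    fulfilled: bool
    interpretation: str = ""  # ascent | blocked | pseudo

    def row(self) -> str:
        verdict = {
            "ascent": "yes",
            "pseudo": "yes, but due to pseudosymmetry",
            "blocked": "no, blocking ascent",
        }.get(self.interpretation, "yes" if self.fulfilled else "no")
        return (
            f"{self.super_} over {self.sub}\t{self.lhs:.7g}\t"
            f"{self.rhs:.7g}\t{verdict}"
        )


@dataclass
class NoiseEstimate:
    epsilon_squared: float
    model: str


@dataclass
class ClassificationReport:
    anchoring_group: str = ""
    genuine_groups: list[str] = field(default_factory=list)
    pseudo_groups: list[str] = field(default_factory=list)
    best_plane_group: str = ""
    laue_anchor: str = ""
    genuine_laue: list[str] = field(default_factory=list)
    best_laue: str = ""
    consistent: bool | None = None
    noise: NoiseEstimate | None = None
    comparisons: list[ComparisonResult] = field(default_factory=list)
    laue_comparisons: list[ComparisonResult] = field(default_factory=list)
    models: dict = field(default_factory=dict)
    laue_models: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "schema": "planesym/classification-report/1",
            "anchoring_group": self.anchoring_group,
            "genuine_groups": self.genuine_groups,
            "pseudo_groups": self.pseudo_groups,
            "best_plane_group": self.best_plane_group,
            "laue_anchor": self.laue_anchor,
            "genuine_laue": self.genuine_laue,
            "best_laue": self.best_laue,
            "consistent": self.consistent,
            "noise": None
            if self.noise is None
            else {"epsilon_squared": self.noise.epsilon_squared,
                  "model": self.noise.model},
            "models": self.models,
            "laue_models": self.laue_models,
            "comparisons": [
                {
                    "sub": c.sub, "super": c.super_, "lhs": c.lhs,
                    "rhs": c.rhs, "fulfilled": c.fulfilled,
                    "interpretation": c.interpretation,
                }
                for c in self.comparisons + self.laue_comparisons
            ],
            "notes": self.notes,
        }
        return json.dumps(payload, indent=1)

    def render_tables(self) -> str:
        lines = ["Model\tJ_cFC\tJ_aFC\tN\tk"]
        for sym, m in self.models.items():
            jc = "-" if m["J_cFC"] is None else f"{m['J_cFC']:.6g}"
            ja = "-" if m["J_aFC"] is None else f"{m['J_aFC']:.6g}"
            lines.append(f"{sym}\t{jc}\t{ja}\t{m['N']}\t{m['k']}")
        lines.append("")
        lines.append("Comparison\tLHS\tRHS\tfulfilled?")
        for c in self.comparisons:
            lines.append(c.row())
        lines.append("")
        lines.append("Laue comparison\tLHS\tRHS\tfulfilled?")
        for c in self.laue_comparisons:
            lines.append(c.row())
        lines.append("")
        lines.append(f"Anchoring group: {self.anchoring_group}")
        lines.append(f"Genuine: {', '.join(self.genuine_groups)}")
        lines.append(f"Pseudosymmetries (strongest first): "
                     f"{', '.join(self.pseudo_groups)}")
        lines.append(f"Best plane group: {self.best_plane_group}")
        lines.append(
            f"Laue: anchor {self.laue_anchor}, best {self.best_laue}, "
            f"consistent: {self.consistent}"
        )
        if self.noise is not None:
            lines.append(
                f"Noise variance estimate ({self.noise.model}): "
                f"{self.noise.epsilon_squared:.6g}"
            )
        return "\n".join(lines)


# --------------------------------------------------------------------------
# the inequality


def gaic_bound(k_l: int, k_m: int, N_l: int, N_m: int) -> float:
    """Right-hand side of the climbing-up inequality (maximal J_m/J_l)."""
    if k_l < 2:
        raise NotTestableError(
            "climbing from a k=1 model is undefined (its residual is zero)"
        )
    if k_m <= k_l:
        raise ValueError("k_m must exceed k_l for a climbing-up test")
    if N_l <= 0 or N_m <= 0:
        raise ValueError("coefficient counts must be positive")
    return 1.0 + (2.0 / (k_l - 1)) * (1.0 - (k_l * N_m) / (k_m * N_l))


def climb_test(
    J_l: float,
    J_m: float,
    k_l: int,
    k_m: int,
    N_l: int,
    N_m: int,
    sub: str = "",
    super_: str = "",
) -> ComparisonResult:
    """Test whether ascent from the less to the more symmetric model is
    statistically permitted."""
    if J_l <= 0:
        raise NotTestableError(
            "J_l = 0: ascent from this model is handled by the anchoring rule"
        )
    rhs = gaic_bound(k_l, k_m, N_l, N_m)
    lhs = J_m / J_l
    return ComparisonResult(sub, super_, lhs, rhs, lhs < rhs)


def noise_variance(model: SymmetrizedModel, use_amplitude=False) -> NoiseEstimate:
    """Variance of the generalized noise from the K-L best model:
    eps^2 = J k / (N (k - 1)) with co-dimension 1 and n = N/k."""
    if model.k < 2:
        raise NotTestableError("noise variance undefined for a k=1 model")
    j = model.J_aFC if use_amplitude else model.J_cFC
    if j is None:
        raise ValueError("model lacks the requested residual sum")
    eps2 = j * model.k / (model.N * (model.k - 1))
    return NoiseEstimate(epsilon_squared=float(eps2), model=model.target)


# --------------------------------------------------------------------------
# anchoring and climbing


def anchoring_group(base_models: dict[str, SymmetrizedModel]) -> str:
    """Least-broken model among the disjoint k = 2, 3 plane groups.

    Ties (exactly symmetric degenerate input) break toward larger k, then
    lexicographically, so the result is deterministic.
    """
    if not base_models:
        raise ValueError("no base-level models supplied")
    return min(
        base_models,
        key=lambda s: (base_models[s].J_cFC, -base_models[s].k, s),
    )


def _edges_among(symbols, tree_edges):
    return [(a, b) for a, b in tree_edges if a in symbols and b in symbols]


#: Residual sums below this are numerically exact symmetry (pure rounding);
#: a ratio of two such floors carries no information.
EXACT_RESIDUAL_TOL = 1e-9


def _run_comparisons(models, edges, residual_attr):
    comparisons = []
    for sub, sup in edges:
        ml, mm = models[sub], models[sup]
        jl = getattr(ml, residual_attr)
        jm = getattr(mm, residual_attr)
        if jl is None or jm is None:
            continue
        if jl == 0.0:
            # the identically-zero root (p1 / Laue class 2): ascent from it
            # is handled by the anchoring rule, not by a ratio test
            continue
        if jl < EXACT_RESIDUAL_TOL:
            # the subgroup symmetry is exactly present in the data: ascent
            # is permitted precisely when the supergroup is exact as well
            rhs = gaic_bound(ml.k, mm.k, ml.N, mm.N)
            comparisons.append(
                ComparisonResult(
                    sub, sup, jm / jl, rhs, bool(jm < EXACT_RESIDUAL_TOL)
                )
            )
            continue
        comparisons.append(
            climb_test(jl, jm, ml.k, mm.k, ml.N, mm.N, sub=sub, super_=sup)
        )
    return comparisons


def _genuine_set(models, comparisons, anchor):
    """Groups connected to the anchor through fully fulfilled climbs.

    A supergroup joins when every climbing test from its evaluated maximal
    subgroups is fulfilled and at least one of those subgroups already
    belongs to the genuine chain.
    """
    by_super: dict[str, list[ComparisonResult]] = {}
    for c in comparisons:
        by_super.setdefault(c.super_, []).append(c)
    genuine = {anchor}
    changed = True
    while changed:
        changed = False
        for sup, tests in by_super.items():
            if sup in genuine:
                continue
            if all(t.fulfilled for t in tests) and any(
                t.sub in genuine for t in tests
            ):
                genuine.add(sup)
                changed = True
    return genuine


def classify_plane_groups(
    models: dict[str, SymmetrizedModel],
    report: ClassificationReport | None = None,
) -> ClassificationReport:
    """Anchor at the least-broken k = 2, 3 model, then climb the hierarchy.

    The returned report is partial: the final best group, the pseudo list
    and the consistency flag are settled by :func:`consistency_check`.
    """
    report = report or ClassificationReport()
    base = {s: m for s, m in models.items() if s in BASE_LEVEL_GROUPS}
    if not base:
        raise ValueError("models for the k = 2, 3 base level are required")
    anchor = anchoring_group(base)
    edges = _edges_among(set(models), catalog._PLANE_EDGES)
    comparisons = _run_comparisons(models, edges, "J_cFC")
    genuine = _genuine_set(models, comparisons, anchor)

    report.anchoring_group = anchor
    report.comparisons = comparisons
    report.genuine_groups = sorted(
        genuine, key=lambda s: (models[s].k, models[s].J_cFC)
    )
    report.models = {s: models[s].summary() for s in models}
    return report


def classify_laue(
    laue_models: dict[str, SymmetrizedModel],
    report: ClassificationReport | None = None,
) -> ClassificationReport:
    """Projected Laue class: anchor at the least-broken k = 4 or 6 class.

    Laue class 2 has a zero amplitude residual by Friedel symmetry, so it
    is always genuine and never the anchor.
    """
    report = report or ClassificationReport()
    candidates = {
        s: m for s, m in laue_models.items() if m.k in (4, 6) and s != "2"
    }
    if not candidates:
        raise ValueError("Laue models at the k = 4 or 6 level are required")
    anchor = min(
        candidates, key=lambda s: (candidates[s].J_aFC, -candidates[s].k, s)
    )
    edges = _edges_among(set(laue_models), tuple(
        (e.sub, e.super_) for e in catalog.laue_tree()
    ))
    comparisons = _run_comparisons(laue_models, edges, "J_aFC")
    genuine = _genuine_set(laue_models, comparisons, anchor)
    genuine.add("2")

    report.laue_anchor = anchor
    report.laue_comparisons = comparisons
    report.genuine_laue = sorted(
        genuine, key=lambda s: catalog.get_laue_class(s).k
    )
    best = max(
        (s for s in genuine if s in laue_models or s == "2"),
        key=lambda s: (catalog.get_laue_class(s).k,
                       -(laue_models[s].J_aFC if s in laue_models else 0.0)),
    )
    report.best_laue = best
    report.laue_models = {s: m.summary() for s, m in laue_models.items()}
    return report


def consistency_check(
    plane_report: ClassificationReport,
    laue_report: ClassificationReport,
    models: dict[str, SymmetrizedModel] | None = None,
) -> ClassificationReport:
    """Merge the two partial reports and enforce crystallographic
    consistency between the best plane group and the best Laue class.

    When the amplitude-map point group of the formally best plane group
    differs from the genuine Laue class, the plane result is demoted to the
    highest genuine-chain group whose Laue class matches, and the report is
    flagged inconsistent.  Disjoint same-level candidates (e.g. p2gg vs p4)
    are resolved the same way without raising the flag.
    """
    report = plane_report
    report.laue_anchor = laue_report.laue_anchor
    report.genuine_laue = laue_report.genuine_laue
    report.best_laue = laue_report.best_laue
    report.laue_comparisons = laue_report.laue_comparisons
    report.laue_models = laue_report.laue_models

    genuine = set(report.genuine_groups)
    info = report.models
    # maximal elements of the genuine chain
    maximal = [
        g for g in genuine
        if not any(
            sup in genuine for sup in catalog.minimal_supergroups(g)
        )
    ]
    target_laue = report.best_laue
    matching = [g for g in maximal if plane_group_laue_class(g) == target_laue]
    if matching:
        best = min(matching, key=lambda g: (-info[g]["k"], info[g]["J_cFC"]))
        consistent = True
    else:
        # demote into the chain: highest genuine group with a matching
        # amplitude-map point group
        ordered = sorted(
            genuine, key=lambda g: (-info[g]["k"], info[g]["J_cFC"])
        )
        best = next(
            (g for g in ordered if plane_group_laue_class(g) == target_laue),
            report.anchoring_group,
        )
        consistent = False
        report.notes.append(
            "crystallographic inconsistency: formally best plane group "
            f"{ordered[0]} has amplitude-map point group "
            f"{plane_group_laue_class(ordered[0])} but the genuine Laue "
            f"class is {target_laue}; demoted to {best}"
        )

    # final genuine chain: anchor-to-best groups that remain connected
    chain = {best}
    frontier = [best]
    while frontier:
        g = frontier.pop()
        for sub in catalog.maximal_subgroups(g):
            if sub in genuine and sub not in chain:
                chain.add(sub)
                frontier.append(sub)
    chain.add(report.anchoring_group)
    demoted = genuine - chain

    involved = {report.anchoring_group}
    for c in report.comparisons:
        if c.fulfilled:
            involved.update((c.sub, c.super_))
    pseudo = (involved - chain) | demoted
    pseudo = {g for g in pseudo if g in info}

    for c in report.comparisons:
        if not c.fulfilled:
            c.interpretation = "blocked"
        elif c.sub in chain and c.super_ in chain:
            c.interpretation = "ascent"
        else:
            c.interpretation = "pseudo"
    for c in report.laue_comparisons:
        if not c.fulfilled:
            c.interpretation = "blocked"
        elif c.super_ in laue_report.genuine_laue:
            c.interpretation = "ascent"
        else:
            c.interpretation = "pseudo"

    report.best_plane_group = best
    report.consistent = consistent
    report.genuine_groups = sorted(
        chain, key=lambda g: (info[g]["k"], info[g]["J_cFC"])
    )
    report.pseudo_groups = sorted(pseudo, key=lambda g: info[g]["J_cFC"])
    if models is not None and best in models:
        report.noise = noise_variance(models[best])
    else:
        m = info.get(best)
        if m and m["k"] >= 2 and m["J_cFC"] is not None:
            report.noise = NoiseEstimate(
                m["J_cFC"] * m["k"] / (m["N"] * (m["k"] - 1)), best
            )
    return report
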