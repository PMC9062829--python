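"""End-to-end classification: image -> lattice -> models -> report."""

from __future__ import annotations

from .catalog import get_group, get_laue_class
from .extraction import (
    ExtractionSettings,
    Lattice2D,
    PatternImage,
    extract_coefficients,
    refine_lattice,
)
from .hka import CoefficientSet
from .selection import (
    ClassificationReport,
    classify_laue,
    classify_plane_groups,
    consistency_check,
)
from .symmetrize import symmetrize_laue, symmetrize_plane_group

__all__ = [
    "default_group_selection",
    "build_models",
    "classify_coefficients",
    "classify_image",
]

# The "judicious selection" of models evaluated by default: the complete
# disjoint k = 2, 3 base level plus the supergroups relevant for the
# detected lattice metric.  Mirror groups whose base-level subgroups are
# all evaluated anyway (p2mm/p2mg/p2gm) can be requested explicitly.
_SQUARE_SELECTION = (
    "p2", "p1m1", "p11m", "p1g1", "p11g", "c1m1", "c11m", "p3",
    "p2gg", "c2mm", "p4", "p4mm", "p4gm",
)
_RECT_SELECTION = (
    "p2", "p1m1", "p11m", "p1g1", "p11g", "c1m1", "c11m", "p3",
    "p2mm", "p2mg", "p2gm", "p2gg", "c2mm",
)
_HEX_SELECTION = (
    "p2", "p1m1", "p11m", "p1g1", "p11g", "c1m1", "c11m", "p3",
    "c2mm", "p6", "p3m1", "p31m", "p6mm",
)

_LAUE_SELECTION = ("2", "2mm", "4", "4mm", "6", "6mm")

# Study conditions for the synthetic-pattern series: the noise mixtures and
# the matching extraction selections (for heavier noise the dynamic range
# and resolution radius are restricted so the retained coefficients remain
# structure dominated, the established practice for noisy patterns).
STUDY_CONDITIONS: dict[str, dict] = {
    "noise_free": {
        "gaussian_sigma": 0.0, "spread_radius": 0,
        "settings": {"dynamic_range": 100.0, "resolution_radius": None},
    },
    "moderate": {
        "gaussian_sigma": 25.0, "spread_radius": 1,
        "settings": {"dynamic_range": 100.0, "resolution_radius": 350.0},
    },
    "heavy": {
        "gaussian_sigma": 50.0, "spread_radius": 3,
        "settings": {"dynamic_range": 20.0, "resolution_radius": 120.0},
    },
}


def run_study_condition(condition: str, seed: int = 0):
    """Generate the reference pattern, apply a named noise condition and
    classify it; returns (report, lattice, coefficient set, noisy image)."""
    from .patterns import PatternSpec, add_gaussian_noise, add_spread_noise, generate

    cond = STUDY_CONDITIONS[condition]
    image, _ = generate(PatternSpec())
    if cond["gaussian_sigma"] > 0:
        image = add_gaussian_noise(image, cond["gaussian_sigma"], seed=seed)
    if cond["spread_radius"] > 0:
        image = add_spread_noise(image, cond["spread_radius"], seed=seed + 1000)
    settings = ExtractionSettings(**cond["settings"])
    report, lattice, cset = classify_image(image, settings)
    return report, lattice, cset, image


def default_group_selection(lattice: Lattice2D | None) -> tuple[str, ...]:
    if lattice is None:
        return _SQUARE_SELECTION
    kind = lattice.lattice_kind()
    if kind == "square":
        return _SQUARE_SELECTION
    if kind == "hexagonal":
        return _HEX_SELECTION
    return _RECT_SELECTION


def build_models(
    cset: CoefficientSet,
    groups=None,
    laue_classes=_LAUE_SELECTION,
    lattice: Lattice2D | None = None,
):
    """Symmetrize the reference set to every requested group and Laue class."""
    if groups is None:
        groups = default_group_selection(lattice)
    plane_models = {}
    for sym in groups:
        plane_models[sym] = symmetrize_plane_group(cset, get_group(sym))
    laue_models = {}
    for sym in laue_classes:
        laue_models[sym] = symmetrize_laue(cset, get_laue_class(sym))
    return plane_models, laue_models


def classify_coefficients(
    cset: CoefficientSet,
    groups=None,
    laue_classes=_LAUE_SELECTION,
    lattice: Lattice2D | None = None,
) -> ClassificationReport:
    """Classify a coefficient set; returns the merged, consistent report."""
    plane_models, laue_models = build_models(
        cset, groups=groups, laue_classes=laue_classes, lattice=lattice
    )
    plane_report = classify_plane_groups(plane_models)
    laue_report = classify_laue(laue_models)
    report = consistency_check(plane_report, laue_report, plane_models)
    report.plane_model_objects = plane_models  # type: ignore[attr-defined]
    report.laue_model_objects = laue_models  # type: ignore[attr-defined]
    return report


def classify_image(
    image: PatternImage,
    settings: ExtractionSettings | None = None,
    groups=None,
) -> tuple[ClassificationReport, Lattice2D, CoefficientSet]:
    """Full pipeline on an image; returns (report, lattice, reference set)."""
    settings = settings or ExtractionSettings()
    lattice = refine_lattice(image, settings)
    cset = extract_coefficients(image, lattice, settings)
    report = classify_coefficients(cset, groups=groups, lattice=lattice)
    return report, lattice, cset
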