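import numpy as np
import pytest

from planesym import catalog as cat
from planesym.extraction import (
    ExtractionSettings,
    extract_coefficients,
    refine_lattice,
)
from planesym.hka import to_unit_scale
from planesym.patterns import apply_operation_to_raster
from planesym.processing import (
    ReconstructionSettings,
    export_image,
    reconstruct,
    reconstruct_cell,
)
from planesym.symmetrize import symmetrize_plane_group

from conftest import square_cell_coefficients


def test_p1_reconstruction_recovers_pattern(clean_pattern, clean_classification):
    """Fourier filtering recovers the original pattern up to the power of
    the dropped coefficients (Parseval bound on the relative L2 error)."""
    image, _ = clean_pattern
    _, lattice, cset = clean_classification
    model = symmetrize_plane_group(cset, cat.get_group("p1"))
    n0 = 256
    start = (cset.metadata["mask_diameter"] - n0) // 2
    recon = reconstruct(
        model, lattice,
        ReconstructionSettings(canvas=n0, offset=(start, start)),
        frame="image",
    ).intensities
    r0, c0 = cset.metadata["window_offset"]
    target = image.intensities[
        r0 + start : r0 + start + n0, c0 + start : c0 + start + n0
    ]
    rel_err = np.linalg.norm(recon - target) / np.linalg.norm(
        target - target.mean()
    )
    assert rel_err < 0.15


def test_reconstruction_mean_conserved(clean_classification):
    _, lattice, cset = clean_classification
    model = symmetrize_plane_group(cset, cat.get_group("p4"))
    recon = reconstruct(model, lattice, ReconstructionSettings(canvas=194))
    assert recon.intensities.mean() == pytest.approx(
        cset.metadata["mean_intensity"], rel=0.02
    )


@pytest.mark.parametrize("symbol", ["p4", "p4gm"])
def test_reconstruction_invariant_under_group(symbol):
    cset, n = square_cell_coefficients(seed=11)
    model = symmetrize_plane_group(cset, cat.get_group(symbol),
                                   origin=(0.0, 0.0))
    cell = reconstruct_cell(model, n=n, frame="symmetric")
    for op in cat.get_group(symbol).operations:
        resid = np.abs(apply_operation_to_raster(cell, op) - cell).max()
        assert resid <= 1e-6 * np.abs(cell).max()


def test_lattice_too_coarse_rejected(clean_classification):
    from planesym.extraction import Lattice2D

    _, _, cset = clean_classification
    model = symmetrize_plane_group(cset, cat.get_group("p1"))
    with pytest.raises(ValueError):
        reconstruct(model, Lattice2D((9000.0, 0.0), (0.0, 9000.0)),
                    ReconstructionSettings(canvas=128))


def test_export_rescale_and_roundtrip(tmp_path, clean_classification):
    import imageio.v3 as iio

    from planesym.extraction import PatternImage

    _, lattice, cset = clean_classification
    model = symmetrize_plane_group(cset, cat.get_group("p4"))
    recon = reconstruct(model, lattice, ReconstructionSettings(canvas=194))
    path = tmp_path / "recon.png"
    export_image(recon, path)
    back = iio.imread(path)
    assert back.min() == 0 and back.max() == 255
    # relative intensities preserved to quantization accuracy
    arr = recon.intensities
    expected = (arr - arr.min()) / (arr.max() - arr.min()) * 255
    assert np.abs(back.astype(float) - expected).max() <= 0.5 + 1e-9

    const = PatternImage(np.full((128, 128), 3.0))
    export_image(const, tmp_path / "const.png")
    assert iio.imread(tmp_path / "const.png").max() == 128  # midtone guard


def test_histogram_sidecar_written(tmp_path, clean_classification):
    _, lattice, cset = clean_classification
    model = symmetrize_plane_group(cset, cat.get_group("p4"))
    recon = reconstruct(model, lattice, ReconstructionSettings(canvas=194))
    path = tmp_path / "with_hist.png"
    export_image(recon, path, with_histogram=True)
    assert path.exists() and path.stat().st_size > 0


def test_higher_symmetry_averaging_narrows_histogram(clean_pattern):
    """Enforcing p4gm on the delta-broken noisy pattern averages twice as
    many asymmetric units as p4: the intensity distribution narrows."""
    from planesym.patterns import add_gaussian_noise, add_spread_noise

    image, _ = clean_pattern
    noisy = add_spread_noise(add_gaussian_noise(image, 50, 21), 3, 1021)
    settings = ExtractionSettings(dynamic_range=20, resolution_radius=120)
    lattice = refine_lattice(noisy, settings)
    cset = extract_coefficients(noisy, lattice, settings)
    var = {}
    for sym in ("p4", "p4gm"):
        model = symmetrize_plane_group(cset, cat.get_group(sym))
        scale = model.metadata["max_amplitude_prenorm"]
        cell = reconstruct_cell(model, n=97) * scale
        var[sym] = cell.var()
    assert var["p4gm"] < var["p4"]
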