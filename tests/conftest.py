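import numpy as np
import pytest

from planesym.extraction import ExtractionSettings
from planesym.hka import CoefficientSet
from planesym.patterns import PatternSpec, generate
from planesym.pipeline import classify_image


@pytest.fixture(scope="session")
def clean_pattern():
    """The reference synthetic pattern: exact p4, delta = 0.2 broken p4gm."""
    image, meta = generate(PatternSpec())
    return image, meta


@pytest.fixture(scope="session")
def clean_classification(clean_pattern):
    image, _ = clean_pattern
    report, lattice, cset = classify_image(
        image, ExtractionSettings(dynamic_range=100)
    )
    return report, lattice, cset


@pytest.fixture()
def toy_coefficient_set():
    """A small hand-made coefficient set on unit scale."""
    return CoefficientSet(
        h=np.array([1, 0, 1, 2]),
        k=np.array([0, 1, 1, -1]),
        amplitude=np.array([1.0, 0.9, 0.5, 0.25]),
        phase=np.array([0.0, 90.0, -30.0, 120.0]),
        metadata={"dynamic_range": 200.0},
    )


def square_cell_coefficients(n=64, seed=0, band=20):
    """Full coefficient set of a random smooth n x n cell (exact spectrum).

    Indices are restricted to a band small enough that square-lattice point
    operations stay alias-free on the n-periodic index grid.
    """
    rng = np.random.default_rng(seed)
    cell = rng.normal(size=(n, n))
    f = np.fft.fft2(cell)
    ky = np.minimum(np.arange(n), n - np.arange(n))
    damp = np.exp(-0.25 * np.hypot(ky[:, None], ky[None, :]))
    f *= damp
    coeffs = f / n**2
    hs, ks, amps, phases = [], [], [], []
    for h in range(0, band + 1):
        for k in range(-band, band + 1):
            if h == 0 and k <= 0:
                continue
            val = coeffs[k % n, h % n]
            hs.append(h)
            ks.append(k)
            amps.append(abs(val))
            phases.append(np.degrees(np.angle(val)))
    return CoefficientSet(
        np.array(hs), np.array(ks), np.array(amps), np.array(phases),
        metadata={"dynamic_range": 1e12},
    ), n
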