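"""Reading and writing CRISP-style ``.hka`` Fourier-coefficient lists.

An ``.hka`` file is a whitespace-separated text table with columns
``H K AMP PHASE`` (phase in degrees).  Amplitudes are on the conventional
file scale where the maximal amplitude is 10000; lines whose first token is
not numeric are treated as comments/headers and skipped, and trailing
columns beyond the fourth are tolerated and ignored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FourierCoefficient",
    "CoefficientSet",
    "read_hka",
    "write_hka",
    "to_unit_scale",
    "HkaFormatError",
]

FILE_SCALE = 10000.0


class HkaFormatError(ValueError):
    """Malformed or empty .hka content."""


@dataclass(frozen=True)
class FourierCoefficient:
    h: int
    k: int
    amplitude: float
    phase: float  # degrees in [-180, 180)

    def __post_init__(self):
        if (self.h, self.k) == (0, 0):
            raise ValueError("(0,0) is the DC term and is not stored")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def wrap_phase_deg(phase) -> np.ndarray | float:
    """Wrap degrees into [-180, 180)."""
    return (np.asarray(phase, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class CoefficientSet:
    """Indexed Fourier coefficients of a 2D-periodic image.

    One Friedel representative is stored per +/-(h,k) pair (the mate is
    implied by the conjugate symmetry of a real image).  ``metadata`` keeps
    extraction settings (mask diameter, dynamic range, resolution radius,
    source label) so downstream models can re-apply the same thresholds.
    """

    h: np.ndarray
    k: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray  # degrees
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=int)
        self.k = np.asarray(self.k, dtype=int)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = wrap_phase_deg(self.phase)
        if len({(int(a), int(b)) for a, b in zip(self.h, self.k)}) != len(self.h):
            raise ValueError("duplicate indices in coefficient set")
        pairs = {(int(a), int(b)) for a, b in zip(self.h, self.k)}
        if any((-a, -b) in pairs for (a, b) in pairs):
            raise ValueError("both Friedel mates present; store one representative")
        if (0, 0) in pairs:
            raise ValueError("(0,0) must not be stored")

    def __len__(self) -> int:
        return len(self.h)

    @property
    def max_amplitude(self) -> float:
        return float(self.amplitude.max()) if len(self) else 0.0

    @property
    def indices(self) -> np.ndarray:
        return np.stack([self.h, self.k], axis=1)

    def complex_values(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * np.deg2rad(self.phase))

    def coefficients(self) -> list[FourierCoefficient]:
        return [
            FourierCoefficient(int(a), int(b), float(m), float(p))
            for a, b, m, p in zip(self.h, self.k, self.amplitude, self.phase)
        ]

    def index_map(self) -> dict[tuple[int, int], int]:
        return {(int(a), int(b)): i for i, (a, b) in enumerate(zip(self.h, self.k))}

    def to_json(self) -> str:
        return json.dumps(
            {
                "metadata": self.metadata,
                "coefficients": [
                    [int(a), int(b), float(m), float(p)]
                    for a, b, m, p in zip(self.h, self.k, self.amplitude, self.phase)
                ],
            },
            indent=1,
        )

    @classmethod
    def from_coefficients(cls, coeffs, metadata=None) -> "CoefficientSet":
        coeffs = list(coeffs)
        return cls(
            h=np.array([c.h for c in coeffs], dtype=int),
            k=np.array([c.k for c in coeffs], dtype=int),
            amplitude=np.array([c.amplitude for c in coeffs], dtype=float),
            phase=np.array([c.phase for c in coeffs], dtype=float),
            metadata=dict(metadata or {}),
        )


def _friedel_representative(h: int, k: int) -> bool:
    return h > 0 or (h == 0 and k > 0)


def read_hka(path) -> CoefficientSet:
    """Read an ``.hka`` text file into a :class:`CoefficientSet`.

    Friedel mates that are both listed are collapsed onto the (h>0, or
    h=0,k>0) representative; a conjugate-consistency warning is emitted when
    the mate's phase disagrees by more than one degree.
    """
    path = Path(path)
    rows: list[tuple[int, int, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                float(tokens[0])
            except ValueError:
                continue  # header/comment line
            if len(tokens) < 4:
                raise HkaFormatError(
                    f"{path.name}:{lineno}: expected 'H K AMP PHASE', got {line!r}"
                )
            try:
                h, k = int(float(tokens[0])), int(float(tokens[1]))
                amp, phase = float(tokens[2]), float(tokens[3])
            except ValueError as exc:
                raise HkaFormatError(f"{path.name}:{lineno}: {exc}") from None
            rows.append((h, k, amp, float(wrap_phase_deg(phase))))
    if not rows:
        raise HkaFormatError(f"{path.name}: no data rows")

    kept: dict[tuple[int, int], tuple[float, float]] = {}
    for h, k, amp, phase in rows:
        if (h, k) == (0, 0):
            continue
        rep, rep_amp, rep_phase = (h, k), amp, phase
        if not _friedel_representative(h, k):
            rep, rep_phase = (-h, -k), float(wrap_phase_deg(-phase))
        if rep in kept:
            prev_amp, prev_phase = kept[rep]
            dphi = abs(float(wrap_phase_deg(prev_phase - rep_phase)))
            if dphi > 1.0 or not np.isclose(prev_amp, rep_amp, rtol=1e-3, atol=1e-6):
                warnings.warn(
                    f"{path.name}: Friedel mates of {rep} disagree "
                    f"(d-phase {dphi:.2f} deg); keeping the first",
                    stacklevel=2,
                )
            continue  # keep first occurrence
        kept[rep] = (rep_amp, rep_phase)

    hs = np.array([ix[0] for ix in kept], dtype=int)
    ks = np.array([ix[1] for ix in kept], dtype=int)
    amps = np.array([v[0] for v in kept.values()], dtype=float)
    phases = np.array([v[1] for v in kept.values()], dtype=float)
    return CoefficientSet(hs, ks, amps, phases, metadata={"source": str(path)})


def write_hka(cset: CoefficientSet, path) -> None:
    """Write ``H K AMP PHASE`` rows, amplitudes rescaled so the max is 10000."""
    if len(cset) == 0:
        raise HkaFormatError("refusing to write an empty coefficient set")
    if cset.max_amplitude <= 0:
        raise HkaFormatError("all-zero amplitudes cannot be put on the file scale")
    scale = FILE_SCALE / cset.max_amplitude
    with open(path, "w") as fh:
        fh.write("H K AMP PHASE\n")
        for h, k, amp, phase in zip(cset.h, cset.k, cset.amplitude, cset.phase):
            fh.write(f"{int(h)} {int(k)} {amp * scale:.4f} {phase:.4f}\n")


def to_unit_scale(cset: CoefficientSet) -> CoefficientSet:
    """Divide amplitudes by the set's own maximum (idempotent)."""
    m = cset.max_amplitude
    if m <= 0:
        raise ValueError("cannot normalize an all-zero coefficient set")
    return CoefficientSet(
        cset.h.copy(),
        cset.k.copy(),
        cset.amplitude / m,
        cset.phase.copy(),
        metadata=dict(cset.metadata),
    )
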