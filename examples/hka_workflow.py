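"""Working with CRISP-style .hka coefficient files.

Extracts the structure-bearing coefficients of the reference pattern,
writes them as an .hka text table (H K AMP PHASE, maximum amplitude
10000), reads them back, and symmetrizes the set to p4 — printing the
residual sums a climbing-up test would consume.
"""

import tempfile
from pathlib import Path

from planesym import (
    ExtractionSettings,
    extract_coefficients,
    read_hka,
    refine_lattice,
    write_hka,
)
from planesym.patterns import PatternSpec, generate
from planesym.symmetrize import symmetrize_plane_group

image, _ = generate(PatternSpec())
settings = ExtractionSettings(dynamic_range=100)
lattice = refine_lattice(image, settings)
cset = extract_coefficients(image, lattice, settings)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "reference.hka"
    write_hka(cset, path)
    print(f"wrote {len(cset)} coefficients; first lines:")
    print("\n".join(path.read_text().splitlines()[:4]))
    again = read_hka(path)

model = symmetrize_plane_group(again, "p4", dynamic_range=100)
print(f"\np4 model: N = {model.N}, k = {model.k}, "
      f"origin = ({model.origin[0]:.4f}, {model.origin[1]:.4f})")
print(f"J_cFC = {model.J_cFC:.6f} (complex residual sum)")
print(f"J_aFC = {model.J_aFC:.6f} (amplitude residual sum)")
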