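"""The heavy-noise failure mode and its detection.

Under heavy mixed Gaussian + spread noise the fine differences between
genuine symmetries and strong Fedorov-type pseudosymmetries can dissolve:
the plane-group ascent may then run all the way to a k = 8 group (p4gm or
p4mm).  The projected Laue class — determined from origin-invariant
amplitudes — is more robust and stays 4.  The crystallographic consistency
check catches the contradiction, flags the report and demotes the plane
group to the highest genuine-chain group compatible with Laue class 4.
"""

from planesym import ExtractionSettings
from planesym.patterns import PatternSpec, add_gaussian_noise, add_spread_noise, generate
from planesym.pipeline import STUDY_CONDITIONS, classify_image

clean, _ = generate(PatternSpec())
cond = STUDY_CONDITIONS["heavy"]
settings = ExtractionSettings(**cond["settings"])

for seed in range(1, 6):
    noisy = add_gaussian_noise(clean, cond["gaussian_sigma"], seed=seed)
    noisy = add_spread_noise(noisy, cond["spread_radius"], seed=seed + 1000)
    report, _, cset = classify_image(noisy, settings)
    flag = "consistent" if report.consistent else "INCONSISTENT -> demoted"
    print(f"seed {seed}: N={len(cset):4d}  best={report.best_plane_group:5s} "
          f"Laue={report.best_laue}  {flag}")
    for note in report.notes:
        print(f"   {note}")
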