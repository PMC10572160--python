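"""Fit the MDA-SH-storage-day surface to the packaged calibration data.

Eight refrigerated oyster batches (days 0..14) each contribute a
batch-mean malondialdehyde (MDA) and total sulfhydryl (SH) value; a
7-term poly31 polynomial maps (MDA, SH) to storage day.
"""

from oysterfresh import fit_surface, load_calibration
from oysterfresh.surface import TERM_NAMES

calibration = load_calibration()
surface = fit_surface(calibration)

print(f"fit on {len(calibration)} batches, R^2 = {surface.r_squared:.4f}")
for name, coef in zip(TERM_NAMES, surface.coefficients):
    print(f"  {name:>6s} : {coef:+.4g}")

for mda, sh in [(5.15, 119.19), (6.25, 106.42), (10.20, 66.37)]:
    day = surface.predict(mda, sh)
    print(f"MDA {mda:5.2f} nmol/mgprot, SH {sh:6.2f} umol/gprot "
          f"-> predicted storage day {day:5.2f}")
# The three inputs are the level-2/3/4 median pairs; the predicted day
# rises as MDA accumulates and SH is lost.
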