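"""dSTORM colocalization: alignment, cross-correlation, pixel ratios.

Generates a binarized two-channel image pair with a planted 50% on-pixel
overlap and a rigid (3, -2) px shift, aligns on fiducial beads, computes
the normalized FFT pair cross-correlation with its radial profile, and
the pixel-by-pixel colocalization percentages.  Writes
results/storm_radial_profile.tsv.
"""

import sys
from pathlib import Path

import numpy as np

from loopforge import synthetic
from loopforge.storm import StormImage, align_by_fiducials, coloc_ratios, cross_correlation

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

overlap, density, shift = 0.5, 0.05, (3, -2)
img_a, img_b, beads_a, beads_b = synthetic.generate_storm_pair(
    overlap, density, shape=(512, 512), shift=shift, n_beads=5, seed=SEED)
a = StormImage(img_a)
aligned = align_by_fiducials(a, beads_a, StormImage(img_b), beads_b)
print(f"planted shift {shift}, estimated {aligned['shift']} "
      f"(bead spread {aligned['spread']:.2f} px)")

cc = cross_correlation(a, aligned["aligned"])
np.savetxt(OUT / "storm_radial_profile.tsv",
           np.column_stack([cc.radial_r, cc.radial_c, cc.radial_counts]),
           delimiter="\t", header="radius_px\tc\tn_pixels", comments="")
print(f"c(0) = {cc.at(0, 0):.2f} for the planted-overlap pair "
      f"(identical channels would give 1/rho = {1 / a.density:.1f}; "
      "uncorrelated channels give 1)")

ratios = coloc_ratios(a, aligned["aligned"])
print(f"colocalization: {ratios['percent_a_with_b']:.1f}% of channel-A pixels share "
      f"channel B, {ratios['percent_b_with_a']:.1f}% vice versa "
      f"(planted overlap {100 * overlap:.0f}%)")
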