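"""Loop calling with the donut filter, loop strength, and APA.

Calls loops on each condition's summed map at the reference settings
(p=2, i=5 at 10 kb), merges lists, measures planted-truth recall and
precision, scores loop strength at every planted pixel, and builds the
aggregate peak analysis.  Writes results/loops.bedpe and
results/apa_matrix.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from loopforge import pipeline, synthetic
from loopforge.hic import ContactMatrix
from loopforge.loops import Loop, apa, call_loops, loop_strength, merge_resolutions

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

cfg_dict = pipeline.default_config()
ls = cfg_dict["loop_scale"]
specs = pipeline.default_loop_specs(ls["chrom_length"], ls["resolution"],
                                    n_loops=ls["n_loops"], enrichment=ls["enrichment"])
cfg = synthetic.SynthConfig(
    chrom_length=ls["chrom_length"], resolution=ls["resolution"], depth=ls["depth"],
    boundary_positions=[tuple(b) for b in ls["boundaries"]],
    loop_specs=specs, replicates_per_condition=ls["replicates"], seed=SEED)
matrices, truth = synthetic.generate_hic_experiment(cfg, seed=SEED)

cal = cfg_dict["caller"]
summed = {c: ContactMatrix.from_dense(sum(m[0].dense() for m in matrices[c]),
                                      resolution=cfg.resolution)
          for c in cfg.conditions}
called = {c: call_loops(summed[c], peak_width=cal["peak_width"],
                        donut_width=cal["donut_width"], fdr=cal["fdr"])
          for c in cfg.conditions}
merged = merge_resolutions({cfg.resolution: called[cfg.conditions[0]]
                            + called[cfg.conditions[1]]})

planted = [(L.bin1, L.bin2) for L in truth.loops]
near = lambda a, b: abs(a[0] - b[0]) <= 1 and abs(a[1] - b[1]) <= 1
callset = [(L.bin1, L.bin2) for L in merged]
recall = np.mean([any(near(c, p) for c in callset) for p in planted])
precision = np.mean([any(near(c, p) for p in planted) for c in callset])
print(f"called {[len(called[c]) for c in cfg.conditions]} loops per condition, "
      f"{len(merged)} after merging; recall {recall:.2f}, precision {precision:.2f} "
      "vs planted truth")

for L in merged:
    L.strength = loop_strength(summed[cfg.conditions[0]], L,
                               cal["peak_width"], cal["donut_width"])
strengths = [L.strength for L in merged if np.isfinite(L.strength)]
print(f"loop strength (center/donut): median {np.median(strengths):.2f}")

truth_loops = [Loop("chr1", L.bin1, L.bin2, cfg.resolution) for L in truth.loops]
for c in cfg.conditions:
    res = apa(summed[c], truth_loops, k=8)
    print(f"APA score [{c}]: {res.score:.2f} over {res.n_loops} loops "
          f"({res.n_skipped} without window support)")
    if c == cfg.conditions[0]:
        np.savetxt(OUT / "apa_matrix.tsv", res.matrix, delimiter="\t")

pipeline._loops_to_bedpe(merged, OUT / "loops.bedpe")
print(f"wrote {OUT / 'loops.bedpe'}")
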