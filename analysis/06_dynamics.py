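"""Domain scores, differential internal interactions, differential loops.

Computes per-replicate domain scores at the planted loops, tests them
between conditions, runs the replicate-aware NB differential-loop
detection with distance regimes, and assigns each gene to its most
dynamic containing loop.  Writes results/domain_scores.tsv and
results/differential_loops.tsv.
"""

import sys
from pathlib import Path

import numpy as np

from loopforge import pipeline, synthetic
from loopforge.annotation import associate_genes
from loopforge.dynamics import (
    assign_gene_to_most_dynamic_loop,
    differential_domain_scores,
    differential_loops,
    domain_score,
)
from loopforge.loops import Loop

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

cfg_dict = pipeline.default_config()
ls = cfg_dict["loop_scale"]
specs = pipeline.default_loop_specs(ls["chrom_length"], ls["resolution"],
                                    n_loops=ls["n_loops"], enrichment=ls["enrichment"])
cfg = synthetic.SynthConfig(
    chrom_length=ls["chrom_length"], resolution=ls["resolution"], depth=ls["depth"],
    loop_specs=specs, replicates_per_condition=ls["replicates"], seed=SEED)
matrices, truth = synthetic.generate_hic_experiment(cfg, seed=SEED)
_, genes = synthetic.generate_expression(truth, cfg, seed=SEED + 2)

loops = [Loop("chr1", L.bin1, L.bin2, cfg.resolution) for L in truth.loops]
dsc = {c: np.array([[domain_score(m[0], L) for L in loops]
                    for m in matrices[c]]).T
       for c in cfg.conditions}
print(f"domain scores at {len(loops)} loops: "
      f"median D = {np.nanmedian(dsc[cfg.conditions[0]]):.3f}")

diff_d = differential_domain_scores(dsc[cfg.conditions[1]], dsc[cfg.conditions[0]])
diff_d.to_csv(OUT / "domain_scores.tsv", sep="\t", index=False)
print(f"differential D-scores: {(diff_d['label'] != 'static').sum()} dynamic")

res = differential_loops(
    {cfg.resolution: {c: [m[0] for m in matrices[c]] for c in cfg.conditions}},
    caller_params={cfg.resolution: (cfg_dict["caller"]["peak_width"],
                                    cfg_dict["caller"]["donut_width"])})
res.to_csv(OUT / "differential_loops.tsv", sep="\t", index=False)
dyn_truth = {(L.bin1, L.bin2) for L in truth.loops
             if L.condition_factors.get("MKO", 1.0) != 1.0}
sig = res[res["significant"]]
hits = sum(1 for b1, b2 in dyn_truth
           if len(sig[(abs(sig.bin1 - b1) <= 1) & (abs(sig.bin2 - b2) <= 1)]))
print(f"differential loops: {len(sig)} significant of {len(res)} tested; "
      f"{hits}/{len(dyn_truth)} planted condition-specific loops recovered")
for regime in ("le150kb", "gt150kb"):
    sub = res[res["regime"] == regime]
    print(f"  {regime}: {sub['significant'].sum()} significant / {len(sub)} tested")

pairs = associate_genes(loops, genes)
if len(pairs) and len(diff_d):
    best = assign_gene_to_most_dynamic_loop(pairs, diff_d)
    best.to_csv(OUT / "gene_most_dynamic_loop.tsv", sep="\t", index=False)
    print(f"{len(best)} genes assigned to their most dynamic containing loop")
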