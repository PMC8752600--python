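"""Generate the study's synthetic datasets with planted architecture.

Writes the loop-scale contact maps (two conditions x two replicates,
10 kb bins), the compartment-scale maps (100 kb bins), ChIP peak tracks,
an expression count table, and the recorded ground truth under
results/simulation/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from loopforge import pipeline, synthetic
from loopforge.hic import write_coo

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results" / "simulation"
OUT.mkdir(parents=True, exist_ok=True)

cfg_dict = pipeline.default_config()
cfg_dict["seed"] = SEED
ls = cfg_dict["loop_scale"]
specs = pipeline.default_loop_specs(ls["chrom_length"], ls["resolution"],
                                    n_loops=ls["n_loops"], enrichment=ls["enrichment"])
cfg = synthetic.SynthConfig(
    chrom_length=ls["chrom_length"], resolution=ls["resolution"], depth=ls["depth"],
    boundary_positions=[tuple(b) for b in ls["boundaries"]],
    loop_specs=specs, replicates_per_condition=ls["replicates"], seed=SEED)
matrices, truth = synthetic.generate_hic_experiment(cfg, seed=SEED)

for cond, reps in matrices.items():
    for r, mats in enumerate(reps):
        write_coo(mats[0], OUT / f"{cond}_rep{r + 1}.coo.txt")
(OUT / "chrom.sizes").write_text(f"chr1\t{ls['chrom_length']}\n")

peaks = synthetic.generate_peak_tracks(truth, cfg, seed=SEED + 1)
for factor, df in peaks.items():
    df.to_csv(OUT / f"peaks_{factor}.tsv", sep="\t", index=False)
counts, genes = synthetic.generate_expression(truth, cfg, seed=SEED + 2)
counts.to_csv(OUT / "expression_counts.tsv", sep="\t")
genes.to_csv(OUT / "gene_models.tsv", sep="\t")

(OUT / "truth.json").write_text(json.dumps({
    "planted_loops": [{"bin1": L.bin1, "bin2": L.bin2, "enrichment": L.enrichment,
                       "condition_factors": L.condition_factors} for L in truth.loops],
    "boundary_bins": truth.boundary_bins["chr1"],
    "n_peak_placements": len(truth.peak_placements),
}, indent=2))

total = sum(m[0].total_cis for reps in matrices.values() for m in reps)
print(f"planted {len(truth.loops)} loops, {len(truth.boundary_bins['chr1'])} boundaries; "
      f"{len(truth.peak_placements)} peak placements; total cis contacts {total:.0f}")
print(f"outputs in {OUT}")
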