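"""End-to-end orchestration on synthetic data: simulate -> compartments /
boundaries / loops -> annotate -> dynamics -> expression -> colocalization.

A single master seed drives every stage through spawned substreams, so a
rerun with the same config reproduces every output bytewise.  Stage
outputs are written as plain-text genomic formats (COO triplets, BED,
BEDPE, TSV) plus one machine-readable ``summary.json`` with provenance.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, compartments, dynamics, expression, insulation, loops as loops_mod, storm, synthetic
from .hic import ContactMatrix, write_coo

__all__ = ["default_config", "default_loop_specs", "run_pipeline"]

_ALLOWED_TOP = {"seed", "conditions", "loop_scale", "compartment_scale", "storm", "caller", "expression"}


def default_loop_specs(chrom_length: int, resolution: int, n_loops: int = 36,
                       enrichment: float = 6.0, conditions: tuple[str, str] = ("WT", "MKO")):
    """A deterministic planted-loop panel exercising every downstream class.

    Loops are spaced along the chromosome with anchor separations from
    ~15 to ~60 bins; binding assignments cycle through the four
    anchor-occupancy classes, every sixth loop is condition-specific
    (three-fold weaker in the second condition, i.e. lost on knockout)
    with a planted expressed gene, and MyoD dynamics cycle
    static/enhanced/reduced.
    """
    n_bins = chrom_length // resolution
    specs = []
    bindings = [("both", "none"), ("both", "left"), ("left", "both"), ("none", "both")]
    dynamics_cycle = ["static", "enhanced", "reduced"]
    pos = 30
    k = 0
    while len(specs) < n_loops and pos < n_bins - 80:
        sep = 15 + (k * 7) % 45
        a1, a2 = pos, pos + sep
        if a2 >= n_bins - 15:
            pos += 20
            k += 1
            continue
        myod, ctcf = bindings[k % 4]
        cond_factor = {conditions[0]: 1.0, conditions[1]: 1.0}
        gene_fc = None
        if k % 6 == 5:
            cond_factor = {conditions[0]: 1.0, conditions[1]: 1.0 / 3.0}
            gene_fc = -1.0
        specs.append(synthetic.LoopSpec(
            anchor1=a1 * resolution, anchor2=a2 * resolution,
            enrichment=enrichment, condition_factors=cond_factor,
            myod=myod, ctcf=ctcf, myod_dynamic=dynamics_cycle[k % 3],
            gene_log2fc=gene_fc,
        ))
        pos += sep + 12
        k += 1
    return specs


def default_config() -> dict:
    return {
        "seed": 0,
        "conditions": ["WT", "MKO"],
        "loop_scale": {
            "chrom_length": 8_000_000,
            "resolution": 10_000,
            "depth": 3_200_000,
            "decay_exponent": 1.0,
            "n_loops": 30,
            "enrichment": 6.0,
            "boundaries": [[2_500_000, 0.3], [5_500_000, 0.5]],
            "replicates": 3,
        },
        "compartment_scale": {
            "chrom_length": 20_000_000,
            "resolution": 100_000,
            "depth": 2_000_000,
            "block_size": 2_000_000,
            "plaid_strength": 1.8,
            "replicates": 4,
        },
        "storm": {"overlap_fraction": 0.5, "density": 0.05, "shape": [256, 256],
                  "shift": [3, -2], "n_beads": 5},
        "caller": {"peak_width": 2, "donut_width": 5, "fdr": 0.10},
        "expression": {"n_background_genes": 300},
    }


def _validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("loop_scale", "compartment_scale"):
        if key not in cfg:
            raise ValueError(f"config missing required block: {key}")


def _sub_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _write_peaks_bed(df: pd.DataFrame, path: Path) -> None:
    cols = ["chrom", "start", "end", "name"]
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=[c for c in cols if c in df.columns])


def _loops_to_bedpe(loop_list, path: Path, extra: dict | None = None) -> None:
    rows = []
    for L in loop_list:
        rows.append({
            "chrom1": L.chrom, "start1": L.anchor1[0], "end1": L.anchor1[1],
            "chrom2": L.chrom, "start2": L.anchor2[0], "end2": L.anchor2[1],
            "name": ".", "score": -np.log10(max(L.qvalue, 1e-300)) if np.isfinite(L.qvalue) else 0.0,
            "strand1": ".", "strand2": ".",
            "strength": L.strength, "class": L.label or ".",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run every stage on synthetic data and write the results bundle.

    Returns the summary dict (also written to ``summary.json``).
    """
    _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    cfg_hash = hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
    master = int(config.get("seed", 0))
    seeds = _sub_seeds(master, 8)
    conds = tuple(config.get("conditions", ["WT", "MKO"]))
    summary: dict = {"config_hash": cfg_hash, "seed": master, "stages": {}}
    log_lines = []

    def log(stage, msg):
        line = f"[{time.time() - t0:7.1f}s] {stage}: {msg}"
        log_lines.append(line)

    # --- stage 1: loop-scale simulation -------------------------------------
    ls = config["loop_scale"]
    loop_specs = default_loop_specs(ls["chrom_length"], ls["resolution"],
                                    n_loops=ls.get("n_loops", 36),
                                    enrichment=ls.get("enrichment", 6.0), conditions=conds)
    synth_cfg = synthetic.SynthConfig(
        chrom_length=ls["chrom_length"], resolution=ls["resolution"], depth=ls["depth"],
        decay_exponent=ls.get("decay_exponent", 1.0),
        boundary_positions=[tuple(b) for b in ls.get("boundaries", [])],
        loop_specs=loop_specs, conditions=conds,
        replicates_per_condition=ls.get("replicates", 2), seed=seeds[0],
    )
    matrices, truth = synthetic.generate_hic_experiment(synth_cfg, seed=seeds[0])
    mat_dir = outdir / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for cond in conds:
        for rep, mats in enumerate(matrices[cond]):
            write_coo(mats[0], mat_dir / f"{cond}_rep{rep + 1}.coo.txt")
    (outdir / "chrom.sizes").write_text(f"chr1\t{ls['chrom_length']}\n")
    peak_tracks = synthetic.generate_peak_tracks(truth, synth_cfg, seed=seeds[1])
    counts, gene_models = synthetic.generate_expression(
        truth, synth_cfg, seed=seeds[2],
        n_background_genes=config.get("expression", {}).get("n_background_genes", 300))
    log("simulate", f"{len(loop_specs)} planted loops, {len(truth.peak_placements)} peaks")
    summary["stages"]["simulate"] = {"n_planted_loops": len(loop_specs),
                                     "n_peak_placements": len(truth.peak_placements)}

    # --- stage 2: compartments ----------------------------------------------
    cs = config["compartment_scale"]
    comp_cfg = synthetic.SynthConfig(
        chrom_length=cs["chrom_length"], resolution=cs["resolution"], depth=cs["depth"],
        compartment_block_size=cs.get("block_size", 2_000_000),
        plaid_strength=cs.get("plaid_strength", 1.8), conditions=conds,
        replicates_per_condition=cs.get("replicates", 4), seed=seeds[3],
    )
    comp_mats, comp_truth = synthetic.generate_hic_experiment(comp_cfg, seed=seeds[3])
    activity = np.where(comp_truth.compartment_labels["chr1"] == "A", 1.0, -1.0)
    tracks = {c: [compartments.compartment_eigenvector(reps[0], activity)
                  for reps in comp_mats[c]] for c in conds}
    majors = {c: compartments.majority_label(tracks[c]) for c in conds}
    shifts = compartments.shift_stats(majors[conds[0]], majors[conds[1]])
    acc = {}
    for c in conds:
        lab = majors[c].labels
        informative = lab != compartments.AMBIGUOUS
        acc[c] = float(100.0 * (lab[informative] == comp_truth.compartment_labels["chr1"][informative]).mean())
    pd.DataFrame({c: majors[c].labels for c in conds}).to_csv(outdir / "compartments.tsv", sep="\t")
    log("compartments", f"shift B->A {shifts['percent_B_to_A']:.2f}%")
    summary["stages"]["compartments"] = {**shifts, "label_accuracy_percent": acc}

    # --- stage 3: insulation / CDBs -----------------------------------------
    window = min(500_000, ls["chrom_length"] // 6)
    per_cond_tracks = {}
    for c in conds:
        summed = sum(m[0].dense() for m in matrices[c])
        cm = ContactMatrix.from_dense(summed, chrom="chr1", resolution=ls["resolution"])
        per_cond_tracks[c] = insulation.insulation_track(cm, window=window)
    cdbs = insulation.detect_cdbs(per_cond_tracks[conds[0]])
    cdb_bins = [c.bin for c in cdbs]
    ri = {}
    for c in conds:
        per_rep = []
        for m in matrices[c]:
            tr = insulation.insulation_track(m[0], window=window)
            per_rep.append(insulation.cdb_ri_at_bins(tr, cdb_bins))
        ri[c] = np.column_stack(per_rep) if per_rep else np.empty((len(cdb_bins), 0))
    diff_cdb = (insulation.differential_cdbs(ri[conds[1]], ri[conds[0]])
                if len(cdb_bins) >= 2 else pd.DataFrame())
    classes = insulation.cdb_binding_classes(cdbs, per_cond_tracks[conds[0]],
                                             peak_tracks["MyoD"], peak_tracks["CTCF"])
    pd.DataFrame({"bin": cdb_bins, "ri": [c.ri for c in cdbs],
                  "class": [c.binding_class for c in cdbs]}).to_csv(
        outdir / "cdbs.tsv", sep="\t", index=False)
    if len(diff_cdb):
        diff_cdb.to_csv(outdir / "differential_cdbs.tsv", sep="\t", index=False)
    log("cdb", f"{len(cdbs)} CDBs")
    summary["stages"]["cdb"] = {
        "n_cdbs": len(cdbs),
        "n_differential": int((diff_cdb["label"] != "static").sum()) if len(diff_cdb) else 0,
        "boundary_bins_planted": [b for b, _ in truth.boundary_bins["chr1"]],
    }

    # --- stage 4: loop calling / APA ----------------------------------------
    cal = config.get("caller", {})
    p, iw, fdr = cal.get("peak_width", 2), cal.get("donut_width", 5), cal.get("fdr", 0.10)
    called = {}
    summed_mats = {}
    for c in conds:
        summed = sum(m[0].dense() for m in matrices[c])
        cm = ContactMatrix.from_dense(summed, chrom="chr1", resolution=ls["resolution"])
        summed_mats[c] = cm
        called[c] = loops_mod.call_loops(cm, peak_width=p, donut_width=iw, fdr=fdr)
    merged = loops_mod.merge_resolutions({ls["resolution"]: called[conds[0]] + called[conds[1]]})
    for L in merged:
        L.strength = loops_mod.loop_strength(summed_mats[conds[0]], L, p, iw)
    apa_res = {c: loops_mod.apa(summed_mats[c], called[c], k=8) for c in conds}
    _loops_to_bedpe(merged, outdir / "loops.bedpe")
    log("loops", f"{[len(called[c]) for c in conds]} called, {len(merged)} merged")
    summary["stages"]["loops"] = {
        "n_called": {c: len(called[c]) for c in conds},
        "n_merged": len(merged),
        "apa_score": {c: apa_res[c].score for c in conds},
    }

    # --- stage 5: annotation -------------------------------------------------
    myod = peak_tracks["MyoD"]
    rep_cols_a = [f"{conds[0]}_rep{r + 1}" for r in range(synth_cfg.replicates_per_condition)]
    rep_cols_b = [f"{conds[1]}_rep{r + 1}" for r in range(synth_cfg.replicates_per_condition)]
    if len(myod):
        labeled = annotation.label_peak_dynamics(myod, rep_cols_a, rep_cols_b)
        pseudo = annotation.make_pseudo_peaks(labeled)
    else:
        labeled, pseudo = myod, {"GM": myod, "DM": myod}
    class_df = annotation.classify_loops(merged, myod, peak_tracks["CTCF"])
    gene_pairs = annotation.associate_genes(merged, gene_models)
    fg, bg = synthetic.generate_sequences(60, 120, 400, seed=seeds[4])
    ebox = annotation.ebox_enrichment(fg, bg)
    _write_peaks_bed(myod, outdir / "myod_peaks.bed")
    class_df.to_csv(outdir / "loop_classes.tsv", sep="\t", index=False)
    log("annotate", f"{len(class_df)} loops classified, E-box p={ebox['pvalue']:.2e}")
    summary["stages"]["annotate"] = {
        "class_counts": {k: v for k, v in class_df["class"].value_counts().items()} if len(class_df) else {},
        "myod_both_xor_neither": [class_df.attrs.get(f"MyoD_percent_{k}") for k in ("Both", "Xor", "Neither")] if len(class_df) else [],
        "n_pseudo_gm": len(pseudo["GM"]), "n_pseudo_dm": len(pseudo["DM"]),
        "ebox": ebox, "n_gene_loop_pairs": len(gene_pairs),
    }

    # --- stage 6: dynamics ---------------------------------------------------
    dsc = {}
    for c in conds:
        cols = []
        for m in matrices[c]:
            cols.append([dynamics.domain_score(m[0], L) for L in merged])
        dsc[c] = np.array(cols).T
    diff_d = (dynamics.differential_domain_scores(dsc[conds[1]], dsc[conds[0]])
              if len(merged) >= 2 else pd.DataFrame())
    diff_loops = dynamics.differential_loops(
        {ls["resolution"]: {c: [m[0] for m in matrices[c]] for c in conds}},
        caller_params={ls["resolution"]: (p, iw)})
    if len(diff_d):
        diff_d.to_csv(outdir / "domain_scores.tsv", sep="\t", index=False)
        gene_best = dynamics.assign_gene_to_most_dynamic_loop(gene_pairs, diff_d)
        gene_best.to_csv(outdir / "gene_most_dynamic_loop.tsv", sep="\t", index=False)
    diff_loops.to_csv(outdir / "differential_loops.tsv", sep="\t", index=False)
    log("dynamics", f"{int(diff_loops['significant'].sum()) if len(diff_loops) else 0} differential loops")
    summary["stages"]["dynamics"] = {
        "n_diff_dscore": int((diff_d["label"] != "static").sum()) if len(diff_d) else 0,
        "n_diff_loops": int(diff_loops["significant"].sum()) if len(diff_loops) else 0,
    }

    # --- stage 7: expression -------------------------------------------------
    de = expression.simple_de(counts, rep_cols_a, rep_cols_b)
    de.to_csv(outdir / "differential_expression.tsv", sep="\t")
    try:
        promoter = expression.promoter_peak_expression_summary(myod, gene_models, de)
    except ValueError:
        promoter = {"n_unchanged": 0, "n_total": 0, "percent_unchanged": float("nan")}
    log("expression", f"{int((de['label'] != 'unchanged').sum())} DE genes")
    summary["stages"]["expression"] = {
        "n_de": int((de["label"] != "unchanged").sum()),
        "promoter_summary": promoter,
    }

    # --- stage 8: dSTORM colocalization --------------------------------------
    st = config.get("storm", {})
    img_a, img_b, beads_a, beads_b = synthetic.generate_storm_pair(
        st.get("overlap_fraction", 0.5), st.get("density", 0.05),
        shape=tuple(st.get("shape", [256, 256])), shift=tuple(st.get("shift", [3, -2])),
        n_beads=st.get("n_beads", 5), seed=seeds[5])
    sa = storm.StormImage(img_a)
    aligned = storm.align_by_fiducials(sa, beads_a, storm.StormImage(img_b), beads_b)
    cc = storm.cross_correlation(sa, aligned["aligned"])
    ratios = storm.coloc_ratios(sa, aligned["aligned"])
    np.savetxt(outdir / "storm_radial_profile.tsv",
               np.column_stack([cc.radial_r, cc.radial_c, cc.radial_counts]),
               delimiter="\t", header="radius_px\tc\tn_pixels", comments="")
    log("storm", f"shift {aligned['shift']}, %A-with-B {ratios['percent_a_with_b']:.1f}")
    summary["stages"]["storm"] = {
        "estimated_shift": list(aligned["shift"]),
        "planted_shift": list(st.get("shift", [3, -2])),
        "c_at_zero": cc.at(0, 0),
        **{k: ratios[k] for k in ("percent_a_with_b", "percent_b_with_a")},
    }

    summary["wall_seconds"] = round(time.time() - t0, 2)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return summary
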