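"""Peak dynamics, pseudo-peaks, loop taxonomy, gene association and E-box scan.

Loop anchors are scaled to 10 kb bins and intersected with MyoD and CTCF
peak sets to classify each loop into one of four anchor-occupancy
classes (plus an "other" bucket for the remaining combinations), with
Both / Xor / Neither occupancy summaries per factor.  Pseudo-peaks
represent a condition's binding repertoire: the growth-condition set is
static plus reduced peaks, the differentiation-condition set static plus
enhanced peaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .loops import Loop

__all__ = [
    "label_peak_dynamics",
    "make_pseudo_peaks",
    "classify_loops",
    "associate_genes",
    "ebox_enrichment",
]


def label_peak_dynamics(
    peaks: pd.DataFrame,
    cond_a_cols: list[str],
    cond_b_cols: list[str],
    fdr: float = 0.05,
    min_fold: float = 1.5,
) -> pd.DataFrame:
    """Label merged peaks static / enhanced / reduced from replicate counts.

    Counts are library-size normalized (per-column total scaled to the
    mean total), Welch-tested on log2(1 + normalized count); a peak is
    ``enhanced`` (up in condition B) or ``reduced`` iff BH FDR < ``fdr``
    and linear fold >= ``min_fold``.  All-zero peaks stay static and are
    flagged.
    """
    if len(cond_a_cols) < 2 or len(cond_b_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    out = peaks.copy()
    cols = list(cond_a_cols) + list(cond_b_cols)
    counts = out[cols].to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a replicate has zero total counts")
    norm = counts * (totals.mean() / totals)
    log = np.log2(1 + norm)
    a = log[:, : len(cond_a_cols)]
    b = log[:, len(cond_a_cols):]

    pvals = np.ones(len(out))
    for k in range(len(out)):
        if np.var(a[k], ddof=1) == 0 and np.var(b[k], ddof=1) == 0:
            pvals[k] = 1.0 if np.mean(a[k]) == np.mean(b[k]) else 0.0
        else:
            pvals[k] = stats.ttest_ind(a[k], b[k], equal_var=False).pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]

    mean_a = norm[:, : len(cond_a_cols)].mean(axis=1)
    mean_b = norm[:, len(cond_a_cols):].mean(axis=1)
    pseudo = 1.0  # avoids division by zero for silent peaks
    fold = (mean_b + pseudo) / (mean_a + pseudo)
    big = np.maximum(fold, 1 / fold) >= min_fold
    sig = (qvals < fdr) & big
    label = np.where(sig & (fold > 1), "enhanced", np.where(sig & (fold < 1), "reduced", "static"))
    all_zero = counts.sum(axis=1) == 0
    label[all_zero] = "static"
    out["pvalue"] = pvals
    out["qvalue"] = qvals
    out["log2_fold"] = np.log2(fold)
    out["dynamic"] = label
    out["all_zero"] = all_zero
    return out


def make_pseudo_peaks(labeled: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Condition-specific binding repertoires from dynamic labels.

    GM pseudo-peaks = static + reduced; DM pseudo-peaks = static +
    enhanced (labels are relative to the second condition).
    """
    if "dynamic" not in labeled.columns:
        raise ValueError("peaks must carry a 'dynamic' label column")
    gm = labeled[labeled["dynamic"].isin(["static", "reduced"])].reset_index(drop=True)
    dm = labeled[labeled["dynamic"].isin(["static", "enhanced"])].reset_index(drop=True)
    return {"GM": gm, "DM": dm}


def _anchor_interval(loop: Loop, which: int, anchor_bin: int) -> tuple[int, int]:
    """Anchor scaled to the containing ``anchor_bin`` bin (half-open)."""
    start = (loop.anchor1 if which == 0 else loop.anchor2)[0]
    b = start // anchor_bin
    return (b * anchor_bin, (b + 1) * anchor_bin)


def _overlaps_any(chrom: str, start: int, end: int, peaks: pd.DataFrame) -> bool:
    if len(peaks) == 0:
        return False
    sub = peaks[peaks["chrom"] == chrom] if "chrom" in peaks.columns else peaks
    if len(sub) == 0:
        return False
    s = sub["start"].to_numpy()
    e = sub["end"].to_numpy()
    return bool(((s < end) & (e > start)).any())


def classify_loops(
    loops: list[Loop],
    myod_peaks: pd.DataFrame,
    ctcf_peaks: pd.DataFrame,
    anchor_bin: int = 10_000,
) -> pd.DataFrame:
    """Four-class anchor-occupancy taxonomy plus Both/Xor/Neither summaries.

    Occupancy is >= 1 bp overlap between the 10 kb-scaled anchor and any
    peak.  Classes: ``MyoD-MyoD(noCTCF)`` — MyoD at both anchors, CTCF at
    neither; ``MyoD-MyoD(CTCF)`` — MyoD at both, CTCF at >= 1;
    ``MyoD-CTCF`` — MyoD at exactly one anchor and CTCF at >= 1;
    ``CTCF-CTCF`` — CTCF at both, MyoD at neither; ``other`` — the rest.
    """
    rows = []
    for loop in loops:
        flags = {}
        for fac, peaks in (("MyoD", myod_peaks), ("CTCF", ctcf_peaks)):
            for which, tag in ((0, "a1"), (1, "a2")):
                s, e = _anchor_interval(loop, which, anchor_bin)
                flags[f"{fac}_{tag}"] = _overlaps_any(loop.chrom, s, e, peaks)
        m1, m2 = flags["MyoD_a1"], flags["MyoD_a2"]
        c1, c2 = flags["CTCF_a1"], flags["CTCF_a2"]
        n_m, n_c = m1 + m2, c1 + c2
        if n_m == 2 and n_c == 0:
            cls = "MyoD-MyoD(noCTCF)"
        elif n_m == 2 and n_c >= 1:
            cls = "MyoD-MyoD(CTCF)"
        elif n_m == 1 and n_c >= 1:
            cls = "MyoD-CTCF"
        elif n_c == 2 and n_m == 0:
            cls = "CTCF-CTCF"
        else:
            cls = "other"
        loop.label = cls
        rows.append({
            "chrom": loop.chrom, "bin1": loop.bin1, "bin2": loop.bin2,
            "resolution": loop.resolution, **flags,
            "class": cls,
            "MyoD_occupancy": {2: "Both", 1: "Xor", 0: "Neither"}[n_m],
            "CTCF_occupancy": {2: "Both", 1: "Xor", 0: "Neither"}[n_c],
        })
    df = pd.DataFrame(rows)
    if len(df):
        for fac in ("MyoD", "CTCF"):
            counts = df[f"{fac}_occupancy"].value_counts()
            for key in ("Both", "Xor", "Neither"):
                df.attrs[f"{fac}_percent_{key}"] = 100.0 * counts.get(key, 0) / len(df)
        for cls, cnt in df["class"].value_counts().items():
            df.attrs[f"count_{cls}"] = int(cnt)
    return df


def associate_genes(
    loops: list[Loop],
    gene_models: pd.DataFrame,
    promoter_halfwidth: int = 3_000,
) -> pd.DataFrame:
    """Gene-loop pairs where the promoter overlaps a loop anchor.

    The promoter is the half-open window ``[TSS - h, TSS + h)`` around
    the annotated TSS (strand only sets where the TSS is, not the
    window).  Overlap is >= 1 bp; a TSS exactly at the anchor start is
    therefore included.
    """
    rows = []
    for gi, g in gene_models.iterrows():
        p_start, p_end = int(g["tss"]) - promoter_halfwidth, int(g["tss"]) + promoter_halfwidth
        for li, loop in enumerate(loops):
            if "chrom" in g and g["chrom"] != loop.chrom:
                continue
            for (a_s, a_e) in (loop.anchor1, loop.anchor2):
                if p_start < a_e and p_end > a_s:
                    rows.append({"gene_id": gi if isinstance(gi, str) else g.get("gene_id", gi),
                                 "loop_index": li, "chrom": loop.chrom,
                                 "bin1": loop.bin1, "bin2": loop.bin2})
                    break
    return pd.DataFrame(rows, columns=["gene_id", "loop_index", "chrom", "bin1", "bin2"])


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def has_ebox(seq: str, consensus: str = "CANNTG") -> bool:
    """Scan both strands for the E-box consensus (N matches any base).

    CANNTG is its own reverse complement, so a single-strand scan
    suffices for the default consensus; both strands are scanned anyway
    for generality.
    """
    seq = seq.upper()
    rc = seq.translate(_COMPLEMENT)[::-1]
    for s in (seq, rc):
        for i in range(len(s) - len(consensus) + 1):
            if all(c == "N" or c == s[i + k] for k, c in enumerate(consensus)):
                return True
    return False


def ebox_enrichment(
    foreground: list[str],
    background: list[str],
    consensus: str = "CANNTG",
) -> dict:
    """Cumulative-binomial enrichment of the consensus in the foreground.

    k = foreground sequences containing >= 1 match, p0 = background
    match fraction, p = P(X >= k) with X ~ Binomial(n_foreground, p0).
    """
    if not background:
        raise ValueError("empty background set")
    if not foreground:
        raise ValueError("empty foreground set")
    k = sum(has_ebox(s, consensus) for s in foreground)
    n = len(foreground)
    p0 = sum(has_ebox(s, consensus) for s in background) / len(background)
    pval = float(stats.binom.sf(k - 1, n, p0)) if k > 0 else 1.0
    return {"k": int(k), "n": int(n), "p0": float(p0), "pvalue": pval}
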