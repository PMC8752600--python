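"""Insulation scores, contact-domain-boundary (CDB) detection and dynamics.

The insulation score of bin *i* is the mean contact count in the square
window pairing the *w* bins upstream with the *w* bins downstream of *i*;
contacts across a domain boundary are depleted, so boundaries appear as
local minima.  Scores are log2-normalized to the chromosome mean
(``NI``), which makes them invariant to sequencing depth.  A boundary's
*relative insulation* (RI) is the mean of the flanking NI maxima within
the delta span minus the NI at the minimum — a depth of the insulation
valley.  Defaults follow the convention of a 1 Mb window, 200 kb delta
span, mean aggregation and a 0.1 noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hic import ContactMatrix

__all__ = [
    "InsulationTrack",
    "CDB",
    "insulation_track",
    "detect_cdbs",
    "cdb_ri_at_bins",
    "differential_cdbs",
    "cdb_binding_classes",
]


@dataclass
class InsulationTrack:
    resolution: int
    raw: np.ndarray        # IS(i); nan where undefined
    normalized: np.ndarray  # NI(i) = log2(IS / chrom mean IS); nan where undefined
    window: int            # bp
    delta_span: int        # bp
    noise_threshold: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.normalized)


@dataclass
class CDB:
    bin: int
    ri: float
    ni: float
    binding_class: str | None = None
    per_sample_ri: dict = field(default_factory=dict)


def insulation_track(
    matrix: ContactMatrix,
    window: int = 1_000_000,
    delta_span: int = 200_000,
    noise_threshold: float = 0.1,
) -> InsulationTrack:
    """Sliding-square insulation with log2 normalization to the chrom mean."""
    res = matrix.resolution
    if window < res:
        raise ValueError("window must be at least one bin")
    w = window // res
    n = matrix.n_bins
    raw = np.full(n, np.nan)
    if n >= 2 * w + 1:
        dense = matrix.dense()
        for i in range(w, n - w):
            raw[i] = dense[i - w : i, i + 1 : i + 1 + w].mean()
    defined = np.isfinite(raw)
    ni = np.full(n, np.nan)
    if defined.any():
        mean_is = raw[defined].mean()
        if mean_is > 0:
            with np.errstate(divide="ignore"):
                ni[defined] = np.log2(raw[defined] / mean_is)
    return InsulationTrack(res, raw, ni, window, delta_span, noise_threshold)


def _flank_max(ni: np.ndarray, i: int, span_bins: int, direction: int) -> float:
    vals = []
    for k in range(1, span_bins + 1):
        j = i + direction * k
        if 0 <= j < ni.size and np.isfinite(ni[j]):
            vals.append(ni[j])
    return max(vals) if vals else np.nan


def detect_cdbs(track: InsulationTrack) -> list[CDB]:
    """Boundaries at local NI minima with relative insulation above the noise floor.

    RI = mean of the flanking NI maxima within the delta span on each
    side, minus NI at the minimum.  Ties at adjacent equal minima break
    toward the lower bin index.
    """
    ni = track.normalized
    span_bins = max(1, track.delta_span // track.resolution)
    out: list[CDB] = []
    for i in range(ni.size):
        if not np.isfinite(ni[i]):
            continue
        left = ni[i - 1] if i - 1 >= 0 and np.isfinite(ni[i - 1]) else np.inf
        right = ni[i + 1] if i + 1 < ni.size and np.isfinite(ni[i + 1]) else np.inf
        # strict on the left, non-strict on the right -> plateau ties go to the lower index
        # strict left / non-strict right: plateau ties resolve to the lower index
        if not (ni[i] < left and ni[i] <= right):
            continue
        lmax = _flank_max(ni, i, span_bins, -1)
        rmax = _flank_max(ni, i, span_bins, +1)
        flanks = [v for v in (lmax, rmax) if np.isfinite(v)]
        if not flanks:
            continue
        ri = float(np.mean(flanks) - ni[i])
        if ri > track.noise_threshold:
            out.append(CDB(bin=i, ri=ri, ni=float(ni[i])))
    return out


def cdb_ri_at_bins(track: InsulationTrack, bins: list[int]) -> np.ndarray:
    """Relative insulation evaluated at given bins (for per-sample RI at shared CDBs)."""
    ni = track.normalized
    span_bins = max(1, track.delta_span // track.resolution)
    out = np.full(len(bins), np.nan)
    for k, i in enumerate(bins):
        if not (0 <= i < ni.size) or not np.isfinite(ni[i]):
            continue
        lmax = _flank_max(ni, i, span_bins, -1)
        rmax = _flank_max(ni, i, span_bins, +1)
        flanks = [v for v in (lmax, rmax) if np.isfinite(v)]
        if flanks:
            out[k] = np.mean(flanks) - ni[i]
    return out


def _welch_row(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def differential_cdbs(
    ri_case: np.ndarray,
    ri_control: np.ndarray,
    fdr: float = 0.01,
    quantile: float = 0.80,
    quantile_mode: str = "absolute",
) -> pd.DataFrame:
    """Label shared CDBs enhanced / reduced / static between two conditions.

    ``ri_case`` and ``ri_control`` are CDB x replicate arrays of relative
    insulation.  A CDB is differential iff its Welch-t BH FDR is below
    ``fdr`` AND its |mean case - control difference| exceeds the
    ``quantile`` quantile of differences over all CDBs (absolute and
    pooled by default; ``quantile_mode="signed"`` uses the signed
    distribution's upper/lower tails).
    """
    ri_case = np.atleast_2d(np.asarray(ri_case, dtype=float))
    ri_control = np.atleast_2d(np.asarray(ri_control, dtype=float))
    if ri_case.shape[1] < 2 or ri_control.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    if ri_case.shape[0] != ri_control.shape[0]:
        raise ValueError("CDB sets differ between conditions")
    diff = ri_case.mean(axis=1) - ri_control.mean(axis=1)
    pvals = np.array([_welch_row(ri_case[k], ri_control[k]) for k in range(ri_case.shape[0])])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    if quantile_mode == "absolute":
        cut = np.quantile(np.abs(diff), quantile)
        big = np.abs(diff) > cut
    elif quantile_mode == "signed":
        hi, lo = np.quantile(diff, quantile), np.quantile(diff, 1 - quantile)
        big = (diff > hi) | (diff < lo)
    else:
        raise ValueError("quantile_mode must be 'absolute' or 'signed'")
    sig = (qvals < fdr) & big
    label = np.where(sig & (diff > 0), "enhanced", np.where(sig & (diff < 0), "reduced", "static"))
    return pd.DataFrame({
        "mean_case": ri_case.mean(axis=1),
        "mean_control": ri_control.mean(axis=1),
        "difference": diff,
        "pvalue": pvals,
        "qvalue": qvals,
        "label": label,
    })


def _interval_peak_distance(start: int, end: int, peaks: pd.DataFrame) -> float:
    """bp gap between the half-open interval [start, end) and the nearest peak (0 on overlap)."""
    if len(peaks) == 0:
        return np.inf
    s = peaks["start"].to_numpy()
    e = peaks["end"].to_numpy()
    d = np.where(e <= start, start - e, np.where(s >= end, s - end, 0))
    return float(d.min())


def cdb_binding_classes(
    cdbs: list[CDB],
    track: InsulationTrack,
    myod_peaks: pd.DataFrame,
    ctcf_peaks: pd.DataFrame,
    distances: tuple[int, int] = (20_000, 40_000),
) -> dict:
    """Classify CDBs by TF binding and compare insulation across classes.

    A CDB bin (half-open interval at the track resolution) is CTCF- or
    MyoD-bound if any peak overlaps it.  ``MyoD_only_leXkb`` classes are
    MyoD-bound CDBs with *no* CTCF peak within X kb of the bin — the
    larger radius is the stricter, nested class.  Membership sets
    overlap; each CDB also gets a single primary label for convenience
    (CTCF-bound wins over MyoD classes, then the strictest exclusion).
    Returns per-class NI distributions and one-sided Mann-Whitney
    p-values (alternative: first class has lower insulation depth RI).
    """
    res = track.resolution
    d20, d40 = distances
    classes: dict[str, list[int]] = {
        "CTCF_bound": [], "MyoD_bound": [],
        f"MyoD_only_le{d20 // 1000}kb": [], f"MyoD_only_le{d40 // 1000}kb": [],
        "unbound": [],
    }
    key20 = f"MyoD_only_le{d20 // 1000}kb"
    key40 = f"MyoD_only_le{d40 // 1000}kb"
    for k, cdb in enumerate(cdbs):
        start = cdb.bin * res
        end = start + res
        ctcf_dist = _interval_peak_distance(start, end, ctcf_peaks)
        myod_dist = _interval_peak_distance(start, end, myod_peaks)
        ctcf_overlap = ctcf_dist == 0
        myod_overlap = myod_dist == 0
        if ctcf_overlap:
            classes["CTCF_bound"].append(k)
        if myod_overlap:
            classes["MyoD_bound"].append(k)
            if ctcf_dist > d20:
                classes[key20].append(k)
            if ctcf_dist > d40:
                classes[key40].append(k)
        if not ctcf_overlap and not myod_overlap:
            classes["unbound"].append(k)
        if ctcf_overlap:
            cdb.binding_class = "CTCF_bound"
        elif myod_overlap:
            if ctcf_dist > d40:
                cdb.binding_class = key40
            elif ctcf_dist > d20:
                cdb.binding_class = key20
            else:
                cdb.binding_class = "MyoD_bound"
        else:
            cdb.binding_class = "unbound"

    ri = np.array([c.ri for c in cdbs])
    dists = {name: ri[idx] for name, idx in classes.items() if len(idx) > 0}
    skipped = [name for name, idx in classes.items() if len(idx) == 0]
    tests = {}
    names = list(dists)
    for i in range(len(names)):
        for j in range(len(names)):
            if i == j:
                continue
            a, b = dists[names[i]], dists[names[j]]
            if len(a) and len(b):
                p = stats.mannwhitneyu(a, b, alternative="less").pvalue
                tests[(names[i], names[j])] = float(p)
    return {"classes": classes, "distributions": dists, "tests": tests, "empty_classes": skipped}
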