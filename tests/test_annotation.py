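"""Peak dynamics, pseudo-peaks, loop taxonomy, gene pairing and E-box scan."""

import numpy as np
import pandas as pd
import pytest

from loopforge.annotation import (
    associate_genes,
    classify_loops,
    ebox_enrichment,
    has_ebox,
    label_peak_dynamics,
    make_pseudo_peaks,
)
from loopforge.loops import Loop


def _peak_df(n, counts_a, counts_b):
    """counts_a / counts_b: per-peak replicate count tuples."""
    rows = []
    for i in range(n):
        rec = {"chrom": "chr1", "start": 1000 * i, "end": 1000 * i + 500, "name": f"p{i}"}
        for r, v in enumerate(counts_a[i]):
            rec[f"a{r + 1}"] = v
        for r, v in enumerate(counts_b[i]):
            rec[f"b{r + 1}"] = v
        rows.append(rec)
    return pd.DataFrame(rows)


class TestPeakDynamics:
    def test_identical_counts_all_static(self):
        df = _peak_df(20, [(50, 60, 55)] * 20, [(50, 60, 55)] * 20)
        out = label_peak_dynamics(df, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert (out["dynamic"] == "static").all()

    def test_planted_fourfold_gains_recovered(self, rng):
        n, gains = 500, 50
        base = rng.poisson(100, size=(n, 6)).astype(float)
        base[:gains, 3:] *= 4  # four-fold up in condition B, 3 reps each
        df = _peak_df(n, [tuple(r[:3]) for r in base], [tuple(r[3:]) for r in base])
        out = label_peak_dynamics(df, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert (out["dynamic"][:gains] == "enhanced").sum() >= 45
        assert (out["dynamic"][:gains] == "reduced").sum() <= 2

    def test_single_condition_rejected(self):
        df = _peak_df(5, [(10, 10)] * 5, [(10, 10)] * 5)
        with pytest.raises(ValueError):
            label_peak_dynamics(df, ["a1"], ["b1", "b2"])


class TestPseudoPeaks:
    def test_composition_rule(self):
        df = _peak_df(3, [(10, 10)] * 3, [(10, 10)] * 3)
        df["dynamic"] = ["static", "enhanced", "reduced"]
        out = make_pseudo_peaks(df)
        assert set(out["GM"]["name"]) == {"p0", "p2"}  # static + reduced
        assert set(out["DM"]["name"]) == {"p0", "p1"}  # static + enhanced

    def test_all_static_both_sets_full(self):
        df = _peak_df(4, [(10, 10)] * 4, [(10, 10)] * 4)
        df["dynamic"] = "static"
        out = make_pseudo_peaks(df)
        assert len(out["GM"]) == len(out["DM"]) == 4

    def test_static_peaks_in_both_sets(self):
        df = _peak_df(6, [(10, 10)] * 6, [(10, 10)] * 6)
        df["dynamic"] = ["static", "enhanced", "reduced"] * 2
        out = make_pseudo_peaks(df)
        static = set(df[df["dynamic"] == "static"]["name"])
        assert static <= set(out["GM"]["name"]) and static <= set(out["DM"]["name"])

    def test_empty_input(self):
        df = _peak_df(0, [], [])
        df["dynamic"] = pd.Series(dtype=object)
        out = make_pseudo_peaks(df)
        assert len(out["GM"]) == 0 and len(out["DM"]) == 0


def _peaks_at(bins, resolution=10_000, width=500):
    return pd.DataFrame([{"chrom": "chr1", "start": b * resolution + 100,
                          "end": b * resolution + 100 + width} for b in bins],
                        columns=["chrom", "start", "end"])


class TestClassifyLoops:
    def test_myod_both_no_ctcf(self):
        loops = [Loop("chr1", 10, 30, 10_000)]
        df = classify_loops(loops, _peaks_at([10, 30]), _peaks_at([]))
        assert df["class"][0] == "MyoD-MyoD(noCTCF)"

    def test_no_peaks_all_neither_and_other(self):
        loops = [Loop("chr1", 10, 30, 10_000), Loop("chr1", 12, 50, 10_000)]
        df = classify_loops(loops, _peaks_at([]), _peaks_at([]))
        assert (df["class"] == "other").all()
        assert df.attrs["MyoD_percent_Neither"] == 100.0

    def test_constructed_flags_match_enumeration_oracle(self):
        # ten loops with hand-chosen occupancy; percentages from enumeration
        cases = [
            ((True, True), (False, False), "MyoD-MyoD(noCTCF)"),
            ((True, True), (True, False), "MyoD-MyoD(CTCF)"),
            ((True, True), (False, True), "MyoD-MyoD(CTCF)"),
            ((True, False), (True, False), "MyoD-CTCF"),
            ((False, True), (False, True), "MyoD-CTCF"),
            ((False, False), (True, True), "CTCF-CTCF"),
            ((True, False), (False, False), "other"),
            ((False, False), (False, False), "other"),
            ((False, False), (True, False), "other"),
            ((True, True), (True, True), "MyoD-MyoD(CTCF)"),
        ]
        loops, myod_bins, ctcf_bins = [], [], []
        for k, ((m1, m2), (c1, c2), _) in enumerate(cases):
            b1, b2 = 10 + 60 * k, 35 + 60 * k
            loops.append(Loop("chr1", b1, b2, 10_000))
            if m1: myod_bins.append(b1)
            if m2: myod_bins.append(b2)
            if c1: ctcf_bins.append(b1)
            if c2: ctcf_bins.append(b2)
        df = classify_loops(loops, _peaks_at(myod_bins), _peaks_at(ctcf_bins))
        assert list(df["class"]) == [c for *_, c in cases]
        # Both/Xor/Neither from direct enumeration
        n_m = [m1 + m2 for (m1, m2), _, _ in cases]
        expect = {2: "Both", 1: "Xor", 0: "Neither"}
        for key in ("Both", "Xor", "Neither"):
            want = 100.0 * sum(1 for x in n_m if expect[x] == key) / len(cases)
            assert df.attrs[f"MyoD_percent_{key}"] == pytest.approx(want)

    def test_partition_and_percentages_sum(self):
        rng = np.random.default_rng(4)
        loops = [Loop("chr1", 10 + 40 * k, 25 + 40 * k, 10_000) for k in range(12)]
        all_bins = [b for L in loops for b in (L.bin1, L.bin2)]
        myod = _peaks_at(list(rng.choice(all_bins, 8, replace=False)))
        ctcf = _peaks_at(list(rng.choice(all_bins, 8, replace=False)))
        df = classify_loops(loops, myod, ctcf)
        assert df["class"].notna().all() and len(df) == 12
        total = sum(df.attrs[f"MyoD_percent_{k}"] for k in ("Both", "Xor", "Neither"))
        assert total == pytest.approx(100.0)


class TestAssociateGenes:
    def _genes(self, tss_list):
        return pd.DataFrame([{"gene_id": f"g{i}", "chrom": "chr1", "tss": t, "strand": "+"}
                             for i, t in enumerate(tss_list)]).set_index("gene_id")

    def test_tss_at_anchor_edge_included(self):
        # promoter [tss-3k, tss+3k) overlaps anchor [100k, 110k) when tss = 100k - 3k + 1
        loops = [Loop("chr1", 10, 30, 10_000)]
        genes = self._genes([97_001])
        pairs = associate_genes(loops, genes)
        assert len(pairs) == 1

    def test_far_gene_excluded(self):
        loops = [Loop("chr1", 10, 30, 10_000)]
        pairs = associate_genes(loops, self._genes([500_000]))
        assert len(pairs) == 0

    def test_matches_brute_force_interval_oracle(self, rng):
        loops = [Loop("chr1", int(a), int(a + d), 10_000)
                 for a, d in zip(rng.integers(5, 80, 8), rng.integers(5, 30, 8))]
        tss = list(rng.integers(0, 1_200_000, 20))
        genes = self._genes(tss)
        pairs = associate_genes(loops, genes)
        got = {(r.gene_id, r.loop_index) for r in pairs.itertuples()}
        h = 3_000
        want = set()
        for gi, t in enumerate(tss):
            for li, L in enumerate(loops):
                for (s, e) in (L.anchor1, L.anchor2):
                    if t - h < e and t + h > s:
                        want.add((f"g{gi}", li))
                        break
        assert got == want


class TestEbox:
    def test_consensus_sequence_matches(self):
        assert has_ebox("CAGCTG")
        assert has_ebox("TTTCACGTGTTT")  # CANNTG with NN = CG
        assert not has_ebox("AAAAAAA")

    def test_scan_is_strand_symmetric(self, rng):
        bases = np.array(list("ACGT"))
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(50):
            s = "".join(bases[rng.integers(0, 4, 30)])
            rc = s.translate(comp)[::-1]
            assert has_ebox(s) == has_ebox(rc)

    def test_zero_foreground_matches_p_one(self):
        out = ebox_enrichment(["AAAA", "CCCC"], ["CAGCTGAA", "GGGG"])
        assert out["k"] == 0 and out["pvalue"] == 1.0

    def test_binomial_tail_matches_direct_sum(self):
        from math import comb

        fg = ["CAGCTG"] * 5 + ["AAAAAA"] * 5          # k = 5, n = 10
        bg = ["CAGCTG"] * 2 + ["AAAAAA"] * 8          # p0 = 0.2
        out = ebox_enrichment(fg, bg)
        direct = sum(comb(10, j) * 0.2**j * 0.8 ** (10 - j) for j in range(5, 11))
        assert out["pvalue"] == pytest.approx(direct, abs=1e-12)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            ebox_enrichment(["CAGCTG"], [])
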