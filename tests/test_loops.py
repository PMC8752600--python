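"""Donut-filter caller, resolution merging, loop strength and APA."""

import math

import numpy as np
import pytest

from loopforge.hic import ContactMatrix, expected_profile, oe_transform
from loopforge.loops import (
    Loop,
    _kernels,
    apa,
    background_lambdas,
    call_loops,
    loop_strength,
    merge_resolutions,
)


def poisson_upper_tail(obs: float, lam: float) -> float:
    """P(X >= obs) by direct pmf summation — independent of scipy."""
    k = int(math.ceil(obs))
    pmf = math.exp(-lam)
    cdf = 0.0
    for j in range(k):
        cdf += pmf
        pmf *= lam / (j + 1)
    return 1.0 - cdf


class TestCallLoops:
    def test_pvalue_matches_direct_poisson_tail(self, recall_sim):
        # every reported loop's p equals the direct tail sum at its lambda
        cfg, matrices, truth = recall_sim
        mat = matrices["WT"][0][0]
        called = call_loops(mat, peak_width=2, donut_width=5, fdr=0.1)
        assert called, "caller found nothing to check"
        prof = expected_profile(mat)
        oe = oe_transform(mat, prof)
        for L in called[:10]:
            lams = background_lambdas(mat, oe, prof.values, L.bin1, L.bin2, 2, 5)
            lam = max(lams.values())
            direct = poisson_upper_tail(L.observed, lam)
            mine = poisson_upper_tail(L.observed, max(L.lambdas.values()))
            assert mine == pytest.approx(direct, abs=1e-12)

    def test_planted_pixel_detected_with_exact_p(self):
        # one strongly enriched pixel on a flat background
        n = 60
        dense = np.full((n, n), 5.0)
        dense[20, 40] = dense[40, 20] = 40.0
        mat = ContactMatrix.from_dense(dense, resolution=10_000)
        called = call_loops(mat, peak_width=2, donut_width=5, fdr=0.1)
        assert any(L.bin1 == 20 and L.bin2 == 40 for L in called)
        hit = next(L for L in called if (L.bin1, L.bin2) == (20, 40))
        lam = max(hit.lambdas.values())
        assert hit.pvalue == pytest.approx(poisson_upper_tail(40.0, lam), abs=1e-12)

    def test_null_matrix_false_positives_bounded(self):
        # pure background: false calls stay within the binomial upper bound
        from loopforge import synthetic

        cfg = synthetic.SynthConfig(chrom_length=3_000_000, resolution=10_000,
                                    depth=1_200_000, replicates_per_condition=1)
        mats, _ = synthetic.generate_hic_experiment(cfg, seed=23)
        called = call_loops(mats["WT"][0][0], peak_width=2, donut_width=5, fdr=0.1)
        assert len(called) <= 5

    def test_bad_distance_bounds_rejected(self):
        mat = ContactMatrix.from_dense(np.full((30, 30), 2.0))
        with pytest.raises(ValueError):
            call_loops(mat, min_dist=10, max_dist=5)

    def test_bad_geometry_rejected(self):
        mat = ContactMatrix.from_dense(np.full((30, 30), 2.0))
        with pytest.raises(ValueError):
            call_loops(mat, peak_width=5, donut_width=5)


class TestPlantedRecovery:
    def test_recall_and_precision_at_enrichment_five(self, recall_sim):
        cfg, matrices, truth = recall_sim
        called = call_loops(matrices["WT"][0][0], peak_width=2, donut_width=5, fdr=0.1)
        planted = [(L.bin1, L.bin2) for L in truth.loops]
        callset = [(L.bin1, L.bin2) for L in called]

        def near(a, b):
            return abs(a[0] - b[0]) <= 1 and abs(a[1] - b[1]) <= 1

        recall = np.mean([any(near(c, p) for c in callset) for p in planted])
        precision = np.mean([any(near(c, p) for p in planted) for c in callset])
        assert recall >= 0.90
        assert precision >= 0.90


class TestMergeResolutions:
    def _loop(self, res, b1, b2):
        return Loop(chrom="chr1", bin1=b1, bin2=b2, resolution=res)

    def test_double_detection_keeps_5kb_record(self):
        five = [self._loop(5_000, 40, 80)]    # anchors at 200 kb / 400 kb
        ten = [self._loop(10_000, 20, 40)]    # same locus at 10 kb
        out = merge_resolutions({5_000: five, 10_000: ten})
        assert len(out) == 1 and out[0].resolution == 5_000

    def test_disjoint_lists_union(self):
        five = [self._loop(5_000, 40, 80)]
        ten = [self._loop(10_000, 60, 90)]
        out = merge_resolutions({5_000: five, 10_000: ten})
        assert len(out) == 2

    def test_empty_lists(self):
        assert merge_resolutions({5_000: [], 10_000: []}) == []


class TestLoopStrength:
    def test_center_equals_donut_mean_gives_one(self):
        dense = np.full((40, 40), 3.0)
        mat = ContactMatrix.from_dense(dense)
        assert loop_strength(mat, Loop("chr1", 15, 25, 10_000)) == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        dense = np.full((40, 40), 3.0)
        dense[15, 25] = dense[25, 15] = 12.0
        mat = ContactMatrix.from_dense(dense)
        assert loop_strength(mat, Loop("chr1", 15, 25, 10_000)) == pytest.approx(4.0)

    def test_matches_naive_reimplementation(self, rng):
        dense = np.triu(rng.poisson(6, (40, 40)).astype(float))
        dense = dense + np.triu(dense, 1).T
        mat = ContactMatrix.from_dense(dense)
        i, j, p, iw = 15, 28, 2, 5
        got = loop_strength(mat, Loop("chr1", i, j, 10_000), p, iw)
        # independent naive loop over the donut footprint
        vals = []
        for du in range(-iw, iw + 1):
            for dv in range(-iw, iw + 1):
                if max(abs(du), abs(dv)) <= p or du == 0 or dv == 0:
                    continue
                vals.append(dense[i + du, j + dv])
        assert got == pytest.approx(dense[i, j] / np.mean(vals), abs=1e-12)

    def test_zero_donut_flagged(self):
        dense = np.zeros((40, 40))
        dense[15, 25] = dense[25, 15] = 3.0
        mat = ContactMatrix.from_dense(dense)
        assert np.isnan(loop_strength(mat, Loop("chr1", 15, 25, 10_000)))

    def test_monotone_in_planted_enrichment(self):
        from loopforge import synthetic

        strengths = []
        for enrich in (2.0, 5.0, 10.0):
            cfg = synthetic.SynthConfig(
                chrom_length=1_000_000, resolution=10_000, depth=500_000,
                loop_specs=[synthetic.LoopSpec(anchor1=300_000, anchor2=600_000,
                                               enrichment=enrich)],
                replicates_per_condition=1)
            mats, truth = synthetic.generate_hic_experiment(cfg, seed=31)
            L = Loop("chr1", truth.loops[0].bin1, truth.loops[0].bin2, 10_000)
            strengths.append(loop_strength(mats["WT"][0][0], L))
        assert strengths[0] < strengths[1] < strengths[2]


class TestAPA:
    def test_uniform_matrix_score_one(self):
        mat = ContactMatrix.from_dense(np.full((80, 80), 4.0))
        res = apa(mat, [Loop("chr1", 20, 60, 10_000)], k=8)
        assert res.score == pytest.approx(1.0)

    def test_forced_arithmetic_center_over_corner(self):
        # aggregate with center 10 and lower-left block mean 2 -> score 5
        k = 10
        dense = np.full((80, 80), 2.0)
        dense[30, 60] = dense[60, 30] = 10.0
        mat = ContactMatrix.from_dense(dense)
        res = apa(mat, [Loop("chr1", 30, 60, 10_000)], k=k, scale="raw")
        assert res.score == pytest.approx(5.0)

    def test_planted_enrichment_recovered(self, recall_sim):
        cfg, matrices, truth = recall_sim
        loops = [Loop("chr1", L.bin1, L.bin2, cfg.resolution) for L in truth.loops]
        res = apa(matrices["WT"][0][0], loops, k=10)
        assert 4.0 <= res.score <= 6.0

    def test_score_invariant_to_cis_rescaling(self, recall_sim):
        from loopforge.hic import normalize_cis

        cfg, matrices, truth = recall_sim
        loops = [Loop("chr1", L.bin1, L.bin2, cfg.resolution) for L in truth.loops]
        mat = matrices["WT"][0][0]
        r1 = apa(mat, loops, k=6)
        r2 = apa(normalize_cis(mat, mat.total_cis / 7), loops, k=6)
        assert r1.score == pytest.approx(r2.score, rel=1e-9)

    def test_matches_naive_aggregation(self, rng):
        dense = np.triu(rng.poisson(5, (60, 60)).astype(float))
        dense = dense + np.triu(dense, 1).T
        mat = ContactMatrix.from_dense(dense)
        loops = [Loop("chr1", 12, 40, 10_000), Loop("chr1", 20, 50, 10_000)]
        k = 5
        res = apa(mat, loops, k=k, scale="raw")
        naive = sum(dense[L.bin1 - k : L.bin1 + k + 1, L.bin2 - k : L.bin2 + k + 1]
                    for L in loops) / len(loops)
        assert np.allclose(res.matrix, naive, atol=1e-12)
        b = max(1, int(round(0.6 * k)))
        assert res.score == pytest.approx(naive[k, k] / naive[2 * k + 1 - b :, :b].mean())

    def test_unusable_loops_rejected(self):
        mat = ContactMatrix.from_dense(np.full((30, 30), 2.0))
        with pytest.raises(ValueError):
            apa(mat, [Loop("chr1", 2, 5, 10_000)], k=10)


class TestKernels:
    def test_geometries_disjoint_from_peak_box(self):
        p, iw = 2, 5
        kerns = _kernels(p, iw)
        center = iw
        peak_box = np.zeros((2 * iw + 1, 2 * iw + 1), dtype=bool)
        peak_box[center - p : center + p + 1, center - p : center + p + 1] = True
        for name, k in kerns.items():
            assert not (k & peak_box).any(), name

    def test_donut_excludes_cross(self):
        k = _kernels(2, 5)["donut"]
        assert not k[5, :].any() and not k[:, 5].any()
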