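"""Domain scores, differential internal interactions, differential loops."""

import numpy as np
import pandas as pd
import pytest

from loopforge.dynamics import (
    assign_gene_to_most_dynamic_loop,
    differential_domain_scores,
    differential_loops,
    domain_score,
)
from loopforge.hic import ContactMatrix
from loopforge.loops import Loop


def _sym(dense):
    dense = np.asarray(dense, dtype=float)
    return ContactMatrix.from_dense(np.triu(dense) + np.triu(dense, 1).T)


class TestDomainScore:
    def test_all_contacts_inside_span_gives_one(self):
        dense = np.zeros((6, 6))
        dense[1, 2] = dense[2, 3] = 4.0
        mat = _sym(dense)
        assert domain_score(mat, Loop("chr1", 1, 3, 10_000)) == pytest.approx(1.0)

    def test_five_bin_toy_oracle(self):
        # span bins 1..3; intra {4,6,2}; crossing {3,5}; outside {7} -> 12/20
        dense = np.zeros((5, 5))
        dense[1, 2], dense[1, 3], dense[2, 3] = 4.0, 6.0, 2.0
        dense[0, 1], dense[3, 4] = 3.0, 5.0
        dense[0, 4] = 7.0
        mat = _sym(dense)
        assert domain_score(mat, Loop("chr1", 1, 3, 10_000)) == pytest.approx(0.6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        dense = rng.poisson(3, (12, 12)).astype(float)
        mat, mat2 = _sym(dense), _sym(dense * 2)
        L = Loop("chr1", 3, 8, 10_000)
        assert domain_score(mat, L) == pytest.approx(domain_score(mat2, L))

    def test_matches_brute_force_on_random_matrices(self, rng):
        # 100 random loops on <= 20-bin matrices vs an all-pairs oracle
        for _ in range(100):
            n = int(rng.integers(6, 21))
            dense = rng.poisson(2, (n, n)).astype(float)
            mat = _sym(dense)
            s = int(rng.integers(0, n - 2))
            e = int(rng.integers(s + 1, n))
            got = domain_score(mat, Loop("chr1", s, e, 10_000))
            full = mat.dense()
            intra = conn = 0.0
            for i in range(n):
                for j in range(i, n):
                    v = full[i, j]
                    if s <= i <= e and s <= j <= e:
                        intra += v
                    if (s <= i <= e) or (s <= j <= e):
                        conn += v
            if conn == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(intra / conn, abs=1e-12)

    def test_no_connected_contacts_flagged(self):
        dense = np.zeros((8, 8))
        dense[6, 7] = 3.0
        mat = _sym(dense)
        assert np.isnan(domain_score(mat, Loop("chr1", 0, 2, 10_000)))


class TestDifferentialDomainScores:
    def test_identical_conditions_all_static(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.2, 0.8, size=(40, 3))
        res = differential_domain_scores(d, d)
        assert (res["label"] == "static").all()

    def test_planted_shift_recovery(self):
        rng = np.random.default_rng(3)
        n, shifted = 200, 20
        base = rng.uniform(0.3, 0.6, size=n)
        sd = 0.02
        control = base[:, None] + rng.normal(0, sd, size=(n, 3))
        case = base[:, None] + rng.normal(0, sd, size=(n, 3))
        # shift sized so a Welch t at n=3 clears BH q < 0.01 with margin
        # (see the power note in the boundary suite)
        case[:shifted] += 20 * sd
        res = differential_domain_scores(case, control)
        assert (res["label"][:shifted] == "enhanced").sum() >= 16
        assert (res["label"][shifted:] != "static").sum() <= 2

    def test_permuted_labels_null_fdp(self):
        rng = np.random.default_rng(11)
        n = 200
        base = rng.uniform(0.3, 0.6, size=n)
        data = base[:, None] + rng.normal(0, 0.02, size=(n, 6))
        from itertools import combinations

        n_false = n_tests = 0
        for pick in combinations(range(6), 3):
            a = data[:, list(pick)]
            b = data[:, [c for c in range(6) if c not in pick]]
            res = differential_domain_scores(a, b)
            n_false += (res["label"] != "static").sum()
            n_tests += n
        assert n_false / n_tests <= 0.05


class TestDifferentialLoops:
    def test_planted_condition_specific_loops_recovered(self, differential_sim):
        cfg, matrices, truth = differential_sim
        res = differential_loops(
            {cfg.resolution: {c: [m[0] for m in matrices[c]] for c in cfg.conditions}},
            caller_params={cfg.resolution: (2, 5)})
        dyn = {(L.bin1, L.bin2) for L in truth.loops
               if L.condition_factors.get("MKO", 1.0) != 1.0}
        sig = res[res["significant"]]
        hits = direction_ok = 0
        for b1, b2 in dyn:
            m = sig[(abs(sig.bin1 - b1) <= 1) & (abs(sig.bin2 - b2) <= 1)]
            if len(m):
                hits += 1
                # loops are weaker in MKO -> enriched in WT
                if (m["direction"] == "WT").all():
                    direction_ok += 1
        assert hits / len(dyn) >= 0.8
        assert direction_ok == hits

    def test_label_swap_flips_directions(self, differential_sim):
        cfg, matrices, truth = differential_sim
        by_cond = {c: [m[0] for m in matrices[c]] for c in cfg.conditions}
        fwd = differential_loops({cfg.resolution: by_cond},
                                 caller_params={cfg.resolution: (2, 5)})
        rev = differential_loops({cfg.resolution: {"MKO": by_cond["MKO"], "WT": by_cond["WT"]}},
                                 caller_params={cfg.resolution: (2, 5)})
        merged = fwd.merge(rev, on=["bin1", "bin2"], suffixes=("_f", "_r"))
        assert len(merged) == len(fwd)
        assert np.allclose(merged["coef_f"], -merged["coef_r"], atol=1e-6)
        assert np.allclose(merged["qvalue_f"], merged["qvalue_r"], atol=1e-6)

    def test_double_detection_keeps_5kb_record(self):
        # constructed: identical flat maps at both resolutions with one
        # planted pixel at the same genomic locus
        def mats_at(res, b1, b2, n):
            dense = np.full((n, n), 6.0)
            dense[b1, b2] = dense[b2, b1] = 60.0
            base = ContactMatrix.from_dense(dense, resolution=res)
            reps = [ContactMatrix.from_dense(dense, resolution=res) for _ in range(2)]
            return {"A": reps, "B": [ContactMatrix.from_dense(np.full((n, n), 6.0) +
                                                              np.diag(np.zeros(n)), resolution=res)
                                     for _ in range(2)]}

        res = differential_loops(
            {5_000: mats_at(5_000, 40, 80, 160), 10_000: mats_at(10_000, 20, 40, 80)},
            caller_params={5_000: (4, 7), 10_000: (2, 5)})
        locus = res[(res["bin1"] * res["resolution"] // 10_000 == 20)
                    & (res["bin2"] * res["resolution"] // 10_000 == 40)]
        assert len(locus) == 1
        assert locus["resolution"].iloc[0] == 5_000

    def test_single_replicate_rejected(self):
        dense = np.full((40, 40), 3.0)
        m = ContactMatrix.from_dense(dense)
        with pytest.raises(ValueError):
            differential_loops({10_000: {"A": [m], "B": [m, m]}})

    def test_regime_assignment_boundary_value(self, differential_sim):
        cfg, matrices, truth = differential_sim
        res = differential_loops(
            {cfg.resolution: {c: [m[0] for m in matrices[c]] for c in cfg.conditions}},
            caller_params={cfg.resolution: (2, 5)})
        le = res[res["distance"] <= 150_000]
        gt = res[res["distance"] > 150_000]
        assert (le["regime"] == "le150kb").all()
        assert (gt["regime"] == "gt150kb").all()


class TestMostDynamicLoop:
    def _pairs(self, entries):
        return pd.DataFrame(entries, columns=["gene_id", "loop_index", "chrom", "bin1", "bin2"])

    def test_single_containing_loop(self):
        pairs = self._pairs([("g1", 0, "chr1", 5, 20)])
        ds = pd.DataFrame({"log2_fold": [0.4]})
        out = assign_gene_to_most_dynamic_loop(pairs, ds)
        assert list(out["loop_index"]) == [0]

    def test_maximal_fold_wins(self):
        pairs = self._pairs([("g1", 0, "chr1", 5, 20), ("g1", 1, "chr1", 3, 40)])
        ds = pd.DataFrame({"log2_fold": [0.1, -1.2]})
        out = assign_gene_to_most_dynamic_loop(pairs, ds)
        assert list(out["loop_index"]) == [1]

    def test_tie_breaks_to_smaller_span_stably(self, rng):
        entries = [("g1", 0, "chr1", 5, 40), ("g1", 1, "chr1", 10, 25),
                   ("g1", 2, "chr1", 12, 27)]
        ds = pd.DataFrame({"log2_fold": [0.7, 0.7, 0.7]})
        picks = set()
        for _ in range(10):
            order = rng.permutation(len(entries))
            pairs = self._pairs([entries[i] for i in order])
            out = assign_gene_to_most_dynamic_loop(pairs, ds)
            picks.add(out["loop_index"].iloc[0])
        assert picks == {1}  # smaller span, lower start, input-order independent
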