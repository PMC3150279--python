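"""Sequence polymorphism, neutrality tests and distance matrices."""

import math
from itertools import combinations

import numpy as np
import pytest

from skyisland import build_model
from skyisland.models import simulate_growth_gene_tree, simulate_gene_tree
from skyisland.seqstats import (
    HaplotypeAlignment, InsufficientDataError, UndefinedStatisticError,
    amova_phi_st, distance_matrices, ewens_k_tail, fu_fs, fu_li_d,
    fu_li_d_star, mk_test, polymorphism_summary,
)
from skyisland.synthetic import SyntheticStudyConfig, simulate_sequences


def _aln(seqs, demes=None, outgroup=None):
    ids = [f"s{i}" for i in range(len(seqs))]
    demes = demes or ["X"] * len(seqs)
    return HaplotypeAlignment(seqs, ids, dict(zip(ids, demes)), outgroup)


class TestPolymorphismSummary:
    def test_monomorphic(self):
        s = polymorphism_summary(_aln(["ACGT"] * 5))[0]
        assert (s.seg_sites, s.n_haplotypes) == (0, 1)
        assert s.haplotype_diversity == 0.0
        assert s.nucleotide_diversity == 0.0

    def test_two_sequences_four_differences(self):
        L = 4029
        s = polymorphism_summary(_aln(["A" * L, "TTTT" + "A" * (L - 4)]))[0]
        assert s.seg_sites == 4
        assert s.n_haplotypes == 2
        assert s.haplotype_diversity == 1.0
        assert s.nucleotide_diversity == pytest.approx(4 / 4029, rel=1e-9)

    def test_unbiased_haplotype_diversity(self):
        """Counts {2,1,1}: Hd = 4(1 - (0.25 + 0.0625 + 0.0625))/3."""
        s = polymorphism_summary(_aln(["AAAA", "AAAA", "AAAT", "AATT"]))[0]
        assert s.haplotype_diversity == pytest.approx(
            4 * (1 - (0.25 + 0.0625 + 0.0625)) / 3, rel=1e-12)

    def test_gap_columns_removed(self):
        # column 2 carries a gap and an N: complete deletion drops it
        s = polymorphism_summary(_aln(["A-GT", "ACGT", "ANGA"]))[0]
        assert s.sites == 3
        assert s.seg_sites == 1

    def test_reorder_and_column_permutation_invariance(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(6)]
        base = polymorphism_summary(_aln(seqs))[0]
        order = rng.permutation(6)
        cols = rng.permutation(30)
        shuffled = ["".join(seqs[i][c] for c in cols) for i in order]
        other = polymorphism_summary(_aln(shuffled))[0]
        assert other.haplotype_diversity == pytest.approx(
            base.haplotype_diversity, abs=1e-12)
        assert other.nucleotide_diversity == pytest.approx(
            base.nucleotide_diversity, abs=1e-12)

    def test_per_deme_scope_and_small_deme_error(self):
        aln = _aln(["AAAA", "AATA", "CCCC", "CCCA"], ["X", "X", "Y", "Y"])
        rows = {s.scope: s for s in polymorphism_summary(aln, "per-deme")}
        assert rows["X"].seg_sites == 1
        assert rows["Y"].seg_sites == 1
        with pytest.raises(InsufficientDataError):
            polymorphism_summary(_aln(["AAAA", "CCCC"], ["X", "Y"]), "per-deme")

    def test_watterson_matches_pi_in_expectation(self, session_rng):
        """Neutral panmictic data: E[theta_W] = E[pi_locus] (500 reps)."""
        cfg = SyntheticStudyConfig(
            deme_names=["A"], deme_sizes={"A": 12}, seq_length=600,
            theta_target=0.01, rng_seed=5)
        model = build_model("single", total_ne=500.0, deme_sizes={"A": 12})
        tw, pis = [], []
        for _ in range(500):
            aln, _ = simulate_sequences(model, cfg, session_rng)
            s = polymorphism_summary(aln)[0]
            tw.append(s.watterson_theta)
            pis.append(s.nucleotide_diversity * s.sites)
        diff = np.array(tw) - np.array(pis)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se


class TestFuFs:
    def test_two_sequence_closed_form(self):
        """n=2: S' = theta/(1+theta) so Fs = ln(theta)."""
        L = 4029
        aln = _aln(["A" * L, "TTTT" + "A" * (L - 4)])
        assert fu_fs(aln) == pytest.approx(math.log(4.0), rel=1e-9)

    def test_ewens_tail_two_sequences(self):
        assert ewens_k_tail(2, 2, 0.5) == pytest.approx(0.5 / 1.5, rel=1e-12)
        assert ewens_k_tail(2, 1, 0.5) == pytest.approx(1.0, rel=1e-12)

    def test_monomorphic_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            fu_fs(_aln(["ACGT"] * 4))

    def test_negative_under_growth(self, session_rng):
        """Star-like growth genealogies give strongly negative Fs (>=95%)."""
        neg = 0
        reps = 200
        for _ in range(reps):
            tree = simulate_growth_gene_tree(40, 2000.0, 50 / 2000.0,
                                             session_rng)
            aln = _jc_alignment(tree, mu_site=0.01 / 2000.0, L=2000,
                                rng=session_rng)
            try:
                neg += fu_fs(aln) < 0
            except UndefinedStatisticError:
                pass
        assert neg / reps >= 0.95

    def test_centred_under_constant_size(self, session_rng):
        fs = []
        for _ in range(200):
            tree = simulate_growth_gene_tree(30, 1000.0, 0.0, session_rng)
            aln = _jc_alignment(tree, mu_site=0.005 / 1000.0, L=2000,
                                rng=session_rng)
            try:
                fs.append(fu_fs(aln))
            except UndefinedStatisticError:
                pass
        fs = np.array(fs)
        se = fs.std(ddof=1) / np.sqrt(len(fs))
        assert abs(fs.mean()) < 3 * se


def _jc_alignment(tree, mu_site, L, rng):
    from skyisland.synthetic import _mutate_jc, _BASES
    mat = _mutate_jc(tree, mu_site, L, rng)
    seqs = ["".join(_BASES[row].astype("U1")) for row in mat]
    ids = [f"s{i}" for i in range(tree.n_tips)]
    return HaplotypeAlignment(seqs, ids, {i: "X" for i in ids})


class TestFuLiD:
    def test_all_singletons_negative(self):
        """Every mutation on an external branch pushes D below zero."""
        base = "A" * 30
        seqs = [base[:i] + "T" + base[i + 1:] for i in range(6)]
        aln = _aln(seqs, outgroup={"OG": base})
        assert fu_li_d(aln) < 0
        assert fu_li_d_star(aln) < 0

    def test_requires_outgroup(self):
        with pytest.raises(ValueError):
            fu_li_d(_aln(["AAAT", "AATT", "ATTT"]))

    def test_no_polymorphism_undefined(self):
        aln = _aln(["AAAA"] * 3, outgroup={"OG": "AAAA"})
        with pytest.raises(UndefinedStatisticError):
            fu_li_d(aln)

    def test_near_zero_under_neutral_constant_size(self, session_rng):
        """Neutral calibration: replicate mean within 3 SE of a small bias
        band around zero (the statistic is not exactly centred)."""
        ds = []
        for _ in range(500):
            tree = simulate_growth_gene_tree(25, 1000.0, 0.0, session_rng)
            aln = _jc_alignment(tree, mu_site=0.005 / 1000.0, L=2000,
                                rng=session_rng)
            og = {"OG": "A" * 2000}
            aln = HaplotypeAlignment(aln.sequences, aln.sample_ids,
                                     aln.deme_of_sample, og)
            try:
                ds.append(fu_li_d_star(aln))
            except UndefinedStatisticError:
                pass
        ds = np.array(ds)
        se = ds.std(ddof=1) / np.sqrt(len(ds))
        assert abs(ds.mean()) < max(3 * se, 0.15)


class TestMKTest:
    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher P on [[10,2],[3,9]] equals the brute-force sum
        of all hypergeometric tables no more probable than the observed."""
        from math import comb
        a, b, c, d = 10, 2, 3, 9
        r1, r2, c1 = a + b, c + d, a + c
        n = r1 + r2

        def prob(x):
            return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

        p_obs = prob(a)
        p_brute = sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                      if prob(x) <= p_obs * (1 + 1e-12))
        from scipy.stats import fisher_exact
        p_impl = fisher_exact([[a, b], [c, d]])[1]
        assert p_impl == pytest.approx(p_brute, rel=1e-9)

    def test_counts_and_degenerate_margin(self):
        # ingroup polymorphism AAA/AAG (syn, K) and fixed AAA vs outgroup GAA
        ing = ["ATGAAA", "ATGAAG"]
        aln = _aln(ing, outgroup={"OG": "ATGAAA"})
        res = mk_test(aln)
        assert res["table"].tolist() == [[1, 0], [0, 0]]
        assert res["p_value"] == 1.0

    def test_nonsynonymous_fixed_difference_counted(self):
        ing = ["ATGAAA", "ATGAAA"]
        aln = _aln(ing, outgroup={"OG": "ATGGAA"})  # AAA(K) vs GAA(E): nonsyn
        res = mk_test(aln)
        assert res["table"].tolist() == [[0, 0], [0, 1]]

    def test_frame_error(self):
        with pytest.raises(ValueError):
            mk_test(_aln(["ACGTA", "ACGTA"], outgroup={"OG": "ACGTA"}))


class TestDistanceMatrices:
    def test_fixed_demes_phi_st_one(self):
        aln = _aln(["AAAA", "AAAA", "TTTT", "TTTT"], ["X", "X", "Y", "Y"])
        assert distance_matrices(aln, "phi_st").loc["X", "Y"] == 1.0

    def test_phi_st_matches_naive_amova_oracle(self, rng):
        """Three hand-built demes: vectorized Phi_ST equals a from-scratch
        double-loop AMOVA computation to 1e-9."""
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(9)]
        demes = ["X"] * 3 + ["Y"] * 3 + ["Z"] * 3
        aln = _aln(seqs, demes)
        impl = distance_matrices(aln, "phi_st")

        m = aln.clean_columns()
        names = np.array(demes)
        for x, y in combinations("XYZ", 2):
            idx = np.flatnonzero((names == x) | (names == y))
            sub = m[idx]
            labs = names[idx]
            n = len(idx)
            d2 = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    d2[i, j] = (sub[i] != sub[j]).sum()
            ssd_t = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
            ssd_w = 0.0
            sizes = []
            for g in (x, y):
                gi = np.flatnonzero(labs == g)
                sizes.append(len(gi))
                ssd_w += sum(d2[i, j] for i in gi for j in gi if i < j) / len(gi)
            sigma_w = ssd_w / (n - 2)
            n_c = (n - sum(s * s for s in sizes) / n) / 1
            sigma_a = ((ssd_t - ssd_w) / 1 - sigma_w) / n_c
            expect = max(sigma_a / (sigma_a + sigma_w), 0.0)
            assert impl.loc[x, y] == pytest.approx(expect, abs=1e-9)

    def test_phi_st_null_centred_at_zero(self, session_rng):
        """Demes drawn from one panmictic pool: untruncated Phi_ST ~ 0."""
        model = build_model("single", total_ne=800.0, deme_sizes={"A": 12})
        cfg = SyntheticStudyConfig(deme_names=["A"], deme_sizes={"A": 12},
                                   seq_length=800, theta_target=0.01, rng_seed=0)
        vals = []
        for _ in range(300):
            aln, _ = simulate_sequences(model, cfg, session_rng)
            m = aln.clean_columns()
            d2 = np.zeros((12, 12))
            for i in range(12):
                d2[i] = (m != m[i]).sum(axis=1)
            groups = np.array([0] * 6 + [1] * 6)
            v = amova_phi_st(d2, groups, truncate=False)
            if np.isfinite(v):
                vals.append(v)
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_small_deme_excluded_from_phi_st(self):
        aln = _aln(["AAAA", "AATA", "CCCC", "CCCA", "GGGG"],
                   ["X", "X", "Y", "Y", "Z"])
        mat = distance_matrices(aln, "phi_st")
        assert "Z" not in mat.index

    def test_p_distance_symmetric_zero_diagonal(self):
        aln = _aln(["AAAA", "AATA", "CCCC", "CCCA"], ["X", "X", "Y", "Y"])
        mat = distance_matrices(aln, "p-distance")
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 0.0)
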