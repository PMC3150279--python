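"""Synthetic-data generator: calibration, determinism and fixtures."""

import numpy as np
import pytest

from skyisland import build_model
from skyisland import io as sio
from skyisland.msat import genetic_distances, locus_summaries
from skyisland.seqstats import polymorphism_summary
from skyisland.synthetic import (
    SyntheticStudyConfig, simulate_env_table, simulate_microsats,
    simulate_sequences, write_fixtures,
)


class TestConfig:
    def test_defaults_mirror_study_design(self):
        cfg = SyntheticStudyConfig()
        assert cfg.n_samples == 80
        assert sorted(cfg.deme_sizes.values()) == sorted(
            [11, 14, 7, 5, 5, 7, 8, 14, 7, 2])
        assert cfg.seq_length == 4029
        assert cfg.n_loci_msat == 10

    def test_validation(self):
        with pytest.raises(ValueError):
            SyntheticStudyConfig(deme_sizes={"DL": 0}, deme_names=["DL"])
        with pytest.raises(ValueError):
            SyntheticStudyConfig(msat_min_allele=5, msat_max_allele=3)


class TestSimulateSequences:
    def test_no_mutation_monomorphic(self):
        cfg = SyntheticStudyConfig(mu_site=0.0, rng_seed=1)
        model = build_model("single", total_ne=1e4)
        aln, _ = simulate_sequences(model, cfg)
        assert polymorphism_summary(aln)[0].seg_sites == 0

    def test_watterson_expectation(self, session_rng):
        """Panmictic, n = 20, theta_locus = 10: E[S] = 10 a_19 (500 reps)."""
        n, theta_locus, L = 20, 10.0, 2000
        ne = 500.0
        mu_site = theta_locus / (2 * ne * L)
        cfg = SyntheticStudyConfig(deme_names=["A"], deme_sizes={"A": n},
                                   seq_length=L, mu_site=mu_site, rng_seed=0)
        model = build_model("single", total_ne=ne, deme_sizes={"A": n})
        ss = []
        for _ in range(500):
            aln, _ = simulate_sequences(model, cfg, session_rng)
            ss.append(polymorphism_summary(aln)[0].seg_sites)
        ss = np.array(ss)
        a_n = sum(1 / i for i in range(1, n))
        se = ss.std(ddof=1) / np.sqrt(len(ss))
        assert abs(ss.mean() - theta_locus * a_n) < 3 * se

    def test_pairwise_diversity_matches_theta(self, session_rng):
        """theta per site 0.004: mean pi over replicates ~ 0.004."""
        cfg = SyntheticStudyConfig(deme_names=["A"], deme_sizes={"A": 10},
                                   seq_length=4029, theta_target=0.004,
                                   rng_seed=0)
        model = build_model("single", total_ne=1000.0, deme_sizes={"A": 10})
        pis = []
        for _ in range(300):
            aln, _ = simulate_sequences(model, cfg, session_rng)
            pis.append(polymorphism_summary(aln)[0].nucleotide_diversity)
        pis = np.array(pis)
        se = pis.std(ddof=1) / np.sqrt(len(pis))
        assert abs(pis.mean() - 0.004) < 3 * se

    def test_seeded_determinism(self):
        cfg = SyntheticStudyConfig(rng_seed=11, seq_length=500)
        model = build_model("single", total_ne=1e4)
        a1, _ = simulate_sequences(model, cfg)
        a2, _ = simulate_sequences(model, cfg)
        assert a1.sequences == a2.sequences

    def test_infinite_sites_no_multiple_hits(self, rng):
        cfg = SyntheticStudyConfig(deme_names=["A"], deme_sizes={"A": 10},
                                   seq_length=5000, theta_target=0.002,
                                   infinite_sites=True, rng_seed=3)
        model = build_model("single", total_ne=1000.0, deme_sizes={"A": 10})
        aln, _ = simulate_sequences(model, cfg, rng)
        m = aln.clean_columns()
        # every variable column carries exactly two states
        for col in range(m.shape[1]):
            assert len(np.unique(m[:, col])) <= 2


class TestSimulateMicrosats:
    def test_no_mutation_monomorphic(self):
        cfg = SyntheticStudyConfig(msat_mu=0.0, rng_seed=2)
        model = build_model("single", total_ne=1e4)
        t = simulate_microsats(model, cfg)
        assert all(s.n_alleles == 1 for s in locus_summaries(t))

    def test_allele_range_bounded(self, rng):
        cfg = SyntheticStudyConfig(rng_seed=5)
        model = build_model("single", total_ne=3e6)
        t = simulate_microsats(model, cfg, rng)
        assert t.alleles.min() >= cfg.msat_min_allele
        assert t.alleles.max() <= cfg.msat_max_allele
        # at most nine allele states per locus by construction
        for j in range(t.n_loci):
            assert len(np.unique(t.alleles[:, j])) <= 9

    def test_seeded_determinism(self):
        cfg = SyntheticStudyConfig(rng_seed=6, n_loci_msat=4)
        model = build_model("single", total_ne=1e5)
        a = simulate_microsats(model, cfg)
        b = simulate_microsats(model, cfg)
        assert np.array_equal(a.alleles, b.alleles)

    def test_long_isolation_differentiation_vs_msprime_oracle(self, session_rng):
        """Deep two-refugia split: F_ST well above panmictic levels, in
        agreement with an independent simulator under the same model."""
        msprime = pytest.importorskip("msprime")
        sizes = {"DL": 12, "MK": 12}
        ne = 200.0
        t_split = 10 * ne
        model = build_model("two_refugia", total_ne=ne, deme_sizes=sizes,
                            divergence_times_years={"root_years": t_split})
        cfg = SyntheticStudyConfig(deme_names=list(sizes), deme_sizes=sizes,
                                   n_loci_msat=10, msat_mu=1e-3,
                                   msat_min_allele=5, msat_max_allele=40,
                                   rng_seed=0)
        ours = []
        for _ in range(10):
            t = simulate_microsats(model, cfg, session_rng)
            ours.append(genetic_distances(t, "fst").loc["DL", "MK"])
        assert np.mean(ours) > 0.2

        # independent oracle: same demography, SMC-free msprime + SMM applied
        # to branch lengths via Poisson steps on the same mutation scale
        dem = msprime.Demography()
        ne_by = dict(zip(model.names, model.branch_ne))
        dem.add_population(name="S", initial_size=ne_by["S"])
        dem.add_population(name="NE", initial_size=ne_by["NE"])
        dem.add_population(name="ROOT", initial_size=ne_by["ROOT"])
        dem.add_population_split(time=t_split, derived=["S", "NE"],
                                 ancestral="ROOT")
        div_ours, div_theirs = [], []
        for _ in range(200):
            gt = __import__("skyisland").simulate_gene_tree(model, sizes,
                                                            session_rng)
            div_ours.append(gt.tmrca)
        for ts in msprime.sim_ancestry(samples={"S": 12, "NE": 12},
                                       demography=dem, ploidy=1,
                                       num_replicates=200, random_seed=5):
            div_theirs.append(ts.first().time(ts.first().root))
        a, b = np.array(div_ours), np.array(div_theirs)
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se


class TestEnvTable:
    def test_one_hot_row_sums(self, rng):
        table, _ = simulate_env_table([f"L{i}" for i in range(9)], 1.0, rng)
        for name in ("vegetation", "subregion"):
            assert np.allclose(table.data[table.sets[name]].sum(axis=1), 1.0)

    def test_too_few_locations(self, rng):
        with pytest.raises(ValueError):
            simulate_env_table(["a", "b"], 1.0, rng)

    def test_null_effect_calibrated(self, session_rng):
        """effect = 0: subregion marginal test non-significant at the 5%
        level in >= 90% of 200 replicates."""
        from skyisland.dbrda import gower_center, marginal_test
        nonsig = 0
        reps = 200
        for _ in range(reps):
            table, latent = simulate_env_table(
                [f"L{i}" for i in range(12)], 0.0, session_rng)
            lat = latent.to_numpy()
            G = gower_center(np.abs(lat[:, None] - lat[None, :]))
            p = marginal_test(G, table.matrix("subregion"), 99,
                              session_rng)["p_value"]
            nonsig += p > 0.05
        assert nonsig / reps >= 0.9

    def test_planted_signal_beats_rainfall(self, session_rng):
        """Maximal effect: subregion %var exceeds rainfall %var in >= 95%."""
        from skyisland.dbrda import gower_center, marginal_test
        wins = 0
        reps = 100
        for _ in range(reps):
            table, latent = simulate_env_table(
                [f"L{i}" for i in range(12)], 10.0, session_rng)
            lat = latent.to_numpy()
            G = gower_center(np.abs(lat[:, None] - lat[None, :]))
            sub = marginal_test(G, table.matrix("subregion"), 99,
                                session_rng)["pct_var"]
            rain = marginal_test(G, table.matrix("rainfall"), 99,
                                 session_rng)["pct_var"]
            wins += sub > rain
        assert wins / reps >= 0.95


class TestFixtures:
    def test_round_trips(self, tmp_path, rng):
        cfg = SyntheticStudyConfig(rng_seed=13, seq_length=300, n_loci_msat=3)
        model = build_model("single", total_ne=1e4)
        aln, tree = simulate_sequences(model, cfg, rng)
        geno = simulate_microsats(model, cfg, rng)
        geno.mask[2, 1] = True  # exercise the missing-data path
        pred, _ = simulate_env_table(list(cfg.deme_names), 1.0, rng)
        paths = write_fixtures({"alignment": aln, "gene_tree": tree,
                                "genotypes": geno, "predictors": pred,
                                "config": cfg}, tmp_path)
        assert all(p.exists() for p in paths)

        aln2 = sio.read_fasta_alignment(tmp_path / "sequences.fasta",
                                        aln.deme_of_sample)
        assert aln2.sequences == aln.sequences
        assert aln2.sample_ids == aln.sample_ids

        geno2 = sio.read_genotypes(tmp_path / "genotypes.tsv")
        assert np.array_equal(geno2.alleles[~geno2.mask], geno.alleles[~geno.mask])
        assert np.array_equal(geno2.mask, geno.mask)

        pred2 = sio.read_predictors(tmp_path / "predictors.tsv")
        assert pred2.sets == pred.sets
        assert np.allclose(pred2.data.to_numpy(), pred.data.to_numpy())

        from skyisland.models import GeneTree
        tree2 = GeneTree.from_dendropy(
            sio.read_newick(tmp_path / "gene_tree.nwk"))
        assert tree2.n_tips == tree.n_tips
        assert tree2.tmrca == pytest.approx(tree.tmrca, abs=1e-9 * tree.tmrca)
        # same topology: identical sorted coalescence times and deme labels
        assert np.allclose(np.sort(tree2.time), np.sort(tree.time),
                           rtol=1e-9)

    def test_metadata_round_trip(self, tmp_path):
        from skyisland.models import SUBREGION_OF_DEME
        deme_of = {"s1": "DL", "s2": "MK"}
        sio.write_metadata(deme_of, SUBREGION_OF_DEME, tmp_path / "m.tsv")
        back, sub = sio.read_metadata(tmp_path / "m.tsv")
        assert back == deme_of
        assert sub["DL"] == "S" and sub["MK"] == "N"
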