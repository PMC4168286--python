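"""Simulator: dated trees, HKY+Gamma sequences, missing-data injection."""

import math

import dendropy
import numpy as np
import pytest
from scipy import stats

from barcodeval import (
    CladeConfig,
    LocusConfig,
    SimulationConfig,
    inject_missing,
    k2p_distance,
    lotus_like_config,
    make_dataset,
    run_evaluation,
    simulate_dated_tree,
    simulate_sequences,
    uniform_radiation_config,
)
from barcodeval.simulate import discrete_gamma_rates, hky_rate_matrix

SMALL_LOCI = (
    LocusConfig("fast", 400, 4.0e-3),
    LocusConfig("slow", 400, 4.0e-4),
)


def small_config(seed=0, **kw):
    defaults = dict(
        clades=(
            CladeConfig("old", 4.0, 4),
            CladeConfig("young", 0.5, 3),
        ),
        loci=SMALL_LOCI,
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateDatedTree:
    def test_single_species_two_accessions_depth_bounded(self):
        cfg = SimulationConfig(
            clades=(CladeConfig("c", 1.0, 1),),
            loci=SMALL_LOCI,
            accessions_per_species=(2, 2),
            intraspecific_depth_mya=0.05,
            seed=1,
        )
        tree, truth = simulate_dated_tree(cfg)
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == 2
        mrca_depth = tree.phylogenetic_distance_matrix().distance(
            leaves[0].taxon, leaves[1].taxon
        ) / 2
        assert mrca_depth <= 0.05 + 1e-12

    def test_tip_count_equals_species_times_accessions(self):
        cfg = small_config(seed=3)
        tree, truth = simulate_dated_tree(cfg)
        assert len(truth["species_clade"]) == 7
        n_tips = sum(1 for _ in tree.leaf_node_iter())
        assert n_tips == len(truth["accession_species"])
        lo, hi = cfg.accessions_per_species
        per_species = {}
        for acc, sp in truth["accession_species"].items():
            per_species[sp] = per_species.get(sp, 0) + 1
        assert all(lo <= n <= hi for n in per_species.values())

    def test_branch_lengths_nonnegative_and_tips_at_present(self):
        tree, _ = simulate_dated_tree(small_config(seed=5))
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                assert nd.edge.length >= 0
        for lf in tree.leaf_node_iter():
            assert lf.age == 0.0

    def test_same_seed_identical_different_seed_differs(self):
        newicks = set()
        for seed in range(20):
            t1, _ = simulate_dated_tree(small_config(seed=seed))
            t2, _ = simulate_dated_tree(small_config(seed=seed))
            s1 = t1.as_string(schema="newick")
            assert s1 == t2.as_string(schema="newick")
            newicks.add(s1)
        assert len(newicks) == 20

    def test_crown_above_stem_rejected(self):
        with pytest.raises(Exception):
            CladeConfig("bad", 1.0, 3, crown_age_fraction=1.5)


class TestHKYGamma:
    def test_rate_matrix_rows_sum_to_zero_and_unit_flux(self):
        freqs = (0.3, 0.2, 0.3, 0.2)
        Q = hky_rate_matrix(2.5, freqs)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert -(np.asarray(freqs) * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_discrete_gamma_categories_have_unit_mean(self):
        for shape in (0.3, 0.8, 2.0):
            r = discrete_gamma_rates(shape, 4)
            assert r.mean() == pytest.approx(1.0, abs=1e-9)
            assert (np.diff(r) > 0).all()

    def test_zero_length_tree_gives_identical_sequences(self):
        tns = dendropy.TaxonNamespace(["a", "b"])
        root = dendropy.Node()
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        for l in ("a", "b"):
            nd = dendropy.Node(taxon=tns.get_taxon(l))
            root.add_child(nd)
            nd.edge.length = 0.0
        aln = simulate_sequences(tree, LocusConfig("L", 300, 1e-3), seed=4)
        a, b = aln.sequences.values()
        assert a == b

    def _two_tip_tree(self, half_path):
        tns = dendropy.TaxonNamespace(["a", "b"])
        root = dendropy.Node()
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        for l in ("a", "b"):
            nd = dendropy.Node(taxon=tns.get_taxon(l))
            root.add_child(nd)
            nd.edge.length = half_path
        return tree

    def test_mean_k2p_distance_matches_2_rate_t(self):
        # divergence path 2*T, rate r -> expected K2P distance 2*r*T
        rate, T, L, reps = 2.0e-2, 0.5, 800, 200
        tree = self._two_tip_tree(T)
        locus = LocusConfig("L", L, rate, gamma_shape=1.0)
        ds = []
        for seed in range(reps):
            aln = simulate_sequences(tree, locus, seed=seed)
            a, b = aln.sequences.values()
            ds.append(k2p_distance(a, b).d)
        expected = 2 * rate * T
        se = np.std(ds, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(ds) - expected) < 3 * se + 1e-12

    def test_huge_kappa_suppresses_transversions(self):
        tree = self._two_tip_tree(0.5)
        locus = LocusConfig("L", 2000, 0.05, kappa=1e6)
        aln = simulate_sequences(tree, locus, seed=9)
        a, b = aln.sequences.values()
        r = k2p_distance(a, b)
        assert r.P > 0
        assert r.Q <= 2 / 2000  # essentially no transversions


class TestInjectMissing:
    def test_fraction_zero_is_identity(self):
        ds = make_dataset(small_config(seed=2, missing_fraction=0.0))
        out = inject_missing(list(ds.loci), 0.0, seed=1)
        assert [a.sequences for a in out] == [a.sequences for a in ds.loci]

    def test_removed_count_within_binomial_99_interval(self):
        from barcodeval.io import LocusAlignment

        rng = np.random.default_rng(0)
        loci = [
            LocusAlignment(
                locus_name=f"L{k}",
                sequences={
                    f"a{i:02d}": "".join(rng.choice(list("ACGT"), size=20))
                    for i in range(50)
                },
            )
            for k in range(6)
        ]
        out = inject_missing(loci, 0.2, seed=7)
        removed = sum(50 - len(a) for a in out)
        n, p = 300, 0.2
        lo = stats.binom.ppf(0.005, n, p)
        hi = stats.binom.ppf(0.995, n, p)
        assert lo <= removed <= hi

    def test_each_accession_keeps_at_least_one_locus(self):
        from barcodeval.io import LocusAlignment

        rng = np.random.default_rng(1)
        loci = [
            LocusAlignment(
                locus_name=f"L{k}",
                sequences={
                    f"a{i:02d}": "".join(rng.choice(list("ACGT"), size=10))
                    for i in range(30)
                },
            )
            for k in range(2)
        ]
        out = inject_missing(loci, 0.7, seed=3)
        for acc in (f"a{i:02d}" for i in range(30)):
            assert any(acc in a.sequences for a in out)

    def test_same_seed_same_pattern(self):
        ds = make_dataset(small_config(seed=4, missing_fraction=0.0))
        o1 = inject_missing(list(ds.loci), 0.3, seed=5)
        o2 = inject_missing(list(ds.loci), 0.3, seed=5)
        assert [set(a.sequences) for a in o1] == [set(a.sequences) for a in o2]


class TestMakeDataset:
    def test_lotus_like_preset_shape(self, tmp_path):
        ds = make_dataset(lotus_like_config(seed=1), out_dir=tmp_path)
        lengths = {a.locus_name: a.aligned_length for a in ds.loci}
        assert lengths == {
            "ITS": 621, "trnH-psbA": 342, "matK": 867,
            "rpoC1": 511, "rbcL": 588, "rpoB": 354,
        }
        assert len(set(ds.truth["species_clade"].values())) == 9
        assert len(ds.truth["species_clade"]) == 38
        assert (tmp_path / "samples.tsv").exists()
        assert (tmp_path / "truth.json").exists()
        assert len({sp for sp in ds.table.df["species"]}) == 38

    def test_truth_species_match_metadata(self):
        ds = make_dataset(small_config(seed=6))
        assert set(ds.truth["species_clade"]) == set(ds.table.df["species"])
        assert set(ds.ages["group"]) == {c.name for c in ds.config.clades}

    def test_deep_divergence_preset_fully_discriminated(self):
        # every species anciently divergent, no missing data
        cfg = SimulationConfig(
            clades=(CladeConfig("c1", 8.0, 3), CladeConfig("c2", 12.0, 3)),
            loci=SMALL_LOCI,
            accessions_per_species=(2, 3),
            missing_fraction=0.0,
            seed=8,
        )
        ds = make_dataset(cfg)
        rep = run_evaluation(
            list(ds.loci), ds.table, schemes=("all",), modes=("A",), its="fast"
        ).reports[0]
        assert rep.totals["n_species_discriminated"] == 6
        assert rep.totals["n_groups_discriminated"] == 2


class TestAgeAndRateProperties:
    def test_discrimination_monotone_in_clade_age(self):
        # success averaged over seeds should rise with crown age
        from barcodeval import age_success_association

        ages = [0.1, 0.5, 1.0, 2.0, 4.0]
        mean_succ = []
        for age in ages:
            vals = []
            for seed in range(20):
                from dataclasses import replace

                cfg = replace(
                    uniform_radiation_config(
                        age, n_clades=2, n_species=4, seed=seed, loci=SMALL_LOCI
                    ),
                    missing_fraction=0.0,
                )
                ds = make_dataset(cfg)
                rep = run_evaluation(
                    list(ds.loci), ds.table, schemes=("all",), modes=("A",),
                    its="fast",
                ).reports[0]
                vals.append(rep.totals["pct_species"])
            mean_succ.append(sum(vals) / len(vals))
        rho = stats.spearmanr(ages, mean_succ).statistic
        assert rho > 0
        assert mean_succ[-1] > mean_succ[0]

    def test_faster_locus_never_discriminates_worse(self):
        diffs = []
        for seed in range(10):
            cfg = small_config(seed=seed, missing_fraction=0.0)
            ds = make_dataset(cfg)
            res = run_evaluation(
                list(ds.loci), ds.table, schemes=("singles",), modes=("A",),
                its="nonexistent",
            )
            by_locus = {r.combination[0]: r.totals["pct_species"] for r in res.reports}
            diffs.append(by_locus["fast"] - by_locus["slow"])
        assert sum(diffs) / len(diffs) >= 0
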