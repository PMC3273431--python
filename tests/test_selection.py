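"""GY94 machinery: generator, likelihood, fits, LRT, posteriors, counting."""
import numpy as np
import pytest

from kunitzkit.codon import (
    CODON_INDEX,
    N_CODONS,
    SINGLE_CHANGE,
    SYNONYMOUS,
    CodonAlignment,
    ReversibleGenerator,
    codon_frequencies,
    gy94_matrix,
    thread_codon_alignment,
)
from kunitzkit.io_formats import SequenceRecord
from kunitzkit.selection import (
    SiteModel,
    beta_category_means,
    fit_models,
    fit_site_model,
    likelihood_ratio_test,
    lrt_critical_value,
    nei_gojobori,
    site_class_log_likelihoods,
    site_mixture_loglik,
    site_posteriors,
)
from kunitzkit.synthetic_data import random_tree, simulate_codon_alignment
from kunitzkit.tree import Node, PhyloTree, parse_newick


def _random_pi(seed):
    return np.random.default_rng(seed).dirichlet(np.ones(N_CODONS))


class TestGenerator:
    @pytest.mark.parametrize("seed", range(4))
    def test_rows_sum_zero_detailed_balance_unit_rate(self, seed):
        rng = np.random.default_rng(seed)
        kappa = float(rng.uniform(0.5, 8))
        omega = float(rng.uniform(0.05, 3))
        pi = _random_pi(seed + 100)
        Q = gy94_matrix(kappa, omega, pi)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-14)
        assert -(pi @ np.diag(Q)) == pytest.approx(1.0, rel=1e-12)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        Q = gy94_matrix(2.0, 0.0, np.full(N_CODONS, 1 / N_CODONS))
        nonsyn = SINGLE_CHANGE & ~SYNONYMOUS
        assert np.all(Q[nonsyn] == 0.0)

    def test_parameter_collapse_equalizes_rates(self):
        Q = gy94_matrix(1.0, 1.0, np.full(N_CODONS, 1 / N_CODONS))
        rates = Q[SINGLE_CHANGE]
        assert np.allclose(rates, rates[0])

    def test_transition_matrix_is_stochastic(self):
        pi = _random_pi(3)
        gen = ReversibleGenerator.from_q(gy94_matrix(2.0, 0.5, pi), pi)
        for t in (0.0, 0.1, 2.0):
            P = gen.transition(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert (P >= 0).all()


class TestCodonFrequencies:
    def test_equal_scheme(self):
        aln = CodonAlignment.from_sequences(["a"], ["ATGAAA"])
        pi = codon_frequencies(aln, "equal")
        assert np.allclose(pi, 1 / N_CODONS)

    def test_f1x4_concentrates_on_observed_nucleotides(self):
        aln = CodonAlignment.from_sequences(["a"], ["AAA" * 5])
        pi = codon_frequencies(aln, "F1x4")
        assert pi[CODON_INDEX["AAA"]] == pytest.approx(1.0)

    @pytest.mark.parametrize("scheme", ["equal", "F1x4", "F3x4"])
    def test_simplex_normalization(self, scheme):
        tree = random_tree(4, seed=5)
        model = SiteModel(name="M0", kappa=2.0, pi=np.full(N_CODONS, 1 / N_CODONS),
                          params={"omega": 0.5})
        aln, _ = simulate_codon_alignment(tree, model, 50, seed=6)
        pi = codon_frequencies(aln, scheme)
        assert pi.sum() == pytest.approx(1.0)
        assert (pi >= 0).all()


class TestThreading:
    def test_gap_columns_become_gap_codons(self):
        rec = SequenceRecord(id="a", residues="M-K")
        aln = thread_codon_alignment([rec], {"a": "ATGAAA"})
        assert aln.codons[0] == ["ATG", "---", "AAA"]

    def test_mismatch_names_first_bad_residue(self):
        rec = SequenceRecord(id="a", residues="MW")
        with pytest.raises(ValueError, match="residue 2"):
            thread_codon_alignment([rec], {"a": "ATGAAA"})

    def test_round_trip_translation(self):
        from kunitzkit.io_formats import translate_cds

        tree = random_tree(4, seed=7)
        model = SiteModel(name="M0", kappa=2.0, pi=np.full(N_CODONS, 1 / N_CODONS),
                          params={"omega": 0.4})
        aln, _ = simulate_codon_alignment(tree, model, 30, seed=8)
        seqs = aln.sequences()
        proteins = [
            SequenceRecord(id=sid, residues=translate_cds(seq))
            for sid, seq in seqs.items()
        ]
        back = thread_codon_alignment(proteins, seqs)
        assert back.sequences() == seqs


class TestLikelihood:
    def test_two_sequence_closed_form(self):
        pi = _random_pi(9)
        kappa, omega, t = 2.5, 0.6, 0.3
        root = Node()
        root.add(Node(label="a", length=0.0))
        root.add(Node(label="b", length=t))
        tree = PhyloTree(root, rooted=True)
        aln = CodonAlignment.from_sequences(["a", "b"], ["ATG", "ACG"])
        model = SiteModel(name="M0", kappa=kappa, pi=pi, params={"omega": omega})
        lnl = site_mixture_loglik(tree, aln, model)
        gen = ReversibleGenerator.from_q(gy94_matrix(kappa, omega, pi), pi)
        i, j = CODON_INDEX["ATG"], CODON_INDEX["ACG"]
        expected = np.log(pi[i] * gen.transition(t)[i, j])
        assert lnl == pytest.approx(expected, rel=1e-10)

    def test_pruning_matches_brute_force_enumeration(self):
        # 4 taxa, 2 sites: sum over all internal-node codon assignments
        newick = "((a:0.2,b:0.35):0.15,(c:0.1,d:0.25):0.05);"
        tree = parse_newick(newick)
        pi = _random_pi(11)
        model = SiteModel(name="M0", kappa=3.0, pi=pi, params={"omega": 0.8})
        aln, _ = simulate_codon_alignment(tree, model, 2, seed=12)
        lnl = site_mixture_loglik(tree, aln, model)

        gen = ReversibleGenerator.from_q(gy94_matrix(3.0, 0.8, pi), pi)
        X = aln.to_indices()
        row = {sid: k for k, sid in enumerate(aln.ids)}
        left, right = tree.root.children
        (a, b), (c, d) = left.children, right.children
        P = {id(n): gen.transition(n.length) for n in (a, b, c, d, left, right)}
        total = 0.0
        for s in range(2):
            xa, xb = X[row[a.label], s], X[row[b.label], s]
            xc, xd = X[row[c.label], s], X[row[d.label], s]
            like = 0.0
            for u in range(N_CODONS):  # root state
                for v in range(N_CODONS):  # left internal
                    for w in range(N_CODONS):  # right internal
                        like += (
                            pi[u]
                            * P[id(left)][u, v] * P[id(a)][v, xa] * P[id(b)][v, xb]
                            * P[id(right)][u, w] * P[id(c)][w, xc] * P[id(d)][w, xd]
                        )
            total += np.log(like)
        assert lnl == pytest.approx(total, abs=1e-10)

    def test_zero_branch_limit_gives_stationary_logprob(self):
        pi = _random_pi(13)
        root = Node()
        for lbl in ("a", "b", "c"):
            root.add(Node(label=lbl, length=1e-9))
        tree = PhyloTree(root)
        aln = CodonAlignment.from_sequences(["a", "b", "c"], ["ATGAAA"] * 3)
        model = SiteModel(name="M0", kappa=2.0, pi=pi, params={"omega": 1.0})
        lnl = site_mixture_loglik(tree, aln, model)
        expected = np.log(pi[CODON_INDEX["ATG"]]) + np.log(pi[CODON_INDEX["AAA"]])
        assert lnl == pytest.approx(expected, rel=1e-6)

    def test_invariant_under_rerooting(self):
        pi = _random_pi(14)
        model = SiteModel(name="M0", kappa=2.0, pi=pi, params={"omega": 0.5})
        t1 = parse_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.07);")
        t2 = parse_newick("(a:0.1,b:0.2,(c:0.3,d:0.1):0.12);")  # same unrooted tree
        aln, _ = simulate_codon_alignment(t1, model, 40, seed=15)
        assert site_mixture_loglik(t1, aln, model) == pytest.approx(
            site_mixture_loglik(t2, aln, model), abs=1e-8
        )

    def test_gap_codons_are_fully_ambiguous(self):
        tree = parse_newick("(a:0.1,b:0.2,c:0.15);")
        pi = np.full(N_CODONS, 1 / N_CODONS)
        model = SiteModel(name="M0", kappa=2.0, pi=pi, params={"omega": 0.5})
        full = CodonAlignment.from_sequences(["a", "b", "c"],
                                             ["ATGAAA", "ATGAAG", "ATGAAC"])
        gapped = CodonAlignment.from_sequences(["a", "b", "c"],
                                               ["ATG---", "ATGAAG", "ATGAAC"])
        l_full = site_class_log_likelihoods(tree, full, model)
        l_gap = site_class_log_likelihoods(tree, gapped, model)
        assert l_gap[0, 0] == pytest.approx(l_full[0, 0])  # site 1 untouched
        assert l_gap[1, 0] > l_full[1, 0]  # marginalized site is less constrained

    def test_unknown_leaf_rejected(self):
        tree = parse_newick("(a:0.1,b:0.2,z:0.15);")
        aln = CodonAlignment.from_sequences(["a", "b", "c"], ["ATG"] * 3)
        model = SiteModel(name="M0", kappa=2.0, pi=np.full(N_CODONS, 1 / N_CODONS),
                          params={"omega": 0.5})
        with pytest.raises(ValueError, match="missing"):
            site_mixture_loglik(tree, aln, model)


class TestBetaDiscretization:
    def test_category_means_average_to_distribution_mean(self):
        for p, q in ((0.5, 0.5), (2.0, 5.0), (0.2, 1.7)):
            means = beta_category_means(p, q, 10)
            assert means.mean() == pytest.approx(p / (p + q), rel=1e-6)
            assert np.all(np.diff(means) > 0)


@pytest.fixture(scope="module")
def small_fit():
    tree = random_tree(5, seed=20, length_range=(0.1, 0.4))
    truth = SiteModel(name="M0", kappa=2.0,
                      pi=np.full(N_CODONS, 1 / N_CODONS),
                      params={"omega": 0.3}, freq_scheme="equal")
    aln, _ = simulate_codon_alignment(tree, truth, 150, seed=21)
    fits = fit_models(aln, tree, ("M0", "M1a", "M2a", "M3", "M7", "M8"),
                      freq_scheme="F3x4", n_restarts=2, seed=22)
    return aln, tree, fits


class TestFitting:
    def test_nesting_inequalities(self, small_fit):
        _, _, fits = small_fit
        tol = 1e-6
        assert fits["M3"].lnL >= fits["M0"].lnL - tol
        assert fits["M2a"].lnL >= fits["M1a"].lnL - tol
        assert fits["M8"].lnL >= fits["M7"].lnL - tol

    def test_m0_estimates_near_truth(self, small_fit):
        _, _, fits = small_fit
        assert fits["M0"].model.params["omega"] == pytest.approx(0.3, abs=0.12)
        assert fits["M0"].model.kappa == pytest.approx(2.0, abs=1.0)
        assert fits["M0"].converged

    def test_identical_sequences_flagged_non_identifiable(self):
        tree = random_tree(4, seed=23)
        aln = CodonAlignment.from_sequences(
            [f"t{i + 1}" for i in range(4)], ["ATGAAAGGG"] * 4
        )
        fit = fit_site_model(aln, tree, "M0", n_restarts=1,
                             optimize_branch_lengths=True)
        assert any("identical" in note for note in fit.notes)
        total = sum(n.length for n in fit.tree.postorder() if n.parent is not None)
        assert total < 1e-3


class TestLRT:
    def test_printed_critical_values(self):
        assert lrt_critical_value(2) == pytest.approx(9.21, abs=0.005)
        assert lrt_critical_value(4) == pytest.approx(13.28, abs=0.005)

    def test_ten_exceeds_df2_threshold(self):
        null = _fake_fit(-100.0)
        alt = _fake_fit(-95.0)
        res = likelihood_ratio_test(null, alt, df=2)
        assert res.two_delta_l == pytest.approx(10.0)
        assert res.significant_1pct

    def test_critical_value_maps_to_one_percent(self):
        res = likelihood_ratio_test(_fake_fit(-100.0), _fake_fit(-100.0 + 9.21 / 2), 2)
        assert res.p_value == pytest.approx(0.01, abs=1e-4)

    def test_identical_fits(self):
        res = likelihood_ratio_test(_fake_fit(-50.0), _fake_fit(-50.0), df=2)
        assert res.two_delta_l == 0.0
        assert res.p_value == 1.0
        assert not res.significant_1pct

    def test_tiny_negative_clamped_large_negative_raises(self):
        assert likelihood_ratio_test(
            _fake_fit(-50.0), _fake_fit(-50.0 - 1e-8), df=2
        ).two_delta_l == 0.0
        with pytest.raises(ValueError, match="optimization"):
            likelihood_ratio_test(_fake_fit(-50.0), _fake_fit(-51.0), df=2)


def _fake_fit(lnl):
    from kunitzkit.selection import FitResult

    model = SiteModel(name="M0", kappa=2.0, pi=np.full(N_CODONS, 1 / N_CODONS),
                      params={"omega": 0.5})
    tree = random_tree(3, seed=1)
    return FitResult(model=model, lnL=lnl, tree=tree, converged=True,
                     n_restarts_used=1)


class TestPosteriors:
    def test_rows_sum_to_one_and_m0_rejected(self):
        tree = random_tree(4, seed=30, length_range=(0.2, 0.5))
        truth = SiteModel(name="M2a", kappa=2.0,
                          pi=np.full(N_CODONS, 1 / N_CODONS),
                          params={"p0": 0.7, "p1": 0.1, "omega0": 0.1,
                                  "omega2": 4.0}, freq_scheme="equal")
        aln, _ = simulate_codon_alignment(tree, truth, 60, seed=31)
        fits = fit_models(aln, tree, ("M0", "M1a", "M2a"), n_restarts=1, seed=32)
        for method in ("NEB", "BEB"):
            post = site_posteriors(fits["M2a"], aln, method=method)
            assert np.allclose(post.site_probs.sum(axis=1), 1.0, atol=1e-9)
            assert all(
                post.positive_probability[s] > 0.95 for s in post.positive_sites
            )
        with pytest.raises(ValueError, match="omega > 1"):
            site_posteriors(fits["M0"], aln)

    def test_null_like_fit_calls_no_sites(self):
        tree = random_tree(4, seed=33, length_range=(0.1, 0.3))
        truth = SiteModel(name="M1a", kappa=2.0,
                          pi=np.full(N_CODONS, 1 / N_CODONS),
                          params={"p0": 0.8, "omega0": 0.2}, freq_scheme="equal")
        aln, _ = simulate_codon_alignment(tree, truth, 100, seed=34)
        fits = fit_models(aln, tree, ("M0", "M1a", "M2a"), n_restarts=1, seed=35)
        post = site_posteriors(fits["M2a"], aln, method="NEB")
        assert post.positive_sites == []


class TestNeiGojobori:
    def test_identical_sequences(self):
        res = nei_gojobori("ATGAAAGGG", "ATGAAAGGG")
        assert res.Sd == res.Nd == 0.0
        assert res.dS == 0.0 and res.dN == 0.0

    def test_glycine_codon_hand_enumeration(self):
        res = nei_gojobori("GGG", "GGA")
        assert res.S == pytest.approx(1.0)
        assert res.N == pytest.approx(2.0)
        assert res.Sd == 1.0 and res.Nd == 0.0
        assert res.pS == pytest.approx(1.0)
        assert res.pN == 0.0
        assert np.isnan(res.dS)  # p = 1 >= 3/4: correction undefined
        assert res.dN == 0.0

    def test_gapped_codons_skipped(self):
        res = nei_gojobori(["ATG", "---", "GGG"], ["ATG", "AAA", "GGA"])
        assert res.Sd == 1.0 and res.Nd == 0.0

    def test_neutral_simulation_gives_ratio_near_one(self):
        root = Node()
        root.add(Node(label="a", length=0.0))
        root.add(Node(label="b", length=0.6))
        tree = PhyloTree(root, rooted=True)
        model = SiteModel(name="M0", kappa=2.0,
                          pi=np.full(N_CODONS, 1 / N_CODONS),
                          params={"omega": 1.0}, freq_scheme="equal")
        aln, _ = simulate_codon_alignment(tree, model, 3000, seed=40)
        seqs = aln.sequences()
        res = nei_gojobori(seqs["a"], seqs["b"])
        assert res.omega == pytest.approx(1.0, abs=0.2)

    def test_omega_zero_gives_zero_dn(self):
        root = Node()
        root.add(Node(label="a", length=0.0))
        root.add(Node(label="b", length=0.5))
        tree = PhyloTree(root, rooted=True)
        model = SiteModel(name="M0", kappa=2.0,
                          pi=np.full(N_CODONS, 1 / N_CODONS),
                          params={"omega": 0.0}, freq_scheme="equal")
        aln, _ = simulate_codon_alignment(tree, model, 500, seed=41)
        seqs = aln.sequences()
        res = nei_gojobori(seqs["a"], seqs["b"])
        assert res.Nd == 0.0
        assert res.Sd > 0
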