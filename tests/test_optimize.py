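"""Estimation blocks: gradients, monotonicity, constraints, recovery."""

import numpy as np
import pytest

from gtrlink.core_model import (
    ExchangeabilityMatrix,
    Profile,
    ProfileMixture,
    lg_matrix,
    poisson_matrix,
    sad,
)
from gtrlink.likelihood import (
    DiscreteRates,
    LikelihoodEngine,
    MixtureModelSpec,
    discretize_gamma,
)
from gtrlink.optimize import (
    FitOptions,
    fit_alpha,
    fit_branch_lengths,
    fit_exchangeabilities,
    fit_joint,
    fit_weights,
)
from gtrlink.phylo_io import Alignment, compress_patterns, parse_newick
from gtrlink.simulate import (
    SimulationSpec,
    biochemical_profiles,
    random_tree,
    simulate_alignment,
)

from conftest import random_codes, random_exchangeability, random_mixture
from oracles import jc20_distance


def _engine(aln, tree):
    table = compress_patterns(aln)
    table.taxa = aln.taxa
    return LikelihoodEngine(table, tree)


class TestAnalyticGradients:
    """The engine's analytic gradients are the optimizer's foundation."""

    def _setup(self, seed, n_taxa=5, n_sites=40):
        rng = np.random.default_rng(seed)
        tree = random_tree(n_taxa, seed=seed + 900)
        S = random_exchangeability(rng)
        mix = random_mixture(rng, 2)
        rates = discretize_gamma(0.8, 2)
        codes = random_codes(rng, n_taxa, n_sites)
        from gtrlink.core_model import AMINO_ACIDS
        rows = ["".join(AMINO_ACIDS[c] if c >= 0 else "-" for c in codes[i])
                for i in range(n_taxa)]
        aln = Alignment(tree.leaf_labels(), rows)
        return rng, aln, tree, S, mix, rates

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exchangeability_gradient_matches_central_differences(self, seed):
        rng, aln, tree, S, mix, rates = self._setup(seed)
        engine = _engine(aln, tree)
        out = engine.loglik_and_gradients(S, mix, rates,
                                          wrt=("exchangeabilities",))
        iu = np.triu_indices(20, k=1)
        for t in rng.choice(190, 8, replace=False):
            i, j = iu[0][t], iu[1][t]
            h = 1e-6 * max(1.0, S.entries[i, j])

            def ll(d):
                m = S.entries.copy()
                m[i, j] += d
                m[j, i] += d
                return engine.loglik(ExchangeabilityMatrix(m), mix, rates)[0]

            fd = (ll(h) - ll(-h)) / (2 * h)
            # central differences carry ~1e-7 absolute round-off here
            assert out["grad_s"][t] == pytest.approx(fd, rel=2e-3, abs=2e-6)

    @pytest.mark.parametrize("seed", [2, 3])
    def test_branch_gradient_matches_central_differences(self, seed):
        _, aln, tree, S, mix, rates = self._setup(seed)
        engine = _engine(aln, tree)
        out = engine.loglik_and_gradients(S, mix, rates,
                                          wrt=("branch_lengths",))
        bl = tree.branch_lengths()
        for b in range(bl.size):
            h = 1e-6
            up, dn = bl.copy(), bl.copy()
            up[b] += h
            dn[b] -= h
            fd = (engine.loglik(S, mix, rates, up)[0]
                  - engine.loglik(S, mix, rates, dn)[0]) / (2 * h)
            assert out["blen"][b] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_weight_gradient_identity(self, rng):
        # sum_c w_c dl/dw_c = n for any mixture (likelihood is 1-homogeneous
        # in the raw weights)
        _, aln, tree, S, mix, rates = self._setup(11)
        engine = _engine(aln, tree)
        out = engine.loglik_and_gradients(S, mix, rates, wrt=("weights",))
        assert float(mix.weights @ out["weights"]) == pytest.approx(
            aln.n_sites, rel=1e-9)


class TestFitExchangeabilities:
    def _sim(self, S_true, n_sites=1200, seed=5):
        tree = random_tree(8, seed=44, mean_length=0.2)
        mix = ProfileMixture(biochemical_profiles(),
                             np.array([0.35, 0.15, 0.25, 0.25]))
        rates = DiscreteRates.homogeneous()
        sim = simulate_alignment(SimulationSpec(tree, S_true, mix, rates,
                                                n_sites, seed=seed))
        return sim.alignment, MixtureModelSpec(S_true, mix, rates, tree)

    def test_initialization_at_truth_barely_moves(self):
        aln, spec = self._sim(poisson_matrix())
        fit = fit_exchangeabilities(aln, spec, FitOptions(max_outer_rounds=3))
        improvement = fit.loglik_trace[-1] - fit.loglik_trace[0]
        # starting at the generating matrix, the gain to the MLE is the
        # Wilks-scale k/2 ~ 95, far below a misspecified start
        assert improvement < 150
        # sampling noise of the MLE at n=1200; far below the 0.5 separation
        # of genuinely different matrices on this scale
        assert sad(fit.S_hat, poisson_matrix()) < 0.3

    def test_constrained_entry_is_exactly_one(self):
        aln, spec = self._sim(lg_matrix())
        fit = fit_exchangeabilities(aln, spec, FitOptions(max_outer_rounds=2,
                                                          max_inner_iter=40))
        assert fit.S_hat.entries[18, 19] == 1.0

    def test_recovery_beats_starting_point(self):
        aln, spec = self._sim(lg_matrix(), n_sites=2000)
        fit = fit_exchangeabilities(aln, spec, FitOptions(max_outer_rounds=3))
        assert sad(fit.S_hat, lg_matrix()) < sad(poisson_matrix(), lg_matrix())
        assert np.all(np.diff(fit.loglik_trace) > -1e-6)


class TestFitWeights:
    def test_single_class_returns_one(self, rng):
        tree = random_tree(4, seed=9)
        mix = ProfileMixture.single(Profile.uniform())
        spec = MixtureModelSpec(poisson_matrix(), mix,
                                DiscreteRates.homogeneous(), tree)
        sim = simulate_alignment(SimulationSpec(tree, poisson_matrix(), mix,
                                                spec.rates, 50, seed=1))
        assert fit_weights(sim.alignment, spec).tolist() == [1.0]

    def test_duplicate_profiles_flagged_but_valid(self):
        tree = random_tree(4, seed=10)
        p = Profile.uniform()
        mix = ProfileMixture((p, p), np.array([0.5, 0.5]), "estimated")
        spec = MixtureModelSpec(poisson_matrix(), mix,
                                DiscreteRates.homogeneous(), tree)
        sim = simulate_alignment(SimulationSpec(tree, poisson_matrix(), mix,
                                                spec.rates, 100, seed=2))
        w = fit_weights(sim.alignment, spec)
        assert abs(w.sum() - 1.0) < 1e-10 and np.all(w > 0)

    def test_recovers_generating_weights(self):
        # the four-class weight setting used throughout the simulation studies
        true_w = np.array([0.35, 0.15, 0.25, 0.25])
        tree = random_tree(8, seed=21, mean_length=0.15)
        mix = ProfileMixture(biochemical_profiles(), true_w, "estimated")
        rates = DiscreteRates.homogeneous()
        sim = simulate_alignment(SimulationSpec(tree, poisson_matrix(), mix,
                                                rates, 6000, seed=3))
        start = mix.with_weights(np.full(4, 0.25))
        spec = MixtureModelSpec(poisson_matrix(), start, rates, tree)
        w = fit_weights(sim.alignment, spec)
        assert np.max(np.abs(w - true_w)) < 0.05


class TestFitAlpha:
    def test_single_category_not_identifiable(self):
        tree = random_tree(4, seed=12)
        mix = ProfileMixture.single(Profile.uniform())
        spec = MixtureModelSpec(poisson_matrix(), mix,
                                DiscreteRates.homogeneous(), tree)
        sim = simulate_alignment(SimulationSpec(tree, poisson_matrix(), mix,
                                                spec.rates, 50, seed=4))
        with pytest.raises(ValueError, match="not identifiable"):
            fit_alpha(sim.alignment, spec)

    def test_recovers_generating_shape(self):
        tree = random_tree(10, seed=23, mean_length=0.15)
        mix = ProfileMixture(biochemical_profiles(),
                             np.array([0.35, 0.15, 0.25, 0.25]))
        rates = discretize_gamma(0.67, 4)
        sim = simulate_alignment(SimulationSpec(tree, lg_matrix(), mix, rates,
                                                6000, seed=5))
        spec = MixtureModelSpec(lg_matrix(), mix, discretize_gamma(1.0, 4), tree)
        alpha = fit_alpha(sim.alignment, spec)
        assert abs(alpha - 0.67) < 0.1

    def test_homogeneous_data_hits_upper_bound(self):
        tree = random_tree(6, seed=24, mean_length=0.2)
        mix = ProfileMixture.single(Profile.uniform())
        rates = DiscreteRates.homogeneous()
        sim = simulate_alignment(SimulationSpec(tree, poisson_matrix(), mix,
                                                rates, 2000, seed=6))
        spec = MixtureModelSpec(poisson_matrix(), mix,
                                discretize_gamma(1.0, 4), tree)
        from gtrlink.optimize import _Fitter, ALPHA_BOUNDS
        options = FitOptions(estimate_alpha=True,
                             estimate_exchangeabilities=False,
                             estimate_weights=False,
                             estimate_branch_lengths=False, init_S="spec")
        fitter = _Fitter(sim.alignment, spec, options)
        fitter.record(fitter.loglik())
        fitter.update_alpha()
        assert fitter.alpha > 0.5 * ALPHA_BOUNDS[1] or \
            any("upper bound" in f for f in fitter.flags)


class TestFitBranchLengths:
    def test_two_taxon_distance_matches_closed_form(self):
        # 20-state equal-rates model: the ML distance has a closed form in
        # the observed proportion of differing sites
        true_t = 0.4
        tree = parse_newick(f"(A:{true_t / 2},B:{true_t / 2});")
        mix = ProfileMixture.single(Profile.uniform())
        rates = DiscreteRates.homogeneous()
        sim = simulate_alignment(SimulationSpec(tree, poisson_matrix(), mix,
                                                rates, 5000, seed=7))
        spec = MixtureModelSpec(poisson_matrix(), mix, rates, tree)
        fitted = fit_branch_lengths(sim.alignment, spec,
                                    FitOptions(gradient_tol=1e-7,
                                               outer_tol=1e-8))
        rows = sim.alignment.rows
        p_diff = np.mean([a != b for a, b in zip(rows[0], rows[1])])
        expected = jc20_distance(p_diff)
        assert fitted.branch_lengths().sum() == pytest.approx(expected,
                                                              abs=1e-4)

    def test_identical_sequences_collapse_to_clamp(self):
        tree = parse_newick("(A:0.1,B:0.1);")
        mix = ProfileMixture.single(Profile.uniform())
        rates = DiscreteRates.homogeneous()
        aln = Alignment(["A", "B"], ["ARNDARND" * 10] * 2)
        spec = MixtureModelSpec(poisson_matrix(), mix, rates, tree)
        fitted = fit_branch_lengths(aln, spec)
        # log-scale optimization approaches the clamp asymptotically
        assert np.all(fitted.branch_lengths() <= 1e-4)

    def test_recovers_simulated_lengths(self):
        tree = random_tree(8, seed=31, mean_length=0.15)
        mix = ProfileMixture(biochemical_profiles(),
                             np.array([0.35, 0.15, 0.25, 0.25]))
        rates = discretize_gamma(0.67, 4)
        sim = simulate_alignment(SimulationSpec(tree, lg_matrix(), mix, rates,
                                                5000, seed=8))
        spec = MixtureModelSpec(lg_matrix(), mix, rates, tree)
        fitted = fit_branch_lengths(sim.alignment, spec)
        err = fitted.branch_lengths() - tree.branch_lengths()
        assert np.median(np.abs(err)) < 0.02
        assert abs(np.mean(err)) < 0.02


class TestFitJoint:
    def test_weights_only_schedule_matches_fit_weights(self):
        tree = random_tree(5, seed=15)
        mix = ProfileMixture(biochemical_profiles(),
                             np.full(4, 0.25), "estimated")
        rates = DiscreteRates.homogeneous()
        sim = simulate_alignment(SimulationSpec(tree, poisson_matrix(), mix,
                                                rates, 400, seed=11))
        spec = MixtureModelSpec(poisson_matrix(), mix, rates, tree)
        options = FitOptions(estimate_exchangeabilities=False,
                             estimate_alpha=False,
                             estimate_branch_lengths=False,
                             estimate_weights=True, init_S="spec")
        joint = fit_joint(sim.alignment, spec, options)
        direct = fit_weights(sim.alignment, spec)
        np.testing.assert_allclose(joint.weights_hat, direct, atol=1e-6)

    def test_joint_dominates_single_block(self):
        tree = random_tree(6, seed=16, mean_length=0.2)
        mix = ProfileMixture(biochemical_profiles(),
                             np.array([0.35, 0.15, 0.25, 0.25]))
        rates = discretize_gamma(0.67, 4)
        sim = simulate_alignment(SimulationSpec(tree, lg_matrix(), mix, rates,
                                                800, seed=12))
        spec = MixtureModelSpec(lg_matrix(), mix, rates, tree)
        small = FitOptions(max_outer_rounds=2, max_inner_iter=60)
        joint = fit_joint(sim.alignment, spec, small)
        single = fit_exchangeabilities(sim.alignment, spec, small)
        assert joint.loglik >= single.loglik - 1e-6
        assert np.all(np.diff(joint.loglik_trace) > -1e-6)

    def test_frozen_nuisance_mode_agrees_with_full_fit(self):
        # two-stage protocol: freeze branch lengths and alpha at the truth,
        # estimate exchangeabilities + weights only; estimates should agree
        # closely with the all-parameters fit
        tree = random_tree(10, seed=17, mean_length=0.2)
        mix = ProfileMixture(biochemical_profiles(),
                             np.array([0.35, 0.15, 0.25, 0.25]))
        rates = discretize_gamma(0.67, 4)
        sim = simulate_alignment(SimulationSpec(tree, lg_matrix(), mix, rates,
                                                3000, seed=13))
        spec = MixtureModelSpec(lg_matrix(), mix, rates, tree)
        frozen = fit_joint(sim.alignment, spec,
                           FitOptions(estimate_alpha=False,
                                      estimate_branch_lengths=False,
                                      max_outer_rounds=2, max_inner_iter=150))
        full = fit_joint(sim.alignment, spec,
                         FitOptions(max_outer_rounds=2, max_inner_iter=150))
        assert sad(frozen.S_hat, full.S_hat) < 0.1

    def test_start_point_robustness(self):
        tree = random_tree(6, seed=18, mean_length=0.2)
        mix = ProfileMixture(biochemical_profiles(),
                             np.array([0.35, 0.15, 0.25, 0.25]))
        rates = DiscreteRates.homogeneous()
        sim = simulate_alignment(SimulationSpec(tree, lg_matrix(), mix, rates,
                                                1000, seed=14))
        spec = MixtureModelSpec(lg_matrix(), mix, rates, tree)
        opts = dict(estimate_alpha=False, estimate_weights=False,
                    estimate_branch_lengths=False, max_outer_rounds=4,
                    gradient_tol=1e-3)
        from_poisson = fit_joint(sim.alignment, spec,
                                 FitOptions(init_S="poisson", **opts))
        from_lg = fit_joint(sim.alignment, spec,
                            FitOptions(init_S="lg", **opts))
        assert abs(from_poisson.loglik - from_lg.loglik) < 0.5

    def test_all_blocks_disabled_rejected(self):
        with pytest.raises(ValueError):
            FitOptions(estimate_exchangeabilities=False,
                       estimate_weights=False, estimate_alpha=False,
                       estimate_branch_lengths=False)
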