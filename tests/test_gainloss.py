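"""Two-state gain/loss model: oracles and posterior event expectations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from defenseflux.gainloss import (
    GainLossModel,
    TwoStateGainLoss,
    _uniformization_tables,
    branch_expected_events,
    discrete_gamma_rates,
    family_loglik,
    fit_gainloss,
    pattern_logliks,
    transition_probability,
)
from defenseflux.simulate import SimulationConfig, simulate_mge_history, simulate_tree
from defenseflux.tree import read_newick


class TestTransitionProbability:
    def test_zero_time_is_identity(self):
        assert np.allclose(transition_probability(2.0, 3.0, 0.0), np.eye(2))

    def test_long_time_reaches_stationarity(self):
        P = transition_probability(1.0, 1.0, 50.0)
        assert np.allclose(P, 0.25 + np.zeros((2, 2)) + 0.25)

    @pytest.mark.parametrize("g,l,t", [(2.0, 1.0, 0.7), (0.3, 5.0, 2.0),
                                       (10.0, 10.0, 0.05)])
    def test_matches_matrix_exponential_oracle(self, g, l, t):
        Q = np.array([[-g, g], [l, -l]])
        assert np.abs(transition_probability(g, l, t) - expm(Q * t)).max() < 1e-10

    def test_rows_sum_to_one(self):
        P = transition_probability(0.2, 7.0, 1.3)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(1.0, 1.0, -0.1)


class TestGammaCategories:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 5.0])
    def test_mean_one_and_ordered(self, alpha):
        r = discrete_gamma_rates(alpha, 4)
        assert r.mean() == pytest.approx(1.0)
        assert (np.diff(r) > 0).all()


def _enumerate_loglik(tree, states, model):
    """Brute-force likelihood: sum over all internal-state assignments,
    averaged over rate categories."""
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    leaves = {int(v): s for v, s in zip(tree.leaf_indices, states)}
    pi = model.root_prior
    total = 0.0
    for rate in model.category_rates:
        for assign in itertools.product((0, 1), repeat=len(internal)):
            state = dict(zip(internal, assign))
            state.update(leaves)
            lik = pi[state[0]]
            for v in range(1, tree.n_nodes):
                P = transition_probability(
                    model.gain_rate * rate, model.loss_rate * rate,
                    tree.lengths[v])
                lik *= P[state[tree.parent[v]], state[v]]
            total += lik
    return np.log(total / len(model.category_rates))


class TestFamilyLoglik:
    def test_single_leaf_is_root_prior(self):
        tree = read_newick("(A:1);")  # root with one child
        model = GainLossModel(2.0, 1.0, 1.0, 1)
        # state 1 at the only leaf: P = pi0*P01 + pi1*P11 marginalised at root
        ll = family_loglik(tree, {"A": 1}, model)
        pi = model.root_prior
        P = transition_probability(2.0, 1.0, 1.0)
        assert ll == pytest.approx(np.log(pi[0] * P[0, 1] + pi[1] * P[1, 1]))

    def test_missing_leaf_state_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            family_loglik(tree, {"A": 1, "B": 0}, GainLossModel(1.0, 1.0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        newick=st.sampled_from([
            "((A:0.3,B:0.5):0.2,C:0.9);",
            "(A:0.2,B:0.4,C:0.6,D:0.8);",
            "(((A:0.1,B:0.2):0.3,C:0.4):0.2,(D:0.5,E:0.6):0.1);",
            "((A:0.7,B:0.1):0.4,(C:0.2,D:0.3):0.6);",
        ]),
        g=st.floats(0.05, 8.0),
        l=st.floats(0.05, 8.0),
        alpha=st.floats(0.2, 5.0),
        K=st.sampled_from([1, 2, 4]),
        pattern_bits=st.integers(0, 31),
    )
    def test_pruning_equals_enumeration(self, newick, g, l, alpha, K,
                                        pattern_bits):
        tree = read_newick(newick)
        model = GainLossModel(g, l, alpha, K)
        states = [(pattern_bits >> i) & 1 for i in range(tree.n_leaves)]
        pattern = dict(zip(tree.leaf_labels, states))
        assert family_loglik(tree, pattern, model) == pytest.approx(
            _enumerate_loglik(tree, np.array(states), model), abs=1e-9)

    def test_pattern_likelihoods_normalise(self):
        tree = read_newick("((A:0.3,B:0.5):0.2,(C:0.9,D:0.1):0.4);")
        model = GainLossModel(1.3, 0.8, 0.7, 4)
        pats = np.array(list(itertools.product((0, 1), repeat=4)),
                        dtype=np.int8).T.reshape(4, 16)
        total = np.exp(pattern_logliks(tree, pats, model)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)


class TestUniformization:
    @pytest.mark.parametrize("g,l,t", [(2.0, 1.0, 0.7), (0.5, 0.5, 2.0),
                                       (4.0, 0.3, 0.2)])
    def test_conditional_counts_match_simulation_oracle(self, g, l, t, rng):
        # fine-discretization simulation conditioned on endpoints
        E01, E10, _, _ = _uniformization_tables(g, l, t)
        n, steps = 120_000, 1500
        dt = t / steps
        for start in (0, 1):
            s = np.full(n, start)
            n01 = np.zeros(n)
            n10 = np.zeros(n)
            for _ in range(steps):
                u = rng.random(n)
                f0 = (s == 0) & (u < g * dt)
                f1 = (s == 1) & (u < l * dt)
                n01 += f0
                n10 += f1
                s = np.where(f0, 1, np.where(f1, 0, s))
            for end in (0, 1):
                m = s == end
                assert n01[m].mean() == pytest.approx(E01[start, end], abs=0.02)
                assert n10[m].mean() == pytest.approx(E10[start, end], abs=0.02)

    def test_forced_transition_counts_at_least_one(self):
        E01, _, G1, _ = _uniformization_tables(1.0, 2.0, 0.4)
        assert E01[0, 1] >= 1.0
        assert G1[0, 1] == pytest.approx(1.0)

    def test_unconditional_average_recovers_prior_flux(self):
        # sum_y P[x,y] E[N01|x,y] from state 0 ~ integral of g*P00(s) ds
        g, l, t = 1.5, 0.7, 0.9
        P = transition_probability(g, l, t)
        E01, _, _, _ = _uniformization_tables(g, l, t)
        lam = g + l
        flux = g * (l / lam * t + g / lam * (1 - np.exp(-lam * t)) / lam)
        assert P[0] @ E01[0] == pytest.approx(flux, abs=1e-8)


class TestFitAndEvents:
    def test_all_constant_matrix_is_no_signal_error(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        X = np.zeros((3, 5), dtype=int)
        with pytest.raises(ValueError, match="no signal"):
            TwoStateGainLoss().fit(X, tree=tree)

    def test_parameter_recovery(self):
        # data simulated at known rates; fitted rates within 20% of truth
        # in most replicates
        hits = 0
        reps = 8
        for seed in range(reps):
            cfg = SimulationConfig(
                n_genomes=100, n_mge_families=400, mge_gain_rate=100.0,
                mge_loss_rate=200.0, clonal_fraction=0.0,
                rate_lognormal_sigma=0.0, tree_height_target=0.02, seed=seed)
            tree = simulate_tree(cfg, seed=seed)
            _, states = simulate_mge_history(tree, cfg, seed=100 + seed)
            est = TwoStateGainLoss(n_categories=1).fit(states, tree=tree)
            if (abs(est.gain_rate_ / 100.0 - 1) < 0.2
                    and abs(est.loss_rate_ / 200.0 - 1) < 0.2):
                hits += 1
        assert hits >= 0.7 * reps

    def test_rate_time_rescaling_identifiability(self):
        cfg = SimulationConfig(n_genomes=60, n_mge_families=150,
                               clonal_fraction=0.0, seed=3)
        tree = simulate_tree(cfg, seed=3)
        _, states = simulate_mge_history(tree, cfg, seed=4)
        est1 = TwoStateGainLoss(n_categories=1).fit(states, tree=tree)
        tree2 = read_newick(tree.newick_string())
        tree2.lengths = tree2.lengths * 2.0
        est2 = TwoStateGainLoss(n_categories=1).fit(states, tree=tree2)
        assert est2.gain_rate_ == pytest.approx(est1.gain_rate_ / 2, rel=0.02)
        assert est2.loss_rate_ == pytest.approx(est1.loss_rate_ / 2, rel=0.02)

    def test_expected_losses_vanish_without_loss_mechanism(self):
        tree = read_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")
        model = GainLossModel(1.0, 1e-6, 1.0, 1)
        states = np.ones((4, 1), dtype=np.int8)
        ev = branch_expected_events(tree, states, model)
        assert ev.expected_losses.max() < 1e-4

    def test_flux_balance_on_small_tree(self):
        # sum over branches of (E[gains] - E[losses]) equals the posterior
        # expected net state change from root to leaves... checked against
        # enumeration of endpoint posteriors
        tree = read_newick("((A:0.4,B:0.6):0.3,C:0.8);")
        model = GainLossModel(1.2, 0.9, 1.0, 1)
        states = np.array([[1], [0], [1]], dtype=np.int8)
        ev = branch_expected_events(tree, states, model)
        net = ev.expected_gains.sum() - ev.expected_losses.sum()
        # oracle: E[sum_leaves X_leaf - n_paths * X_root] via enumeration is
        # awkward; instead check per-branch: E[gains-losses] = P(end=1)-P(start=1)
        # summed telescopically along each root-to-leaf path.
        # Here: verify additivity against a direct per-branch computation.
        from defenseflux.gainloss import _up_pass
        from scipy.special import logsumexp
        up, _, P, llk = _up_pass(tree, states, 1.2, 0.9, np.ones(1))
        # posterior state probabilities per node by enumeration
        internal = [v for v in range(tree.n_nodes) if tree.children[v]]
        pi = model.root_prior
        post = np.zeros((tree.n_nodes, 2))
        total = 0.0
        leaves = {int(v): int(s) for v, s in zip(tree.leaf_indices, states[:, 0])}
        for assign in itertools.product((0, 1), repeat=len(internal)):
            state = dict(zip(internal, assign))
            state.update(leaves)
            lik = pi[state[0]]
            for v in range(1, tree.n_nodes):
                Pv = transition_probability(1.2, 0.9, tree.lengths[v])
                lik *= Pv[state[tree.parent[v]], state[v]]
            total += lik
            for v in range(tree.n_nodes):
                post[v, state[v]] += lik
        post /= total
        expected_net = 0.0
        for i, v in enumerate(range(1, tree.n_nodes)):
            expected_net += post[v, 1] - post[tree.parent[v], 1]
        assert net == pytest.approx(expected_net, abs=1e-8)

    def test_event_expectations_additive_over_families(self, small_dataset):
        ds = small_dataset
        model = GainLossModel(50.0, 100.0, 1.0, 2)
        ev = branch_expected_events(ds.tree, ds.matrix.df, model)
        n = len(ev.family_ids)
        mask1 = np.arange(n) < n // 2
        agg_all = ev.aggregate()
        agg1 = ev.aggregate(mask1)
        agg2 = ev.aggregate(~mask1)
        assert np.allclose(agg_all["expected_gains"],
                           agg1["expected_gains"] + agg2["expected_gains"])
        assert (ev.expected_gains >= 0).all()
        assert (ev.expected_losses >= 0).all()

    def test_total_inferred_gains_track_truth(self):
        # on data simulated from the model itself, total inferred expected
        # gains are within 10% of the true simulated count (averaged seeds)
        ratios = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(
                n_genomes=80, n_mge_families=500, mge_gain_rate=10.0,
                mge_loss_rate=20.0, clonal_fraction=0.0,
                rate_lognormal_sigma=0.5, tree_height_target=0.02, seed=seed)
            tree = simulate_tree(cfg, seed=seed)
            hist, states = simulate_mge_history(tree, cfg, seed=100 + seed)
            est = TwoStateGainLoss(n_categories=4).fit(states, tree=tree)
            ev = est.expected_events(states, tree=tree)
            ratios.append(ev.expected_gains.sum()
                          / (hist.events["event"] == "gain").sum())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_functional_wrapper(self, small_dataset):
        model = fit_gainloss(small_dataset.tree, small_dataset.matrix, K=2)
        assert model.gain_rate > 0 and model.loss_rate > 0
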