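"""Sampler mechanics: moves, prior sampling, ESS, log combining."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shapedyn.calib import DatedSample
from shapedyn.fbd import FBDParams, _PQ
from shapedyn.mcmc import (MCMCConfig, PosteriorTrace, _FastPriors, _MOVES,
                           _State, combine_logs, convergence_report, ess,
                           run_mcmc, shift_for_inference)
from shapedyn.simulate import SimScenario, make_study_scenario, \
    simulate_fbd_tree
from shapedyn.tree import Node, SATree


@pytest.fixture(scope="module")
def study16():
    return make_study_scenario(16, seed=3)


def small_run(result, seed=1, gens=4000, **kw):
    shifted, bounds, _ = shift_for_inference(result.samples)
    cfg = MCMCConfig(n_generations=gens, sample_every=20, seed=seed, **kw)
    return run_mcmc(result.traits, shifted, cfg, boundaries=bounds)


class TestRunMCMC:
    def test_trace_invariants(self, study16):
        trace = small_run(study16)
        df = trace.df
        assert np.allclose(df["posterior"],
                           df["likelihood"] + df["prior"], atol=1e-8)
        assert np.all(np.diff(df["generation"]) == 20)

    def test_reproducible_given_seed(self, study16):
        a = small_run(study16, seed=9, gens=2000)
        b = small_run(study16, seed=9, gens=2000)
        pd.testing.assert_frame_equal(a.df, b.df)
        assert [t.to_newick() for _, t in a.trees] == \
            [t.to_newick() for _, t in b.trees]

    def test_under_prior_zero_likelihood(self, study16):
        trace = small_run(study16, under_prior=True, gens=2000)
        assert (trace.df["likelihood"] == 0.0).all()

    def test_sampled_trees_stay_valid(self, study16):
        trace = small_run(study16, gens=3000)
        for _, tree in trace.trees[::7]:
            tree.validate()

    def test_tip_ages_respect_bounds(self, study16):
        shifted, bounds, _ = shift_for_inference(study16.samples)
        trace = small_run(study16, gens=3000)
        lims = {s.taxon_id: (s.age_min, s.age_max) for s in shifted}
        for s in shifted:
            col = trace.df[f"age_{s.taxon_id}"]
            lo, hi = lims[s.taxon_id]
            assert (col >= lo - 1e-12).all() and (col <= hi + 1e-12).all()

    @pytest.mark.parametrize("clock", ["ncat2", "strict"])
    def test_alternative_clock_models(self, study16, clock):
        trace = small_run(study16, gens=2000, clock_model=clock)
        df = trace.df
        assert np.allclose(df["posterior"],
                           df["likelihood"] + df["prior"], atol=1e-8)
        if clock == "ncat2":
            assert {"clock_rate1", "clock_rate2"} <= set(df.columns)
            assert (df[["clock_rate1", "clock_rate2"]] > 0).all().all()
        else:
            assert "clock_sd" not in df.columns

    def test_needs_two_samples(self, study16):
        with pytest.raises(ValueError):
            run_mcmc(study16.traits, study16.samples[:1], MCMCConfig())

    def test_missing_trait_rows_rejected(self, study16):
        bad = study16.traits.subset(study16.traits.taxa[:10])
        with pytest.raises(ValueError, match="without trait rows"):
            run_mcmc(bad, study16.samples, MCMCConfig())


@pytest.fixture(scope="module")
def prior_trace():
    res = make_study_scenario(16, seed=3)
    shifted, bounds, _ = shift_for_inference(res.samples)
    weights = {k: 0.0 for k in
               ["scale_sigma2", "slide_corr", "slide_root_value",
                "scale_clock_mean", "scale_clock_sd",
                "scale_branch_rate", "swap_rate_variance"]}
    weights |= {"scale_birth": 1.0, "scale_death": 1.0,
                "scale_sampling": 1.0}
    cfg = MCMCConfig(n_generations=300_000, sample_every=150, seed=11,
                     sample_priors_only=True, under_prior=True,
                     move_weights=weights)
    return run_mcmc(res.traits, shifted, cfg, boundaries=())


class TestPriorSampling:
    """With the likelihood and tree density disabled, the chain must
    reproduce the analytic priors (validates the MH kernel)."""

    @pytest.mark.parametrize("col", ["lambda_0", "mu_0", "psi_0"])
    def test_rate_marginals_match_exp10(self, prior_trace, col):
        x = prior_trace.burned()[col].to_numpy()
        ks = stats.kstest(x, stats.expon(scale=0.1).cdf)
        assert ks.pvalue > 0.01


class TestMoveMechanics:
    def make_state(self, **cfg_kw):
        root = Node(2.0)
        root.add_child(Node(0.9, "a"))
        root.add_child(Node(0.4, "b"))
        tree = SATree(root, 3.0)
        cfg = MCMCConfig(clock_model="strict", **cfg_kw)
        from shapedyn.bm import ClockState
        state = _State(tree, FBDParams([0.2], [0.1], [0.3]), None,
                       ClockState("strict", mean=0.1), None,
                       {"a": (0.9, 0.9), "b": (0.4, 0.4)},
                       _FastPriors(), cfg)
        state.refresh()
        return state

    def test_scale_move_hastings_is_log_factor(self):
        state = self.make_state()
        rng = np.random.default_rng(0)
        old = state.fbd.lam[0]
        hr, changed, undo = _MOVES["scale_birth"](state, rng)
        c = state.fbd.lam[0] / old
        assert hr == pytest.approx(math.log(c))
        assert set(changed) == {"P", "F"}
        undo()
        assert state.fbd.lam[0] == old

    def test_node_slide_symmetric_within_window(self):
        state = self.make_state()
        rng = np.random.default_rng(1)
        hr, _, undo = _MOVES["slide_node_age"](state, rng)
        assert hr == 0.0
        assert 0.9 <= state.tree.root.age <= 3.0
        undo()

    def test_tree_height_scale_hastings(self):
        state = self.make_state()
        rng = np.random.default_rng(3)
        old_root = state.tree.root.age
        res = _MOVES["scale_tree_heights"](state, rng)
        assert res is not None
        hr, _, undo = res
        c = state.tree.root.age / old_root
        assert hr == pytest.approx(2 * math.log(c))  # root + origin scaled
        undo()
        assert state.tree.root.age == old_root

    def test_sa_toggle_round_trip_restores_shape(self):
        state = self.make_state()
        rng = np.random.default_rng(12)
        # collapse the older tip onto its sibling's lineage, then expand
        for _ in range(200):
            res = _MOVES["sa_toggle"](state, rng)
            if res is None:
                continue
            _, _, undo = res
            undo()
            state.tree.validate()
        assert state.tree.n_samples() == 2


class TestESS:
    def test_iid_normal_near_n(self, rng):
        x = rng.normal(0, 1, 10_000)
        assert abs(ess(x) - 10_000) < 1_500

    def test_ar1_matches_closed_form(self, rng):
        n, rho = 40_000, 0.9
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(0, 1, n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert abs(ess(x) - expected) / expected < 0.35

    def test_never_exceeds_length_for_constant(self):
        assert ess(np.ones(500)) == 500.0

    def test_too_short_fails(self):
        with pytest.raises(ValueError):
            ess(np.arange(5))


class TestCombineAndReport:
    def make_trace(self, n, seed=0, offset=0.0):
        rng = np.random.default_rng(seed)
        like = rng.normal(offset, 1.0, n)
        prior = rng.normal(0.0, 1.0, n)
        df = pd.DataFrame({
            "generation": np.arange(n) * 10,
            "likelihood": like, "prior": prior,
            "posterior": like + prior,
        })
        return PosteriorTrace(df, trees=[("x", None)] * n)

    def test_two_chains_twenty_percent_burnin(self):
        combined = combine_logs([self.make_trace(1000, 1),
                                 self.make_trace(1000, 2)], 0.20)
        assert len(combined) == 1600
        assert len(combined.trees) == 1600

    def test_single_chain_truncation(self):
        combined = combine_logs([self.make_trace(500, 3)], 0.20)
        assert len(combined) == 400

    def test_combined_mean_is_weighted_mean(self):
        a, b = self.make_trace(800, 4), self.make_trace(400, 5, offset=2.0)
        combined = combine_logs([a, b], 0.25)
        oracle = np.concatenate([a.df["likelihood"][200:],
                                 b.df["likelihood"][100:]]).mean()
        assert combined.df["likelihood"].mean() == pytest.approx(oracle)

    def test_schema_mismatch_fails(self):
        a = self.make_trace(100, 6)
        b = self.make_trace(100, 7)
        b.df["extra"] = 1.0
        with pytest.raises(ValueError):
            combine_logs([a, b])

    def test_report_white_noise_passes(self):
        report = convergence_report(self.make_trace(5000, 8), threshold=200)
        assert report.attrs["pass"]

    def test_short_chain_fails_threshold(self):
        report = convergence_report(self.make_trace(50, 9), threshold=200)
        assert not report.attrs["pass"]

    def test_posterior_identity_enforced(self):
        df = pd.DataFrame({"generation": [0], "posterior": [1.0],
                           "likelihood": [0.3], "prior": [0.3]})
        with pytest.raises(ValueError):
            PosteriorTrace(df, trees=[])


class TestShiftForInference:
    def test_shifts_relative_to_window_close(self):
        samples = [DatedSample("a", "l", 12.0, 11.8, 12.2),
                   DatedSample("b", "l", 14.0, 13.9, 14.1)]
        shifted, bounds, present = shift_for_inference(
            samples, boundaries=(14.6, 12.9, 11.7), present=11.0)
        assert present == 11.0
        assert shifted[0].median_age == pytest.approx(1.0)
        assert bounds == pytest.approx((3.6, 1.9, 0.7))

    def test_all_shifted_ages_positive(self):
        samples = [DatedSample("a", "l", 11.0, 10.9, 11.2),
                   DatedSample("b", "l", 14.0, 13.9, 14.1)]
        shifted, _, present = shift_for_inference(samples, present=11.0)
        assert present < 10.9
        assert all(s.age_min > 0 for s in shifted)
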