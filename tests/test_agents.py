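"""Tests for the multi-agent loop: LHS, perturbation, replacement, full runs."""
import numpy as np
import pytest

from strainrl._rng import substream
from strainrl.agents import (
    RunConfig,
    gram_schmidt,
    init_enzyme_levels,
    latin_hypercube,
    perturb_agents,
    replace_worst,
    run_marl,
    warmup,
)
from strainrl.environments import Environment, make_surface_env

from conftest import make_stub_env


def gram_det(vectors):
    g = np.array([[a @ b for b in vectors] for a in vectors])
    return np.linalg.det(g)


SMALL = dict(n_agents=4, n_groups=2, tau=2, n_iterations=6)


class TestLatinHypercube:
    @pytest.mark.parametrize("n", [4, 6, 20])
    @pytest.mark.parametrize("d", [1, 3, 13])
    def test_one_sample_per_equiprobable_stratum(self, n, d):
        bounds = [[0.1, 10.0]] * d
        x = latin_hypercube(n, bounds, substream(0, f"lhs-{n}-{d}"))
        assert x.shape == (n, d)
        for j in range(d):
            strata = np.floor((x[:, j] - 0.1) / (9.9 / n)).astype(int)
            strata = np.clip(strata, 0, n - 1)
            assert sorted(strata) == list(range(n))

    def test_single_sample_inside_bounds(self):
        x = latin_hypercube(1, [[-1.0, 1.0], [0.0, 5.0]], substream(1, "lhs"))
        assert -1 <= x[0, 0] <= 1 and 0 <= x[0, 1] <= 5

    def test_degenerate_bound_warns_and_is_constant(self):
        with pytest.warns(UserWarning):
            x = latin_hypercube(5, [[2.0, 2.0], [0.0, 1.0]], substream(2, "lhs"))
        np.testing.assert_array_equal(x[:, 0], 2.0)

    def test_deterministic_given_seed(self):
        a = latin_hypercube(8, [[0.0, 1.0]] * 3, substream(3, "lhs"))
        b = latin_hypercube(8, [[0.0, 1.0]] * 3, substream(3, "lhs"))
        np.testing.assert_array_equal(a, b)


class TestGramSchmidt:
    def test_normalizes_single_vector(self):
        out, flags = gram_schmidt([np.array([3.0, 0.0])], substream(0, "gs"))
        np.testing.assert_allclose(out[0], [1.0, 0.0])
        assert flags == [False]

    def test_orthogonal_pair_keeps_directions(self):
        out, _ = gram_schmidt([np.array([1.0, 0.0]), np.array([0.0, 2.0])], substream(1, "gs"))
        np.testing.assert_allclose(out[0], [1.0, 0.0])
        np.testing.assert_allclose(out[1], [0.0, 1.0])

    def test_hand_example(self):
        out, _ = gram_schmidt([np.array([1.0, 0.0]), np.array([1.0, 1.0])], substream(2, "gs"))
        np.testing.assert_allclose(out[0], [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(out[1], [0.0, 1.0], atol=1e-12)

    def test_dependent_input_substituted_with_orthogonal_unit(self):
        vs = [np.array([1.0, 0.0, 0.0]), np.array([2.0, 0.0, 0.0])]
        out, flags = gram_schmidt(vs, substream(3, "gs"))
        assert flags == [False, True]
        assert abs(out[0] @ out[1]) < 1e-10
        assert np.linalg.norm(out[1]) == pytest.approx(1.0)

    def test_more_vectors_than_dimensions_flagged(self):
        vs = [np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([1.0, 1.0])]
        out, flags = gram_schmidt(vs, substream(4, "gs"))
        assert flags[2] is True
        assert np.linalg.norm(out[2]) == pytest.approx(1.0)


class TestPerturbAgents:
    def test_single_action_unchanged(self):
        a = np.array([0.3, -0.4])
        out = perturb_agents([a], 0.8, substream(0, "p"))
        np.testing.assert_allclose(out[0], a, atol=1e-12)

    def test_orthogonal_actions_keep_directions(self):
        acts = [np.array([0.5, 0.0]), np.array([0.0, 0.2])]
        out = perturb_agents(acts, 0.8, substream(1, "p"))
        for a, b in zip(acts, out):
            cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_pair(self):
        sq = 1.0 / np.sqrt(2.0)
        acts = [np.array([1.0, 0.0]), np.array([sq, sq])]
        out = perturb_agents(acts, 0.8, substream(2, "p"))
        # independent evaluation of the three algorithm lines
        v2 = np.array([0.0, 1.0])
        t2 = 0.2 * acts[1] + 0.8 * v2
        expected2 = t2 / np.linalg.norm(t2)
        np.testing.assert_allclose(out[0], acts[0], atol=1e-12)
        np.testing.assert_allclose(out[1], expected2, atol=1e-12)
        assert gram_det(out) > gram_det(acts)

    def test_volume_growth_and_norm_preservation(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            sz = int(rng.integers(2, 7))
            d = int(rng.integers(2, 14))
            acts = [rng.standard_normal(d) for _ in range(sz)]
            c = float(rng.uniform(0.0, 1.0))
            out = perturb_agents(acts, c, rng)
            for a, b in zip(acts, out):
                assert abs(np.linalg.norm(b) - np.linalg.norm(a)) < 1e-9
            assert gram_det(out) >= gram_det(acts) - 1e-10

    def test_zero_action_replaced_by_small_random(self):
        out = perturb_agents([np.zeros(3), np.array([1.0, 0.0, 0.0])], 0.8, substream(3, "p"))
        assert np.linalg.norm(out[0]) == pytest.approx(1e-3, rel=1e-9)


class TestReplaceWorst:
    def test_lowest_median_agent_replaced(self):
        levels = [np.array([1.0]), np.array([2.0])]
        new, worst, donor = replace_worst(levels, [[5.0, 5.0], [1.0, 1.0]], substream(0, "r"))
        assert worst == 1 and donor == 0
        np.testing.assert_array_equal(new[1], levels[0])

    def test_tie_goes_to_lowest_index(self):
        levels = [np.array([1.0]), np.array([2.0])]
        _, worst, _ = replace_worst(levels, [[3.0], [3.0]], substream(1, "r"))
        assert worst == 0

    def test_four_agents_median_argmin(self):
        levels = [np.array([float(i)]) for i in range(4)]
        series = [[3.0, 3.0], [2.0, 2.0], [4.0, 4.0], [1.0, 1.0]]
        new, worst, donor = replace_worst(levels, series, substream(2, "r"))
        assert worst == 3
        assert donor in {0, 1, 2}
        np.testing.assert_array_equal(new[3], levels[donor])

    def test_needs_two_agents(self):
        with pytest.raises(ValueError):
            replace_worst([np.array([1.0])], [[1.0]], substream(3, "r"))


class TestWarmup:
    def test_row_counts_and_reward_bookkeeping(self, stub_env):
        cfg = RunConfig(n_agents=2, n_groups=1, tau=3)
        wd = warmup(stub_env, cfg, substream(0, "w"))
        assert wd.designs.shape == (2, 3, 3)
        assert wd.states.shape == (2, 3, 4)
        # constant environment: every reward (including the first, taken
        # against the identical baseline) is zero
        np.testing.assert_allclose(wd.rewards, 0.0, atol=1e-14)

    def test_deterministic_given_seed(self, stub_env):
        cfg = RunConfig(n_agents=2, tau=2)
        a = warmup(stub_env, cfg, substream(1, "w"))
        b = warmup(stub_env, cfg, substream(1, "w"))
        np.testing.assert_array_equal(a.designs, b.designs)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_first_action_measured_from_wild_type(self):
        env = make_surface_env(3, seed=0)
        cfg = RunConfig(n_agents=1, n_groups=1, tau=2)
        wd = warmup(env, cfg, substream(2, "w"))
        # wild type transforms to the zero vector, so action_1 = design_1
        np.testing.assert_allclose(wd.actions[0, 0], wd.designs[0, 0], atol=1e-12)
        np.testing.assert_allclose(
            wd.actions[0, 1], wd.designs[0, 1] - wd.designs[0, 0], atol=1e-12
        )

    def test_environment_failure_carries_context(self):
        def boom(d, p):
            raise RuntimeError("simulator crashed")

        env = Environment("bad", 2, 2, lambda d, p: (np.zeros(2), 1.0))
        env._step_fn = boom
        with pytest.raises(RuntimeError, match="warm-up"):
            warmup(env, RunConfig(n_agents=1, n_groups=1, tau=1), substream(3, "w"))


class TestInitEnzymeLevels:
    def test_single_top_design_selected(self, stub_env):
        cfg = RunConfig(n_agents=1, n_groups=1, tau=4, upper_quantile=0.75)
        wd = warmup(stub_env, cfg, substream(0, "i"))
        wd.responses[:] = [[1.0, 2.0, 3.0, 4.0]]
        levels = init_enzyme_levels(wd, cfg, stub_env, substream(1, "i"))
        np.testing.assert_array_equal(levels[0], wd.designs[0, 3])

    def test_median_of_top_two_matches_hand_computation(self, stub_env):
        cfg = RunConfig(n_agents=2, n_groups=1, tau=4, upper_quantile=0.75)
        wd = warmup(stub_env, cfg, substream(2, "i"))
        responses = np.array([[1.0, 8.0, 2.0, 3.0], [7.0, 4.0, 5.0, 6.0]])
        wd.responses[:] = responses
        levels = init_enzyme_levels(wd, cfg, stub_env, substream(3, "i"))
        designs = wd.designs.reshape(-1, 3)
        top2 = designs[np.argsort(responses.ravel())[::-1][:2]]
        np.testing.assert_allclose(levels[0], np.median(top2, axis=0))
        assert len(levels) == 2

    def test_identical_designs_returned_as_is(self, stub_env):
        cfg = RunConfig(n_agents=1, n_groups=1, tau=3)
        wd = warmup(stub_env, cfg, substream(4, "i"))
        wd.designs[:] = 0.25
        levels = init_enzyme_levels(wd, cfg, stub_env, substream(5, "i"))
        np.testing.assert_allclose(levels[0], 0.25)


class TestRunMarl:
    def test_zero_iterations_logs_warmup_only(self, stub_env):
        cfg = RunConfig(n_agents=2, n_groups=1, tau=3, n_iterations=0)
        res = run_marl(stub_env, cfg)
        assert len(res.log) == 2 * 3
        assert set(res.log["phase"]) == {"warmup"}

    def test_identical_seeds_give_identical_logs(self):
        env = make_surface_env(3, seed=1)
        cfg = RunConfig(seed=7, **SMALL)
        a = run_marl(env, cfg)
        b = run_marl(env, cfg)
        assert a.log.to_csv(index=False) == b.log.to_csv(index=False)

    def test_budget_accounting_exact(self):
        calls = {"n": 0}
        base = make_surface_env(3, seed=2)

        def counting_step(d, p):
            calls["n"] += 1
            return base.step(d, prev_design=p)

        counted = Environment("counted", 3, base.n_state, counting_step)
        calls["n"] = 0  # constructor consumed one baseline call
        cfg = RunConfig(seed=0, **SMALL)
        res = run_marl(counted, cfg)
        assert res.n_env_calls == 4 * (2 + 6)
        assert calls["n"] == res.n_env_calls

    def test_log_row_count_and_schema(self):
        env = make_surface_env(3, seed=3)
        cfg = RunConfig(seed=1, **SMALL)
        res = run_marl(env, cfg)
        assert len(res.log) == 4 * (2 + 6)
        for col in ("round", "agent", "group", "phase", "response", "reward",
                    "design_t_1", "design_raw_1", "state_1"):
            assert col in res.log.columns

    def test_executed_designs_stay_in_valid_enzyme_range(self):
        env = make_surface_env(3, seed=4)
        res = run_marl(env, RunConfig(seed=2, **SMALL))
        raw = res.log[[f"design_raw_{j}" for j in (1, 2, 3)]].to_numpy()
        assert np.all(raw >= 0.1 - 1e-12) and np.all(raw <= 10.0 + 1e-12)

    def test_best_found_series_non_decreasing(self):
        env = make_surface_env(3, seed=5)
        res = run_marl(env, RunConfig(seed=3, **SMALL))
        bf = res.best_found()
        for _, sub in bf.groupby("agent"):
            assert np.all(np.diff(sub["best"].to_numpy()) >= 0)

    def test_shared_warmup_is_reused_verbatim(self):
        env = make_surface_env(3, seed=6)
        cfg = RunConfig(seed=4, **SMALL)
        wd = warmup(env, cfg, substream(4, "warmup"))
        res = run_marl(env, cfg, warmup_data=wd)
        logged = res.log[res.log["phase"] == "warmup"]
        for i in range(cfg.n_agents):
            got = logged[logged["agent"] == i][["design_t_1", "design_t_2", "design_t_3"]]
            np.testing.assert_allclose(got.to_numpy(), wd.designs[i])

    def test_plateau_stop_shortens_run(self, stub_env):
        cfg = RunConfig(n_agents=2, n_groups=1, tau=2, n_iterations=30, plateau_patience=3)
        res = run_marl(stub_env, cfg)
        assert res.log["round"].max() < 32
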