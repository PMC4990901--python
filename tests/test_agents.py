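"""Agents: softmax policy, TD learning, budgeted planning, replay, arbitration."""

import numpy as np
import pytest

from gridsail.agents import (
    AgentConfig,
    ArbitratedAgent,
    CriticActorState,
    ExploratoryAgent,
    LearnedModel,
    ModelBasedAgent,
    MotorMemory,
    MotorMemoryAgent,
    memory_update,
    plan,
    softmax_select,
    td_update,
)
from gridsail.environment import (
    KEYS,
    GridSpec,
    Position,
    TimingModel,
    TrialContext,
    TrialResult,
    run_trial,
)
from gridsail.solver import shortest_path_length

from conftest import make_spec


def _freqs(prefs, beta, n=6000, seed=0):
    rng = np.random.default_rng(seed)
    counts = {k: 0 for k in KEYS}
    for _ in range(n):
        counts[softmax_select(prefs, beta, rng)] += 1
    return {k: c / n for k, c in counts.items()}


class TestSoftmaxSelect:
    def test_equal_preferences_are_uniform(self):
        f = _freqs([1.0, 1.0, 1.0], beta=2.0)
        assert all(abs(p - 1 / 3) < 0.03 for p in f.values())

    def test_beta_zero_ignores_preferences(self):
        f = _freqs([10.0, -5.0, 0.0], beta=0.0)
        assert all(abs(p - 1 / 3) < 0.03 for p in f.values())

    def test_large_beta_is_greedy(self):
        f = _freqs([1.0, 0.0, 0.0], beta=50.0)
        assert f["K1"] > 0.999

    def test_probabilities_sum_to_one_by_construction(self):
        # sampled frequencies over any preference vector form a distribution
        f = _freqs([0.3, -1.2, 2.0], beta=1.5)
        assert abs(sum(f.values()) - 1.0) < 1e-12


class TestTDUpdate:
    def test_zero_values_zero_reward_no_change(self):
        state = CriticActorState()
        s = ("km", "sg", Position(0, 0))
        s2 = ("km", "sg", Position(0, 1))
        delta = td_update(state, (s, "K1", s2, 0.0, False), AgentConfig())
        assert delta == 0.0 and state.V[s] == 0.0 and state.H[(s, "K1")] == 0.0

    def test_terminal_reward_moves_value_by_learning_rate(self):
        state = CriticActorState()
        s = ("km", "sg", Position(0, 0))
        cfg = AgentConfig(alpha_critic=0.5)
        td_update(state, (s, "K1", s, 1.0, True), cfg)
        assert state.V[s] == pytest.approx(0.5)

    def test_two_state_chain_converges_to_discounted_return(self):
        # deterministic chain s0 -> s1 -> terminal(r=1); closed form:
        # V(s1) = 1, V(s0) = gamma
        cfg = AgentConfig(alpha_critic=0.1, alpha_actor=0.1, gamma=0.8)
        state = CriticActorState()
        s0 = ("km", "sg", Position(0, 0))
        s1 = ("km", "sg", Position(0, 1))
        sT = ("km", "sg", Position(0, 2))
        for _ in range(10_000):
            td_update(state, (s0, "K1", s1, 0.0, False), cfg)
            td_update(state, (s1, "K1", sT, 1.0, True), cfg)
        assert state.V[s1] == pytest.approx(1.0, abs=1e-3)
        assert state.V[s0] == pytest.approx(cfg.gamma, abs=1e-3)


class TestPlan:
    def _complete_model(self, km):
        m = LearnedModel()
        m.known[km.id] = {k: km.direction(k) for k in KEYS}
        return m

    def test_complete_model_plans_are_solver_optimal(self, inventory):
        for km in inventory.kms:
            model = self._complete_model(km)
            for sg in inventory.sgs:
                seq = plan(model, km.id, sg.start, sg.goal, inventory.grid, 10**6)
                q = shortest_path_length(km, sg, inventory.grid)
                assert seq is not None and len(seq) == q.shortest_len

    def test_empty_model_plans_nothing(self, inventory):
        sg = inventory.sgs[0]
        assert plan(LearnedModel(), "KM1", sg.start, sg.goal, inventory.grid, 10**6) is None

    def test_zero_budget_plans_nothing(self, inventory):
        km, sg = inventory.kms[0], inventory.sgs[0]
        model = self._complete_model(km)
        assert plan(model, km.id, sg.start, sg.goal, inventory.grid, 0) is None


class TestModelBasedPolicy:
    def test_cached_plan_is_emitted_in_order(self, inventory, rng):
        km, sg = inventory.kms[0], inventory.sgs[0]
        agent = ModelBasedAgent()
        agent.model.known[km.id] = {k: km.direction(k) for k in KEYS}
        ctx = TrialContext(km=km, sg=sg, grid=inventory.grid,
                           spec=make_spec(start_mode="delayed", delay_s=5.0))
        agent.begin_trial(ctx)
        agent.on_delay(ctx, 5.0, rng)
        assert agent._plan is not None
        expected = list(agent._plan)
        emitted = []
        pos = sg.start
        for _ in expected:
            key = agent.choose(ctx, pos, rng)
            emitted.append(key)
            pos = pos.moved(km.direction(key))
        assert emitted == expected

    def test_partial_model_probes_unobserved_keys_in_key_order(self, inventory, rng):
        km, sg = inventory.kms[0], inventory.sgs[1]
        agent = ModelBasedAgent()
        agent.model.entries(km.id)["K1"] = km.direction("K1")
        ctx = TrialContext(km=km, sg=sg, grid=inventory.grid, spec=make_spec())
        agent.begin_trial(ctx)
        assert agent.choose(ctx, sg.start, rng) == "K2"  # first unobserved, tie-break

    def test_complete_model_ample_budget_scores_100_first_trial(self, inventory, rng):
        for km in inventory.kms:
            for sg in inventory.sgs:
                agent = ModelBasedAgent(AgentConfig(budget_immediate=10**6))
                agent.model.known[km.id] = {k: km.direction(k) for k in KEYS}
                res = run_trial(agent, make_spec(km=km.id, sg=sg.id), km, sg,
                                inventory.grid, TimingModel(), rng)
                assert res.reward == 100

    def test_delay_budget_arithmetic(self):
        cfg = AgentConfig(budget_immediate=25, budget_per_delay_second=50.0)
        agent = ModelBasedAgent(cfg)
        km_id, delay = "KM1", 5.0
        assert int(cfg.budget_immediate + cfg.budget_per_delay_second * delay) == 275

    def test_exploratory_agent_is_delay_invariant(self, inventory):
        km, sg = inventory.kms[0], inventory.sgs[0]

        def presses(start_mode, delay):
            agent = ExploratoryAgent()
            rng = np.random.default_rng(5)
            spec = make_spec(km=km.id, sg=sg.id, start_mode=start_mode, delay_s=delay)
            return run_trial(agent, spec, km, sg, inventory.grid, TimingModel(), rng).presses

        assert presses("immediate", 0.0) == presses("delayed", 5.0)


class TestMotorMemory:
    def _result(self, reward, presses=(("K1", True), ("K2", True))):
        return TrialResult(presses=tuple(presses), path=(), reached=reward > 0,
                           n_keystrokes=len(presses), oversteps=0, reward=reward,
                           rt_s=0.0, et_s=0.0, shortest_len=2)

    def test_first_success_is_stored(self):
        mem = MotorMemory()
        memory_update(mem, "km", "sg", self._result(90))
        assert mem.stored_reward("km", "sg") == 90

    def test_better_overwrites_worse_never_the_reverse(self):
        mem = MotorMemory()
        memory_update(mem, "km", "sg", self._result(90))
        memory_update(mem, "km", "sg", self._result(100, (("K3", True),) * 2))
        assert mem.stored_reward("km", "sg") == 100
        memory_update(mem, "km", "sg", self._result(85))
        assert mem.stored_reward("km", "sg") == 100
        assert mem.sequence("km", "sg") == ("K3", "K3")

    def test_only_valid_presses_are_stored(self):
        mem = MotorMemory()
        memory_update(mem, "km", "sg",
                      self._result(95, (("K1", True), ("K2", False), ("K3", True))))
        assert mem.sequence("km", "sg") == ("K1", "K3")

    def test_zero_lapse_replay_reproduces_stored_reward(self, inventory, rng):
        from gridsail.solver import enumerate_optimal_sequences

        km, sg = inventory.kms[0], inventory.sgs[0]
        seq = enumerate_optimal_sequences(km, sg, inventory.grid, max_count=1)[0]
        agent = MotorMemoryAgent(AgentConfig(epsilon_motor=0.0))
        agent.memory.store[(km.id, sg.id)] = (seq, 100)
        res = run_trial(agent, make_spec(km=km.id, sg=sg.id), km, sg,
                        inventory.grid, TimingModel(), rng)
        assert res.reward == 100 and res.n_keystrokes == len(seq)

    def test_full_lapse_is_uniform_random(self, inventory):
        km, sg = inventory.kms[0], inventory.sgs[0]
        agent = MotorMemoryAgent(AgentConfig(epsilon_motor=1.0))
        agent.memory.store[(km.id, sg.id)] = (("K1",) * 10, 100)
        ctx = TrialContext(km=km, sg=sg, grid=inventory.grid, spec=make_spec())
        rng = np.random.default_rng(3)
        agent.begin_trial(ctx)
        picks = [agent.choose(ctx, sg.start, rng) for _ in range(3000)]
        freqs = {k: picks.count(k) / len(picks) for k in KEYS}
        assert all(abs(f - 1 / 3) < 0.05 for f in freqs.values())


class TestArbitration:
    def _ctx(self, inventory, km, sg):
        return TrialContext(km=km, sg=sg, grid=inventory.grid,
                            spec=make_spec(km=km.id, sg=sg.id))

    def test_stored_success_hands_control_to_motor_memory(self, inventory):
        agent = ArbitratedAgent()
        km, sg = inventory.kms[0], inventory.sgs[0]
        agent.motor.memory.store[(km.id, sg.id)] = (("K1",), 100)
        assert agent.arbitrate(self._ctx(inventory, km, sg)) == "motor_memory"

    def test_known_model_without_memory_hands_to_model_based(self, inventory):
        agent = ArbitratedAgent()
        km, sg = inventory.kms[0], inventory.sgs[0]
        agent.model_based.model.entries(km.id)["K1"] = km.direction("K1")
        assert agent.arbitrate(self._ctx(inventory, km, sg)) == "model_based"

    def test_naive_agent_explores(self, inventory):
        agent = ArbitratedAgent()
        km, sg = inventory.kms[0], inventory.sgs[0]
        assert agent.arbitrate(self._ctx(inventory, km, sg)) == "exploratory"

    def test_below_threshold_memory_does_not_take_control(self, inventory):
        agent = ArbitratedAgent(AgentConfig(memory_threshold=80.0))
        km, sg = inventory.kms[0], inventory.sgs[0]
        agent.motor.memory.store[(km.id, sg.id)] = (("K1",), 75)
        agent.model_based.model.entries(km.id)["K1"] = km.direction("K1")
        assert agent.arbitrate(self._ctx(inventory, km, sg)) == "model_based"
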