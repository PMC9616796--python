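"""The three RL agent classes: TD updates, planning, ITM, influence zones."""
import numpy as np
import pytest
from scipy import stats as sps

from escapenav.agents import (DynaQAgent, IZAgent, IZParams, LearningParams,
                              QTableAgent, dyna_planning,
                              epsilon_greedy_action, greedy_action,
                              itm_update, iz_update, td_update)
from escapenav.arena import ACTIONS, Action, GridWorld
from escapenav.errors import ContractViolationError, ValidationError


class TestLearningParams:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": 0.0}, {"alpha": 1.5}, {"gamma": 1.0}, {"gamma": -0.1},
        {"epsilon": 1.2}, {"epsilon_decay": 0.0},
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            LearningParams(**kwargs)


class TestTDUpdate:
    def test_zero_td_error_leaves_q_unchanged(self, open_world):
        agent = QTableAgent(open_world)
        td_update(agent, (5, 5), Action.RIGHT, 0.0, (5, 6))
        assert not agent.Q.any()

    def test_single_update_forced_by_rule(self, open_world):
        agent = QTableAgent(open_world, LearningParams(alpha=0.1, gamma=0.9))
        td_update(agent, (5, 5), Action.RIGHT, 1.0, (5, 6))
        assert agent.q_value((5, 5), Action.RIGHT) == pytest.approx(0.1)
        # only (s, a) was modified
        assert np.count_nonzero(agent.Q) == 1

    def test_two_state_chain_converges_to_closed_form(self):
        """Repeated updates on a rewarded 2-cell loop converge to the
        fixed point r / (1 - gamma)."""
        occ = np.zeros((1, 2), dtype=bool)
        occ[0, :] = True
        world = GridWorld(occ, (0, 0), (0, 1))
        gamma = 0.9
        agent = QTableAgent(world, LearningParams(alpha=0.5, gamma=gamma))
        for _ in range(600):
            td_update(agent, (0, 0), Action.RIGHT, 1.0, (0, 1))
            td_update(agent, (0, 1), Action.LEFT, 1.0, (0, 0))
        expected = 1.0 / (1.0 - gamma)
        assert agent.q_value((0, 0), Action.RIGHT) == pytest.approx(
            expected, rel=1e-6)
        assert agent.q_value((0, 1), Action.LEFT) == pytest.approx(
            expected, rel=1e-6)

    def test_inaccessible_cell_rejected(self, corridor):
        agent = QTableAgent(corridor)
        with pytest.raises(ContractViolationError):
            td_update(agent, (0, 0), Action.RIGHT, 0.0, (0, 1))

    def test_q_values_respect_discount_bound(self, corridor):
        """After arbitrary training, |Q| <= (1 + 1e-8) / (1 - gamma)."""
        params = LearningParams(alpha=1.0, gamma=0.95)
        agent = QTableAgent(corridor, params)
        cw = agent.cw
        rng = np.random.default_rng(3)
        s = cw.flat(corridor.start_cell)
        for _ in range(5000):
            a = int(rng.integers(8))
            nxt = cw.next_flat[s, a]
            if nxt < 0:
                agent.learn(s, a, cw.params.illegal_penalty, s)
            else:
                agent.learn(s, a, cw.goal_reward_flat[nxt] + 1e-8, int(nxt))
                s = int(nxt)
        bound = (1.0 + 1e-8) / (1.0 - params.gamma)
        assert np.abs(agent.Q).max() <= bound + 1e-9


class TestDynaPlanning:
    def test_empty_model_is_noop(self, open_world):
        agent = DynaQAgent(open_world)
        dyna_planning(agent, np.random.default_rng(0))
        assert not agent.Q.any()

    def test_single_entry_sampled_planning_samples_times(self, open_world):
        agent = DynaQAgent(open_world, LearningParams(alpha=0.5, gamma=0.0))
        td_update(agent, (5, 5), Action.RIGHT, 1.0, (5, 6))
        q0 = agent.q_value((5, 5), Action.RIGHT)
        dyna_planning(agent, np.random.default_rng(0))
        # 20 further alpha-relaxations toward the target 1.0
        expected = 1.0 - (1.0 - q0) * 0.5 ** agent.planning_samples
        assert agent.q_value((5, 5), Action.RIGHT) == pytest.approx(expected)

    def test_fixed_seed_reproducible(self, open_world):
        qs = []
        for _ in range(2):
            agent = DynaQAgent(open_world)
            for i in range(6):
                td_update(agent, (5, i), Action.RIGHT, float(i == 5), (5, i + 1))
            dyna_planning(agent, np.random.default_rng(42))
            qs.append(agent.Q.copy())
        assert np.array_equal(qs[0], qs[1])

    def test_planning_on_experienced_corridor_reaches_goal(self, corridor):
        """After planning on a fully-experienced corridor the greedy policy
        is optimal and Q at the start matches value iteration."""
        from escapenav.arena import RewardParams
        gamma = 0.9
        rp = RewardParams(goal_radius_cells=1.0)   # reward on the goal cell only
        agent = DynaQAgent(corridor, LearningParams(alpha=0.5, gamma=gamma),
                           reward_params=rp)
        cw = agent.cw
        rng = np.random.default_rng(7)
        # experience every left/right transition once
        for c in range(7):
            s, s2 = cw.flat((1, c)), cw.flat((1, c + 1))
            agent.learn(s, ACTIONS.index(Action.RIGHT),
                        cw.goal_reward_flat[s2], s2)
            agent.learn(s2, ACTIONS.index(Action.LEFT),
                        cw.goal_reward_flat[s], s)
        for _ in range(400):
            agent.plan(rng)
        # value iteration over the same experienced two-action MDP
        q = np.zeros((8, 2))                       # columns: [right, left]
        rew = [cw.goal_reward_flat[cw.flat((1, c))] for c in range(8)]
        for _ in range(500):
            for c in range(7):
                q[c, 0] = rew[c + 1] + gamma * q[c + 1].max()
            for c in range(1, 8):
                q[c, 1] = rew[c - 1] + gamma * q[c - 1].max()
        from escapenav.training import evaluate_greedy
        ev = evaluate_greedy(agent, corridor)
        assert ev.outcome.success
        assert ev.outcome.steps_taken == 7
        assert agent.q_value((1, 0), Action.RIGHT) == pytest.approx(
            q[0, 0], rel=1e-3)

    def test_model_stores_only_experienced_transitions(self, open_world):
        agent = DynaQAgent(open_world)
        td_update(agent, (5, 5), Action.RIGHT, 0.5, (5, 6))
        assert agent.model_size == 1
        assert agent.model_entry((5, 5), Action.RIGHT) == (0.5, (5, 6))
        assert agent.model_entry((5, 5), Action.LEFT) is None


class TestITM:
    def test_first_two_distinct_positions_bootstrap_an_edge(self, open_world):
        agent = IZAgent(open_world)
        itm_update(agent, (2.0, 2.0))
        itm_update(agent, (4.0, 2.0))
        assert agent.n_nodes == 2
        assert agent.edges[0] == {1} and agent.edges[1] == {0}

    def test_repeated_identical_position_is_stable(self, open_world):
        agent = IZAgent(open_world)
        for _ in range(50):
            itm_update(agent, (3.0, 3.0))
            itm_update(agent, (3.0, 4.5))
        n = agent.n_nodes
        for _ in range(50):
            itm_update(agent, (3.0, 3.0))
        assert agent.n_nodes == n

    def test_no_self_edges_and_positions_in_bounds(self, arena4):
        agent = IZAgent(arena4)
        rng = np.random.default_rng(1)
        cells = arena4.accessible_cells()
        for _ in range(2000):
            r, c = cells[rng.integers(len(cells))]
            itm_update(agent, (float(r), float(c)))
        for i in range(agent.n_nodes):
            assert i not in agent.edges[i]
        pos = agent.node_positions
        assert (pos[:, 0] >= 0).all() and (pos[:, 0] <= 49).all()
        assert (pos[:, 1] >= 0).all() and (pos[:, 1] <= 49).all()

    def test_arm_coverage_yields_connected_sparse_graph(self, arena4):
        """Walking both arms produces one connected component with fewer
        nodes than accessible cells."""
        from escapenav.synth import _arm_routes
        agent = IZAgent(arena4)
        routes = _arm_routes(arena4)
        for _ in range(6):
            for arm in ("right_arm", "left_arm"):
                for cell in routes[arm] + routes[arm][::-1]:
                    itm_update(agent, (float(cell[0]), float(cell[1])))
        assert 2 < agent.n_nodes < arena4.n_accessible
        seen = {0}
        frontier = [0]
        while frontier:
            n = frontier.pop()
            for m in agent.edges[n]:
                if m not in seen:
                    seen.add(m)
                    frontier.append(m)
        assert len(seen) == agent.n_nodes


class TestIZUpdate:
    def _line_map_agent(self, world, n_nodes=10, gamma=0.9):
        agent = IZAgent(world, LearningParams(alpha=0.5, gamma=gamma),
                        iz_params=IZParams(itm_max_error=0.8))
        for c in range(n_nodes):
            itm_update(agent, (1.0, float(c)))
        return agent

    def test_empty_map_is_error(self, corridor):
        agent = IZAgent(corridor)
        with pytest.raises(ContractViolationError):
            iz_update(agent, (1, 0), Action.RIGHT, 0.0, (1, 1))

    def test_zero_td_error_changes_nothing(self, corridor):
        agent = self._line_map_agent(corridor, n_nodes=8)
        vals = agent.node_values
        iz_update(agent, (1, 2), Action.RIGHT, 0.0, (1, 3))
        assert np.array_equal(agent.node_values, vals)

    def test_single_node_map_reduces_to_one_step_update(self, corridor):
        agent = IZAgent(corridor, LearningParams(alpha=0.5, gamma=0.9))
        itm_update(agent, (1.0, 3.0))
        iz_update(agent, (1, 3), Action.RIGHT, 1.0, (1, 4))
        # one node: delta = r + gamma*v - v with v = 0 -> v' = alpha * r
        assert agent.node_values[0] == pytest.approx(0.5)

    def test_terminal_reward_propagates_monotonically(self, corridor):
        """On a line map with a rewarded end, converged node values grow
        monotonically toward the rewarded transition.

        Rewards attach to transitions, so the gradient peaks at the node of
        the transition's source cell; nodes farther along the graph carry
        geometrically discounted values.
        """
        occ = np.zeros((3, 12), dtype=bool)
        occ[1, :] = True
        world = GridWorld(occ, (1, 0), (1, 11))
        agent = self._line_map_agent(world, n_nodes=12)
        order = np.argsort(agent.node_positions[:, 1])
        for _ in range(300):
            iz_update(agent, (1, 10), Action.RIGHT, 1.0, (1, 11))
        vals = agent.node_values[order]
        src = agent.nearest_node((1.0, 10.0))
        peak = int(np.nonzero(order == src)[0][0])
        # non-decreasing up to the rewarded transition's node
        assert (np.diff(vals[:peak + 1]) >= -1e-9).all()
        assert vals[peak] == vals.max()
        assert vals[peak] > vals[0] > 0.0

    def test_only_node_values_change(self, corridor):
        agent = self._line_map_agent(corridor, n_nodes=8)
        pos = agent.node_positions
        edges = [set(e) for e in agent.edges]
        iz_update(agent, (1, 5), Action.RIGHT, 1.0, (1, 6))
        assert np.array_equal(agent.node_positions, pos)
        assert [set(e) for e in agent.edges] == edges


class TestActionSelection:
    def test_all_values_equal_ties_break_to_first_action(self, open_world):
        for agent in (QTableAgent(open_world), IZAgent(open_world)):
            assert greedy_action(agent, (5, 5)) is ACTIONS[0]

    def test_epsilon_zero_equals_greedy(self, open_world):
        agent = QTableAgent(open_world)
        agent.Q[agent.cw.flat((5, 5)), 3] = 1.0
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert epsilon_greedy_action(agent, (5, 5), 0.0, rng) \
                is greedy_action(agent, (5, 5))

    def test_epsilon_one_is_uniform(self, open_world):
        """With epsilon = 1 the action distribution is uniform over the 8
        directions (chi-square test over 10,000 draws)."""
        agent = QTableAgent(open_world)
        rng = np.random.default_rng(11)
        counts = np.zeros(8)
        for _ in range(10_000):
            a = epsilon_greedy_action(agent, (5, 5), 1.0, rng)
            counts[ACTIONS.index(a)] += 1
        _, p = sps.chisquare(counts)
        assert p > 1e-3

    def test_greedy_picks_argmax(self, open_world):
        agent = QTableAgent(open_world)
        s = agent.cw.flat((4, 4))
        agent.Q[s, 6] = 2.0
        agent.Q[s, 2] = 1.0
        assert greedy_action(agent, (4, 4)) is ACTIONS[6]
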