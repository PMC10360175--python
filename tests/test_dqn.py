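"""DQN agent: network, replay buffer, action selection, TD updates, loop."""

import numpy as np
import pytest

from adaptaug.dqn import (AgentConfig, QNetwork, QNetworkSpec, ReplayBuffer,
                          greedy_actions, select_actions, sync_target, td_loss,
                          train)
from adaptaug.features import StateElement
from adaptaug.planted import (PlantedRuleEnv, default_rule, make_state_pool,
                              policy_accuracy)
from adaptaug.rlenv import Transition


def _state(seed=0):
    rng = np.random.default_rng(seed)
    return StateElement(*rng.uniform(size=12))


class _StubQ:
    """Fixed Q-table stub exposing the interface select/td_loss require."""

    def __init__(self, rows):
        self.rows = np.atleast_2d(np.asarray(rows, dtype=float))
        self.spec = QNetworkSpec(output_dim=self.rows.shape[1])
        self.backward_calls = []

    def forward(self, states, cache=None):
        n = np.atleast_2d(np.asarray(states)).shape[0]
        out = np.repeat(self.rows, n, axis=0) if len(self.rows) == 1 else self.rows
        if cache is not None:
            cache.append(out)
        return out

    def backward(self, cache, d_out):
        self.backward_calls.append(d_out)
        return []


def test_pure_exploration_is_uniform():
    q = _StubQ([[0, 0, 0, 0, 0, 0, 0, 10]])
    rng = np.random.default_rng(0)
    states = [_state()] * 10_000
    actions = select_actions(q, states, epsilon=1.0, rng=rng)
    counts = np.bincount(actions, minlength=8)
    expected = len(states) / 8
    sigma = np.sqrt(len(states) * (1 / 8) * (7 / 8))
    assert (np.abs(counts - expected) < 3 * sigma).all()


def test_pure_exploitation_follows_argmax():
    q = _StubQ([[0, 0, 0, 0, 5, 0, 0, 0]])
    actions = select_actions(q, [_state()] * 20, epsilon=0.0,
                             rng=np.random.default_rng(0))
    assert actions == [4] * 20


def test_greedy_tie_breaks_to_lowest_action_id():
    q = _StubQ([[0, 0, 7, 0, 0, 7, 0, 0]])
    actions = select_actions(q, [_state()], epsilon=0.0,
                             rng=np.random.default_rng(0))
    assert actions == [2]
    assert greedy_actions(q, [_state()]) == [2]


def test_td_loss_hand_computed_value():
    # single transition: Q1(s,a)=0.3, max_a Q2(s',a)=0.5, r=0.2, gamma=1
    q1 = _StubQ([[0.3, -1.0]])
    q2 = _StubQ([[0.5, 0.1]])
    tr = Transition(s=_state(1), a=0, r=0.2, s_next=_state(2))
    loss, _ = td_loss(q1, q2, [tr], gamma=1.0)
    assert loss == pytest.approx((0.2 + 0.5 - 0.3) ** 2)
    # at the fixed point the loss vanishes
    q1b = _StubQ([[0.7, -1.0]])
    loss_fp, _ = td_loss(q1b, q2, [tr], gamma=1.0)
    assert loss_fp == pytest.approx(0.0)


def test_td_loss_gradients_flow_to_q1_only():
    q1 = _StubQ([[0.3, -1.0]])
    q2 = _StubQ([[0.5, 0.1]])
    tr = Transition(s=_state(1), a=0, r=0.2, s_next=_state(2))
    td_loss(q1, q2, [tr])
    assert len(q1.backward_calls) == 1
    assert len(q2.backward_calls) == 0


def test_td_gradients_match_numerical_differentiation():
    spec = QNetworkSpec(hidden_layers=(8,), seed=1)
    q1, q2 = QNetwork(spec), QNetwork(QNetworkSpec(hidden_layers=(8,), seed=2))
    rng = np.random.default_rng(0)
    batch = [Transition(s=_state(i), a=int(rng.integers(8)),
                        r=float(rng.normal()), s_next=_state(i + 50))
             for i in range(5)]
    _, grads = td_loss(q1, q2, batch, gamma=0.9)
    eps = 1e-6
    for layer in range(len(q1.weights)):
        for idx in [(0, 0), (3, 2)]:
            orig = q1.weights[layer][idx]
            q1.weights[layer][idx] = orig + eps
            up, _ = td_loss(q1, q2, batch, gamma=0.9)
            q1.weights[layer][idx] = orig - eps
            dn, _ = td_loss(q1, q2, batch, gamma=0.9)
            q1.weights[layer][idx] = orig
            numeric = (up - dn) / (2 * eps)
            assert grads[layer][0][idx] == pytest.approx(numeric, abs=1e-5)


def test_network_copy_and_param_round_trip():
    net = QNetwork(QNetworkSpec(seed=3))
    clone = net.copy()
    x = np.random.default_rng(0).uniform(size=(4, 12))
    assert (clone.forward(x) == net.forward(x)).all()
    clone.weights[0][0, 0] += 1.0
    assert not (clone.forward(x) == net.forward(x)).all()


def test_sync_target_period_semantics():
    q1 = QNetwork(QNetworkSpec(seed=4))
    q2 = QNetwork(QNetworkSpec(seed=5))
    x = np.random.default_rng(1).uniform(size=(6, 12))
    for step in range(1, 10):
        sync_target(q1, q2, step, 10)
    assert not (q2.forward(x) == q1.forward(x)).all()
    sync_target(q1, q2, 10, 10)
    assert (q2.forward(x) == q1.forward(x)).all()
    # C=1 keeps them locked
    q1.weights[0][0, 0] += 0.5
    sync_target(q1, q2, 11, 1)
    assert (q2.forward(x) == q1.forward(x)).all()
    assert q2.forward(x).max(axis=1) == pytest.approx(q1.forward(x).max(axis=1))


def test_replay_buffer_is_fifo_bounded():
    buf = ReplayBuffer(capacity=10)
    trs = [Transition(s=_state(0), a=i % 8, r=float(i), s_next=_state(1))
           for i in range(14)]
    buf.extend(trs)
    assert len(buf) == 10
    stored = [t.r for t in buf]
    assert stored == [float(i) for i in range(4, 14)]  # 4 oldest evicted


def test_replay_sampling_is_uniform():
    buf = ReplayBuffer(capacity=200)
    for i in range(200):
        buf.push(Transition(s=_state(0), a=0, r=float(i), s_next=_state(1)))
    rng = np.random.default_rng(0)
    counts = np.zeros(200)
    draws, k = 400, 50
    for _ in range(draws):
        for t in buf.sample(k, rng):
            counts[int(t.r)] += 1
    p = k / 200
    expected = draws * p
    sigma = np.sqrt(draws * p * (1 - p))
    assert (np.abs(counts - expected) < 3 * sigma + 1).all()
    with pytest.raises(ValueError):
        buf.sample(500, rng)


class _CountingEnv:
    """Minimal vector environment: m states, zero reward, counts steps."""

    class _Cfg:
        steps_per_episode = 3

    def __init__(self, m=5):
        self.cfg = self._Cfg()
        self.m = m
        self.steps = 0
        self._states = tuple(_state(i) for i in range(m))

    def reset(self):
        return self._states

    def step(self, actions):
        assert len(actions) == self.m
        self.steps += 1
        return self._states, 0.0, False, {}


def test_train_loop_accounting():
    env = _CountingEnv(m=5)
    cfg = AgentConfig(episodes=2, batch_size=4, seed=0)
    q1, rewards, logs = train(env, cfg)
    assert env.steps == 6
    assert len(rewards) == 6
    assert len(logs) == 6
    assert logs[0]["buffer_size"] == 5
    assert logs[-1]["buffer_size"] == 30  # 6 steps x 5 transitions each


def test_train_raises_on_non_finite_reward():
    class _NaNEnv(_CountingEnv):
        def step(self, actions):
            return self._states, float("nan"), False, {}

    with pytest.raises(FloatingPointError):
        train(_NaNEnv(), AgentConfig(episodes=1, seed=0))


def test_training_on_bandit_is_deterministic():
    pool = make_state_pool(30, seed=1)
    kwargs = dict(episodes=4, batch_size=16, discount=0.0, seed=7)
    histories = []
    for _ in range(2):
        env = PlantedRuleEnv(pool, steps_per_episode=25, seed=3)
        _, rewards, _ = train(env, AgentConfig(**kwargs))
        histories.append(rewards)
    assert histories[0] == histories[1]


def test_agent_learns_planted_rule_quickly():
    # a shortened recovery run: the greedy policy should already beat chance
    # by a wide margin after ~1500 transitions
    pool = make_state_pool(100, seed=1)
    env = PlantedRuleEnv(pool, steps_per_episode=50, seed=0)
    cfg = AgentConfig(episodes=30, batch_size=64, learning_rate=1e-2,
                      target_sync_period=5, discount=0.0, seed=0)
    q1, rewards, _ = train(env, cfg)
    held = make_state_pool(40, seed=9)
    acc = policy_accuracy(lambda ss: greedy_actions(q1, ss), held)
    assert acc >= 0.7
    assert np.mean(rewards[-250:]) > np.mean(rewards[:250])


def test_agent_config_validation():
    with pytest.raises(ValueError):
        AgentConfig(batch_size=0)
    with pytest.raises(ValueError):
        AgentConfig(epsilon_start=0.1, epsilon_end=0.5)
    with pytest.raises(ValueError):
        AgentConfig(discount=1.5)
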