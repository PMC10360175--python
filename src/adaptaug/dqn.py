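"""Deep Q-learning agent: decision network Q1, target network Q2, experience
replay, ε-greedy selection, squared-TD loss and the outer training loop.

The Q-network is a fully-connected 12→64→64→8 net with ReLU hidden layers
and a linear head, implemented directly on numpy arrays with manual
backpropagation and an Adam optimizer, so training is single-threaded and
bit-reproducible under a seed.

The loss on a sampled batch is

    L(θ) = mean_i [ r_i + γ · max_a Q2(s'_i, a) − Q1(s_i, a_i) ]²

with gradients flowing to Q1 only; Q2 is a frozen copy of Q1 refreshed every
C gradient steps.  γ defaults to 1.0, matching a loss written without a
discount, and is configurable in (0, 1].
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import StateElement
from .rlenv import Transition, collect_transitions

__all__ = [
    "QNetworkSpec",
    "QNetwork",
    "ReplayBuffer",
    "AgentConfig",
    "select_actions",
    "td_loss",
    "sync_target",
    "train",
    "greedy_actions",
]


@dataclass(frozen=True)
class QNetworkSpec:
    input_dim: int = 12
    output_dim: int = 8
    hidden_layers: tuple[int, ...] = (64, 64)
    seed: int = 0


class QNetwork:
    """Feed-forward action-value network (ReLU hidden layers, linear head)."""

    def __init__(self, spec: QNetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        dims = (spec.input_dim, *spec.hidden_layers, spec.output_dim)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            scale = math.sqrt(2.0 / d_in)  # He initialization
            self.weights.append(rng.normal(0.0, scale, size=(d_in, d_out)))
            self.biases.append(np.zeros(d_out))

    # -- forward / backward -------------------------------------------------

    def forward(self, states: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Q-values (n, output_dim) for a batch of state arrays (n, input_dim)."""
        h = np.atleast_2d(np.asarray(states, dtype=float))
        if cache is not None:
            cache.append(h)
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < n_layers - 1:
                h = np.maximum(h, 0.0)
            if cache is not None:
                cache.append(h)
        return h

    def backward(self, cache: list, d_out: np.ndarray
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradients [(dW, db), ...] given d(loss)/d(output)."""
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        delta = d_out
        for i in range(len(self.weights) - 1, -1, -1):
            h_in = cache[i]
            if i < len(self.weights) - 1:
                # cache[i+1] holds the post-ReLU activation of layer i
                delta = delta * (cache[i + 1] > 0)
            grads.append((h_in.T @ delta, delta.sum(axis=0)))
            delta = delta @ self.weights[i].T
        grads.reverse()
        return grads

    # -- parameter plumbing -------------------------------------------------

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for pair in zip(self.weights, self.biases) for p in pair]

    def set_params(self, params: Sequence[np.ndarray]) -> None:
        it = iter(params)
        for i in range(len(self.weights)):
            self.weights[i] = next(it).copy()
            self.biases[i] = next(it).copy()

    def copy(self) -> "QNetwork":
        clone = QNetwork(self.spec)
        clone.set_params(self.get_params())
        return clone


class Adam:
    """Adam optimizer over a QNetwork's flat parameter list."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None
        self.t = 0

    def step(self, net: QNetwork,
             grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        flat = [g for pair in grads for g in pair]
        params = [p for pair in zip(net.weights, net.biases) for p in pair]
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        for p, g, m, v in zip(params, flat, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1 ** self.t)
            v_hat = v / (1 - self.beta2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class ReplayBuffer:
    """Bounded FIFO of transitions with uniform sampling."""

    def __init__(self, capacity: int = 10_000):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._items: deque[Transition] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._items)

    def push(self, transition: Transition) -> None:
        self._items.append(transition)

    def extend(self, transitions: Sequence[Transition]) -> None:
        for tr in transitions:
            self.push(tr)

    def sample(self, n: int, rng: np.random.Generator) -> list[Transition]:
        if n > len(self._items):
            raise ValueError(f"cannot sample {n} from buffer of {len(self._items)}")
        idx = rng.choice(len(self._items), size=n, replace=False)
        return [self._items[i] for i in idx]

    def __iter__(self):
        return iter(self._items)


@dataclass(frozen=True)
class AgentConfig:
    """DQN hyperparameters.

    ``epsilon_decay_steps=None`` resolves, inside :func:`train`, to half the
    total number of environment steps (linear 1.0 → 0.05 schedule).
    ``target_sync_period`` counts gradient updates.
    """

    batch_size: int = 64
    target_sync_period: int = 5
    episodes: int = 10
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_steps: int | None = None
    discount: float = 1.0
    learning_rate: float = 1e-2
    buffer_capacity: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.target_sync_period < 1:
            raise ValueError("batch_size and target_sync_period must be >= 1")
        if not 0.0 <= self.epsilon_end <= self.epsilon_start <= 1.0:
            raise ValueError("need 0 <= epsilon_end <= epsilon_start <= 1")
        if not 0.0 <= self.discount <= 1.0:
            raise ValueError("discount must lie in [0, 1]")


def _states_to_matrix(states: Sequence[StateElement]) -> np.ndarray:
    return np.stack([s.to_array() for s in states])


def select_actions(q1: QNetwork, states: Sequence[StateElement],
                   epsilon: float, rng: np.random.Generator) -> list[int]:
    """ε-greedy per state element; greedy ties break to the lowest action id."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    qvals = q1.forward(_states_to_matrix(states))
    greedy = np.argmax(qvals, axis=1)  # argmax returns the first maximum
    actions = []
    for g in greedy:
        if rng.random() < epsilon:
            actions.append(int(rng.integers(q1.spec.output_dim)))
        else:
            actions.append(int(g))
    return actions


def greedy_actions(q1: QNetwork, states: Sequence[StateElement]) -> list[int]:
    """Purely greedy policy (ε = 0)."""
    qvals = q1.forward(_states_to_matrix(states))
    return [int(a) for a in np.argmax(qvals, axis=1)]


def td_loss(q1: QNetwork, q2: QNetwork, batch: Sequence[Transition],
            gamma: float = 1.0
            ) -> tuple[float, list[tuple[np.ndarray, np.ndarray]]]:
    """Mean squared TD error and its gradients w.r.t. Q1's parameters.

    Q2 is evaluated without building a gradient path (it is a frozen target).
    """
    if len(batch) == 0:
        raise ValueError("batch must be nonempty")
    s = np.stack([tr.s.to_array() for tr in batch])
    a = np.array([tr.a for tr in batch], dtype=int)
    r = np.array([tr.r for tr in batch], dtype=float)
    s_next = np.stack([tr.s_next.to_array() for tr in batch])

    target = r + gamma * q2.forward(s_next).max(axis=1)
    cache: list = []
    q = q1.forward(s, cache=cache)
    pred = q[np.arange(len(batch)), a]
    delta = pred - target
    loss = float(np.mean(delta ** 2))

    d_out = np.zeros_like(q)
    d_out[np.arange(len(batch)), a] = 2.0 * delta / len(batch)
    return loss, q1.backward(cache, d_out)


def sync_target(q1: QNetwork, q2: QNetwork, step_counter: int, period: int) -> None:
    """Copy Q1's parameters into Q2 whenever step_counter hits the period."""
    if period < 1:
        raise ValueError("period must be >= 1")
    if step_counter % period == 0:
        q2.set_params(q1.get_params())


def train(env, agent_cfg: AgentConfig, qspec: QNetworkSpec = QNetworkSpec()
          ) -> tuple[QNetwork, list[float], list[dict]]:
    """Run the full DQN loop over ``agent_cfg.episodes`` episodes.

    ``env`` must expose ``reset() -> states``, ``step(actions) ->
    (next_states, reward, done, info)`` and ``cfg.steps_per_episode``.
    Returns the trained decision network, the per-step reward history and
    per-step log records.  A non-finite reward raises.
    """
    rng = np.random.default_rng(agent_cfg.seed)
    q1 = QNetwork(qspec)
    q2 = q1.copy()
    optimizer = Adam(lr=agent_cfg.learning_rate)
    buffer = ReplayBuffer(agent_cfg.buffer_capacity)

    steps_per_episode = env.cfg.steps_per_episode
    total_steps = agent_cfg.episodes * steps_per_episode
    decay_steps = agent_cfg.epsilon_decay_steps
    if decay_steps is None:
        decay_steps = max(1, total_steps // 2)

    rewards: list[float] = []
    logs: list[dict] = []
    grad_steps = 0
    for episode in range(agent_cfg.episodes):
        states = env.reset()
        for step in range(steps_per_episode):
            global_step = episode * steps_per_episode + step
            frac = min(1.0, global_step / decay_steps)
            epsilon = (agent_cfg.epsilon_start
                       + frac * (agent_cfg.epsilon_end - agent_cfg.epsilon_start))
            actions = select_actions(q1, states, epsilon, rng)
            next_states, r, done, info = env.step(actions)
            if not np.isfinite(r):
                raise FloatingPointError(f"non-finite reward {r!r} at step {global_step}")
            buffer.extend(collect_transitions(states, actions, r, next_states))

            loss = float("nan")
            if len(buffer) >= agent_cfg.batch_size:
                batch = buffer.sample(agent_cfg.batch_size, rng)
                loss, grads = td_loss(q1, q2, batch, agent_cfg.discount)
                optimizer.step(q1, grads)
                grad_steps += 1
                sync_target(q1, q2, grad_steps, agent_cfg.target_sync_period)

            rewards.append(float(r))
            logs.append({"episode": episode, "step": step, "epsilon": epsilon,
                         "reward": float(r), "loss": loss,
                         "buffer_size": len(buffer), **{
                             k: v for k, v in info.items()
                             if k in ("dice", "retrain_size")}})
            states = next_states
            if done:
                break
    return q1, rewards, logs
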