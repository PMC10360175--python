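"""A mock contextual-bandit environment with a planted best action.

This bypasses segmentation entirely: states are real 12-feature state
elements extracted from generated images, but the reward is +1 when the
chosen action matches a planted state-dependent rule and -1 otherwise.
Because the optimal policy is known exactly, the environment measures
whether the DQN machinery (replay, ε-greedy, target network, TD updates)
can recover a state-conditional policy — independently of the segmentation
backend's reward landscape.

The default rule: pick action 1 (vertical flip) when the rust centroid lies
in the top half of the image (y_r < 0.5, which includes spot-free images
whose rust features are all zero), otherwise action 2 (horizontal flip).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .data import GeneratorConfig, generate_dataset
from .features import MaskSource, StateElement, extract_state_vector

__all__ = ["default_rule", "PlantedRuleEnv", "make_state_pool",
           "policy_accuracy", "run_planted_policy_experiment"]


def default_rule(s: StateElement) -> int:
    """Action 1 if the rust centroid is in the top half, else action 2."""
    return 1 if s.y_r < 0.5 else 2


def make_state_pool(n_images: int, seed: int,
                    image_size: int = 64) -> tuple[StateElement, ...]:
    """States of freshly generated images (oracle masks)."""
    cfg = GeneratorConfig(image_size=image_size, n_images=n_images, seed=seed)
    return extract_state_vector(generate_dataset(cfg), MaskSource())


class PlantedRuleEnv:
    """Contextual bandit over a fixed pool of image states.

    Each step presents one state drawn uniformly from the pool; the reward
    is +1 if the action matches ``rule(state)``, else -1.  Episodes are a
    bookkeeping horizon only — the reward never depends on history, so the
    natural agent discount here is γ = 0.
    """

    class _Cfg:
        def __init__(self, steps: int):
            self.steps_per_episode = steps

    def __init__(self, states: Sequence[StateElement],
                 rule: Callable[[StateElement], int] = default_rule,
                 steps_per_episode: int = 50, seed: int = 0):
        if len(states) == 0:
            raise ValueError("state pool must be nonempty")
        self.states = tuple(states)
        self.rule = rule
        self.cfg = self._Cfg(steps_per_episode)
        self._rng = np.random.default_rng(seed)
        self._current: tuple[StateElement, ...] = ()
        self.t = 0

    def _draw(self) -> tuple[StateElement, ...]:
        return (self.states[self._rng.integers(len(self.states))],)

    def reset(self) -> tuple[StateElement, ...]:
        self.t = 0
        self._current = self._draw()
        return self._current

    def step(self, actions: Sequence[int]
             ) -> tuple[tuple[StateElement, ...], float, bool, dict]:
        if len(actions) != 1:
            raise ValueError("the bandit presents exactly one state per step")
        want = self.rule(self._current[0])
        r = 1.0 if int(actions[0]) == want else -1.0
        self.t += 1
        self._current = self._draw()
        done = self.t >= self.cfg.steps_per_episode
        return self._current, r, done, {"wanted": want}


def policy_accuracy(policy: Callable[[Sequence[StateElement]], Sequence[int]],
                    states: Sequence[StateElement],
                    rule: Callable[[StateElement], int] = default_rule) -> float:
    """Fraction of states on which a policy matches the planted rule."""
    chosen = policy(states)
    want = [rule(s) for s in states]
    return float(np.mean([int(c) == w for c, w in zip(chosen, want)]))


def run_planted_policy_experiment(seed: int = 0, pool_size: int = 200,
                                  held_out: int = 40, episodes: int = 96,
                                  steps_per_episode: int = 50) -> dict:
    """Train a DQN agent on the bandit and score its greedy policy.

    Defaults run 4,800 transitions; held-out accuracy of the final greedy
    policy against the planted rule is the headline result.
    """
    from .dqn import AgentConfig, greedy_actions, train

    pool = make_state_pool(pool_size, seed=seed + 100)
    held = make_state_pool(held_out, seed=seed + 200)
    env = PlantedRuleEnv(pool, steps_per_episode=steps_per_episode, seed=seed)
    agent_cfg = AgentConfig(episodes=episodes, batch_size=128,
                            learning_rate=1e-2, target_sync_period=5,
                            discount=0.0, epsilon_end=0.02, seed=seed)
    q1, rewards, _logs = train(env, agent_cfg)
    acc = policy_accuracy(lambda ss: greedy_actions(q1, ss), held)
    return {
        "accuracy": acc,
        "n_transitions": len(rewards),
        "mean_reward_last_500": float(np.mean(rewards[-500:])),
        "q1": q1,
    }
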