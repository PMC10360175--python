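"""The augmentation MDP: father/child image vectors, per-step fine-tune and
evaluate, Dice-difference reward, episode reset.

One environment step:

1. apply the per-image actions to the father vector, producing the child;
2. build the retrain set = original training images I0 ++ child (size 2m);
3. restore the pre-trained model snapshot and fine-tune it on the retrain set;
4. evaluate on the fixed test set to get per-image IoUs and the Dice ratio d_t;
5. reward = 100 * (d_t - d_{t-1});
6. the child becomes the next father (augmentation accumulates within an
   episode); at reset the father reverts to I0 and d_prev to the pre-trained
   model's Dice.

The pre-trained snapshot is never mutated, so restoring it always reproduces
the same evaluation — each step measures the effect of its own retrain set
against the same baseline model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .augment import apply_action_vector
from .data import ImageVector
from .features import MaskSource, StateElement, extract_state_vector
from .metrics import reward as step_reward
from .segbackend import TrainConfig, evaluate, finetune, restore

__all__ = ["EnvConfig", "Transition", "AugmentEnv", "collect_transitions"]


@dataclass(frozen=True)
class EnvConfig:
    """Environment hyperparameters.

    ``steps_per_episode`` defaults to 3 (the reported per-step and per-episode
    wall times imply three steps per episode).  ``dice_factor`` is the
    constant in the Dice-ratio definition.
    """

    steps_per_episode: int = 3
    mask_source: MaskSource = field(default_factory=MaskSource)
    finetune_cfg: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=15, learning_rate=0.8))
    dice_factor: float = 2.0
    eval_target: str = "rust"
    noise_sigma: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps_per_episode < 1:
            raise ValueError("steps_per_episode must be >= 1")


@dataclass(frozen=True)
class Transition:
    """One replay record at per-image granularity.

    The reward is the step-level scalar shared by every image of the step
    (uniform credit assignment: the step's Dice change is attributed to each
    selected action equally).
    """

    s: StateElement
    a: int
    r: float
    s_next: StateElement


def collect_transitions(s: Sequence[StateElement], a: Sequence[int], r: float,
                        s_next: Sequence[StateElement]) -> list[Transition]:
    """Pair up aligned state/action/next-state sequences with the shared reward."""
    if not (len(s) == len(a) == len(s_next)):
        raise ValueError("state, action and next-state sequences must align")
    return [Transition(s=si, a=int(ai), r=float(r), s_next=ni)
            for si, ai, ni in zip(s, a, s_next)]


class AugmentEnv:
    """The adaptive-augmentation environment.

    Parameters
    ----------
    pretrain_set, test_set:
        I0 and the fixed test images.
    model_snapshot:
        Snapshot blob of the model pre-trained on I0; restored at every step.
    cfg:
        Environment hyperparameters.
    """

    def __init__(self, pretrain_set: ImageVector, test_set: ImageVector,
                 model_snapshot: bytes, cfg: EnvConfig = EnvConfig()):
        if len(pretrain_set) == 0 or len(test_set) == 0:
            raise ValueError("pretrain and test sets must be nonempty")
        self.cfg = cfg
        self.pretrain_set = pretrain_set
        self.test_set = test_set
        self.pretrain_snapshot = bytes(model_snapshot)
        base_model = restore(self.pretrain_snapshot)  # raises if incompatible
        _, _, dice0 = evaluate(base_model, test_set, cfg.eval_target)
        self._baseline_dice = dice0.d
        self.father = pretrain_set
        self.t = 0
        self.d_prev = dice0.d
        self.episode_index = 0

    # -- properties ---------------------------------------------------------

    @property
    def m(self) -> int:
        """Number of images per vector (constant within an episode)."""
        return len(self.pretrain_set)

    @property
    def baseline_dice(self) -> float:
        """Dice of the restored pre-trained model on the test set."""
        return self._baseline_dice

    # -- MDP interface ------------------------------------------------------

    def reset(self) -> tuple[StateElement, ...]:
        """Start a new episode: father := I0, d_prev := baseline Dice."""
        self.father = self.pretrain_set
        self.t = 0
        self.d_prev = self._baseline_dice
        self.episode_index += 1
        return extract_state_vector(self.father, self.cfg.mask_source)

    def current_state(self) -> tuple[StateElement, ...]:
        return extract_state_vector(self.father, self.cfg.mask_source)

    def step(self, actions: Sequence[int]
             ) -> tuple[tuple[StateElement, ...], float, bool, dict]:
        """Execute one augmentation round; returns (next_state, reward, done, info)."""
        if len(actions) != len(self.father):
            raise ValueError(
                f"need {len(self.father)} actions, got {len(actions)}")
        if self.t >= self.cfg.steps_per_episode:
            raise RuntimeError("episode is over; call reset()")
        noise_rng = np.random.default_rng(
            (self.cfg.seed, self.episode_index, self.t))
        child = apply_action_vector(self.father, actions, noise_rng=noise_rng,
                                    noise_sigma=self.cfg.noise_sigma)
        retrain_set = ImageVector(
            items=self.pretrain_set.items + child.items,
            generation_index=child.generation_index)
        model = finetune(restore(self.pretrain_snapshot), retrain_set,
                         self.cfg.finetune_cfg)
        ious, mset, dice = evaluate(model, self.test_set, self.cfg.eval_target)
        r = step_reward(dice.d, self.d_prev)
        next_state = extract_state_vector(child, self.cfg.mask_source)
        self.father = child
        self.d_prev = dice.d
        self.t += 1
        done = self.t >= self.cfg.steps_per_episode
        info = {
            "episode": self.episode_index,
            "step": self.t,
            "dice": dice.d,
            "metrics": mset,
            "per_image_iou": ious,
            "retrain_size": len(retrain_set),
        }
        return next_state, r, done, info
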