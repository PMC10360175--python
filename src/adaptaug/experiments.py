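"""End-to-end pipelines and comparison experiments.

`run_pipeline` wires the stages together: generate (or load) a dataset,
split 8:2, pre-train the segmentation backend, build the augmentation
environment and train the DQN agent.  `compare_single_methods` reproduces
the single-augmentation-method comparison (each of the eight actions applied
uniformly to the training images, plus the learned policy's per-image
choices), and `random_baseline` the uniform-random-augmentation control.

One global seed fans out into named per-stage seeds (data, split, pretrain,
env, agent, baseline) so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .augment import ACTION_NAMES, N_ACTIONS, apply_action_vector
from .data import GeneratorConfig, ImageVector, generate_dataset, load_dataset, split_dataset
from .dqn import AgentConfig, QNetwork, QNetworkSpec, greedy_actions, train
from .features import MaskSource, extract_state_vector
from .metrics import MetricSet
from .rlenv import AugmentEnv, EnvConfig
from .segbackend import TrainConfig, evaluate, finetune, pretrain, restore, snapshot

__all__ = [
    "RunConfig",
    "stage_seeds",
    "run_pipeline",
    "compare_single_methods",
    "random_baseline",
    "run_full_loop_experiment",
]

_STAGES = ("data", "split", "pretrain", "env", "agent", "baseline")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Derive one independent sub-seed (< 2^31) per pipeline stage."""
    state = np.random.SeedSequence(global_seed).generate_state(len(_STAGES))
    return {name: int(s) & 0x7FFFFFFF for name, s in zip(_STAGES, state)}


@dataclass
class RunConfig:
    """Full configuration of a pipeline run; serializable to YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    test_fraction: float = 0.2
    pretrain_cfg: TrainConfig = field(default_factory=TrainConfig)
    finetune_cfg: TrainConfig = field(
        default_factory=lambda: TrainConfig(epochs=15, learning_rate=0.8))
    env_cfg: EnvConfig = field(default_factory=EnvConfig)
    agent_cfg: AgentConfig = field(default_factory=AgentConfig)
    qspec: QNetworkSpec = field(default_factory=QNetworkSpec)
    data_dir: str | None = None   # load instead of generate when set
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["env_cfg"].pop("mask_source", None)  # not a plain value; oracle mode assumed
        return d

    def dump_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _reseeded(cfg, seed: int):
    return dataclasses.replace(cfg, seed=seed)


def _metrics_row(label: str, mset: MetricSet, dice: float) -> dict:
    return {"method": label, **mset.as_dict(), "dice": dice}


def run_pipeline(cfg: RunConfig, out_dir: str) -> dict:
    """Execute the full pipeline and write artifacts under ``out_dir``.

    Writes: the resolved config (config.yaml), the pre-trained model snapshot
    (pretrain_snapshot.json), per-step training records (steps.csv) and a
    summary (summary.json).  Returns the summary dict.
    """
    os.makedirs(out_dir, exist_ok=True)
    seeds = stage_seeds(cfg.seed)

    if cfg.data_dir is not None:
        try:
            dataset = load_dataset(cfg.data_dir)
        except (OSError, ValueError) as exc:
            raise RuntimeError(f"[stage:data] failed to load dataset: {exc}") from exc
    else:
        dataset = generate_dataset(_reseeded(cfg.generator, seeds["data"]))

    pretrain_set, test_set = split_dataset(dataset, cfg.test_fraction,
                                           seed=seeds["split"])
    model, _history = pretrain("surrogate", pretrain_set, test_set,
                               _reseeded(cfg.pretrain_cfg, seeds["pretrain"]))
    blob = snapshot(model)
    with open(os.path.join(out_dir, "pretrain_snapshot.json"), "wb") as fh:
        fh.write(blob)

    env_cfg = dataclasses.replace(cfg.env_cfg, seed=seeds["env"],
                                  finetune_cfg=cfg.finetune_cfg)
    env = AugmentEnv(pretrain_set, test_set, blob, env_cfg)
    agent_cfg = _reseeded(cfg.agent_cfg, seeds["agent"])
    q1, rewards, logs = train(env, agent_cfg, cfg.qspec)

    cfg_resolved = dataclasses.replace(cfg, seed=cfg.seed)
    cfg_resolved.dump_yaml(os.path.join(out_dir, "config.yaml"))
    pd.DataFrame(logs).to_csv(os.path.join(out_dir, "steps.csv"), index=False)

    summary = {
        "n_images": len(dataset),
        "n_pretrain": len(pretrain_set),
        "n_test": len(test_set),
        "baseline_dice": env.baseline_dice,
        "n_steps": len(rewards),
        "mean_reward": float(np.mean(rewards)),
        "final_dice": logs[-1]["dice"] if logs else None,
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"summary": summary, "q1": q1, "rewards": rewards, "logs": logs,
            "env": env, "pretrain_set": pretrain_set, "test_set": test_set,
            "snapshot": blob}


def run_full_loop_experiment(seed: int = 0, n_images: int = 25,
                             episodes: int = 10) -> dict:
    """Full agent-environment loop at desk scale; reward-trend diagnostics.

    Generates 25 synthetic 64×64 images, splits 8:2 into 20 training and 5
    test images, pre-trains the surrogate to convergence, then trains the
    DQN for ``episodes`` episodes of 3 steps.  Returns the reward history
    plus the first- and last-quartile means of the per-step rewards (a
    non-degradation summary: learning should not make augmentation choices
    worse).
    """
    gen = GeneratorConfig(image_size=64, n_images=n_images, seed=seed + 1)
    vec = generate_dataset(gen)
    pre, test = split_dataset(vec, 0.2, seed=seed)
    model, _ = pretrain("surrogate", pre, test, TrainConfig(seed=seed))
    blob = snapshot(model)
    env = AugmentEnv(pre, test, blob, EnvConfig(seed=seed + 3))
    agent_cfg = AgentConfig(episodes=episodes, seed=seed)
    q1, rewards, logs = train(env, agent_cfg)
    r = np.asarray(rewards)
    q = max(1, len(r) // 4)
    return {
        "rewards": rewards,
        "first_quartile_mean": float(r[:q].mean()),
        "last_quartile_mean": float(r[-q:].mean()),
        "baseline_dice": env.baseline_dice,
        "final_dice": logs[-1]["dice"],
        "q1": q1,
        "pretrain_set": pre,
        "test_set": test,
        "snapshot": blob,
    }


def _retrain_and_score(pretrain_set: ImageVector, test_set: ImageVector,
                       blob: bytes, finetune_cfg: TrainConfig,
                       actions: list[int], noise_rng: np.random.Generator,
                       target: str = "rust") -> tuple[MetricSet, float]:
    child = apply_action_vector(pretrain_set, actions, noise_rng=noise_rng)
    retrain = ImageVector(items=pretrain_set.items + child.items,
                          generation_index=1)
    model = finetune(restore(blob), retrain, finetune_cfg)
    _, mset, dice = evaluate(model, test_set, target)
    return mset, dice.d


def compare_single_methods(pretrain_set: ImageVector, test_set: ImageVector,
                           blob: bytes, finetune_cfg: TrainConfig,
                           policy: QNetwork | None = None,
                           seed: int = 0, target: str = "rust") -> pd.DataFrame:
    """Score each single augmentation action, plus the learned policy.

    For action i, every training image is augmented with action i, the
    restored pre-trained model is fine-tuned on originals + augmented and
    evaluated on the test set.  The final row applies the greedy policy's
    per-image action choices instead.  Returns a 9-row table (8 single
    methods + the policy row; the policy row is omitted when no policy is
    given).
    """
    rows = []
    m = len(pretrain_set)
    for action in range(N_ACTIONS):
        noise_rng = np.random.default_rng((seed, action))
        mset, d = _retrain_and_score(pretrain_set, test_set, blob,
                                     finetune_cfg, [action] * m, noise_rng,
                                     target)
        rows.append(_metrics_row(ACTION_NAMES[action], mset, d))
    if policy is not None:
        states = extract_state_vector(pretrain_set, MaskSource())
        actions = greedy_actions(policy, states)
        noise_rng = np.random.default_rng((seed, N_ACTIONS))
        mset, d = _retrain_and_score(pretrain_set, test_set, blob,
                                     finetune_cfg, actions, noise_rng, target)
        rows.append(_metrics_row("dqn_policy", mset, d))
    return pd.DataFrame(rows)


def random_baseline(pretrain_set: ImageVector, test_set: ImageVector,
                    blob: bytes, finetune_cfg: TrainConfig,
                    seed: int = 0, target: str = "rust") -> pd.DataFrame:
    """Uniform-random action per image, then fine-tune and evaluate."""
    rng = np.random.default_rng(seed)
    actions = [int(a) for a in rng.integers(N_ACTIONS, size=len(pretrain_set))]
    noise_rng = np.random.default_rng((seed, N_ACTIONS + 1))
    mset, d = _retrain_and_score(pretrain_set, test_set, blob, finetune_cfg,
                                 actions, noise_rng, target)
    row = _metrics_row("random_augment", mset, d)
    row["actions"] = actions
    return pd.DataFrame([{k: v for k, v in row.items() if k != "actions"}]), actions
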