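"""The two benchmark tasks: multiple choice and object collection.

Both environments expose a plain reset/step interface with discrete actions
and are fully seeded: every random element (target schedule, stimulus noise,
screen order, spawn sequence) flows through named integer-keyed generator
streams derived from the task seed, so identical specs give identical runs
and the train/test stimulus streams of the multiple-choice task are
guaranteed to be disjoint.

* :class:`MultipleChoiceTask` — three fixed categories; each trial shows one
  fresh stimulus per category in randomised screen order; choosing the
  current target category pays +1, anything else 0; the target is resampled
  uniformly at every ``block_length``-trial boundary.
* :class:`ObjectCollectionGame` — objects fall down a grid; the agent slides
  left/right along the bottom row and catches an object by occupying its
  landing column.  Either the rewarded identity (reward revaluation) or the
  set of identities present (state revaluation) switches once, unannounced,
  at ``revaluation_episode``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ContractError, FeatureTensor
from .feature_backends import (
    BackendSpec,
    CategoryProfile,
    make_profiles,
    render_scene,
    render_stimulus,
)

__all__ = [
    "MCTaskSpec",
    "OCTaskSpec",
    "EpisodeLog",
    "MultipleChoiceTask",
    "ObjectCollectionGame",
    "spawn_columns_reachable",
]


@dataclass(frozen=True)
class MCTaskSpec:
    """Multiple-choice task configuration (one target among n_choices categories)."""

    backend: BackendSpec
    n_choices: int = 3
    block_length: int = 50
    train_blocks: int = 200
    test_blocks: int = 10
    reward_target: float = 1.0
    reward_other: float = 0.0
    force_change: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend.n_categories < self.n_choices:
            raise ContractError(
                "backend must define at least n_choices categories"
            )

    def n_trials(self, phase: str) -> int:
        blocks = self.train_blocks if phase == "train" else self.test_blocks
        return blocks * self.block_length


@dataclass(frozen=True)
class OCTaskSpec:
    """Object-collection game configuration.

    Defaults are desk-scale: a 12x12 grid, a spawn every 6 decision steps,
    objects falling one row per step, 100-step episodes and 200 episodes on
    each side of the revaluation.  In ``reward_revaluation`` mode all
    identities are present throughout and the rewarded identity switches at
    the midpoint; in ``state_revaluation`` mode exactly one identity is
    present per phase (always rewarded) and the identity itself switches.
    """

    backend: BackendSpec
    grid_h: int = 12
    grid_w: int = 12
    spawn_interval: int = 6
    fall_rate: int = 1
    episode_length: int = 100
    n_episodes: int = 400
    revaluation_episode: int = 200
    mode: str = "reward_revaluation"
    n_identities: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("reward_revaluation", "state_revaluation"):
            raise ContractError("unknown revaluation mode")
        if not 0 < self.revaluation_episode < self.n_episodes:
            raise ContractError("revaluation_episode must be inside the run")
        if self.backend.n_categories < self.n_identities:
            raise ContractError("backend must define n_identities categories")
        if self.mode == "state_revaluation" and self.n_identities < 2:
            raise ContractError("state revaluation needs at least two identities")
        if self.backend.H != self.grid_h or self.backend.W != self.grid_w:
            raise ContractError("backend spatial grid must match the game grid")


@dataclass
class EpisodeLog:
    """Per-episode record: reward, 20-episode rolling mean, attention summary."""

    seed: int
    condition: str
    phase: str
    index: int
    total_reward: float
    rolling_reward_20: float
    attention_entropy: float
    attention_mass_on_target: float


class MultipleChoiceTask:
    """Changing-target multiple choice over synthetic category stimuli."""

    def __init__(self, spec: MCTaskSpec) -> None:
        self.spec = spec
        self.profiles: list[CategoryProfile] = make_profiles(spec.backend)[
            : spec.n_choices
        ]
        self.phase: Optional[str] = None
        self.reset("train")

    # phase ids keep the train and test noise streams disjoint
    _PHASE_ID = {"train": 0, "test": 1}

    def reset(self, phase: str) -> None:
        if phase not in self._PHASE_ID:
            raise ContractError("phase must be 'train' or 'test'")
        pid = self._PHASE_ID[phase]
        self.phase = phase
        self.trial = 0
        s = self.spec.seed
        self._target_rng = np.random.default_rng([s, 101, pid])
        self._order_rng = np.random.default_rng([s, 102, pid])
        self._stim_rng = np.random.default_rng([s, 103, pid])
        self.target = int(self._target_rng.integers(self.spec.n_choices))
        self.last_rewarded_category: Optional[int] = None
        self._pending: Optional[list[int]] = None

    @property
    def block(self) -> int:
        return self.trial // self.spec.block_length

    @property
    def target_channels(self) -> np.ndarray:
        return self.profiles[self.target].discriminative_channels

    def observe(self) -> tuple[list[FeatureTensor], list[int]]:
        """Fresh stimuli for this trial and the category shown at each position."""
        order = list(self._order_rng.permutation(self.spec.n_choices))
        stimuli = [
            render_stimulus(self.profiles[c], self.spec.backend, self._stim_rng)
            for c in order
        ]
        self._pending = order
        return stimuli, order

    def step(self, choice: int) -> tuple[float, dict]:
        """Reward the choice, record the trial and advance the target schedule."""
        if self._pending is None:
            raise ContractError("observe() must be called before step()")
        if not 0 <= choice < self.spec.n_choices:
            raise ContractError(f"invalid choice {choice}")
        chosen_category = self._pending[choice]
        reward = (
            self.spec.reward_target
            if chosen_category == self.target
            else self.spec.reward_other
        )
        info = {
            "block": self.block,
            "trial": self.trial,
            "target": self.target,
            "chosen_category": chosen_category,
            # visible to the ideal observer only: which category the
            # environment rewarded on this trial
            "last_rewarded_category": self.target,
        }
        self.last_rewarded_category = self.target
        self._pending = None
        self.trial += 1
        if self.trial % self.spec.block_length == 0:
            if self.spec.force_change:
                others = [
                    c for c in range((self.spec.n_choices)) if c != self.target
                ]
                self.target = int(others[self._target_rng.integers(len(others))])
            else:
                self.target = int(self._target_rng.integers(self.spec.n_choices))
        return reward, info


class ObjectCollectionGame:
    """Falling-object catching game with a mid-run revaluation.

    Each decision step: the agent moves one column left or right (clamped to
    the grid), every object falls ``fall_rate`` rows, an object reaching the
    bottom row is caught iff its column equals the agent's (paying +1 iff
    its identity is currently rewarded) and then disappears, and every
    ``spawn_interval`` steps a new object with a uniformly random active
    identity appears at a uniformly random column of the top row.
    """

    ACTIONS = {0: -1, 1: +1}  # left, right

    def __init__(self, spec: OCTaskSpec) -> None:
        self.spec = spec
        self.profiles = make_profiles(spec.backend)
        self._rng = np.random.default_rng([spec.seed, 201])
        self.noise_rng = np.random.default_rng([spec.seed, 202])
        self.episode = -1
        if spec.mode == "reward_revaluation":
            self.active_identities = list(range(spec.n_identities))
            self.rewarded_identity = int(self._rng.integers(spec.n_identities))
        else:
            first = int(self._rng.integers(spec.n_identities))
            self.active_identities = [first]
            self.rewarded_identity = first
        self._revalued = False

    @property
    def phase(self) -> str:
        return "pre" if self.episode < self.spec.revaluation_episode else "post"

    @property
    def target_channels(self) -> np.ndarray:
        return self.profiles[self.rewarded_identity].discriminative_channels

    def _apply_revaluation(self) -> None:
        spec = self.spec
        if spec.mode == "reward_revaluation":
            others = [
                i for i in range(spec.n_identities) if i != self.rewarded_identity
            ]
            self.rewarded_identity = int(others[self._rng.integers(len(others))])
        else:
            others = [
                i
                for i in range(spec.n_identities)
                if i not in self.active_identities
            ]
            new = int(others[self._rng.integers(len(others))])
            self.active_identities = [new]
            self.rewarded_identity = new
        self._revalued = True

    def new_episode(self) -> None:
        """Advance the episode counter, applying the revaluation exactly once."""
        self.episode += 1
        if self.episode == self.spec.revaluation_episode and not self._revalued:
            self._apply_revaluation()
        self.agent_col = self.spec.grid_w // 2
        self.objects: list[list[int]] = []  # [identity, row, col]
        self.t = 0

    def observe(self) -> FeatureTensor:
        return render_scene(
            [(o[0], o[1], o[2]) for o in self.objects],
            self.agent_col,
            self.spec.backend,
            self.profiles,
            self.noise_rng,
        )

    def step(self, action: int) -> tuple[float, bool]:
        """Apply one decision step; returns (reward, episode_done)."""
        if action not in self.ACTIONS:
            raise ContractError(f"invalid action {action}")
        spec = self.spec
        self.agent_col = int(
            np.clip(self.agent_col + self.ACTIONS[action], 0, spec.grid_w - 1)
        )
        reward = 0.0
        surviving = []
        for obj in self.objects:
            obj[1] += spec.fall_rate
            if obj[1] >= spec.grid_h - 1:
                # object reaches the bottom row: caught iff columns align;
                # caught or not, it is removed from play
                if obj[2] == self.agent_col and obj[0] == self.rewarded_identity:
                    reward += 1.0
                continue
            surviving.append(obj)
        self.objects = surviving
        self.t += 1
        if self.t % spec.spawn_interval == 0:
            identity = int(
                self.active_identities[
                    self._rng.integers(len(self.active_identities))
                ]
            )
            col = int(self._rng.integers(spec.grid_w))
            self.objects.append([identity, 0, col])
        return reward, self.t >= spec.episode_length


def spawn_columns_reachable(spec: OCTaskSpec) -> bool:
    """Breadth-first check that every spawn column is catchable.

    From any starting column, the agent (moving one column per step) must be
    able to occupy any other column within the number of steps an object
    takes to fall from the top row to the bottom row.  This guarantees the
    ceiling reward of the game is positive for every spawn.
    """
    fall_steps = (spec.grid_h - 1 + spec.fall_rate - 1) // spec.fall_rate
    for start in range(spec.grid_w):
        reached = {start}
        frontier = {start}
        for _ in range(fall_steps):
            frontier = {
                int(np.clip(c + d, 0, spec.grid_w - 1))
                for c in frontier
                for d in (-1, 1)
            }
            reached |= frontier
        if len(reached) < spec.grid_w:
            return False
    return True
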