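"""Value-function learners that consume attended features.

Two learners expose the ``V(s; A)`` contract the particle filter scores
particles against:

* :class:`MonteCarloValueNet` — an epsilon-greedy one-step Monte-Carlo value
  network trained with RMSProp (multiple-choice task);
* :class:`A2CLearner` — an advantage actor-critic with a shared rectified
  trunk, separate policy/value heads, entropy regularisation and Adam
  (object-collection game).

Both are plain single-hidden-layer networks written directly on numpy
arrays.  Particle scoring uses frozen forward passes only (``evaluate`` /
``evaluate_batch`` never touch parameters); the batched path lets the filter
score all unique particle states with one matmul.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    AttentionVector,
    ContractError,
    FeatureTensor,
    apply_attention,
)

__all__ = [
    "ValueLearnerConfig",
    "Transition",
    "NStepReturn",
    "MonteCarloValueNet",
    "A2CLearner",
    "SubsetOracleValue",
    "select_action_egreedy",
    "compute_nstep_return",
]


@dataclass(frozen=True)
class ValueLearnerConfig:
    """Learner hyper-parameters.

    Defaults: the Monte-Carlo value net uses epsilon=0.2 exploration and
    RMSProp with learning rate 0.00025, moving-average momentum kappa=0.95
    and denominator constant iota=0.01; the actor-critic uses entropy
    strength beta=0.01, discount gamma=0.99, frame skip m=8 and Adam with
    learning rate alpha=0.0001.
    """

    variant: str = "monte_carlo"
    epsilon: float = 0.2
    lr: float = 0.00025
    rmsprop_momentum: float = 0.95
    rmsprop_eps: float = 0.01
    entropy_beta: float = 0.01
    gamma: float = 0.99
    frame_skip: int = 8
    adam_lr: float = 0.0001
    hidden_units: int = 256

    def __post_init__(self) -> None:
        if self.variant not in ("monte_carlo", "a2c"):
            raise ContractError("variant must be 'monte_carlo' or 'a2c'")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ContractError("epsilon must lie in [0, 1]")
        if self.hidden_units < 1:
            raise ContractError("hidden_units must be positive")


@dataclass(frozen=True)
class Transition:
    """One environment step: features, chosen action, reward, next features.

    ``next_features`` is ``None`` when the step ended the episode.
    """

    features: FeatureTensor
    action: int
    reward: float
    next_features: Optional[FeatureTensor]


@dataclass(frozen=True)
class NStepReturn:
    """A discounted n-step return with the features that opened its window."""

    return_value: float
    length: int
    start_features: Optional[FeatureTensor] = None


def compute_nstep_return(
    rewards: Sequence[float],
    bootstrap_value: Optional[float],
    gamma: float,
    t_max: int,
    start_features: Optional[FeatureTensor] = None,
) -> NStepReturn:
    """``R = sum_i gamma^i r_i + gamma^n * bootstrap`` (bootstrap 0 if terminal)."""
    n = len(rewards)
    if n < 1:
        raise ContractError("rewards must contain at least one entry")
    if n > t_max:
        raise ContractError(f"return window length {n} exceeds t_max={t_max}")
    discounts = gamma ** np.arange(n)
    r = float(discounts @ np.asarray(rewards, dtype=float))
    if bootstrap_value is not None:
        r += float(gamma**n * bootstrap_value)
    return NStepReturn(return_value=r, length=n, start_features=start_features)


def select_action_egreedy(
    values: Sequence[float], epsilon: float, rng: np.random.Generator
) -> int:
    """Argmax with probability 1-epsilon (uniform among exact ties), else uniform."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ContractError("no candidate actions")
    if rng.random() < epsilon:
        return int(rng.integers(v.size))
    ties = np.flatnonzero(v == v.max())
    return int(ties[rng.integers(ties.size)])


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def _flat_batch(features: FeatureTensor, weight_matrix: np.ndarray) -> np.ndarray:
    """Attended inputs for a batch of attention vectors: (U, K*H*W)."""
    k = features.n_channels
    flat = features.values.reshape(k, -1)
    return (weight_matrix[:, :, None] * flat[None, :, :]).reshape(
        weight_matrix.shape[0], -1
    )


class MonteCarloValueNet:
    """Single-hidden-layer value network trained by one-step Monte-Carlo backup.

    The network maps flattened attended features to a scalar value; each
    update is one RMSProp step on the squared error between the predicted
    value of the chosen stimulus and the reward actually obtained.
    """

    def __init__(
        self,
        K: int,
        spatial_shape: tuple[int, int] = (1, 1),
        config: Optional[ValueLearnerConfig] = None,
        seed: int = 0,
    ) -> None:
        self.config = config or ValueLearnerConfig(variant="monte_carlo")
        if self.config.variant != "monte_carlo":
            raise ContractError("MonteCarloValueNet requires variant='monte_carlo'")
        self.K = K
        self.spatial_shape = tuple(spatial_shape)
        d = K * spatial_shape[0] * spatial_shape[1]
        h = self.config.hidden_units
        rng = np.random.default_rng(seed)
        self.params = {
            "W1": _he_init(rng, d, (d, h)),
            "b1": np.zeros(h),
            "w2": np.zeros(h),
            "b2": np.zeros(1),
        }
        self._sq = {k: np.zeros_like(v) for k, v in self.params.items()}

    # -- frozen forward passes (the V(s; A) contract) -----------------------

    def evaluate(self, features: FeatureTensor, attention: AttentionVector) -> float:
        x = apply_attention(features, attention).reshape(-1)
        h = np.maximum(x @ self.params["W1"] + self.params["b1"], 0.0)
        return float(h @ self.params["w2"] + self.params["b2"][0])

    __call__ = evaluate

    def evaluate_batch(
        self, features: FeatureTensor, weight_matrix: np.ndarray
    ) -> np.ndarray:
        x = _flat_batch(features, np.asarray(weight_matrix, dtype=float))
        h = np.maximum(x @ self.params["W1"] + self.params["b1"], 0.0)
        return h @ self.params["w2"] + self.params["b2"][0]

    # -- training -----------------------------------------------------------

    def mc_update(
        self, features: FeatureTensor, attention: AttentionVector, reward: float
    ) -> float:
        """One RMSProp step on ``(reward - V)^2``; returns the pre-update loss."""
        p = self.params
        x = apply_attention(features, attention).reshape(-1)
        z = x @ p["W1"] + p["b1"]
        h = np.maximum(z, 0.0)
        v = float(h @ p["w2"] + p["b2"][0])
        dv = 2.0 * (v - reward)
        grads = {
            "w2": dv * h,
            "b2": np.array([dv]),
        }
        dh = dv * p["w2"]
        dz = dh * (z > 0)
        grads["W1"] = np.outer(x, dz)
        grads["b1"] = dz
        cfg = self.config
        for name, g in grads.items():
            s = self._sq[name]
            s *= cfg.rmsprop_momentum
            s += (1.0 - cfg.rmsprop_momentum) * g * g
            p[name] -= cfg.lr * g / np.sqrt(s + cfg.rmsprop_eps)
        return (reward - v) ** 2

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        np.savez_compressed(path, **self.params, **{f"sq_{k}": v for k, v in self._sq.items()})

    def load(self, path) -> None:
        with np.load(path) as data:
            for k in self.params:
                self.params[k] = data[k]
                self._sq[k] = data[f"sq_{k}"]


class A2CLearner:
    """Advantage actor-critic on attended features.

    A shared rectified trunk feeds separate policy and value heads.  One
    update consumes a trajectory segment of at most ``t_max`` transitions and
    takes a single Adam step on the summed policy-gradient loss (advantage
    ``R - V`` detached), value regression ``0.5 (R - V)^2`` and entropy bonus
    ``-beta * H(pi)``.  Heads are zero-initialised so the initial policy is
    uniform and the initial value is exactly zero.
    """

    def __init__(
        self,
        K: int,
        spatial_shape: tuple[int, int] = (1, 1),
        n_actions: int = 2,
        config: Optional[ValueLearnerConfig] = None,
        seed: int = 0,
    ) -> None:
        self.config = config or ValueLearnerConfig(variant="a2c")
        if self.config.variant != "a2c":
            raise ContractError("A2CLearner requires variant='a2c'")
        self.K = K
        self.spatial_shape = tuple(spatial_shape)
        self.n_actions = n_actions
        d = K * spatial_shape[0] * spatial_shape[1]
        h = self.config.hidden_units
        rng = np.random.default_rng(seed)
        self.params = {
            "W1": _he_init(rng, d, (d, h)),
            "b1": np.zeros(h),
            "Wp": np.zeros((h, n_actions)),
            "bp": np.zeros(n_actions),
            "wv": np.zeros(h),
            "bv": np.zeros(1),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- frozen forward passes ----------------------------------------------

    def _forward(self, x: np.ndarray):
        p = self.params
        z = x @ p["W1"] + p["b1"]
        h = np.maximum(z, 0.0)
        logits = h @ p["Wp"] + p["bp"]
        logits = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=-1, keepdims=True)
        value = h @ p["wv"] + p["bv"][0]
        return z, h, probs, value

    def policy(self, features: FeatureTensor, attention: AttentionVector) -> np.ndarray:
        x = apply_attention(features, attention).reshape(-1)
        return self._forward(x)[2]

    def act(
        self,
        features: FeatureTensor,
        attention: AttentionVector,
        rng: np.random.Generator,
    ) -> int:
        probs = self.policy(features, attention)
        return int(rng.choice(self.n_actions, p=probs))

    def evaluate(self, features: FeatureTensor, attention: AttentionVector) -> float:
        x = apply_attention(features, attention).reshape(-1)
        return float(self._forward(x)[3])

    __call__ = evaluate

    def evaluate_batch(
        self, features: FeatureTensor, weight_matrix: np.ndarray
    ) -> np.ndarray:
        x = _flat_batch(features, np.asarray(weight_matrix, dtype=float))
        return np.asarray(self._forward(x)[3], dtype=float)

    # -- training -----------------------------------------------------------

    def a2c_update(
        self,
        trajectory: Sequence[Transition],
        attention,
        return_attention_grads: bool = False,
    ):
        """One Adam step on a trajectory segment.

        ``attention`` is either a single :class:`AttentionVector` used for
        every step or a sequence with one vector per transition (the
        self-attention baseline recomputes attention each step).  With
        ``return_attention_grads=True`` the per-step gradients of the total
        loss with respect to the attention weights are returned so an
        attention module can be trained through the same loss.
        """
        cfg = self.config
        n = len(trajectory)
        if n < 1:
            raise ContractError("trajectory must contain at least one transition")
        if isinstance(attention, AttentionVector):
            attns = [attention] * n
        else:
            attns = list(attention)
            if len(attns) != n:
                raise ContractError("one attention vector per transition required")

        xs = np.stack(
            [
                apply_attention(t.features, a).reshape(-1)
                for t, a in zip(trajectory, attns)
            ]
        )
        z, h, probs, values = self._forward(xs)

        # n-step returns to the segment end, bootstrapped with a frozen
        # value estimate of the state after the last transition.
        last = trajectory[-1]
        if last.next_features is None:
            r = 0.0
        else:
            r = self.evaluate(last.next_features, attns[-1])
        returns = np.empty(n)
        for i in range(n - 1, -1, -1):
            r = trajectory[i].reward + cfg.gamma * r
            returns[i] = r

        adv = returns - values  # detached: used as a constant in the policy loss
        actions = np.array([t.action for t in trajectory])
        onehot = np.zeros((n, self.n_actions))
        onehot[np.arange(n), actions] = 1.0

        logp = np.log(np.clip(probs, 1e-12, None))
        entropy = -(probs * logp).sum(axis=1)
        # d/dlogits of [-logpi(a) * adv] + [-beta * H]
        dlogits = (probs - onehot) * adv[:, None] + cfg.entropy_beta * probs * (
            logp + entropy[:, None]
        )
        dvalue = values - returns  # d/dV of 0.5 (R - V)^2

        p = self.params
        grads = {
            "Wp": h.T @ dlogits,
            "bp": dlogits.sum(axis=0),
            "wv": h.T @ dvalue,
            "bv": np.array([dvalue.sum()]),
        }
        dh = dlogits @ p["Wp"].T + dvalue[:, None] * p["wv"][None, :]
        dz = dh * (z > 0)
        grads["W1"] = xs.T @ dz
        grads["b1"] = dz.sum(axis=0)

        attn_grads = None
        if return_attention_grads:
            dxs = dz @ p["W1"].T
            attn_grads = []
            for i, t in enumerate(trajectory):
                dx = dxs[i].reshape(t.features.values.shape)
                attn_grads.append((dx * t.features.values).sum(axis=(1, 2)))

        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for name, g in grads.items():
            m = self._adam_m[name]
            v = self._adam_v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            p[name] -= cfg.adam_lr * mhat / (np.sqrt(vhat) + eps)

        if return_attention_grads:
            return attn_grads
        return None

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        np.savez_compressed(path, adam_t=self._adam_t, **self.params)

    def load(self, path) -> None:
        with np.load(path) as data:
            self._adam_t = int(data["adam_t"])
            for k in self.params:
                self.params[k] = data[k]


class SubsetOracleValue:
    """Diagnostic value function that knows the task-relevant channel subset.

    Predicts the return as the attention mass on the relevant subset ``S``,
    gated by whether the observed stimulus carries that subset's signature
    (mean activation on ``S`` clearly above the typical channel level).  Used
    to test the particle filter in isolation from value learning: a particle
    whose support lies inside ``S`` predicts the +1 return of a target
    stimulus perfectly, and every particle correctly predicts 0 for
    non-target stimuli.
    """

    def __init__(self, target_channels: Sequence[int], K: int) -> None:
        self.K = K
        self.target_channels = np.asarray(sorted(target_channels), dtype=int)

    def retarget(self, target_channels: Sequence[int]) -> None:
        self.target_channels = np.asarray(sorted(target_channels), dtype=int)

    def _signature(self, features: FeatureTensor) -> float:
        m = features.channel_means
        off = np.delete(m, self.target_channels)
        baseline = off.mean() if off.size else 0.0
        return 1.0 if m[self.target_channels].mean() > 2.0 * baseline + 1e-12 else 0.0

    def evaluate(self, features: FeatureTensor, attention: AttentionVector) -> float:
        mass = float(attention.weights[self.target_channels].sum())
        return mass * self._signature(features)

    __call__ = evaluate

    def evaluate_batch(
        self, features: FeatureTensor, weight_matrix: np.ndarray
    ) -> np.ndarray:
        mass = np.asarray(weight_matrix, dtype=float)[:, self.target_channels].sum(
            axis=1
        )
        return mass * self._signature(features)
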