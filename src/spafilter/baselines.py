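"""Comparison attention sources.

* ``all_attention`` — the uniform 1/K vector: attend to every channel
  equally (the "attend to everything" control).
* ``random_attention`` — a fixed random binary subset of channels,
  normalised; frozen for the whole run (controls for the benefit of random
  dimensionality reduction).
* ``ideal_observer_choice`` — ceiling policy for the multiple-choice task:
  pick the stimulus of the most recently rewarded category, with
  epsilon-exploration.  It reads category labels and reward history only,
  never feature values.
* :class:`SelfAttentionHead` — a single query/key soft-attention head over
  channel means, trained by backpropagation through the downstream
  learner's loss; the gradient-based alternative to the particle filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import AttentionVector, ContractError, FeatureTensor

__all__ = [
    "SelfAttentionConfig",
    "all_attention",
    "random_attention",
    "ideal_observer_choice",
    "SelfAttentionHead",
]


def all_attention(K: int) -> AttentionVector:
    """Uniform attention: every channel weighted 1/K, constant over the run."""
    if K < 1:
        raise ContractError("K must be positive")
    return AttentionVector.uniform(K)


def random_attention(K: int, seed: int) -> AttentionVector:
    """A fixed random binary channel subset, normalised to sum to one.

    Entries are i.i.d. Bernoulli(0.5); an all-zero draw is redrawn so the
    normalisation is always defined.  The vector is a function of the seed
    alone and stays frozen for the whole run.
    """
    if K < 1:
        raise ContractError("K must be positive")
    rng = np.random.default_rng([seed, 301])
    while True:
        bits = (rng.random(K) < 0.5).astype(float)
        if bits.sum() > 0:
            return AttentionVector.from_unnormalized(bits)


def ideal_observer_choice(
    screen_categories: Sequence[int],
    last_rewarded_category: Optional[int],
    epsilon: float,
    rng: np.random.Generator,
) -> int:
    """Pick the position showing the last rewarded category (epsilon-greedy).

    Before any reward has been observed the choice is uniform.  This
    baseline sees only category labels — an information ceiling, not a
    feature-based agent.
    """
    n = len(screen_categories)
    if n == 0:
        raise ContractError("no stimuli on screen")
    if last_rewarded_category is None or rng.random() < epsilon:
        return int(rng.integers(n))
    for i, c in enumerate(screen_categories):
        if c == last_rewarded_category:
            return i
    return int(rng.integers(n))


@dataclass(frozen=True)
class SelfAttentionConfig:
    """Query/key dimensionality and optimiser settings for the learned head."""

    d: int = 128
    lr: float = 0.0001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ContractError("d must be >= 1")


class SelfAttentionHead:
    """One scaled dot-product attention head over channel means.

    The query ``q = Wq m`` is a learned linear map of the K channel means
    ``m``; channel ``j`` contributes a key ``k_j = m_j E_j`` through its own
    learned embedding row.  Attention is ``softmax(q . k_j / sqrt(d))`` —
    a K-vector summing to one, applied to features exactly like the particle
    filter's vector.  Parameters are trained by backpropagating the
    downstream RL loss through the attention weights (``train_step`` takes
    ``dLoss/dA``) with Adam.

    Zero parameter maps give exactly uniform attention; the default
    initialisation is small random values because the bilinear form has zero
    gradient at the all-zero point.
    """

    def __init__(self, K: int, config: Optional[SelfAttentionConfig] = None) -> None:
        self.K = K
        self.config = config or SelfAttentionConfig()
        d = self.config.d
        rng = np.random.default_rng([self.config.seed, 303])
        self.params = {
            "Wq": 0.01 * rng.standard_normal((d, K)),
            "E": 0.01 * rng.standard_normal((K, d)),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def attention(self, features: FeatureTensor) -> AttentionVector:
        return self._forward(features)[0]

    def _forward(self, features: FeatureTensor):
        m = features.channel_means
        q = self.params["Wq"] @ m
        keys = m[:, None] * self.params["E"]
        logits = keys @ q / np.sqrt(self.config.d)
        logits = logits - logits.max()
        e = np.exp(logits)
        probs = e / e.sum()
        return AttentionVector(probs), (m, q, keys, probs)

    def _backward(self, cache, dA: np.ndarray) -> dict[str, np.ndarray]:
        m, q, keys, probs = cache
        dlogits = probs * (dA - float(probs @ dA))  # softmax jacobian-vector
        scale = 1.0 / np.sqrt(self.config.d)
        dq = scale * (keys.T @ dlogits)
        dkeys = scale * np.outer(dlogits, q)
        return {
            "Wq": np.outer(dq, m),
            "E": m[:, None] * dkeys,
        }

    def train_step(
        self,
        features_list: Sequence[FeatureTensor],
        attention_grads: Sequence[np.ndarray],
    ) -> None:
        """One Adam step on accumulated ``dLoss/dA`` gradients.

        ``attention_grads[i]`` is the gradient of the downstream loss with
        respect to the attention weights emitted for ``features_list[i]``.
        """
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        for features, dA in zip(features_list, attention_grads):
            _, cache = self._forward(features)
            for name, g in self._backward(cache, np.asarray(dA, dtype=float)).items():
                grads[name] += g
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for name, g in grads.items():
            mm = self._adam_m[name]
            vv = self._adam_v[name]
            mm *= b1
            mm += (1 - b1) * g
            vv *= b2
            vv += (1 - b2) * g * g
            self.params[name] -= (
                self.config.lr
                * (mm / (1 - b1**t))
                / (np.sqrt(vv / (1 - b2**t)) + eps)
            )
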