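"""Particle-filter inference of a soft attention vector over feature channels.

The filter maintains ``N`` binary particles, each a hypothesis about which of
``K`` feature channels are useful for the task at hand.  Each update applies,
in order:

1. a *movement* step — a fraction ``phi`` of particles is redrawn toward the
   currently most active channels (bottom-up attention, strength ``tau_bu``);
2. an *observation* step — each particle is scored by how well the value
   function, evaluated under that particle's normalised state as the
   attention vector, predicts the observed return (top-down attention,
   strength ``tau_td``);
3. multinomial *resampling* with replacement proportional to those scores;
4. the emitted attention vector is the mean of the particle states,
   normalised to sum to one.

All randomness flows through the ensemble's own ``numpy`` Generator so runs
are bit-reproducible given ``SPAConfig.seed``.  Scheduling (how often the
caller invokes :func:`update_attention`, gated by ``c_max``) lives in the
experiment loop; this module is purely functional over its inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DegenerateInputError",
    "ContractError",
    "SPAConfig",
    "AttentionVector",
    "FeatureTensor",
    "ReturnObservation",
    "ParticleEnsemble",
    "init_ensemble",
    "bottom_up_probs",
    "movement_step",
    "particle_attention",
    "particle_errors",
    "resampling_weights",
    "resample",
    "ensemble_attention",
    "update_attention",
    "apply_attention",
    "ensemble_to_csv",
    "attention_to_csv",
    "save_ensemble",
    "load_ensemble",
]

# exp() underflows to an exact 0.0 below ~-745; clip well before that so
# weight ratios are monotone down to ~1e-304 and never produce NaNs.
_EXP_CLIP = -700.0


class ConfigurationError(ValueError):
    """Invalid filter configuration (non-positive counts, phi outside [0,1])."""


class DegenerateInputError(ValueError):
    """An input with no usable signal (e.g. all-zero channel means)."""


class ContractError(ValueError):
    """A caller violated an operation's precondition (shapes, normalisation)."""


@dataclass(frozen=True)
class SPAConfig:
    """Hyper-parameters of the particle-filter attention mechanism.

    Parameters
    ----------
    K:
        Number of feature channels the attention vector gates.
    N:
        Number of particles (default 250).
    tau_bu:
        Bottom-up strength: sharpness of the movement-step refresh toward
        currently active channels.  0 makes every channel equally likely.
    tau_td:
        Top-down strength: how strongly inaccurate return predictions are
        penalised during resampling.  0 gives uniform resampling weights.
    phi:
        Per-update probability that a given particle is redrawn in the
        movement step.
    c_max:
        Attention-update period, in environment steps: the caller invokes
        one filter update every ``c_max`` steps.
    t_max:
        Maximum length (in steps) of the return window scored in the
        observation step.
    seed:
        Seed for the ensemble's random stream.
    p_init:
        Bernoulli parameter for the initial i.i.d. particle states.
    zero_particle_fallback:
        How an all-zero particle state is turned into an attention vector:
        ``"uniform"`` maps it to 1/K everywhere; ``"redraw"`` additionally
        redraws all-zero particles once from the movement distribution
        during updates.
    obs_buffer:
        Number of recent return windows a particle is scored against per
        update.  1 scores the single most recent window; larger values
        average the squared error over a buffer of windows, denoising the
        likelihood when individual returns are dominated by environment
        stochasticity (useful when updates are infrequent, ``c_max`` large).
    """

    K: int
    N: int = 250
    tau_bu: float = 10.0
    tau_td: float = 10.0
    phi: float = 0.1
    c_max: int = 1
    t_max: int = 1
    seed: int = 0
    p_init: float = 0.5
    zero_particle_fallback: str = "uniform"
    obs_buffer: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise ConfigurationError(f"K must be a positive integer, got {self.K!r}")
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ConfigurationError(f"N must be a positive integer, got {self.N!r}")
        if not 0.0 <= self.phi <= 1.0:
            raise ConfigurationError(f"phi must lie in [0, 1], got {self.phi!r}")
        if self.tau_bu < 0 or self.tau_td < 0:
            raise ConfigurationError("tau_bu and tau_td must be nonnegative")
        if self.c_max < 1 or self.t_max < 1:
            raise ConfigurationError("c_max and t_max must be positive integers")
        if not 0.0 <= self.p_init <= 1.0:
            raise ConfigurationError("p_init must lie in [0, 1]")
        if self.zero_particle_fallback not in ("uniform", "redraw"):
            raise ConfigurationError(
                "zero_particle_fallback must be 'uniform' or 'redraw'"
            )
        if self.obs_buffer < 1:
            raise ConfigurationError("obs_buffer must be a positive integer")

    @classmethod
    def multiple_choice(cls, K: int, seed: int = 0, **overrides) -> "SPAConfig":
        """Preset for the multiple-choice task: tau_bu=10, update every trial."""
        kw = dict(N=250, tau_bu=10.0, tau_td=10.0, c_max=1, t_max=1, seed=seed)
        kw.update(overrides)
        return cls(K=K, **kw)

    @classmethod
    def object_collection(cls, K: int, seed: int = 0, **overrides) -> "SPAConfig":
        """Preset for the object-collection game: tau_bu=1, update every 1000 steps."""
        kw = dict(N=250, tau_bu=1.0, tau_td=10.0, c_max=1000, t_max=10, seed=seed)
        kw.update(overrides)
        return cls(K=K, **kw)


@dataclass(frozen=True)
class AttentionVector:
    """Nonnegative weights over K channels, summing to one."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1:
            raise ContractError("attention weights must be one-dimensional")
        if np.any(w < 0):
            raise ContractError("attention weights must be nonnegative")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ContractError(
                f"attention weights must sum to 1 (got {float(w.sum())!r})"
            )

    def __len__(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def uniform(cls, K: int) -> "AttentionVector":
        return cls(np.full(K, 1.0 / K))

    @classmethod
    def from_unnormalized(cls, values: np.ndarray) -> "AttentionVector":
        """Normalise nonnegative values to sum 1; an all-zero input maps to uniform."""
        v = np.asarray(values, dtype=float)
        total = float(v.sum())
        if total <= 0.0:
            return cls.uniform(v.shape[0])
        return cls(v / total)

    @property
    def entropy(self) -> float:
        """Shannon entropy (nats) of the weight distribution."""
        w = self.weights[self.weights > 0]
        return float(-(w * np.log(w)).sum())


@dataclass(frozen=True)
class FeatureTensor:
    """K channels of nonnegative activations on an H x W grid (H=W=1 for vectors)."""

    values: np.ndarray
    channel_means: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None, None]
        if v.ndim != 3:
            raise ContractError(
                f"feature values must be K x H x W (got ndim={v.ndim})"
            )
        if np.any(v < 0):
            raise ContractError("feature activations must be nonnegative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channel_means", v.mean(axis=(1, 2)))

    @classmethod
    def from_vector(cls, values: np.ndarray) -> "FeatureTensor":
        return cls(np.asarray(values, dtype=float)[:, None, None])

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


@dataclass(frozen=True)
class ReturnObservation:
    """A (start-state features, scalar return) pair used to score particles."""

    start_features: FeatureTensor
    return_value: float


@dataclass
class ParticleEnsemble:
    """N binary hypothesis vectors of length K plus the filter's random stream."""

    states: np.ndarray
    rng: np.random.Generator

    def __post_init__(self) -> None:
        s = np.asarray(self.states)
        if s.ndim != 2:
            raise ContractError("particle states must be an N x K array")
        if not np.isin(s, (0, 1)).all():
            raise ContractError("particle states must be binary")
        self.states = s.astype(np.uint8)

    @property
    def n_particles(self) -> int:
        return self.states.shape[0]

    @property
    def n_channels(self) -> int:
        return self.states.shape[1]


def init_ensemble(config: SPAConfig) -> ParticleEnsemble:
    """Draw an N x K ensemble of i.i.d. Bernoulli(p_init) particle states."""
    rng = np.random.default_rng(config.seed)
    states = (rng.random((config.N, config.K)) < config.p_init).astype(np.uint8)
    return ParticleEnsemble(states=states, rng=rng)


def bottom_up_probs(channel_means: np.ndarray, tau_bu: float) -> np.ndarray:
    """Per-channel Bernoulli parameters for the movement-step redraw.

    Channel means are normalised to sum to one, exponentiated at strength
    ``tau_bu`` and divided by the maximum, so the most active channel always
    has probability exactly 1 and every probability lies in (0, 1].
    """
    m = np.asarray(channel_means, dtype=float)
    total = float(m.sum())
    if total <= 0.0:
        raise DegenerateInputError("all channel means are zero")
    v = m / total
    return np.exp(np.clip((v - v.max()) * tau_bu, _EXP_CLIP, 0.0))


def movement_step(
    ensemble: ParticleEnsemble, probs: np.ndarray, phi: float
) -> ParticleEnsemble:
    """Redraw each particle with probability ``phi`` from Bernoulli(``probs``).

    A selected particle has *all* K entries redrawn; unselected particles are
    untouched.  ``phi = 0`` returns the ensemble unchanged (same rng draws
    are still consumed for the selection mask, keeping streams aligned).
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (ensemble.n_channels,):
        raise ContractError("probs must have length K")
    if np.any((p < 0) | (p > 1)):
        raise ContractError("probs must lie in [0, 1]")
    selected = ensemble.rng.random(ensemble.n_particles) < phi
    states = ensemble.states.copy()
    n_sel = int(selected.sum())
    if n_sel:
        draws = ensemble.rng.random((n_sel, ensemble.n_channels)) < p
        states[selected] = draws.astype(np.uint8)
    return replace(ensemble, states=states)


def particle_attention(state: np.ndarray) -> AttentionVector:
    """Normalise one binary particle state into an attention vector.

    An all-zero state maps to the uniform vector 1/K, which keeps the
    particle's likelihood defined and matches attend-to-everything semantics.
    """
    return AttentionVector.from_unnormalized(np.asarray(state, dtype=float))


def particle_errors(
    ensemble: ParticleEnsemble, obs: ReturnObservation, value_fn
) -> np.ndarray:
    """Squared return-prediction error of every particle.

    ``value_fn`` follows the contract ``(FeatureTensor, AttentionVector) ->
    float``; the value function is evaluated at most once per *unique*
    particle state (duplicate rows produced by resampling share one
    evaluation).  If ``value_fn`` exposes an ``evaluate_batch(features,
    weight_matrix)`` method it is called once with the stacked unique
    attention vectors instead.
    """
    uniq, inverse = np.unique(ensemble.states, axis=0, return_inverse=True)
    atts = np.empty((uniq.shape[0], ensemble.n_channels))
    for i, row in enumerate(uniq):
        atts[i] = particle_attention(row).weights
    batch = getattr(value_fn, "evaluate_batch", None)
    if batch is not None:
        preds = np.asarray(batch(obs.start_features, atts), dtype=float)
    else:
        preds = np.array(
            [float(value_fn(obs.start_features, AttentionVector(a))) for a in atts]
        )
    deltas = (obs.return_value - preds) ** 2
    return deltas[inverse]


def resampling_weights(errors: np.ndarray, tau_td: float) -> np.ndarray:
    """Normalised resampling weights ``w_i \\propto exp(-(d_i - min_j d_j) * tau_td)``.

    Any argmin particle attains the maximal weight; weights are monotonically
    nonincreasing in the error.  ``tau_td = 0`` yields uniform weights.
    """
    d = np.asarray(errors, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ContractError("errors must be finite")
    w = np.exp(np.clip(-(d - d.min()) * tau_td, _EXP_CLIP, 0.0))
    return w / w.sum()


def resample(ensemble: ParticleEnsemble, weights: np.ndarray) -> ParticleEnsemble:
    """Multinomial resampling with replacement: N i.i.d. index draws."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (ensemble.n_particles,):
        raise ContractError("weights must have length N")
    if abs(float(w.sum()) - 1.0) > 1e-8:
        raise ContractError("weights must sum to 1")
    idx = ensemble.rng.choice(ensemble.n_particles, size=ensemble.n_particles, p=w)
    return replace(ensemble, states=ensemble.states[idx].copy())


def ensemble_attention(ensemble: ParticleEnsemble) -> AttentionVector:
    """Mean of the particle states, normalised to sum to one."""
    return AttentionVector.from_unnormalized(ensemble.states.mean(axis=0))


def update_attention(
    ensemble: ParticleEnsemble,
    current: FeatureTensor,
    obs,
    value_fn,
    config: SPAConfig,
) -> tuple[ParticleEnsemble, AttentionVector]:
    """One full filter update: movement, observation, resampling, mean.

    ``current`` supplies the channel means driving the bottom-up movement
    step (the feature snapshot at the update step); ``obs`` is the most
    recently completed return window, or a sequence of recent windows whose
    squared errors are averaged per particle (``config.obs_buffer`` caps how
    many are used).  If the current features carry no signal at all, the
    movement redraw falls back to all-ones probabilities (every channel
    equally, and maximally, likely).
    """
    if isinstance(obs, ReturnObservation):
        obs_list = [obs]
    else:
        obs_list = list(obs)[-config.obs_buffer :]
        if not obs_list:
            raise ContractError("at least one return observation required")
    try:
        probs = bottom_up_probs(current.channel_means, config.tau_bu)
    except DegenerateInputError:
        probs = np.ones(config.K)
    ens = movement_step(ensemble, probs, config.phi)
    if config.zero_particle_fallback == "redraw":
        dead = ens.states.sum(axis=1) == 0
        n_dead = int(dead.sum())
        if n_dead:
            states = ens.states.copy()
            states[dead] = (
                ens.rng.random((n_dead, config.K)) < probs
            ).astype(np.uint8)
            ens = replace(ens, states=states)
    deltas = np.mean(
        [particle_errors(ens, o, value_fn) for o in obs_list], axis=0
    )
    weights = resampling_weights(deltas, config.tau_td)
    ens = resample(ens, weights)
    return ens, ensemble_attention(ens)


def apply_attention(features: FeatureTensor, attention: AttentionVector) -> np.ndarray:
    """Gate features channel-wise: channel k is scaled by ``attention[k]``.

    The attention value is replicated across all spatial units of its
    channel, preserving the spatial layout; the result can be flattened into
    a single vector for a downstream learner.
    """
    if len(attention) != features.n_channels:
        raise ContractError(
            f"attention length {len(attention)} != channel count "
            f"{features.n_channels}"
        )
    return features.values * attention.weights[:, None, None]


# ---------------------------------------------------------------------------
# serialization


def ensemble_to_csv(ensemble: ParticleEnsemble, path) -> None:
    """One row per particle, one column per channel."""
    df = pd.DataFrame(
        ensemble.states,
        columns=[f"ch{k}" for k in range(ensemble.n_channels)],
    )
    df.insert(0, "particle", np.arange(ensemble.n_particles))
    df.to_csv(path, index=False)


def attention_to_csv(attention: AttentionVector, path) -> None:
    """One row per channel."""
    pd.DataFrame(
        {"channel": np.arange(len(attention)), "weight": attention.weights}
    ).to_csv(path, index=False)


def save_ensemble(ensemble: ParticleEnsemble, path) -> None:
    """Portable compressed snapshot (states + rng state) for resuming runs."""
    np.savez_compressed(
        path,
        states=ensemble.states,
        rng_state=np.frombuffer(
            json.dumps(ensemble.rng.bit_generator.state).encode(), dtype=np.uint8
        ),
    )


def load_ensemble(path) -> ParticleEnsemble:
    with np.load(path) as data:
        states = data["states"]
        state = json.loads(bytes(data["rng_state"]).decode())
    rng = np.random.default_rng()
    rng.bit_generator.state = state
    return ParticleEnsemble(states=states, rng=rng)
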