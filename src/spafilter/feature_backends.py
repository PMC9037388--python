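"""Synthetic feature tensors emulating convolutional feature-map statistics.

A pretrained convolutional network responds to an object category with a
characteristic per-channel activation profile: a handful of strongly active
discriminative channels on top of a shared background level.  The generator
here reproduces that structure with explicit control over how separable the
category profiles are (``signal_ratio``), how much the discriminative sets
overlap, and how noisy individual renders are (gamma noise, parameterised by
a coefficient of variation).  ``profile_distances`` gives the pairwise
Euclidean separation between category mean-profiles used to characterise
easy versus hard category combinations.

A real-CNN adapter interface is declared (:class:`FeatureExtractor`) for
feeding images through an actual pretrained network; no image pipeline is
shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import ContractError, FeatureTensor

__all__ = [
    "BackendSpec",
    "CategoryProfile",
    "FeatureExtractor",
    "make_profiles",
    "agent_profile",
    "render_stimulus",
    "render_scene",
    "profile_distances",
    "profiles_to_csv",
]


class FeatureExtractor(Protocol):
    """Adapter contract for a real pretrained CNN backend.

    Implementations accept an H x W x 3 image array and return a
    :class:`FeatureTensor` of K channel maps.  The synthetic generator below
    is the tested default; this protocol only fixes the boundary a real
    image pipeline would plug into.
    """

    def __call__(self, image: np.ndarray) -> FeatureTensor: ...


@dataclass(frozen=True)
class BackendSpec:
    """Configuration of the synthetic category-signature generator.

    ``n_discriminative`` channels per category sit at ``signal_ratio`` times
    the shared ``base_level``; all other (non-reserved) channels sit at
    ``off_ratio`` times the base level (1 gives the near-uniform profile
    shape of hard-to-separate categories; small values emulate selective
    channels that barely respond to non-preferred objects).  ``overlap`` is
    the probability that a discriminative channel is shared with a
    previously assigned category (0 gives fully disjoint sets).  Individual
    renders draw each unit from a gamma distribution with the profile's
    mean and coefficient of variation ``noise_cv``; empty scene cells use
    ``background_cv`` instead (defaults to ``noise_cv``; large values give
    the sporadic, heavy-tailed distractor activity of channels with no
    object present).  The last ``n_agent_channels`` channels are reserved
    for the agent signature in spatial scenes and never assigned to
    categories.
    """

    K: int = 32
    H: int = 1
    W: int = 1
    n_categories: int = 3
    n_discriminative: int = 2
    signal_ratio: float = 8.0
    overlap: float = 0.0
    noise_cv: float = 0.3
    base_level: float = 1.0
    off_ratio: float = 1.0
    scene_background: float = 0.1
    background_cv: Optional[float] = None
    n_agent_channels: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        free = self.K - self.n_agent_channels
        if self.overlap == 0.0 and self.n_discriminative * self.n_categories > free:
            raise ContractError(
                "disjoint discriminative sets need "
                f"{self.n_discriminative * self.n_categories} channels but only "
                f"{free} are available"
            )
        if self.signal_ratio < 1.0:
            raise ContractError("signal_ratio must be >= 1")
        if not 0.0 <= self.overlap <= 1.0:
            raise ContractError("overlap must lie in [0, 1]")
        if self.noise_cv < 0.0:
            raise ContractError("noise_cv must be nonnegative")
        if not 0.0 <= self.off_ratio <= 1.0:
            raise ContractError("off_ratio must lie in [0, 1]")


@dataclass(frozen=True)
class CategoryProfile:
    """A category's mean activation per channel and its discriminative set."""

    category: int
    mean_activations: np.ndarray
    discriminative_channels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def make_profiles(spec: BackendSpec) -> list[CategoryProfile]:
    """Draw one activation profile per category.

    Discriminative channels are sampled from the non-reserved channels —
    disjoint across categories when ``overlap`` is 0, otherwise each channel
    is taken from the already-used pool with probability ``overlap``.
    """
    rng = np.random.default_rng([spec.seed, 11])
    free = np.arange(spec.K - spec.n_agent_channels)
    unused = list(free)
    rng.shuffle(unused)
    used: list[int] = []
    profiles = []
    for c in range(spec.n_categories):
        chans: list[int] = []
        for _ in range(spec.n_discriminative):
            take_shared = used and rng.random() < spec.overlap
            if take_shared:
                pool = [k for k in used if k not in chans]
            else:
                pool = [k for k in unused if k not in chans]
            if not pool:
                pool = [k for k in free if k not in chans]
            k = int(pool[int(rng.integers(len(pool)))])
            chans.append(k)
            if k in unused:
                unused.remove(k)
            if k not in used:
                used.append(k)
        means = np.full(spec.K, spec.off_ratio * spec.base_level)
        means[chans] = spec.signal_ratio * spec.base_level
        profiles.append(
            CategoryProfile(
                category=c,
                mean_activations=means,
                discriminative_channels=np.array(sorted(chans), dtype=int),
            )
        )
    return profiles


def agent_profile(spec: BackendSpec) -> CategoryProfile:
    """Signature added at the agent's grid cell: reserved channels at signal level."""
    means = np.full(spec.K, spec.off_ratio * spec.base_level)
    chans = np.arange(spec.K - spec.n_agent_channels, spec.K)
    means[chans] = spec.signal_ratio * spec.base_level
    return CategoryProfile(
        category=-1, mean_activations=means, discriminative_channels=chans
    )


def _gamma_noise(
    means: np.ndarray, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Nonnegative noise with the requested means and coefficient of variation."""
    if cv == 0.0:
        return means.copy()
    shape = 1.0 / cv**2
    out = np.zeros_like(means)
    pos = means > 0
    out[pos] = means[pos] * cv**2 * rng.standard_gamma(shape, size=int(pos.sum()))
    return out


def render_stimulus(
    profile: CategoryProfile,
    spec: BackendSpec,
    rng: Optional[np.random.Generator] = None,
) -> FeatureTensor:
    """One noisy draw of a category stimulus on the spec's spatial grid."""
    if rng is None:
        rng = np.random.default_rng([spec.seed, 13, profile.category])
    means = np.broadcast_to(
        profile.mean_activations[:, None, None], (spec.K, spec.H, spec.W)
    ).copy()
    return FeatureTensor(_gamma_noise(means, spec.noise_cv, rng))


def render_scene(
    objects: Sequence[tuple[int, int, int]],
    agent_col: int,
    spec: BackendSpec,
    profiles: Sequence[CategoryProfile],
    rng: Optional[np.random.Generator] = None,
) -> FeatureTensor:
    """Spatial feature maps for a game frame.

    ``objects`` is a list of ``(identity, row, col)``; each object's profile
    replaces the background at its cell across all channels, so objects are
    visible as occupancy on every channel and identifiable on their
    discriminative channels.  The agent signature occupies the bottom row at
    ``agent_col``.  Empty cells carry only the low ``scene_background``
    level.
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, 17])
    means = np.full((spec.K, spec.H, spec.W), spec.scene_background)
    occupied = np.zeros((spec.H, spec.W), dtype=bool)
    for identity, row, col in objects:
        if not (0 <= row < spec.H and 0 <= col < spec.W):
            raise ContractError(f"object position ({row}, {col}) outside grid")
        means[:, row, col] += (
            profiles[identity].mean_activations - spec.scene_background
        )
        occupied[row, col] = True
    if agent_col is not None:
        if not 0 <= agent_col < spec.W:
            raise ContractError(f"agent column {agent_col} outside grid")
        means[:, spec.H - 1, agent_col] += (
            agent_profile(spec).mean_activations - spec.scene_background
        )
        occupied[spec.H - 1, agent_col] = True
    bg_cv = spec.noise_cv if spec.background_cv is None else spec.background_cv
    if bg_cv == spec.noise_cv:
        values = _gamma_noise(means, spec.noise_cv, rng)
    else:
        values = _gamma_noise(means, bg_cv, rng)
        if occupied.any():
            cols = np.flatnonzero(occupied.ravel())
            flat_means = means.reshape(spec.K, -1)[:, cols]
            values.reshape(spec.K, -1)[:, cols] = _gamma_noise(
                flat_means, spec.noise_cv, rng
            )
    return FeatureTensor(values)


def profile_distances(
    profiles: Sequence[CategoryProfile],
) -> tuple[np.ndarray, float]:
    """Pairwise Euclidean distances between mean profiles, and their mean.

    Returns the symmetric zero-diagonal distance matrix and the mean over
    all off-diagonal pairs.
    """
    if len(profiles) < 2:
        raise ContractError("need at least two profiles")
    vecs = np.stack([p.mean_activations for p in profiles])
    if len({v.shape for v in vecs}) > 1:
        raise ContractError("profiles must share the channel count")
    condensed = pdist(vecs, metric="euclidean")
    return squareform(condensed), float(condensed.mean())


def profiles_to_csv(profiles: Sequence[CategoryProfile], path) -> None:
    """Long-format dump: one row per (category, channel)."""
    rows = []
    for p in profiles:
        for k, m in enumerate(p.mean_activations):
            rows.append(
                {
                    "category": p.category,
                    "channel": k,
                    "mean": m,
                    "discriminative": int(k in p.discriminative_channels),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
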