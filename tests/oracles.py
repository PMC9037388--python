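"""Independent brute-force reference implementations.

Plain-Python/loop versions of every filter equation, kept deliberately
separate from the package's vectorised code paths so the two can be checked
against each other on small instances.
"""

import math


def bottom_up_probs_naive(means, tau_bu):
    total = sum(means)
    v = [m / total for m in means]
    vmax = max(v)
    return [math.exp((vi - vmax) * tau_bu) for vi in v]


def particle_attention_naive(state):
    s = sum(state)
    if s == 0:
        return [1.0 / len(state)] * len(state)
    return [x / s for x in state]


def particle_errors_naive(states, features, return_value, value_fn):
    """Per-particle squared error, evaluating the value function row by row."""
    out = []
    for state in states:
        att = particle_attention_naive(state)
        out.append((return_value - value_fn(features, att)) ** 2)
    return out


def resampling_weights_naive(errors, tau_td):
    dmin = min(errors)
    raw = [math.exp(-(d - dmin) * tau_td) for d in errors]
    total = sum(raw)
    return [w / total for w in raw]


def ensemble_attention_naive(states):
    n = len(states)
    k = len(states[0])
    mean = [sum(states[i][j] for i in range(n)) / n for j in range(k)]
    total = sum(mean)
    if total == 0:
        return [1.0 / k] * k
    return [m / total for m in mean]


def nstep_return_naive(rewards, bootstrap_value, gamma):
    r = 0.0
    for i, rew in enumerate(rewards):
        r += gamma**i * rew
    if bootstrap_value is not None:
        r += gamma ** len(rewards) * bootstrap_value
    return r


def apply_attention_naive(values, weights):
    """values: K x H x W nested lists; weights: length K."""
    return [
        [[weights[k] * u for u in row] for row in values[k]]
        for k in range(len(values))
    ]
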