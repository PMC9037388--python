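# spafilter

Selective particle attention: a particle filter that learns, from reward
feedback alone, which feature channels a reinforcement-learning agent
should attend to.

## The problem

Deep RL agents that act on pre-learned representations (for example the
512 feature maps of a pretrained convolutional network) still feed *every*
feature to the policy. That wastes capacity on irrelevant channels, slows
learning, and makes the learned function brittle when the task changes:
after a reward switch, the whole mapping has to be relearned by
backpropagation. Biological agents instead *select* a task-relevant subset
of existing features — selective attention — and re-select quickly when the
task changes.

`spafilter` implements a bio-inspired mechanism for this selection. A
sequential importance resampling filter maintains N = 250 binary particles
x ∈ {0,1}^K, each a hypothesis about which of the K channels matter. The
attention vector A (nonnegative, Σ A_k = 1) is the normalised particle
mean, applied to the features channel-wise:

* **movement** (bottom-up): with probability φ a particle is redrawn toward
  the currently most active channels, p_k = exp(τ_BU (v_k − v_max)) with v
  the normalised channel means;
* **observation** (top-down): each particle is scored by how well the value
  function predicts an observed return under that particle's attention,
  δ_i = (R − V(s; A_i))²;
* **resampling**: particles are redrawn with replacement with weights
  w_i ∝ exp(−τ_TD (δ_i − min_j δ_j)).

No gradient ever flows into the attention: the filter adapts within a
handful of reward observations, which is what makes it fast and flexible
compared to learned (self-)attention.

The package ships the filter (`spafilter.core`), numpy value learners — an
ε-greedy one-step Monte-Carlo value network and an advantage actor-critic
(`spafilter.value_models`) — a synthetic convolutional-feature generator
with controllable category separation (`spafilter.feature_backends`), the
two revaluation benchmarks (`spafilter.environments`), the comparison
attention sources including uniform, frozen-random and a trained
self-attention head (`spafilter.baselines`), and seeded experiment drivers
with a CLI (`spafilter.experiments`, `spafilter.cli`). Everything runs
from synthetic features; no images, downloads or pretrained weights are
involved.

## Worked example

Run the filter against an oracle value function that knows which two of 32
channels the rewarded category activates, then switch the target and watch
the attention move:

```python
import numpy as np
from spafilter import SPAConfig, experiments as exp

spec = exp.oracle_mc_spec(signal_ratio=8.0)          # 3 categories, K=32
cfg = SPAConfig.multiple_choice(spec.backend.K)      # N=250, tau_bu=tau_td=10
df = exp.run_mc_oracle(spec, cfg, n_trials=260, seed=0)

tgt = int(df.loc[199, "target"])
print("mass on rewarded channels after 200 trials:",
      round(df.loc[199, f"mass_cat{tgt}"], 3))
new = int(df.loc[200, "target"])
post = df[df["index"] >= 200]
cross = post[post[f"mass_cat{new}"] > post[f"mass_cat{tgt}"]]["index"].iloc[0]
print("trials to re-orient after the switch:", int(cross) - 200)
```

prints

```
mass on rewarded channels after 200 trials: 0.997
trials to re-orient after the switch: 3
```

After 200 trials the filter has moved 99.7% of the attention mass onto the
two channels that identify the rewarded category (uniform attention would
put 2/32 ≈ 6% there), and three trials after an unannounced target switch
the new target's channels already outweigh the old ones.

The benchmark comparisons run from the command line, e.g.

```bash
spafilter run-mc --condition spa  --out runs    # particle-filter attention
spafilter run-mc --condition all  --out runs    # attend to everything
spafilter run-oc --condition spa  --out runs    # object collection game
spafilter summarize runs/*.csv --revaluation-index 150
```

Each run writes a per-trial/per-episode CSV (reward, 20-episode rolling
reward, attention entropy, attention mass on the rewarded channels) plus a
manifest with the exact configuration.

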