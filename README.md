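# escapenav

Reinforcement-learning models and behavioral statistics for **escape-route
selection in mice**.

When a mouse on an elevated two-path arena is startled, it runs for the
shelter — and when the two paths differ in length or in initial angle to the
shelter, it reliably prefers the shorter, straighter one after only a few
minutes of spontaneous exploration. This package re-implements the
computational side of that finding for researchers in behavioral
neuroscience and reinforcement learning:

* **Grid worlds** — 50×50 occupancy-lattice versions of the experimental
  arenas (packaged as text-mask fixtures), with 8-direction movement, a
  reward of 1 for reaching within 3 cells of the shelter, and a −0.1 penalty
  for attempted moves into inaccessible cells.
* **Three agent classes** — tabular Q-learning (model-free, with a tiny
  novelty bonus), DYNA-Q (model-based replay, 20 sampled updates per
  planning step), and Influence Zones (IZ): value learning on an
  Instantaneous Topological Map, a self-organizing graph whose nodes tile
  visited space, with TD errors propagated through node neighborhoods.
* **Two training regimes** — *free exploration* (250 ε-greedy episodes of up
  to 500 steps, greedy evaluation after each episode) and *guided
  exploration* (a single pass in which the agent's actions are forced to
  follow a mouse's exploration trajectory).
* **Tracking pipeline** — DeepLabCut-style pose tables → median filtering,
  likelihood masking, affine registration → grid-cell paths, shelter↔threat
  trips, heading directions, escape classification (10-s shelter rule,
  35 cm/s / 4-s criteria for arm-choice analyses).
* **Choice statistics** — pooled arm-choice probabilities, a Beta-Binomial
  posterior (implementing the study's printed update
  `a' = a + k − 1, b' = b + n − k − 1` verbatim, with a `standard`
  conjugate option), naive-vs-experienced resampling, time-binned
  posteriors, a cross-validated binomial GLM predicting the chosen arm from
  geodesic ratio, angle ratio, trial time and origin arm, and heading-based
  decoding of the escape arm.
* **Synthetic data** — seeded generators for exploration sessions
  (persistent biased walks with 4–6 one-way shelter↔threat trips and
  ~754 ± 267 cell-to-cell state changes), trial tables, and GLM datasets
  with known ground truth, so the entire pipeline is testable without the
  experimental recordings.

The key quantity throughout is the **geodesic ratio**
`left / (left + right)` of the two path lengths (and the analogous **angle
ratio**); arenas 1–5 span ratios 0.50–0.68.

## Worked example

Train 8 Influence-Zones agents on the arena-4 grid world (the 0.68 geodesic
ratio arena) and evaluate them greedily from the threat platform:

```sh
$ escapenav simulate free --arena 4 --model iz --reps 8 --episodes 250 \
      --seed 1 --out results/free
{
  "model": "iz",
  "arena": 4,
  "reps": 8,
  "episodes": 250,
  "final_success_rate": 1.0,
  "short_arm_fraction": 1.0,
  "episodes_to_80pct": 92
}
```

All eight agents reach the shelter in the final greedy evaluation
(`final_success_rate`), every goal-reaching agent escapes along the short
right arm (`short_arm_fraction`), and the smoothed learning curve crosses
80% evaluation success at episode 92 (`episodes_to_80pct`). Per-episode
curves and per-repetition outcomes are written as CSV next to the summary,
with a JSON manifest recording the seed and config snapshot.

The same from Python:

```python
from escapenav import build_gridworld, run_free_exploration

world = build_gridworld(4)          # 126 accessible cells
result = run_free_exploration("dynaq", world, n_reps=8, seed=1)
print(result.final_success_rate, result.short_arm_fraction())
```

Guided training on a synthetic mouse session:

```sh
escapenav generate session --seed 3 --noise-sd 0 --out results/session
escapenav simulate guided --path results/session/cell_path.csv \
    --model dynaq --reps 10 --seed 0 --out results/guided
```

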