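# Methods

This note documents the models, the numerical choices, and the synthetic
data behind `escapenav`, in enough detail to judge what the test suite does
and does not establish.

## Environment

Arenas are elevated two-path mazes: a threat platform and a shelter platform
joined by a left and a right arm. An `ArenaSpec` records the physical
geometry — geodesic path lengths (cm) and initial path angles (degrees from
the shelter direction) — from which the dimensionless geodesic and angle
ratios `left / (left + right)` follow. The five packaged specs span geodesic
ratios 0.50 / 0.60 / 0.63 / 0.68 / 0.50 and angle ratios 0.50 ×4 / 0.33,
with the right arm fixed at 505 cm in arenas 1–4. The "dynamic" arena is the
0.68 geometry plus a `flipped()` mirror.

The simulation environment is a 50×50 occupancy lattice per arena
(arenas 2–4 are packaged). Coordinates are `(row, col)`, 0-based, row 0 at
the top; the shelter sits at the top, the threat platform at the bottom.
The arena-4 lattice has exactly 126 accessible cells; its arms are
single-cell-wide corridors whose geodesic lengths (75 vs 35 moves) stand in
the 0.68 ratio of the physical arena. The exact occupancy layouts are not
published, so the masks are hand-authored, versioned text fixtures: a 0/1
occupancy mask, a letter-coded region mask (S helter / T hreat / L eft /
R ight arm), and a YAML sidecar with start and goal cells. One lattice cell
corresponds to 12 cm (`CM_PER_CELL`), chosen so that the ~125-cell total
path length matches the ~15 m of physical path and typical exploration
speeds (~1 cell/s) land in the observed 10–20 cm/s range.

Agents move in the 8 king directions, one cell at a time. A move ending
strictly closer than 3 cells (Euclidean, between cell centers; Chebyshev is
available in config) to the goal cell earns +1 and ends the episode; an
attempted move into an inaccessible cell leaves the agent in place and
costs −0.1. Diagonal moves are legal whenever the destination is accessible
(corner-cutting permitted). The model-free class additionally receives
1e−8 on each move into a never-visited cell; the visited set persists
across episodes within one agent, since the bonus exists to drive global
exploration. Rewards are additive and any single step's reward lies in
[−0.1, 1 + 1e−8].

`shortest_path_length` is an exact 8-connected BFS with unit step cost; an
unreachable target yields an explicit infinite sentinel rather than an
exception. This oracle is used for policy-optimality checks and for the
gap policy below, and is itself cross-checked against an independent
Dijkstra implementation in the tests.

## Agent classes

**Q-learning** (`QTableAgent`): tabular state–action values, zero
initialization, update `Q(s,a) += α (r + γ max_a' Q(s',a') − Q(s,a))`.
Greedy ties break toward the first action in the canonical order
(up, up-right, … counter-clockwise), making evaluation deterministic.

**DYNA-Q** (`DynaQAgent`): Q-learning plus a deterministic transition model
holding every experienced `(s, a) → (r, s')`. After each real step the
agent replays 20 uniformly sampled stored transitions through the same TD
rule. All sampling draws from an explicit `numpy` generator; in guided
training this sampler is the only source of variability.

**Influence Zones** (`IZAgent`): values live on the nodes of an
Instantaneous Topological Map — an incremental self-organizing graph fed
with the stream of visited positions. Per stimulus: the nearest node adapts
toward it (rate 0.2), an edge joins the nearest and second-nearest nodes,
edges failing the Thales-sphere criterion are pruned (orphans removed), a
node is inserted where the stimulus falls outside the permitted error
(max error 1.2, lattice-cell units — the units are an assumption), and the
runner-up is removed when it sits closer than half the max error to the
winner. On the packaged arenas this yields a connected graph of roughly
50–70 nodes for 126 cells.

Value learning on the map departs from plain on-policy TD in four ways
that proved necessary for a usable value gradient:

1. *Self-transitions with non-positive reward are skipped.* A move (or a
   penalized wall attempt) inside one node's zone carries no information at
   the map's resolution; bootstrapping on it merely decays the node and, in
   heavily dwelled regions, inverts the gradient. Rewarded self-transitions
   are kept so the goal region becomes a self-sustaining value source.
2. *The one-step target is off-policy over the map*: the bootstrap uses the
   best-valued node reachable in one map move (the observed successor or
   any graph neighbor). On-policy targets under ε-greedy behavior converge
   to a near-flat random-walk value profile whose noise creates local
   maxima that freeze the greedy policy mid-corridor; the off-policy target
   relaxes node values toward the γ-per-hop optimality fixed point.
3. *The TD target follows each regime's true continuation structure.*
   Free-exploration episodes end on goal entry, so rewarded transitions
   use the terminal target r; guided walks genuinely continue through the
   goal zone, so their rewarded transitions bootstrap as usual. This is
   not a detail: with bootstrapped goal entries in episodic training, the
   corridor nodes on the arrival side pump each other toward 1/(1−γ), so
   whichever arm currently carries the traffic towers over the other — a
   policy-dependent bistability that locks a fraction of agents onto the
   long arm. The terminal target caps both arms' value sources at the
   same level, making a stable long-arm preference impossible at the
   fixed point.
4. *n-step propagation is a raise-only relaxation*: when a node's update
   survives the one-step threshold (1e−10), its neighborhood is swept
   breadth-first; a node at depth d moves toward γ^d times the source
   value and is never raised above it, so repeated waves cannot inflate
   values past the fixed point, and the influence zone extends through a
   node only while that node's correction exceeds the n-step threshold
   (0.1). Together with the regime-correct targets of point 3, this
   keeps a 5%-per-hop value slope across the map in both regimes; under
   bootstrapped goal entries the same sweep left either inflated
   arrival-side plateaus (episodic training) or a value scale too small
   for the fixed 0.1 threshold to resolve (single guided passes).

Action selection translates map moves into lattice moves: the movement
target is the highest-valued node within two map hops of the current
nearest node (two hops let the agent cut across open platforms instead of
tracing node chains), and the eight actions are scored by the projection of
their unit displacement onto the direction to the target. Bootstrap-era
edges much longer than the map resolution (> 3× max error) are ignored as
movement targets — they can cross inaccessible space. Because the map has
no sub-node spatial resolution, the agent also keeps a per-cell memory of
moves it has experienced as legal, penalized, or rewarded, and biases the
translation accordingly (never repeat a known wall attempt; prefer known
moves; take a remembered goal-entry move). This memory is part of the
model-based agent's world model, in the same spirit as DYNA-Q's transition
store; without it the deterministic greedy policy reliably cuts diagonal
corridor joints into walls and hovers one step short of the goal zone,
because the rewarded cell shares a node with its surroundings.

Default hyperparameters (all config-overridable): α = 0.3, γ = 0.95,
ε₀ = 1.0 with multiplicative decay 0.985 per episode. The originating
study's exact values are not published; these were chosen so that all three
classes reach the goal within the 250-episode budget on the packaged
arenas (α = 0.15 leaves the model-free class short of that bar).

## Training regimes

*Free exploration*: 250 episodes × ≤500 steps (≤125,000 training steps).
Each episode starts at a uniformly random accessible cell outside the goal
zone (starts inside it would teach nothing) and ends on goal entry or at
the step cap; ε decays after each episode. After every episode the agent
is evaluated greedily from the threat-platform start cell; evaluation never
mutates the agent, an attempted illegal move terminates it as a failure,
and an un-terminated run is a timeout failure at 500 steps. 64 repetitions
are aggregated as mean ± SEM per episode and smoothed with a 6-episode
rolling mean.

*Guided exploration*: the agent is initialized at the first cell of a
recorded cell path and forced through the corresponding actions for one
pass, learning exactly as in free exploration, except that the novelty
bonus is not delivered: it is an exploration-shaping device, and with
forced actions it shapes nothing while leaving a sub-numerical (~1e−9)
first-visit gradient that the final greedy argmax would follow as a
breadcrumb trail — an artifact, not learning. Consecutive path cells that
are not 8-neighbors (tracking gaps) are bridged along a BFS shortest path;
identical consecutive cells are rejected (stationary frames must be removed
upstream). A session counts as solved when at least 8 of 10 repetitions
reach the goal on greedy evaluation. Q-table and IZ guided training is
bit-reproducible; DYNA-Q varies only through its planning sampler.

## Tracking pipeline

Post-processing follows the standard recipe: per-coordinate median filter
(7 frames), masking of samples with likelihood < 0.995 followed by linear
interpolation (chosen over dropping frames to preserve alignment with the
stimulus log; a bodypart with no confident frame at all is unrecoverable
and raises), and affine registration to the template from ≥3 point
correspondences. Frames are snapped to the nearest accessible cell center
(exact ties to the lexicographically smaller (row, col)); consecutive
duplicates collapse so only state changes remain; any frame farther than a
configurable 2 cells from the lattice invalidates the session. Heading is
the mean of the normalized tail-base→body and body→snout vectors, reported
as a signed angle from the shelter direction (0° toward shelter, range
(−180°, 180°]). Trips are complete platform-to-platform journeys — a trip
starts at the last frame on the origin platform and ends on arrival;
excursions returning to their origin are discarded. A stimulus trial is an
escape iff the shelter is reached within 10 s; arm-choice and dead-end
analyses additionally require leaving the threat platform within 4 s at
more than 35 cm/s (speed via central differences with 5-frame smoothing,
robust to jitter at 30–40 fps).

## Choice statistics

The Beta-Binomial posterior implements the study's printed update
`a' = a + k − 1`, `b' = b + n − k − 1` verbatim. With the unit prior this
is improper at k = 0 or k = n; those cases raise an explicit domain error,
and `convention="standard"` switches to the usual conjugate update. The
naive-vs-experienced comparison subsamples experienced trials without
replacement to the naive count (default 100 resamples — the protocol is
described with both 10 and 100; 100 is the default, configurable) and
reports the mean and 95th-percentile interval. Time-binned posteriors use
overlapping 300-s bins every 120 s over the first hour; empty or
degenerate bins are flagged gaps, not estimates.

The choice GLM is a binomial model with logit link over four predictors
(geodesic ratio, angle ratio, session time, origin arm one-hot), each
min-max normalized to [0, 1], fitted under 5-fold × 4-repeat
cross-validation stratified on arena so test folds stay arena-balanced.
Accuracy is the Pearson correlation between predicted P(right) and the
observed choice (right = 1) on held-out trials; the null control permutes
outcomes before fitting. The held-out test fraction for the heading
decoder is 1/3 (the protocol's "0.33%" is read as 33%). Coefficient
recovery is judged against the fit's asymptotic standard errors; the
across-fold spread is also reported but understates sampling error since
folds share most of their data. Heading decoding fits a one-predictor
logistic regression per normalized timepoint over 100 random stratified
train/test splits; single-class timepoints are flagged NaN and excluded.

## Synthetic data

The generators exist so every stage is testable without the deposited
recordings; they emulate only the statistics the analyses consume.

A synthetic session is a schedule of waypoint-directed persistent walks on
the arena lattice: 2–3 round trips (4–6 one-way trips, matching the
observed 4.2 ± 0.9) interleaved with incomplete out-and-back excursions
into the arms (the piecemeal sampling seen in natural exploration), padded
by platform "milling" steps to hit an exact target state-change count drawn
from Normal(754, 267) truncated above 100. Each walk step moves toward the
current waypoint with probability 0.9 (`walk_bias`) and to a uniformly
random accessible neighbor otherwise; 0.9 reflects bout-like rodent
locomotion at the 12-cm cell scale, where de-duplicated cell paths rarely
backtrack. The far platform is blocked during excursions, so the trip
ground truth is exact by construction. Cell sequences are rendered to
frame-level bodypart tables (4 frames per state change, longer platform
dwells, bodyparts offset along the instantaneous heading) with Gaussian
position jitter, Beta(50, 1) likelihoods, and a 2% fraction of corrupted
low-likelihood frames to exercise the confidence filter. At
`noise_sd = 0` the rendering is exact — positions are cell centers (the
midpoint of a diagonal move is nudged off the 4-way tie), corruption is
disabled, and `assign_cells` recovers the planned path cell-for-cell.

What the generator does **not** emulate: continuous rodent kinematics,
posture, within-cell micro-movement, systematic tracking bias, or
session-to-session behavioral idiosyncrasies. Tests passing on synthetic
sessions therefore establish the pipeline's correctness contracts
(filtering, registration, segmentation, counting) and the relative
learnability ordering of the agent classes, not quantitative agreement
with any particular animal's trajectory. One sensitivity worth knowing:
the guided-regime separation between model-free and model-based classes
depends on the micro-reversal rate of the walk — cell-level ping-pong
reversals act as extra TD sweeps that can let even Q-learning build a
value chain. At the realistic persistence used here the model-free class
fails all guided sessions, as observed experimentally.

Trial tables draw i.i.d. Bernoulli arm choices at a specified P(right),
with one naive (first-ever) trial per synthetic mouse; GLM datasets sample
choices from an explicit logistic model on the normalized predictors and
return the generating weights.

## Scales, determinism, limitations

Study-scale quantities are computed at the study's own sizes: 64
repetitions × 250 episodes for free exploration, 42 sessions × 10
repetitions for guided training. Every stochastic routine takes an explicit
seed; repetition streams are spawned from a root `SeedSequence`, and
deterministic pipelines re-run bit-exactly (covered by tests).

Known limitations: the occupancy masks are reconstructions constrained by
the published cell count and length ratios, not the original layouts; the
IZ action-translation and value-propagation details are this package's own
design (the cited algorithm's full specification was not available), so IZ
results characterize this implementation; Q-learning agents that reach the
goal here do so almost exclusively via the short arm, a sharper preference
than the partially converged mixture reported experimentally — with
single-cell-wide corridors and a 35-vs-75-step asymmetry, any convergent
value chain resolves the junction decisively.
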