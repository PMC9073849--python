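# Methods

This note records the models, conventions and parameter choices behind
`connqa`, in the order the workflow runs.

## Task records and the queue

The document store keeps six record types (volumes, nodes, graphs,
questions, decisions, users) as one JSON-lines file each. It is a
deliberately local, serverless stand-in for the networked document
databases that annotation platforms deploy: same schema, desk-scale.
Timestamps are ISO-8601 UTC strings produced by an injectable clock
that is forced strictly monotonic (a repeated wall-clock reading is
bumped by 1 µs), so creation order is always recoverable from
`created_at` and the priority queue's FIFO tie-break is well defined.
Dispatch order is highest priority first, then earliest creation.
Priority is a signed integer with default 0. Questions are pre-assigned
to a named assignee; a shared-pool pull model and reassignment after
abandonment are intentionally out of scope. The "maybe" verdict is
always legal at the schema level; task authors can disable it
per-question through the payload.

## Subvolume sampling

Assessment boxes are axis-aligned, half-open voxel boxes. Physical box
sizes (5×5×5 µm for synapse assessment; 12×12×12 µm axon and 7×7×7 µm
dendrite boxes around 1×1×1 µm seed volumes for tracing) are converted
to voxels with per-axis ceiling at the volume's nm-per-voxel
resolution. Sampling is with replacement over integer origins inside a
padded extent; the weighted strategy discretises the weight field on a
coarse grid of candidate origins (pitch defaults to half the box shape)
and draws origins proportionally. Degenerate boxes are dropped when
the synapse count is below 5 or the masked-voxel fraction exceeds 0.5;
the count threshold is the workflow's standard, while 0.5 quantifies
"heavily masked" and is configurable. The seed-sampling edge-exclusion
margin is exposed as the padding parameter with no claimed default.

## Decision fusion

*Keypoints.* All points are scaled per axis to nanometres and clustered
by single-linkage agglomeration cut at `cluster_radius_nm` (equivalent
to connected components of the within-radius graph, which is what the
test oracle computes). Within a cluster each annotator contributes at
most one point — the one nearest the cluster centroid — and a cluster
reaching `agreement_min` distinct annotators (default 3, matching the
deployed 3-of-5 rule) emits a consensus point at the centroid of the
contributing points. Default radius 300 nm: comfortably larger than
annotator jitter, smaller than typical synapse spacing; every fusion
property in the tests is radius-parameterised.

*Forced choice.* "maybe" is abstention-with-signal: counted in the vote
tally, excluded from the margin. The fused verdict is the majority
literal when (majority − minority) ≥ `margin` and at least `min_votes`
non-maybe votes exist; otherwise `undecided`, which the workflow
escalates to an expert. Confidence is the fraction of non-maybe votes
agreeing with the verdict (0 when undecided with no decisive votes).

*Graphs.* Vertices merge across annotators exactly as keypoints do; a
consensus edge requires `edge_support_min` annotators to have drawn an
edge between the merged endpoints. Polarity metadata is resolved by
majority, ties becoming `"unknown"`. Stitching across adjacent task
volumes identifies vertices of different fragments that lie in the
boxes' geometric overlap within `merge_radius_nm` (nearest-neighbour
pairing, union-find closure), so connectivity crosses box boundaries
exactly when the overlap margin contains shared trace vertices.
Per-user reliability weighting of votes is deliberately not
implemented; the decision records carry the fields a weighting scheme
would need.

## Scoring

*Matching.* Test and reference keypoints are matched by minimum-cost
assignment (`scipy.optimize.linear_sum_assignment`) on pairwise
Euclidean distances computed after per-axis resolution scaling — the
anisotropy correction. The distance threshold (default 400 nm,
configurable everywhere) interacts with the solver in the default
"before" mode: over-threshold costs are made prohibitively expensive
(larger than any total feasible cost), so the optimum maximises the
number of feasible pairs and, among those, minimises total distance;
any residual over-threshold pair is dissolved into unmatched. An
"after" mode (solve on raw costs, then dissolve) is available behind a
flag because either order is defensible. Equal-cost optima are accepted
as returned; tests compare cost, never pairing identity. Duplicate
suppression before matching is greedy in file order: a point within the
dedup radius of an already-kept point is dropped.

*P/R/F1.* Empty denominators yield 0, not NaN, so an empty test set
scores 0 rather than propagating missing values. Expert adjudication
operates on unmatched candidates only: `overturn` converts a candidate
FP or FN into a true positive, `ambiguous` removes it from all counts,
`confirm` keeps it; metrics are then recomputed.

*NRI.* The implemented definition is the pair-counting F-score over
unordered synaptic-terminal pairs co-assigned to one cell: TP pairs
co-assigned in both mappings, FP only in test, FN only in truth,
`NRI = 2TP/(2TP+FP+FN)`. Group-by-cell counting makes this O(n); the
test oracle enumerates all pairs. When neither mapping co-assigns any
pair the score is defined as 1 (no pair disagreements exist).

*ERL.* Runs are maximal connected subtrees of one ground-truth skeleton
whose vertices share one test label. An edge whose endpoints disagree
is an error locus; its length is split evenly between the two adjacent
runs (the unbiased estimate of where along the edge the error sits). A
label appearing on more than one skeleton is a merge: its runs keep
their cable weight in the denominator but traverse zero distance. ERL
is the cable-weighted mean traversable run length, which reduces to
Σlen²/Σlen for merge-free labelings; this component (rather than
root-to-leaf path) definition was chosen because it alone makes a
perfectly labelled *branched* tree score its full cable length, and it
makes every merge strictly decrease ERL. ERL never exceeds total cable
length, and run lengths per skeleton sum to that skeleton's length.

*Variance curves.* For each sample size `s`, the variance of the mean
score over `n_boot` bootstrap resamples of size `s` (with replacement).
Under independent volumes this tracks (population variance)/s; the
curve answers "how many assessment volumes until the dataset-level F1
stabilises".

## Synthetic worlds

Skeletons are biased random walks (persistent direction plus Gaussian
perturbation, step 200 nm, reflecting at the extent boundary) with a
per-step branch probability (default 0.03) and a node budget per cell
(default 150; tests use larger budgets when they need more cable).
Synapse count is Poisson with mean density × volume (default studies
use 1–2 per µm³, the order observed in cortical neuropil); each synapse
sits at a uniform point on a uniformly chosen edge of its presynaptic
cell, with a distinct postsynaptic cell. Because synapses are physical
structures, no two are placed within `min_separation_nm` (default
500 nm); a draw landing closer is resampled, and dropped only if a
skeleton region is saturated. Without this exclusion the generator
produces truth points closer together than any real synapse pair,
which no clustering radius could separate.

Simulated annotators drop each truth synapse with probability
`fn_rate`, jitter survivors with isotropic Gaussian noise specified in
nm and converted to voxels per axis (so jitter respects anisotropy
exactly as scoring does), and add Poisson(`fp_rate` × truth count)
uniform spurious points. Forced-choice annotators abstain with
probability `maybe_rate`, else answer correctly with probability
`choice_accuracy`.

Merge/split injection models *independent* reconstruction errors: each
cell participates in at most one event. Merge victim pairs are drawn
uniformly without replacement from one seeded shuffle; split victims
come from the opposite end of the same shuffle, so the two selections
stay disjoint and growing either count yields nested event sets. Split
bipartitions are uniform over nonempty two-part splits and depend only
on (seed, cell). Consequently every event strictly decreases NRI and a
seed's cumulative trajectory is monotone — which would not hold if
sequential events could touch the same cell, since merging the two
halves of an earlier split reverses it. Worlds are pure functions of
(parameters, seed).

What the generator does **not** emulate: imagery and image artifacts
(mask fractions arrive as precomputed scalars), realistic neurite
morphology (tortuosity, caliber, tiling), spatially correlated
annotator errors, and annotator skill drift. Passing tests therefore
demonstrate the correctness and calibration of the assessment
machinery, not the accuracy of any human annotator population.

## Problem sizes and numerics

Test and acceptance runs use compact conditions chosen to give the
statistics stated power: 200 random matcher instances with ≤6 points
per side (exhaustive oracle is 6! per instance), 50 seeds for the
fusion-gain comparison on ~8.6 µm³ worlds with ~20 synapses, 10,000
items for forced-choice calibration (binomial SE ≈ 0.0023), 20 seeds ×
5 events for NRI trajectories on 12-cell worlds, and 4,000 bootstrap
resamples for the variance law. Monte-Carlo assertions use 3-standard-
error bands; exact assertions (formula identities, oracle equality)
use machine-precision or printed-precision tolerances. All random
draws flow through `numpy.random.default_rng` seeded explicitly.
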