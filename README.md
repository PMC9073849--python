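# connqa — connectome quality assessment

Modern electron-microscopy connectomes are produced by automated
segmentation pipelines whose two canonical failure modes — **merge
errors** (distinct cells sharing one segment id) and **split errors**
(one cell broken into several ids) — cannot be found by exhaustive human
proofreading at dataset scale. `connqa` implements the alternative:
assess a *black-box* reconstruction by sampling many small subvolumes,
collecting short, atomic annotation and forced-choice tasks from several
(possibly novice) annotators, fusing their responses into consensus
annotations, and scoring the reconstruction against that consensus.

It is a library plus a thin CLI for connectomics evaluation teams:

* **datamodel** — the task/record schema (volumes, nodes, graphs,
  questions, decisions, user metadata) with a priority-and-FIFO task
  queue and a local JSON-lines document store;
* **sampling** — uniform or weighted subvolume sampling with edge
  padding, micrometre→voxel conversion, degenerate-volume filtering
  (too few synapses, or heavily masked by imaging artifacts) and seed
  synapse selection;
* **fusion** — consensus keypoints by single-linkage clustering with a
  physical radius and a minimum annotator agreement (default 3 of 5);
  margin-majority fusion of yes/no/maybe verdicts with expert
  escalation of close calls; consensus skeleton graphs; stitching of
  traces across overlapping task volumes;
* **scoring** — anisotropy-corrected optimal (Hungarian) keypoint
  matching under a distance threshold, duplicate suppression, precision
  / recall / F1 with expert adjudication, **NRI** and **ERL**, and
  bootstrap variance-vs-sample-size curves;
* **synthetic** — ground-truth worlds (random-walk neurite skeletons,
  Poisson synapses, terminal assignments), simulated error-prone
  annotators and merge/split error injection, so the whole workflow is
  testable without imagery.

## The metrics

With `tp` matched keypoints, `fp` unmatched test points and `fn`
unmatched reference points (matching minimises total physical distance,
with voxel coordinates scaled per axis by the nm-per-voxel resolution):

```
P = tp/(tp+fp)   R = tp/(tp+fn)   F1 = 2PR/(P+R)
```

**NRI** (neural reconstruction integrity) scores a test cell assignment
of synaptic terminals against the truth assignment over all unordered
terminal pairs: `TP` pairs co-assigned in both, `FP` co-assigned only in
the test (merges), `FN` co-assigned only in the truth (splits), and

```
NRI = 2·TP / (2·TP + FP + FN)
```

**ERL** (expected run length) is the expected error-free distance along
the ground-truth skeletons: each skeleton is partitioned into maximal
same-label runs, a run whose label also appears on another skeleton
(a merge) traverses zero distance, and ERL is the cable-length-weighted
mean run length — `Σ len(run)² / Σ len(run)` when no merges are present.

## Worked example

```python
import numpy as np
from connqa import *

extent = BoundingBox((0, 0, 0), (256, 256, 256))
world = generate_world(extent, (8.0, 8.0, 8.0), n_cells=5,
                       synapse_density_per_um3=2.0, seed=7)
print(f"world: {len(world.skeletons)} cells, {len(world.synapses)} synapses")

profile = AnnotatorProfile(fn_rate=0.2, fp_rate=0.1, jitter_sigma_nm=30)
sets = [simulate_keypoint_annotator(world, profile, seed=100 + a, annotator=f"a{a}")
        for a in range(5)]
consensus = fuse_keypoints(sets, agreement_min=3, cluster_radius_nm=300,
                           resolution=world.resolution)
print(f"consensus: {len(consensus)} keypoints from 5 annotators")

pts = np.array([c.position for c in consensus])
match = match_keypoints(pts, world.synapse_positions(), world.resolution,
                        max_dist_nm=400)
report = precision_recall_f1(match)
print(f"tp={report.tp} fp={report.fp} fn={report.fn} "
      f"precision={report.precision:.3f} recall={report.recall:.3f} f1={report.f1:.3f}")

corrupted = inject_reconstruction_errors(world.truth_assignment,
                                         n_merge=1, n_split=1, seed=7)
r = nri(world.truth_assignment, corrupted)
print(f"NRI after 1 merge + 1 split: {r.nri:.3f} (tp={r.tp} fp={r.fp} fn={r.fn})")
```

prints

```
world: 5 cells, 19 synapses
consensus: 19 keypoints from 5 annotators
tp=19 fp=0 fn=0 precision=1.000 recall=1.000 f1=1.000
NRI after 1 merge + 1 split: 0.807 (tp=111 fp=25 fn=28)
```

Five annotators who each miss 20% of synapses and add 10% spurious
points nevertheless fuse, at minimum agreement 3, to a consensus that
recovers the ground truth exactly; a single merge plus a single split
error drops NRI from 1.0 to 0.807 because 25 terminal pairs were
falsely joined and 28 truth pairs destroyed.

The same operations are exposed as subcommands
(`connqa sample|simulate|fuse|score|report|queue`), e.g.

```
connqa score --test performer.csv --truth expert.csv \
             --resolution 4,4,40 --max-dist-nm 400
```

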