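# Methods

## Label schemes and exclusion semantics

Reference volumes carry an 8-structure annotation: cortical gray matter
(1), basal ganglia (2), white matter (3), white matter lesions (4),
peripheral CSF (5), lateral ventricles (6), cerebellum (7), brainstem (8).
Scoring happens in the merged tissue scheme — GM = {1,2}, WM = {3,4},
CSF = {5,6} — because basal ganglia are gray matter and lesions are
(diseased) white matter, and methods are asked to segment tissue classes,
not structures.

Cerebellum and brainstem are excluded from the evaluation. The mechanics of
the exclusion are this package's choice: voxels labeled 7/8 **in the
reference** are masked out of both reference and candidate before any
metric, and whatever the candidate put at those voxels is ignored. The
rationale is that methods were never asked to segment those structures, so
neither a reward nor a penalty there is meaningful.

Candidates are expected in the tissue scheme (0 background, 1 GM, 2 WM,
3 CSF); a raw-scheme candidate is merged automatically. On reading a NIfTI
file the scheme is inferred from the label range (max label > 3 ⇒ raw)
unless stated by the caller. Float-stored labels are accepted within 1e-6
of integers — a common NIfTI dialect issue — and rejected beyond that.

Geometry: voxel (i, j, k) sits at physical center (i·dx, j·dy, k·dz) with
spacing from the header. Orientation matrices beyond spacing are ignored
after asserting that candidate and reference share shape and spacing —
evaluation assumes a common registered grid, which is how challenge data is
distributed. Resampling and registration are out of scope.

## The three measures

* **Dice** is computed on voxel counts; the percentage scale (0–100) is
  used throughout. It is undefined (an error) only when both masks are
  empty.
* **H95** needs boundary point sets. A voxel is a boundary point iff it is
  in the mask and at least one of its 6 face neighbors is outside the mask
  or outside the image; the image border counts as outside. The 6-connected
  convention and the border rule are stated explicitly because different
  choices move H95 by up to one voxel diagonal. Points are physical voxel
  centers; minimum distances are found with a KD-tree and verified in the
  test suite against an O(N²) all-pairs oracle, which must agree exactly,
  not approximately.
* The **directed h95** is the K-th order statistic of the sorted minimum
  distances with K = ceil(0.95 · N), no interpolation: ceil keeps
  K/N ≥ 95% for every N and makes h95 of a set against itself exactly 0.
  Interpolated percentiles would differ by a fraction of a voxel on small
  boundaries; the order statistic is the literal "K-th ranked distance"
  reading and is deterministic.
* **AVD** uses voxel counts directly — on a shared grid the voxel volume
  cancels. It is normalized by the reference volume and hence asymmetric by
  design.

Degenerate candidates do not crash the pipeline: an empty candidate
component yields Dice 0 and AVD 100 straight from the formulas, while H95
is recorded as undefined (NaN plus a flag). Aggregation excludes flagged
cases from that cell's mean/σ with a logged warning and a reduced count;
ranking replaces an undefined column mean with a worst-possible sentinel so
a failing method ranks last instead of disappearing.

## Aggregation and ranking

Per method, the mean μ and standard deviation σ of each (measure,
component) cell are taken over the test cases; σ is the sample standard
deviation (n−1), with σ = 0 for a single case. The σ convention is a
documented choice — nothing downstream is sensitive to it because the
tie-break only uses σ orderings, which n−1 vs n never changes.

Ranking: per column, methods are sorted on the mean (Dice descending, H95
and AVD ascending) and ranked 1..n. The overall score s sums the nine
GM/WM/CSF ranks; brain and ICV columns are ranked for display only. Final
ranks sort s ascending. Ties:

* *within a column*, equal means are ordered by the column's σ ascending
  (the steadier method wins), then by method name — every method gets a
  distinct integer rank, so rank columns are always permutations of 1..n.
  Published leaderboards assign distinct ranks even where rounded printed
  means coincide, implying full-precision ranking; a deterministic rule is
  required for reproducibility once only rounded values exist.
* *between equal overall scores*, the σ rank decides: the whole ranking
  procedure re-run on σ instead of μ (σ always ascending). Because the σ
  machinery inherits the name fallback, σ ranks are themselves a strict
  permutation, so the final ordering is total. A pair whose overall score
  AND σ score both tie is ordered purely lexicographically and flagged as a
  residual tie in the leaderboard output.

The package ships the printed cells of a published 18-method leaderboard as
reference data. Its printed per-column ranks sum exactly to the printed
overall scores (verified for all 18 rows), and re-ranking its printed mean
Dice columns reproduces the printed positions where the rounded means are
untied. The per-method means themselves cannot be recomputed here — they
require the original MRI volumes — so they serve as ranking inputs, not as
targets.

## White-matter-lesion sensitivity

Lesions should be segmented as WM. Sensitivity = 100 · (lesion voxels the
candidate labels WM) / (all lesion voxels), pooled over all cases of a test
set rather than averaged per case, so large-lesion cases weigh more. It is
undefined when no reference contains lesions.

## The phantom generator

The phantom emulates the reference-standard label scheme on the target
anisotropic grid: default 128 × 128 × 48 voxels at 0.96 × 0.96 × 3.00 mm,
so anisotropy bugs (distances computed in voxel units, axis mix-ups)
surface in tests. Geometry is nested ellipsoids — an ICV ellipsoid whose
shell is peripheral CSF, a cortical GM shell, a WM core, mirrored
lateral-ventricle ellipsoids with adjacent basal-ganglia blobs, spherical
WM lesions placed by a seeded RNG strictly inside plain WM, and an inferior
hindbrain blob split into cerebellum and brainstem. Defaults (ICV semi-axes
52/56/46 mm, four lesions of 3–6 mm radius) give realistic volume
proportions for an elderly head: ICV ≈ 561 cm³ with the measured voxel
volume within 0.1% of the analytic ellipsoid volume.

What the phantom does *not* emulate: cortical folding, partial-volume
mixtures at 3 mm slices, intensity data (there is none — only label maps),
inter-rater ambiguity, and topological defects of real segmentations.
Passing tests therefore demonstrate that the evaluation arithmetic is
correct on anisotropic label volumes, not that any segmentation method is
accurate on real MRI.

Controlled corruptions for testing: `perturb_relabel` switches an exact
uniformly-chosen fraction of one label (so AVD is predictable to one voxel),
`perturb_shift` translates all content by whole voxels (so H95 is a known
multiple of the spacing), `perturb_dilate` grows a structure layer by layer
(so Dice/AVD degrade monotonically). All are deterministic per seed.

## Problem sizes and numerical choices

The test suite uses a 48 × 48 × 24 phantom with proportionally scaled
semi-axes (generation in milliseconds, boundary sets of a few thousand
points) and the acceptance script the full 128 × 128 × 48 default; both
complete in seconds. Brute-force oracles in tests run on masks up to 20³
voxels, where the all-pairs distance matrix is still exact float64
arithmetic, and agreement with the KD-tree path is asserted to 1e-12 mm.
CSV output keeps full precision; only the display leaderboard rounds μ/σ to
one decimal.

## Known limitations

* Only diagonal-affine (axis-aligned) geometry is honored; volumes in
  mismatched orientations must be resampled upstream.
* The within-column tie rule (σ, then name) and the residual lexicographic
  rule are this package's conventions; other frameworks that rank on
  full-precision means will practically never hit them, but results on
  heavily rounded inputs can differ from an implementation with a different
  tie rule.
* The σ tie-break is only invoked for exactly equal overall scores, as in
  the original procedure; near-ties are not smoothed.
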