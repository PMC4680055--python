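# brainsegeval

Evaluation and ranking framework for brain MRI tissue segmentation.

Automatic segmentation of gray matter (GM), white matter (WM) and
cerebrospinal fluid (CSF) on 3T scans of elderly subjects is a crowded
field, and published accuracies are rarely comparable: different data,
different reference standards, different measures. Challenge-style
evaluation fixes this by scoring every method against the same expert
manual reference with the same measures and combining the results into a
single leaderboard. `brainsegeval` implements that evaluation stack as a
reusable library for challenge organizers and method developers: label
harmonization, the three evaluation measures, per-component aggregation,
the sum-of-ranks leaderboard with its standard-deviation tie-break, and a
synthetic phantom generator so the whole pipeline is testable without any
clinical data.

## The measures and the ranking

A candidate segmentation *A* is compared with the reference *G* per
anatomical component (GM, WM, CSF, brain = GM∪WM, intracranial volume
ICV = GM∪WM∪CSF) with:

* **Dice overlap** — D = 2|A∩G| / (|A|+|G|) · 100 (%);
* **95th-percentile Hausdorff distance** — H95(A,G) =
  max(h95(A,G), h95(G,A)), where h95 is the K-th ranked minimum Euclidean
  distance between boundary point sets with K/N = 95%. Using the 95th
  percentile instead of the maximum makes the boundary measure robust to
  outliers. All distances are physical millimetres, which matters on
  anisotropic grids (the target geometry is 0.96 × 0.96 × 3.00 mm voxels);
* **absolute volume difference** — AVD = |V_a − V_g| / V_g · 100 (%).

The reference uses an 8-structure annotation (cortical GM 1, basal
ganglia 2, WM 3, WM lesions 4, peripheral CSF 5, lateral ventricles 6,
cerebellum 7, brainstem 8) that is merged to GM/WM/CSF for scoring;
cerebellum and brainstem are excluded from the evaluation entirely.

For the leaderboard, each method's mean over the test cases is ranked per
(measure, tissue) column — Dice descending, H95 and AVD ascending — and the
overall score *s* is the sum of the nine GM/WM/CSF ranks (brain and ICV are
reported but not scored). Final ranks sort *s* ascending; methods with
equal *s* are separated by the σ rank, the same procedure re-run on the
standard deviations. The package also computes white-matter-lesion
sensitivity — the percentage of lesion voxels labeled WM — as a robustness
measure against ageing-related pathology.

## Worked example

```python
from brainsegeval import evaluate_case, generate_phantom, perturb_relabel
from brainsegeval.phantom import PhantomSpec
from brainsegeval.volumes import as_tissue

reference = generate_phantom(PhantomSpec(seed=1))   # 8-label synthetic head
candidate = perturb_relabel(as_tissue(reference), 2, 1, 0.1, seed=2)
result = evaluate_case(candidate, reference)
for comp, t in result.components.items():
    print(f"{comp.value:<6} D={t.dice:6.1f}%  H95={t.h95:5.2f}mm  AVD={t.avd:5.2f}%")
```

prints

```
GM     D=  95.6%  H95=10.51mm  AVD= 9.30%
WM     D=  94.7%  H95= 9.00mm  AVD=10.00%
CSF    D= 100.0%  H95= 0.00mm  AVD= 0.00%
brain  D= 100.0%  H95= 0.00mm  AVD= 0.00%
ICV    D= 100.0%  H95= 0.00mm  AVD= 0.00%
```

Relabeling 10% of WM as GM costs exactly 10% WM volume (AVD) and degrades
GM/WM overlap, but brain and ICV stay perfect: the relabeled voxels never
leave those unions. The scripts in `examples/` walk through this case, the
embedded 18-method leaderboard reproduction, and lesion sensitivity.

A thin CLI covers the same pipeline from the shell:

```bash
brainsegeval phantom  --spec spec.yaml --out data/
brainsegeval evaluate --method mymethod --pairs manifest.csv --out results/
brainsegeval rank     --summaries 'results/summary_*.csv' --out results/
```

where `manifest.csv` has columns `case_id, candidate_path, reference_path`
and volumes are NIfTI label maps.

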