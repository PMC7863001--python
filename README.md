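# aisclf

An artificial immune system (AIS) classifier with a hormone-concentration
decision rule, built for recurrence-risk prediction on small, heavily
imbalanced clinical cohorts — together with the machinery needed to
evaluate it honestly: bootstrap minority oversampling, a wrapper feature
selector (SFS-AIS), filter baselines (Relief, information gain), four
comparison learners (BPNN, RBF-SVM, fuzzy c-means, ant k-means), clinical
confusion-matrix metrics with explicit undefined-value semantics, and a
synthetic registry-style cohort generator with planted ground truth.

## Who this is for

Biostatisticians and ML practitioners working with registry-scale
clinical data (hundreds of records, ~5% event rate, mixed continuous and
coded variables) who want to study how clonal-selection classifiers and
class-balancing interact with that regime. The motivating application is
predicting recurrence of endometrial cancer from 20 registry variables
(age, histology, behavior code, grade, stage, surgery, radiotherapy,
chemotherapy, doses, lifestyle factors, …) in a cohort of 599 patients
with 38 recurrences.

## The model

Training samples are *antigens* on the min–max normalized unit cube.
Per class, k-means seeds a small population of *antibodies*, refined by
clonal selection: an antibody with mean affinity

    aff(a) = mean_x 1 / (1 + ||a − x||)        (x over the class's antigens)

produces `max(1, round(10 · aff))` clones per round, each coordinate
mutated by `N(0, σ²)` with `σ = 0.2 (1 − aff)`; a clone replaces its
parent only on affinity improvement. The survivors are archived as
*memory cells* (MC). Each class's *hormone* concentration at a query `x`
is a Gaussian-kernel sum over its memory cells (bandwidth 0.1),
normalized across classes into probabilities. Classification combines
the nearest memory cell with the hormone argmax; near-ties within the
*burring area* (hormone gap < 0.1 and nearest MC within radius 0.1) fall
to the nearest cell, other conflicts to the strongest hormone.

Because clinical cohorts are imbalanced, the benchmark pairs every
classifier with *bootstrap balancing*: the minority class is resampled
with replacement until both classes are equal — by default inside each
training fold only, so duplicates never leak into test folds.

## Worked example

```python
import aisclf as a

cohort = a.generate_cohort(a.CohortSpec(seed=1))   # 599 rows, 38 recurrent
report = a.run_benchmark(cohort, a.BenchmarkConfig(k_folds=5, seed=1))
print(report.render())
```

```
bpnn [     none] (all): accuracy 93.66 | sensitivity 0.00 | specificity 100.00 | PPV NaN | NPV 93.66
 svm [     none] (all): accuracy 93.66 | sensitivity 0.00 | specificity 100.00 | PPV NaN | NPV 93.66
 fcm [     none] (all): accuracy 93.66 | sensitivity 0.00 | specificity 100.00 | PPV NaN | NPV 93.66
  ak [     none] (all): accuracy 93.66 | sensitivity 0.00 | specificity 100.00 | PPV NaN | NPV 93.66
 ais [     none] (all): accuracy 72.79 | sensitivity 60.53 | specificity 73.62 | PPV 13.45 | NPV 96.50
bpnn [bootstrap] (all): accuracy 73.96 | sensitivity 78.95 | specificity 73.62 | PPV 16.85 | NPV 98.10
 svm [bootstrap] (all): accuracy 77.63 | sensitivity 73.68 | specificity 77.90 | PPV 18.42 | NPV 97.76
 fcm [bootstrap] (all): accuracy 53.09 | sensitivity 36.84 | specificity 54.19 | PPV 5.17 | NPV 92.68
  ak [bootstrap] (all): accuracy 51.42 | sensitivity 50.00 | specificity 51.52 | PPV 6.53 | NPV 93.83
 ais [bootstrap] (all): accuracy 75.46 | sensitivity 65.79 | specificity 76.11 | PPV 15.72 | NPV 97.05
```

Reading the numbers: without balancing, four of the five classifiers
call *every* case non-recurrent — 93.66% accuracy that is pure majority
prevalence, sensitivity 0, PPV undefined (`NaN`: no positive calls at
all). Balancing the training folds lifts sensitivity to 37–79% at the
cost of specificity. The immune classifier is the exception: its
per-class architecture already gives the minority class equal
representation, so it detects recurrences (sensitivity 60.53%) without
any balancing, and bootstrap barely changes it.

Feature selection on the same cohort (the generator plants the
discriminative signal on features 2 and 10, the histology and
chemotherapy analogues):

```python
sub = a.sfs_ais_select(cohort, target_k=11, seed=1)
print("SFS-AIS selected:", sub.selected)
print("Relief top 5:", a.select_top_k(a.relief_scores(cohort, seed=1), 5).selected)
print("Info gain top 5:", a.select_top_k(a.info_gain_scores(cohort), 5).selected)
```

```
SFS-AIS selected: [2, 4, 6, 7, 9, 10, 11, 13, 15, 16, 20]
Relief top 5: [10, 2, 16, 19, 9]
Info gain top 5: [10, 2, 13, 15, 14]
```

All three selectors agree on the planted features — the consensus
pattern one hopes to see on real data, here verifiable against ground
truth.

The same operations are available from the shell:

```bash
aisclf synth-cohort --out cohort.csv --seed 1
aisclf fit --train cohort.csv --out model.json
aisclf select --in cohort.csv --method relief --k 11
aisclf bench --in cohort.csv --out results/ --seed 1
```

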