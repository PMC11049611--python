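# triplescore

A p16–CD8–Ki67 triple immunohistochemical score for predicting **CDKN2A
homozygous deletion** in multiple primary melanoma (MPM) and familial
melanoma (FM), with the diagnostic-evaluation harness needed to assess it:
confusion matrices, sensitivity/specificity, threshold sweeps with the
Youden index, per-group marker statistics with Welch's t-test, bootstrap
confidence intervals, and a synthetic-cohort generator for testing at
arbitrary size.

CDKN2A encodes p16^INK4a^, the G1-checkpoint inhibitor of the cyclin
D/CDK4–pRb axis; around 40% of familial melanomas carry CDKN2A alterations.
Confirming a deletion requires FISH or sequencing. This package implements a
cost-saving triage rule for dermatopathologists and pathology researchers:
three routine IHC readings — the percentage of p16-positive tumour cells,
the percentage of CD8-positive peritumoral tumour-infiltrating lymphocytes
(TILs), and the Ki67 proliferation index — are each binned to an ordinal
sub-score, and the sum flags tumours likely to carry biallelic CDKN2A loss.

## The score

| marker | score 0 | score 1 | score 2 | score 3 | score 4 |
|---|---|---|---|---|---|
| p16-positive tumour cells | 51–100% | 11–50% | 1–10% | 0% | — |
| CD8+ peritumoral TILs | 61–100% | 20–60% | 1–19% | 0% | — |
| Ki67 index | 0–1% | 2–5% | 6–10% | 11–20% | 21–100% |

Total S = s_p16 + s_CD8 + s_Ki67 ∈ [0, 10]; **S ≥ 9 predicts homozygous
CDKN2A deletion**. On the bundled 23-patient MPM/FM reference cohort (7
homozygous deletions, 3 heterozygous deletions, 6 monosomies, 7 disomies)
the rule attains sensitivity 7/7 = 100% with one false positive
(specificity 15/16 = 93.75%); the three heterozygous-deletion carriers score
below 9, the expected misses of a test targeting homozygous loss. See
`docs/methods.md` for boundary semantics, known discrepancies in the
originally reported figures, and design rationale.

## Worked example

```python
>>> import triplescore as ts
>>> cohort = ts.bundled_cohort()
>>> scored = ts.score_cohort(cohort, threshold=9)
>>> cols = ["patient_id", "p16_score", "cd8_score", "ki67_score", "total", "predicted_positive"]
>>> scored[cols].head(5)
  patient_id  p16_score  cd8_score  ki67_score  total  predicted_positive
0      SV001          1          3           4      8               False
1      MS002          1          1           3      5               False
2      IM003          1          3           4      8               False
3      HV004          3          3           4     10                True
4      CV005          1          1           4      6               False
>>> cm = ts.confusion_matrix(scored, "homozygous_deletion", threshold=9)
>>> cm.tp, cm.fp, cm.tn, cm.fn, cm.sensitivity, cm.specificity
(7, 1, 15, 0, 1.0, 0.9375)
```

HV004 (p16 0%, CD8 0%, Ki67 40%) scores 3 + 3 + 4 = 10 — the full biallelic
loss phenotype — and is correctly called positive; MS002, a heterozygous
carrier, scores 5 and stays negative. The confusion matrix says all seven
homozygous deletions are caught (sensitivity 1.0) at the cost of one false
positive among the sixteen non-carriers (specificity 0.9375).

The same rule is available as a scikit-learn-style estimator, so the cut-off
can be examined with standard model-selection tooling:

```python
>>> clf = ts.TripleScoreClassifier(threshold=9).fit(cohort.to_frame())
>>> clf.predict([[0, 0, 40], [50, 70, 60]])   # columns: p16, CD8, Ki67 %
array([ True, False])
```

Group-level marker statistics (wild type = disomy ∪ monosomy, mutated =
homo- ∪ heterozygous deletion) with Welch's unequal-variance t-test:

```text
$ triplescore summarize --fixture --quiet
marker,mean_wt,mean_mut,n_wt,n_mut,t_statistic,welch_df,p_value
p16,42.3,15.0,13,10,2.954062603037704,16.619650336579017,0.009045612202670545
cd8,19.61,5.0,13,10,1.7162564316713913,14.35645672802303,0.10760531308702938
ki67,35.38,42.5,13,10,-0.8040059302850419,20.277500747941378,0.4307189456658513
```

p16 expression is significantly lower in the mutated group (p ≈ 0.009);
CD8+ TIL depletion and Ki67 elevation trend the expected way without
reaching significance at this cohort size. The CLI also offers `score`
(per-patient CSV), `evaluate` (JSON report with sweep, group comparisons and
optional bootstrap intervals), `sweep` (threshold table) and `simulate`
(synthetic cohorts drawn from genotype-conditional marker distributions);
`--help` lists the flags.

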