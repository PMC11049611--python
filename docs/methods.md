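# Methods

## The scoring model

`triplescore` implements a semi-quantitative immunohistochemical (IHC)
algorithm that predicts **homozygous deletion of CDKN2A** in patients with
multiple primary melanoma (MPM) or familial melanoma (FM) from three routine
IHC readings, avoiding up-front genetic testing. CDKN2A encodes p16^INK4a^,
the G1 checkpoint inhibitor of the cyclin D/CDK4-pRb axis; biallelic loss is
the alteration the score targets. The ground-truth label is the per-patient
CDKN2A copy-number call from dual-colour FISH, one of *disomy*, *monosomy*,
*heterozygous deletion* or *homozygous deletion*. Disomy and monosomy form
the wild-type group; the two deletions form the mutated group used for group
statistics.

Each marker percentage is mapped onto an ordinal sub-score so that points
accumulate for the phenotype of homozygous CDKN2A loss — absent p16
expression, depleted CD8+ peritumoral tumour-infiltrating lymphocytes
(TILs), high Ki67 proliferation:

| marker | score 0 | score 1 | score 2 | score 3 | score 4 |
|---|---|---|---|---|---|
| p16-positive tumour cells | 51–100% | 11–50% | 1–10% | 0% | — |
| CD8+ peritumoral TILs | 61–100% | 20–60% | 1–19% | 0% | — |
| Ki67 index | 0–1% | 2–5% | 6–10% | 11–20% | 21–100% |

The composite total is the plain sum, S = s_p16 + s_CD8 + s_Ki67 ∈ [0, 10],
and a tumour is called positive for homozygous deletion when
S ≥ θ with θ = 9 by default.

### Boundary semantics

The prose class limits ("<20%", "2–5%" vs "6–10%") leave boundary and gap
ambiguities. The package resolves them by defining every scale as **closed
integer ranges on the 0–100 integer percent grid**, with fractional inputs
rounded half-up on ingest. Two boundary placements are pinned by the
reference cohort itself: p16 = 50% scores 1 (the ">50%" class is strict,
forced by patient SV001's total of 8) and CD8 = 20% scores 1 (the "20–60%"
class includes its lower bound, forced by MS002's total of 5). Under these
semantics the recomputed totals match the reference cohort's published
totals for 22 of 23 patients. The sole exception, CV005
(p16 50, CD8 20, Ki67 60), computes to 1 + 1 + 4 = 6 against a published 5;
no rubric consistent with the SV001 and MS002 constraints can yield 5, so
the published entry is treated as a typesetting error and excluded from the
exact-total regression. The classification at θ = 9 is unaffected.

The threshold comparison is ≥ (at least 9), and `classify`/the estimator
accept any θ ∈ [0, 10] for sensitivity analysis; the bins themselves are
fixed constants of the method, overridable only through an explicit
`ScoreRubric` for what-if analyses.

## The reference cohort

The bundled cohort contains the 23 MPM/FM patients the rubric was derived
on: 7 homozygous deletions, 3 heterozygous deletions, 6 monosomies and
7 disomies, with the original 11-patient test / 12-patient validation split
preserved in the `split` field. The originally reported per-patient totals
ship as regression metadata (`reported_totals()`); the scorer never reads
them. The split is stored rather than re-randomised because the original
assignment is only knowable from the published per-split listings.

At θ = 9 on all 23 patients the score attains sensitivity 7/7 = 100% with
one false positive (VS019, a monosomy with p16 0%, CD8 0%, Ki67 80% —
an IHC phenotype indistinguishable from biallelic loss) and three
heterozygous-deletion carriers below threshold, the expected misses of a
test targeting homozygous loss only. Two published figures are **not**
reproducible and are flagged in report notes rather than asserted:

- specificity was reported as 94.11% (= 16/17), but the cohort has 16
  negatives and the standard tn/(tn+fp) gives 15/16 = 93.75%; the reported
  denominator is not recoverable;
- the CD8 group-comparison p-value was reported as 0.1185, while Welch's
  test on the cohort values gives ≈0.108 (and the pooled-variance t-test
  ≈0.142).

## Statistics

Group comparisons use **Welch's unequal-variance two-tailed t-test** with
Welch–Satterthwaite degrees of freedom. The original analysis does not name
its test; Welch reproduces the published p16 p-value (computed 0.009046 vs
reported 0.009045612) and Ki67 p-value (0.430719 vs 0.430718946) essentially
exactly, where pooled-variance and one-tailed variants do not. Degenerate
inputs (n < 2, or two zero-variance samples) raise instead of returning NaN.

Displayed group means are **truncated** to two decimals (42.3077 → 42.30),
matching the display convention of the reference results; all internal
comparisons use full precision.

Diagnostic accuracy is summarised by the 2×2 confusion matrix at a chosen
threshold, a full threshold sweep (θ = 0..10) with the Youden index
J = sensitivity + specificity − 1, and percentile (2.5/97.5) bootstrap
intervals from case resampling. Bootstrap replicates in which a metric is
undefined (no positive, resp. negative, cases drawn) are redrawn; if more
than half of the attempted replicates are undefined the cohort is deemed too
small to bootstrap and an error is raised. Because positivity is S ≥ θ,
sensitivity is non-increasing and specificity non-decreasing in θ; on the
reference cohort θ = 9 is the largest fully sensitive cut-off and maximises
specificity among them.

## Synthetic cohorts

Real MPM/FM cohorts are small (the reference study reflects roughly five
years of accrual at one centre), so the generator exists to exercise every
downstream stage at arbitrary size. It draws each marker independently from
a per-genotype categorical distribution on the integer percent grid — the
discrete structure the reference cohort exhibits (p16 concentrated on
{0, 50}, all markers on a multiple-of-5 grid). `empirical_config` extracts
these distributions from any observed cohort; the defaults used by
`triplescore simulate` are exactly the reference cohort's empirical
distributions and genotype counts (7/3/6/7).

What the generator deliberately does **not** model: within-genotype marker
correlation (reduced p16 and elevated Ki67 co-occur in real tumours),
lesion-level heterogeneity, multiple tumours per patient, and anatomic-site
or sex covariates. Passing tests on synthetic cohorts therefore demonstrate
correctness of the scoring and tallying machinery, not clinical performance
on real populations.

Reproducibility contract: a config carries one root seed; generation spawns
one child stream per genotype via `numpy.random.SeedSequence.spawn` in the
fixed genotype enumeration order, so draws for one genotype are invariant to
the counts requested for the others. The stratified test/validation splitter
(`split_cohort`) shuffles each stratum of the wild-type/mutated dichotomy
with a seeded generator and assigns the first `round(fraction · n)` records
to the test set; a stratum with fewer than two records cannot be divided and
goes entirely to the test set with a warning.

## Numerical and design choices

- **Integer grid.** Percentages are stored as integers; fractional CSV
  input is rounded half-up before binning so the three scales partition
  [0, 100] totally and exhaustively (verified by brute force over all 101
  values against independently constructed lookup tables).
- **Estimator shape.** The rubric is exposed as a scikit-learn-style
  classifier (`TripleScoreClassifier`) with a validating no-op `fit`, so the
  threshold can be examined with standard model-selection tooling
  (e.g. leave-one-out grid search over θ); module-level functions remain the
  thin functional surface.
- **Evaluation pooling.** Default evaluation pools the test and validation
  splits, since the headline accuracy figures follow analysis of both sets;
  per-split evaluation is available via a filter.
- **Positive class.** Defaults to homozygous deletion (the score's design
  target); an `any_mutation` mode supports the wild-type/mutated dichotomy
  used by the group statistics.
- **Determinism.** CLI outputs carry no timestamps; identical inputs and
  flags produce byte-identical outputs. JSON reports serialise full-precision
  numbers alongside separately truncated/rounded display fields.

## Problem sizes used in the checks

The bundled-cohort computations are instantaneous (n = 23). Large-sample
properties are checked at the sizes where their guarantees are sharp enough
to assert: tally-oracle equivalence on a 10,000-record synthetic cohort,
law-of-large-numbers agreement of generated marker means at 100× the
reference counts (within 3 standard errors), detection-rate convergence
against exact enumeration of the categorical support products at 4,000
homozygous draws, and parameter recovery to total-variation distance < 0.05
at 10,000 draws per genotype.

## Known limitations

- The rubric is fixed, not learned; it encodes published cut-offs and is
  not recalibrated to new cohorts (a deliberate non-goal).
- The score predicts homozygous deletion only; heterozygous carriers are
  expected false negatives, and promoter-methylation silencing of CDKN2A is
  invisible to it.
- The reference cohort is small (23 patients, one centre); bootstrap
  intervals on it are wide, and external validation is out of scope.
- Marker independence in the generator overstates how easily synthetic
  genotypes separate compared to correlated real data.
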