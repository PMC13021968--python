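# Methods

This note documents the statistical procedures `danscreen` implements, the
design choices made where the procedure left room, what the synthetic-study
generator does and does not emulate, and the known limitations.

## The triage model

The pipeline treats candidate triage as a monotone chain of per-gene gates:

```
in_catalog → tested_primary → primary_hit → primary_concordant
           → secondary_hit → secondary_concordant → replicated
           → (down in KD panel 1) ∧ (down in KD panel 2) → final_candidate
```

Screens are scored per RNAi line; genes aggregate over their lines by an
ANY rule (a gene passes a stage if any of its tested lines passes), because
candidate lists are gene lists while availability is line-level. The
`StageLedger` enforces the chain as an invariant: setting a later flag
without its prerequisite is an error, and `finalize()` re-derives
`final_candidate` and re-validates the whole ledger.

## Behavioral screen

- **Performance index.** PI = (CS⁻ − CS⁺)/(CS⁻ + CS⁺) per T-maze choice
  test; one *data point* is the arithmetic mean of the two halves of an
  odor-counterbalanced pair. Unpaired halves cannot form a data point.
- **Trimming.** With n = 4 data points per line, the single point with the
  largest absolute deviation from the four-point mean is discarded.
  Dropping the farthest point can never increase the variance of the
  retained points about their own mean (property-tested). Ties are broken
  by dropping the earliest such point in input order — deterministic and
  order-stable. Lists of ≤ 3 points pass through unchanged with a warning.
- **Control reference.** Controls are interleaved throughout the screen and
  averaged *globally per library* (not per day); each line is scored
  against the reference of its own library. A non-positive reference aborts
  ratio computation: PI ratios across zero are meaningless.
- **Hit calling.** memory score = trimmed mean PI / reference; high iff
  score − 1 > 0.25 strictly, low iff 1 − score > 0.25 strictly. A score of
  exactly 1.25 or 0.75 is not a hit. Calling is scale-invariant in
  (mean, reference).
- **Concordance.** A hit is carried forward iff the gene's adjusted p is
  < 0.05 (strict) and the direction matches: high memory with log2FC < 0,
  low memory with log2FC > 0. Genes with log2FC exactly 0 have no
  direction and never pass.

## Vesicle-marker screen

Hemisphere ROI means are averaged to one value per animal (a single
hemisphere stands alone when the other was excluded; whole-brain ROIs are
single measurements by contract). Line mean over control mean gives the
fluorescence-intensity ratio; the same strict ±25% rule applies, and the
direction must match the memory direction (high memory × marker increase,
low memory × marker decrease). Six animals per line is the screening
standard; fewer triggers a warning rather than an error — screening is
tolerant, validation is not. Percent-of-control normalization maps the
control group's own mean to exactly 100.

## Two-group testing and the replication gate

`two_group_test` runs Shapiro–Wilk (α = 0.05) on each group; if both are
consistent with normality it uses Student's t, otherwise Mann–Whitney U,
always two-tailed. Behavioral comparisons force the t-test (PI scores are
normally distributed); shock-AUC comparisons default to Mann–Whitney.
Groups below n = 3 are refused. Two identical constant groups return
p = 1 and direction 0. The gate passes a candidate only when the memory
retest *and* the marker retest are both significant at α = 0.05 and both
point in the expected direction. Calibration: under the null (both groups
N(0,1), n = 10) the rejection rate sits in [0.03, 0.07] (checked over
1000 seeded simulations).

## Expression re-validation

- **Normalization.** For sample j, the scale factor is
  s_j = exp(grand mean of log-geometric-means) / geometric mean of the
  housekeeping counts in j; all counts in j are multiplied by s_j. After
  scaling, the housekeeping geometric mean is identical in every sample.
  Rescaling one raw sample by c is absorbed up to a common factor c^(1/n)
  applied to the whole matrix (the grand-mean anchor shifts); relative
  expression and all downstream ratios are exactly invariant. A zero
  housekeeping count is an error naming the gene and sample. This
  geometric-mean scaling is the documented standard for digital counting
  panels; the platform vendor's proprietary pipeline specifies only the
  housekeeping set, not the algorithm, so the surrogate's p-values are not
  treated as an exchangeable surface — ratios are.
- **Testing.** Welch's t-test, two-sided, on log2(normalized + 1), no
  multiple-testing correction (per-gene significance is reported the way
  panel software reports it). "Down" on a panel means significant ∧ ratio
  < 1 ∧ not the knockdown target itself (the target is only the
  manipulation check).
- **ΔΔCt.** Triplicate Ct values are arithmetically averaged first; ΔCt =
  target − housekeeping per sample, ΔΔCt subtracts the mean control ΔCt,
  fold = 2^(−ΔΔCt). Folds at ±ΔΔCt multiply to 1; a single control sample
  has fold exactly 1. No outlier handling among triplicates.

## Functional imaging

F₀ is the mean fluorescence over the 5 s before the *first* shock — one
baseline per recording, not per pulse. The alternative (re-baselining
before each pulse) is deliberately not the default: a single ΔF/F trace per
recording is the standard presentation, and per-pulse baselines would
absorb exactly the sustained-release signal the statistic is designed to
detect. "5 s intervals" is onset-to-onset: 12 onsets at 5 s span 55 s plus
a 1.25 s pulse, fitting the 1 min shock epoch, whereas offset-to-offset
would overrun it. The AUC window runs from the onset of pulse 7 to one full
interval after the onset of pulse 12, so each late pulse contributes its
complete 5 s epoch. Integration is trapezoidal at the native 4 Hz sampling
with no resampling, for determinism; ΔF/F is invariant under any global
gain applied to the raw trace, and the AUC is linear in ΔF/F.

## Rescue and epistasis classifiers

Four-group designs are compared with ANOVA + Tukey HSD by default; a
Kruskal–Wallis + Dunn (Bonferroni) backend is available via
`method="kruskal_dunn"` since both appear in practice (the Dunn z-test is
written out in `triage.py` because no installed package provides it).
"Not significant" means adjusted p ≥ 0.05 — absence of significance, not
an equivalence test. Full rescue: rescue genotype ≁ knockdown and ~
control. Partial rescue: different from both with its mean strictly
between theirs. Same-pathway epistasis: double knockdown differs from
control but from neither single. Additive: the double significantly
exceeds both singles in the effect direction.

## The synthetic-study generator

`gen_study(StudyConfig(seed=...))` emits every input table from one seeded
RNG, with planted ground truth. Defaults are the modeled study's stated
conditions where stated, and field-realistic choices where not:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 160 | DEG count (92 up / 68 down) |
| `n_planted_downstream` | 5 | true downstream genes |
| `control_pi_mean` / `control_pi_sd` | 0.4 / 0.08 | control PI; sd of a *single half-vial* measurement |
| `pi_effect_size` | +0.35 | relative PI shift of planted genes |
| `day_effect_sd` | 0.03 | additive day effect shared by all genotypes run that day |
| `false_signal_rate` | 0.05 | non-planted genes given a real memory-only effect (random sign) |
| `fi_effect_size` / `fi_cv` | +0.5 / 0.15 | marker increase of planted genes; per-animal CV |
| `count_dispersion` | 0.01 | NB α; CV ≈ 10–12%, the scale of panel replicates that each pool 150 brains |
| `planted_expression_ratio` | 0.5 | KD/control ratio of planted genes in *both* panels |
| `retest_n` | 12 | per-group retest size (within the 4–17 range such retests use) |
| `panel_n_per_group` | 4 | biological replicates per panel group |
| `trace_amp_pct`, `trace_decay`, `trace_noise_sd` | 40%, 0.8, 2% | triangular pulse responses; control amplitudes decay geometrically, knockdown amplitudes sustain |

Structure mirrored from the screening campaign: 4 genes without lines, 6
genes whose only line is lethal, 13 genes with a second line (so the
catalog accounting reproduces 169 obtained / 163 tested / 150 genes),
controls interleaved per day and library, four data points per line across
distinct days, PI points realized as integer 60-fly choice counts.

What it does **not** emulate: odor-specific biases beyond what
counterbalancing cancels, heavy-tailed vial failures (noise is Gaussian,
so the trim rule is exercised but not stress-tested), probe-level panel
background, bleaching or motion in traces, and any biophysics of vesicle
release. Passing tests therefore demonstrate the *pipeline's* correctness
and calibration under its stated noise model, not robustness to every
artifact of real data.

Design note on planted truth: all planted genes are down-regulated in both
knockdown panels, so the expected final-candidate set equals the planted
set and end-to-end sensitivity is measured per planted gene. At the default
effect sizes the primary screen is the binding constraint: a planted gene's
expected memory score is 1.35 against a threshold of 1.25 with a score sd
of ≈ 0.11 (trimmed mean of 3 of 4 points), giving per-gene primary-stage
sensitivity ≈ 0.82 and end-to-end sensitivity ≈ 0.83; the other stages
operate near ceiling. False positives are controlled almost entirely by
the requirement of independent effects in four modalities — measured false
final candidates are ≈ 0 per run.

## Problem sizes

The recovery simulations use 100 seeded studies (500 planted-gene trials)
for sensitivity and false-candidate rates, 100 null studies for
specificity, 30 studies per planted ratio for panel recovery, 1000
simulations for test calibration, and 100 seeds of 12 + 12 traces for AUC
power — sizes chosen so every Monte Carlo estimate has a standard error
well under its decision margin while a full run stays around a minute.

## Known limitations

- The per-line duplicate structure of the real catalog is not published;
  the worked-example catalog encodes the aggregate accounting exactly and
  places the duplicate lines on placeholder genes.
- The panel surrogate's p-values can differ marginally from the vendor
  pipeline's; expression *ratios* are the stable quantity.
- Rescue labels are per experiment; the classifier does not adjudicate
  between, e.g., larval and adult results that disagree.
- The ledger's ANY-line aggregation means a gene with many lines gets more
  chances at each screen; the generator mirrors the real multiplicity
  (≈ 8% of genes) rather than correcting for it, as the campaign did not.
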