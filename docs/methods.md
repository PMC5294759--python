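# Methods

## Scope and data model

The package predicts RNAi activity (normalized target knockdown in [0, 1])
from the 21-nt guide strand of an siRNA and, optionally, the mRNA region it
targets. Positions 1..21 index the guide 5'→3'; guides of any other length
are rejected rather than trimmed, because every positional feature assumes
exactly 21 positions. T is accepted on input and normalized to U. A record
with activity strictly above 0.7 is called potent; activity exactly at the
threshold is classed nonpotent (the two strict inequalities of the
potent/nonpotent definition leave the boundary unassigned, so we close the
nonpotent side and document it here).

## Feature extraction

**Positional window codes.** The digit map A→1, U→2, G→3, C→4 turns each
dinucleotide window into (f−1)·4+s and each trinucleotide window into
(f−1)·16+(s−1)·4+t, with f, s, t read from the first, second and third base
of the window respectively. These are mixed-radix positional encodings —
bijections onto {1..16} and {1..64} — and are passed to the forest as
integer codes (trees split categorical-as-ordinal codes adequately; an
explicit one-hot mode was considered and left out to keep the 230-column
layout stable).

**Thermodynamics.** The duplex is modeled as the guide paired with its
perfect Watson–Crick complement. ΔG_duplex is the plain sum of the 20
nearest-neighbor stacking increments using the Xia et al. (1998) RNA/RNA
parameters at 37 °C, shipped as a versioned TSV
(`data/xia1998_wc_stacking_dG37.tsv`, version `xia1998-v1`); the 10 unique
published values expand to all 16 ordered guide steps by duplex symmetry.
Helix initiation, terminal-AU and symmetry corrections are deliberately
excluded: the statistic of interest is a per-step stability profile, not an
absolute folding free energy. ΔΔG compares the terminal five nucleotides of
each end — four nearest-neighbor steps per window — as (5' window) − (3'
window); "five terminal nucleotides" could alternatively be read as five
steps, but five bases span four steps and we fix that reading. Positive ΔΔG
means the 5' end of the guide is the less stable duplex terminus, the
orientation favoring guide-strand loading.

**Compositions.** k-mer fractions (k = 1..3) use overlapping windows with
denominator L − k + 1, the standard k-mer convention, so each k-block sums
to exactly 1. The 168 composition features split 84 (guide) + 84 (mRNA
context). The context block defaults to the full provided context string; a
`context_window` option clips it to ±w nucleotides around the first exact
occurrence of the reverse complement of the guide, for users whose contexts
are whole transcripts. No secondary-structure or target-accessibility
features are computed.

## Regression model

`fit_forest` wraps scikit-learn's `RandomForestRegressor` with bootstrap
bookkeeping retained: N trees (default 500), mtry = ⌊D/3⌋ candidate features
per split unless set, unlimited depth, minimum leaf size 5 (a common
regression-forest default; the original description is silent on depth
control), and a single root seed threaded through bootstrap, split sampling
and importance permutations. Grid search over (N, mtry) maximizes
cross-validated PCC with ties resolved toward the smaller N, then smaller
mtry.

## Importance and selection

Permutation importance is computed per tree on its out-of-bag records: the
increase in MSE after permuting one column (for the binary potency reading,
a decrease-in-accuracy variant is available via
`mode="classification_accuracy"`; the default is the regression form because
the fitted model is a regressor). A feature a tree never splits on
contributes exactly 0 for that tree; a tree with no out-of-bag records
contributes 0 with a warning. The z-score divides the mean per-tree
importance by its standard error, σ̂/√n_tree (the standard normalization;
an alternative σ̂/n_tree scaling would rescale all z-scores by the same
constant and leave the ranking — the only thing selection consumes —
unchanged). Features with zero per-tree spread get z = 0. Ranking is by
descending z with original column order breaking ties, so it is
deterministic.

The binary search over the ranking (BSFS) evaluates the full set k = D,
then halves k by floor division while the oracle score does not decrease;
when a halving from k_hi to k_lo decreases the score it bisects upward,
evaluating k_lo + (k_hi − k_lo)//2 and moving the lower bound up whenever
the score does not exceed the best seen, until the interval is exhausted.
The selected threshold is the evaluated k with the maximal score; ties go
to the earliest (largest-k) evaluation, so a flat oracle returns the full
feature set rather than an arbitrary subset. Oracle calls are cached by k.
The control flow is validated by exact replay against the published
nine-step trace of the original 230-feature model (visits 230, 115, 57, 28,
42, 49, 53, 55, 56; selects 57). Two oracle constructions are provided:
K-fold cross-validated PCC on the training set (default 5 folds) and a
fixed held-out split; a stub oracle replays any k→score table.

## Evaluation

PCC is computed in the paired-z-score form, 1/(n−1) Σ ẑₓᵢ ẑᵧᵢ with sample
(ddof = 1) standard deviations; zero-variance input is an error, not a 0.
ROC analysis takes operating points at every distinct predicted value
(plus the sentinel endpoint), computes sensitivity TP/(TP+FN) and
specificity TN/(TN+FP) at each cut, and integrates by the trapezoid rule;
the test suite asserts the closed-form identity AUC = U/(n₊·n₋) against the
Mann–Whitney statistic to 1e-10. `sensitivity_at(s)` reads the curve
conservatively: the maximal sensitivity among operating points with
specificity ≥ s.

## Motif enrichment

For each window position and each k-mer (k = 2, 3), the per-record binary
occurrence indicators of the potent and nonpotent classes are compared with
a two-sample Student's t-test (pooled variance; on 0/1 data this is
algebraically the classic two-proportion pooled test with a t reference
distribution — the test suite asserts exact agreement with an independent
t-test on the expanded indicator vectors). Welch's variant is available
behind a flag. When both groups have zero variance the p-value is reported
as 1 with a degenerate-input flag. The enrichment table keeps, per
position, the minimal-p motif in each direction (potent-enriched /
nonpotent-enriched) with p below α = 0.05 by default; ties on p break
lexicographically by motif. Raw p-values are reported because the
table-style output this mirrors reports raw values; a Bonferroni option
exists and is off by default.

## Synthetic data

The generator emulates the structure the predictor assumes, not any real
assay: guides uniform over {A,C,G,U}²¹; an mRNA context of configurable
length (default 60 nt) embedding the perfect target site (reverse
complement of the guide) at a random offset, which makes guide and context
compositions correlated but not identical; activities through a logistic
link, η = Σⱼ wⱼ·z(xⱼ) + ε, activity = 1/(1+e^(−η)), with the chosen feature
columns standardized before weighting because raw feature scales span
~0.1 (representations) to ~−50 kcal/mol (ΔG_duplex). The default
specification plants 10 informative features among the 230 — thermodynamic,
positional and composition columns — with |w| = 0.8 and noise σ = 0.5 on
the logit scale, a strong-but-noisy sequence determinant whose activities
straddle the 0.7 potency cut (roughly a third of default records are
potent).

Two class-structured mechanisms support the enrichment tests: a latent
Bernoulli(½) potent/nonpotent class that shifts η by ±`class_separation`,
and motif plants that overwrite a guide window with a fixed motif, with a
given excess probability, in records of one latent class. The
`class_separation` field exists because class-conditional motif plants can
only correlate with potency labels if the latent class also moves the
activity; with the default value 0 the plain logistic-link formula is
recovered exactly.

What passing tests on this generator do show: the extractor, ranking,
selection and evaluation machinery recover known planted structure at
realistic sample sizes (planted dinucleotide recovered at n = 1000 with
p < 0.05; ≥ 8 of 10 planted features selected and selected-model PCC ≥
all-feature PCC at n = 2000). What they do not show: performance on real
reporter-assay data, whose noise is heteroscedastic and position-dependent,
whose guides are not uniform random sequences, and whose activity scale
reflects assay-specific normalization. Absolute PCC/AUC values obtained on
synthetic data are properties of the simulation, not benchmark claims.

## Problem sizes and numerical choices

The shipped test suite runs the heaviest check — the end-to-end
planted-feature recovery — at n = 2000 records, 230 features, 200 trees
with a fixed 1600/400 holdout, which completes in well under a minute on a
single core; the 50-repetition importance calibration uses n = 150, 8
features, 100 trees per repetition. These sizes were chosen as the smallest
at which the statistical claims are comfortably identifiable. Composition
block sums are exact to 1e-12; PCC agrees with the covariance-ratio form to
1e-12; AUC agrees with Mann–Whitney to 1e-10. All randomness flows from
explicit integer seeds; repeated runs are byte-identical.

## Known limitations

- The 2-3NT codes are ordinal encodings of categorical windows; trees can
  split them, but linear models consuming the exported feature matrix
  should one-hot them externally.
- ΔG values are per-step sums without initiation or terminal corrections
  and should not be compared against full folding free energies.
- The mRNA composition block depends on how much context the user supplies;
  two datasets with different context lengths are not directly comparable
  unless `context_window` is used.
- No multiple-testing correction is applied to enrichment tables by
  default; with 16–64 motifs × ~20 positions, expect false positives at
  α = 0.05 on null data.
- The selection search assumes a roughly unimodal score-vs-k profile; on a
  rugged profile it returns a good local threshold along its trajectory,
  not a global optimum over all k.
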