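# Methods

## Model

A peptide over the 20 standard amino acids is represented only by its
amino-acid composition (AAC): the 20-vector of residue frequencies
`aa_i = count_i / length`. The classifier is a linear functional of that
vector, `S(P) = Σ aa_i · APS_i`, thresholded at a single cutoff with a
strict inequality (`S(P) > Cutoff` → positive; equality is non-positive).
Because `S(P)` is a convex combination of the card entries, every score lies
between the smallest and largest card score, and scoring is invariant to
residue order — the model deliberately ignores positional and motif
structure (e.g. RGD/NGR placement) in exchange for interpretability.

Printed card scores are integers on a 0–1000 scale; reported peptide scores
are rounded half away from zero. Classification thresholds the raw
(unrounded) score; the difference matters only within 0.5 of the cutoff.

## Card estimation

**Initial card.** For each residue `i`, the mean composition in the positive
class `p_i` and negative class `n_i` gives the raw propensity ratio
`r_i = p_i / n_i`. A residue absent from a class receives a
pseudo-composition of `1/(total residues in that class)` — the smallest
observable nonzero composition — so the ratio is always defined while
leaving observed values untouched. The 20 ratios are min–max rescaled to
[0, 1000] (so min = 0 and max = 1000 exactly) and rounded to integers.
If all ratios are equal the card is degenerate; it is set to all-500 and a
warning is raised.

**GA refinement.** Genes are the 20 integer scores, clamped to [0, 1000]
after every operation. The population is seeded with the initial card plus
uniformly perturbed copies (±mutation_step per gene), guaranteeing the
initial card is present at generation 0, hence optimized fitness ≥ initial
fitness. Each generation applies tournament selection (size 3), uniform
crossover (rate 0.8, per-gene 50% swap), per-gene mutation (rate 0.05,
uniform integer step in ±100) and elitism (2 individuals), so the best
fitness per generation is non-decreasing. Defaults: population 50,
generations 100 — standard settings in the scoring-card literature, all
exposed through `GAConfig`.

**Fitness.** `Fit = w1·AUC + w2·R` with defaults `w1 = 0.9`, `w2 = 0.1`.
The AUC term is the pooled out-of-fold AUC under seeded stratified 10-fold
assignment; since a candidate card is a fixed scorer (nothing is re-fitted
per fold), pooled out-of-fold scores coincide with scoring the full training
set, which is what makes a GA with thousands of fitness evaluations cheap
(one 20-dimensional dot product per peptide plus a rank statistic). `R` is
the Pearson correlation between the candidate's and the initial card's 20
scores; a constant (zero-variance) candidate gets `R = 0` with a warning.

**Cutoff.** After training, the cutoff is the integer in the score range
maximizing training accuracy under the strict-`>` rule; ties are broken
toward the smallest maximizer, for determinism.

**Multiple runs.** `run_experiments` performs independent GA runs with
seeds `seed+0 … seed+n−1` and sorts the results by cross-validation
accuracy (descending); model selection uses CV accuracy rather than any
held-out result, so the independent set stays untouched.

**Reported CV metrics.** Re-running the GA inside every CV fold would
multiply training cost ~10× without changing what the metrics measure for
this model family (the card is a fixed linear scorer once trained). The
`cv_metrics` attached to a training result therefore hold the card's scores
fixed and re-select only the cutoff on each training fold, pooling
out-of-fold predictions and scores into one ACC/Sn/Sp/MCC/AUC bundle. The
generic `cross_validate` accepts any card-building procedure for callers
who want full per-fold retraining.

## Evaluation

ACC, Sn, Sp and MCC follow the standard confusion-matrix definitions; MCC
returns 0 when any marginal is empty (the usual convention, logged). AUC is
computed as the Mann–Whitney rank statistic with midrank tie handling,
which equals the trapezoidal area under the ROC curve; tests verify it
against exhaustive pairwise counting and against scikit-learn. Stratified
fold assignment shuffles each class with a seeded generator and deals
round-robin, so balanced data yield exactly balanced folds and identical
seeds yield identical metrics.

## Property characterization

AAIndex1 records are parsed from the flat-file layout (H accession,
D description, I values in the canonical A R N D C Q E G H I / L K M F P S
T W Y V two-row order) and re-keyed by one-letter symbol, making the
card–property pairing order-independent. Records containing `NA` are
flagged and excluded from screening. Screening ranks properties by signed
Pearson r with the card (anti-correlated properties are thereby
de-prioritized, a deliberate choice) and flags candidates at `r > 0.5`
strictly.

Peptide-level properties reproduce the published benchmark-table columns
that are recoverable from sequence alone:

- **Extinction coefficient (280 nm)**: `5500·n_Trp + 1490·n_Tyr +
  125·⌊n_Cys/2⌋` — every possible cysteine pair is assumed
  disulfide-bonded; an odd cysteine contributes nothing. This rule matches
  all 40 published rows exactly.
- **Net charge**: `n_Arg + n_Lys − n_Asp − n_Glu`, histidine neutral — the
  unique integer rule consistent with all 40 published rows.
- **Molecular weight**: average (not monoisotopic) masses via Biopython.
  Average-mass tables differ by ~0.015 Da per residue between dialects, so
  the agreement contract with printed values scales with length:
  ±max(0.2, 0.02·L) Da. Isoelectric point and the hydrophobicity column are
  not implemented: the pKa set and hydrophobicity scale behind the printed
  values are unidentified, and guessing a scale would produce numbers that
  look authoritative but are not comparable.

## Synthetic data generator

The generator emulates the one feature the model reads: per-class residue
composition. Each class draws residues i.i.d. from a categorical
distribution that is uniform except for a multiplicative weight (`bias`) on
an enriched set (positives) or a depleted set (negatives); lengths are
uniform on [length_min, length_max]. Defaults mirror the real benchmark's
training split — 490 peptides per class, lengths 4–10, positives enriched
in C/W/R, negatives in I/K/V, bias 8, which reproduces the direction and
rough magnitude of the cysteine composition gap seen in real THP data
(~9.6% vs ~1.1%).

What passing tests on this generator do **not** show: real THPs carry motif
structure (RGD, NGR), disulfide topology and length–activity relationships
that an i.i.d. composition model cannot express. The generator validates
the estimation machinery (parameter recovery, calibration of the GA, fold
arithmetic), not biological generalization; claims about real data require
the external benchmark sets.

## Numerical choices and edge cases

- Rounding is half away from zero (112.5 → 113), matching the published
  score tables including the half-integer cases.
- Score-card serialization is a 2-column TSV with an optional
  `#cutoff=<value>` header; round-trips are exact.
- Sequence validation is strict: any character outside the 20-letter
  alphabet (including B, J, O, U, X, Z, gaps, stops) is rejected with the
  record name and offending character; lowercase is accepted and
  uppercased. Duplicate sequences are retained (the benchmarks contain
  them) and counted in a log message.
- Degenerate metric inputs (single-class AUC or cutoff selection) raise;
  zero-variance correlations return NaN (property screening) or 0 with a
  warning (fitness), so a pathological candidate is penalized rather than
  fatal.
- All randomness (fold assignment, GA, generator) flows through
  `numpy.random.default_rng` seeds carried in the relevant config objects;
  identical seeds give bit-identical results.

## Problem sizes

The bundled worked examples are desk-scale (40 peptides, 20-point
correlations) and run in milliseconds. Training demonstrations and tests
use the generator's default 490+490 split with GA population 50; a full
100-generation run takes on the order of a second, and test configurations
use smaller populations/generation counts where the property under test
does not require the full run.
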