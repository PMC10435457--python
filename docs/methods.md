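# Methods

## The modeling problem

The critical micelle concentration of an ionic surfactant depends on its
molecular structure and on the solution it sits in: temperature, pH, and —
decisively for brines — the dissolved-salt content, expressed here as the
NaCl-equivalent salinity *S*eq (the NaCl concentration giving the same
brine resistivity as the actual mixed salts). The package models
log₁₀(CMC) as a function of (*T*, pH, *S*eq) plus a small set of molecular
descriptors of the surfactant anion. Descriptor computation itself
(structure drawing, MM2 optimization, Dragon-style descriptor export) is
upstream of this package: the input is a modeling table CSV with the
physical variables, the response, and precomputed descriptor columns.

## Statistics

For observed *y*ᵉˣᵖ and predicted *y*ᶜᵃˡ:

* R² = 1 − SSres/SStot, SStot about the mean of the supplied observed
  vector. The caller chooses the population (training mean for training
  R², pooled mean for whole-dataset statistics); functions never cache a
  mean. Whether a pooled "total" R² should use the pooled or the training
  mean is genuinely open in the field's reporting conventions; the pooled
  mean is used here.
* RMSD = √(SSres/n); MAE = mean |residual|.
* RSD = √(SSres/(n − d − 1)), d = number of model variables. RSD is the
  subset-selection objective; it penalizes extra variables through the
  degrees of freedom.
* Q²/RMSECV: the same algebraic forms applied to out-of-fold predictions.
  Q² may be negative and is never clamped — the y-randomization scatter
  depends on seeing poor (low or negative) values.

## Subset selection (RM / ERM)

The replacement method is specified in the literature at the level of "swap
the least reliable variable"; the concrete traversal implemented here is:

1. Fit the current d-subset by OLS.
2. Visit the unlocked position with the largest relative standard error
   SE/|β| of its coefficient.
3. Try every pool column not currently in the subset at that position;
   accept the replacement that minimizes RSD if it strictly improves,
   otherwise lock the position.
4. Repeat until all positions lock (capped at `max_passes` visits).

The modified-RM pass is identical except the first visited position takes
its best replacement *unconditionally* — one deliberate uphill move. That
position is then locked for the remainder of the pass; without this lock
the next RM step can immediately undo the escape move, which would make the
pass a no-op. ERM runs RM → modified-RM → RM from each random restart
(default 10) and returns the best subset seen anywhere, including initial
subsets and intermediate states. Ties break to the lowest column index
(candidates are scanned in index order and only strict improvements are
accepted). Candidate subsets whose augmented design is singular or has
condition number above 1e10 are skipped silently (logged at debug level);
the OLS core refuses such designs rather than regularizing, because
selection integrity depends on honest failures.

The subset-size scan runs ERM for d = d_min … d_max (starting at 2) and
chooses the smallest d whose relative RSD improvement to d+1 falls below
2%. The 2% plateau threshold is a design choice: the underlying selection
curves flatten visibly past the right subset size but no exact criterion is
standard. An RSD at rounding-error level (≤ max(1e-12, 1e-10·sd(y))) is
treated as an exact fit and stops the scan.

Selection operates on whatever pool the caller passes — typically the
descriptor columns only, with T, pH, S_eq appended to the model afterwards.

## Linear model and validation battery

OLS with an always-included intercept, classical standard errors with
residual variance SSres/(n − d − 1), no scaling or regularization anywhere
(coefficients act on raw variable values, so fitted models are directly
comparable to printed correlations).

* **LOO** uses the exact PRESS identity (deleted residual = eᵢ/(1 − hᵢᵢ));
  it is algebraically identical to refitting without each sample and is
  verified against an explicit refit loop in the tests. LOO is
  deterministic: repetition cannot change it.
* **LNO** partitions the samples into ceil(1/fraction) disjoint random
  groups per repeat (defaults: leave 25% out, 3 repeats); remainders are
  distributed one-extra-per-group from the front. Each sample is predicted
  exactly once per repeat.
* **Split-resampling** ("bootstrapping" in the QSPR sense) repeatedly
  splits the data at random — literal repeated splitting, not sampling
  with replacement — fits on the training part and records training R² and
  LOO Q²; averages over 5000 splits by default, test fraction 0.1 (the
  source procedure does not state its fraction; 0.1 mirrors the external
  split).
* **y-randomization** permutes the response 1000 times with the design
  fixed; no chance-correlation risk requires every shuffled R² and Q²
  below 0.2 *and* the real model's statistics above the whole cloud.
* **External validation** fits on the 90% training split and scores the
  held-out 10%; both R²ext and Q²ext use the external set's own mean in
  the denominator (the source is silent; using the set's own mean keeps
  the statistic self-contained).
* **Overfit verdict**: R² − Q² > 0.3 (the cited range is 0.2–0.3; the
  permissive end is the default, configurable).

The 90/10 split takes |test| = floor(0.1·n) — for n = 488 that is 48 test
and 440 training records, matching the reported partition (rounding up
would give 49). The split is uniform random, unstratified: whether the
original split was stratified by surfactant family is unstated.

## Multi-gene symbolic regression

A model is bias + Σ wᵢ·geneᵢ(x) with the weights refit by (minimum-norm)
least squares at every fitness evaluation, so evolution searches only the
space of functional forms. Settings stated for the original run and kept
as defaults: population 180, generations 180, operator set
{+, −, ×, /, exp}. Everything else is an undocumented assumption and uses
standard multi-gene symbolic-regression values, all configurable: ramped
half-and-half initialization at depths 2–4, tournament size 4, crossover
0.85 (half gene-level two-point list exchange, half subtree), subtree
mutation 0.1, elitism 1, max 8 genes of depth ≤ 5, ephemeral constants
uniform in [−10, 10]. Fitness is training RMSD.

Numerical protection guarantees finite outputs for finite inputs: a/b = 1
when |b| < 1e-12, exp arguments clamped to ≤ 50, and every operator output
clipped to ±1e100 as an overflow guard. Children exceeding the depth cap
revert to their parent gene. Models serialize to infix text
(`1 + 2*(x1)` canonical form) and to JSON; a parser reads the serialized
grammar back for round-trip checks.

## Stochastic gradient boosting

Least-squares boosting of depth-limited regression trees, each stage fit on
a random row subsample without replacement. The tree core is
scikit-learn's `GradientBoostingRegressor`; the module's own contract is
the workflow above it: staged train/test RMSD after every stage, tree
count selected at the minimum of the test curve (earliest stage on ties),
a learning-rate scan with a shared seed (grid includes 0.09, the optimum
reported for this model family), and split-gain variable importances
rescaled so the maximum is 100. Defaults: depth 3, subsample 0.5, up to
3000 trees — the subsample fraction, depth and importance definition used
originally are unreported, so these are documented package choices. With
subsample = 1 the staged training RMSD is provably non-increasing for
squared-error loss at learning rates below 2 (each stage's tree is the
least-squares fit of the current residuals).

## Published correlations

The eight-variable linear correlation ships as a JSON model document at
full printed precision; the printed ± uncertainties are stored as metadata
and not used in prediction. Comparisons against 3-d.p. printed values use
a ±0.0005 half-ulp tolerance.

The GP closed form is typeset with two ambiguous junctions: the place where
the (BEHp2+G3s)(…S_eq, T…) bracket meets the 0.01423·EEig12x·(pH+G3s)/G3s
factor (multiplication as the terms abut, or a dropped subtraction sign),
and a trailing "− +0.4997". `gp_cmc_2023` therefore takes a `reading`
argument (`as_typeset` or `subtractive`, each documented with its exact
formula in `GP_READINGS`), returns a per-term breakdown on request, and
reports deviations from the printed reference value for the worked example
rather than silently "fixing" the formula. At the shipped SDS record —
where EEig12x = 0 makes the junction term vanish either way — the two
readings evaluate to −0.997 and −1.521 against a printed 0.729, so the
printed value is treated as a disambiguation reference, not a target.

## Synthetic data generator

The generator emulates the structure of the experimental table, which is
not publicly deposited: physical variables uniform over the observed ranges
(T 273.15–363.15 K, S_eq 0–70131.36 ppm, pH 6.146–11.133), descriptors in
equicorrelated Gaussian blocks of 5 (within-block correlation 0.3,
independent across blocks — a realistic collinearity challenge for
selection), and a response from a planted sparse linear truth plus Gaussian
noise. Default planted model: five descriptor terms of weight ≈ 0.4–0.6 on
unit-variance columns plus T/pH/S_eq terms at the published linear
correlation's coefficients, intercept 1.0. The default noise level
(sd 0.40) was derived from the planted signal variance so that training R²
lands near 0.9, the regime of the reported linear model. What the
generator does *not* emulate: real descriptor distributions (heavy tails,
discreteness, exact-zero patterns such as EEig12x for short chains),
family structure among surfactants, heteroscedastic measurement error, and
any true nonlinearity of CMC in the physical variables. Passing tests
therefore demonstrate algorithmic correctness and statistical behaviour
under the stated conditions, not chemical accuracy on real measurements.

A near-constant-descriptor filter is included; its tolerance acts on the
standard-deviation scale (the descriptor's own units), with tol = 0
removing exactly-constant columns.

## Problem sizes in the test suite

Tests run the full 180×180 GP budget once (n = 300) and otherwise use
planted datasets of n = 60–300 with descriptor pools of 6–40 columns,
split-resampling at 5–200 repeats and y-randomization at up to 1000
repeats — sizes at which every oracle comparison (exhaustive subset
enumeration, explicit LOO refit loops, manual split replays) is exact and
fast. The generator's 488 × 1410 default is exercised where the partition
arithmetic itself is the point.

## Known limitations

* The experimental table is unavailable, so the original R²/Q² values and
  the boosted-tree optimum (tree count, test RMSD) cannot be recomputed;
  they are covered by property-based equivalents on synthetic data.
* ERM is a heuristic: equality with the exhaustive optimum is guaranteed
  only on the tested pool sizes (≤ 12 columns); on large pools it inherits
  the usual local-search caveats, mitigated by restarts.
* The GP engine's hyperparameters beyond population/generations/operators
  are package choices; evolved formulas are not expected to match the
  published closed form.
* NaCl-equivalent salinity conversion from mixed-brine compositions is out
  of scope; the input table must already carry S_eq.
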