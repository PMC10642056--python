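# Methods

## The problem

Empirical force-field programs such as FoldX predict the stability change of
a protein (or protein complex) upon a missense mutation as a free-energy
difference ΔΔG (kcal/mol, positive = destabilizing).  Point predictions are
cheap, but their error against experiment varies by an order of magnitude
between mutations, and the programs themselves emit no per-prediction
uncertainty.  This package models that uncertainty directly: it regresses the
observed discrepancy

    Error = |ΔΔG_FoldX − ΔΔG_exp|

on quantities available *without* knowing ΔΔG_exp — the FoldX energy-term
decomposition, the variability of those terms across molecular-dynamics (MD)
snapshots, and biochemical properties of the mutated residue — and converts
the fitted model into a per-mutation error bound B such that the true value
lies within ΔΔG_FoldX ± B at a stated probability.

## Model and error bound

The Error is modelled by ordinary least squares on a predictor pool chosen
from five nested designs (single-structure energy terms; + biochemical
properties; MD-snapshot term means; + biochemical properties; + per-term
snapshot SDs — the full model).  Predictor subsets are ranked by

    BIC = −2·loglike + ln(n)·d

with the Gaussian maximum log-likelihood and d the number of fitted slope
coefficients (secondary-structure dummies counted individually, intercept
excluded; a `plus_intercept` convention is available and shifts every model
by the same constant at fixed n).

For a new mutation with predictor vector x₀, the textbook out-of-sample
prediction interval is

    x₀ᵀβ̂ ± t(1 − α/2, n − p) · s · √(1 + x₀ᵀ(XᵀX)⁻¹x₀).

The *error bound* B is the upper prediction limit.  Two constructions are
provided, and the choice matters:

* **`one_sided` (default).**  B = x₀ᵀβ̂ + t(level, n−p)·s·√(1 + x₀ᵀ(XᵀX)⁻¹x₀).
  For a correctly specified Gaussian model, P(Error < B) = level exactly.
  This is the calibrated object for the coverage statistic below.
* **`two_sided_upper`.**  The upper limit of the central two-sided interval
  at the same level (quantile (1+level)/2).  This is what one obtains from a
  stock regression `predict()` call and is the construction used in the
  original benchmark analyses.  On a correctly specified model it captures
  the Error with probability (1+level)/2 (97.5% at level 0.95); reported
  ~95% capture rates for this construction arise only when the response is a
  folded magnitude whose fitted lower limit falls below zero, which soaks up
  the lower tail.  We verified both behaviours by simulation (two-sided
  upper: ~97.3% LOSO capture on calibrated synthetic data; one-sided: ~94.8%).

Nothing clamps the interval's lower end at zero; downstream analyses use
only B.

## Validation: leave-one-system-out coverage

Mutations within one protein system share structure and measurement context,
so folds are whole systems: the model — including subset selection, which is
re-run on the training fold only, so nothing leaks from the held-out system —
is fit on the remaining systems and every held-out mutation j receives a
bound B_j.  Coverage is the strict fraction

    Coverage = (1/N) Σᵢ Σⱼ I(Error_j < B_j),

which decomposes exactly into the n_i-weighted mean of per-system coverages.
The reported "median width" is the median of the bounds B_j themselves (the
interpretable "± B kcal/mol" margin); a flag switches to the full interval
width for sensitivity checks.  Mutations with Error ≥ B are outliers; their
concentration in particular systems is tested by a chi-squared goodness of
fit against expected counts proportional to system size, with a Monte-Carlo
p-value (default 2000 replicates, p = (b+1)/(reps+1)) or the asymptotic χ²
with (#systems − 1) degrees of freedom.

If a held-out system carries a categorical level absent from the training
fold (e.g. a secondary-structure class), the corresponding dummy column is
constant-zero in training and dropped as aliased; affected held-out rows are
predicted with the reference-level contribution and flagged per row rather
than aborting the fold.

## Subset search

Selection operates on *blocks*: each scalar predictor is its own block and
the secondary-structure dummies form a single block that enters or leaves
together (the category is one predictor; its dummies are retained or removed
as a unit).  Two searches are provided:

* **Best subset.**  Exact branch and bound for pools of ≤ `exact_limit`
  (default 15) blocks: the RSS of a node's relaxed model (chosen blocks plus
  all still-available blocks) lower-bounds the RSS of every completion, so a
  node is pruned when even that RSS plus the smallest reachable BIC penalty
  cannot beat the incumbent.  Pools larger than `exact_limit` are first
  screened to their best `exact_limit` blocks by a greedy forward-RSS pass
  and then searched exactly within the screen; exhaustive search over ~40
  blocks is combinatorially infeasible (C(40, ≤12) ≈ 5.6·10⁹ candidate
  subsets) and pure-noise blocks defeat RSS-only pruning.  The intercept-only
  model is always a candidate.  BIC ties break toward fewer blocks, then
  lexicographic block order.
* **Stepwise.**  Greedy bidirectional search adding or removing one block per
  step, taking the largest BIC decrease, stopping when no move improves.
  Deterministic given data and start.

Numerical policy: exactly aliased columns are dropped keep-first with a
logged warning; candidate subsets whose Gram matrix is non-Cholesky or has
condition number above 1e10 are skipped with a note; a zero RSS makes the
log-likelihood infinite and is an error unless an explicit floor
(RSS ≥ 1e−12·n·var(y)) is requested for degenerate noise-free fixtures.

## Biochemical predictors

Per-mutation properties are derived from frozen residue tables shipped with
the package (van der Waals volumes; hydrophobicity indices at pH 7; formal
side-chain charges; theoretical and empirical maximum accessible surface
areas): proline involvement (0/1), absolute changes in volume,
hydrophobicity and charge, the DSSP secondary-structure class (8 levels
B/E/G/H/I/S/T/none; dummy-coded against reference B), and relative solvent
accessibility RSA = ACC/maxASA clipped to [0, 1] (theoretical maxASA by
default).  Histidine carries charge 0 by default (pKa ≈ 6); a fractional
convention is configurable.  DSSP files are parsed through Biopython; a
wild-type/DSSP residue mismatch is an error in strict mode and a warning
otherwise.

## Classification with error bounds

Point classification uses the conventional ±0.5 kcal/mol thresholds, with
the neutral class owning the boundaries.  With a bound B, the closed
interval [ΔΔG_FoldX − B, ΔΔG_FoldX + B] is intersected with the three class
bands; a mutation is classified unambiguously only when exactly one band is
overlapped, and the overlapped set grows monotonically with B.  Frequency
summaries bin mutations along a ΔΔG axis into left-open right-closed bins
(default width 1 kcal/mol, aligned to the ±0.5 thresholds, open outer bins).
The resampling analysis draws n_per_bin rows with replacement from every
nonempty ΔΔG_exp bin — flattening the destabilizing-skewed experimental
distribution — with one master seed spawning an independent child stream per
bin for reproducibility without cross-bin coupling.

## Synthetic data: what it does and does not emulate

The generator produces datasets with the statistical shape of a multi-system
ΔΔG benchmark: 10 systems of 19–190 mutations (uniform) by default, 16
constituent energy terms plus a total (= sum of constituents + noise, so the
total correlates with but is not aliased to them), per-term snapshot SDs
(log-normal, scaled by a shared per-row conformational-variability factor),
optional noisier single-structure term columns, and biochemical properties
derived from the real residue tables via uniformly drawn ordered residue
pairs (proline involvement forced with probability 0.05 by default;
secondary-structure classes drawn from a fixed distribution that never emits
the rare π-helix class I; RSA from a Beta(0.9, 1.8), buried-skewed).

The response is generated forward from the stated truth,
Error = intercept + xᵀβ + u_system + ε with ε Gaussian and optional
system-level effects u, then inverted into ΔΔG_exp = ΔΔG_FoldX − s·Error
with the sign s chosen per row to skew the experimental classes roughly
70/20/10 destabilizing/neutral/stabilizing.  Default true coefficients sit
on MD-mean van der Waals, van der Waals clash, side-chain entropy, the SD of
the total energy, and the proline flag — magnitudes of order 0.4–0.7
kcal/mol per unit, the scale reported for such models.  Because the Error is
a magnitude, negative draws are resampled (row-wise redraw of ε); the
default intercept of 2.0 kcal/mol keeps the linear predictor ≈ 3.5 noise-SDs
above zero, making that guard an ~2·10⁻⁴ event so OLS coefficient recovery
stays unbiased.  The cost of that choice is scale: synthetic Errors are
centred near 3 kcal/mol, larger than real benchmarks' medians (~0.7), which
is immaterial for calibration and recovery claims (both are
scale-equivariant) but means absolute widths should not be compared against
real-data tables.  A clamp flag exists to study the truncation
misspecification deliberately.

Not emulated: FoldX physics, real correlations among energy terms (terms are
drawn independently), MD autocorrelation, experimental measurement error,
and the folded (|·|) response structure of real Error data.  A green
calibration test therefore establishes that the pipeline is internally
correct, not that real FoldX errors follow a linear Gaussian model.

## Numerical and design choices

* Snapshot aggregation uses the sample SD (n−1) by default; population SD is
  a flag.  SDs are forced to exactly 0 when all snapshot values are equal.
* Tidy tables are read with round-trip float parsing, so read → write →
  read is the identity.  Duplicate mutation keys are an error, never
  averaged.
* Coverage uses the strict inequality Error < B; an exact tie counts as a
  miss (ties have measure zero in practice).
* The model ladder re-runs selection inside each fold for its headline
  metrics and reports coefficients, p-values and interval-width effects from
  the all-data fit; the effect of a predictor on the bound is the difference
  between bounds at the means of its top and bottom deciles (1 vs 0 for
  binary flags), all other predictors at dataset-wide means.
* Per-fold selected subsets are exposed so fold heterogeneity and leakage
  can be audited.

## Known limitations

* The Error response is fit on the raw scale; heteroscedastic, quantile or
  GLM alternatives for non-negative responses are out of scope.
* Best-subset results above 15 candidate blocks are exact only conditional
  on the forward screen.
* The generator draws energy terms independently; a correlation hook would
  be needed to study collinear-pool behaviour realistically.
* Real-data reproduction of the published benchmark tables requires the
  deposited dataset (an external download) and inherits that study's
  selection ambiguities.
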