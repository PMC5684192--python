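# Methods

## Clonotype definition and aggregation

A clonotype is the set of T cells sharing one CDR3 amino-acid sequence
of the TCR-beta chain. Aggregation keys on (donor, subset, CDR3) only;
V/J gene calls are carried as annotation (taken from the most abundant
contributing row) and never enter clonotype identity. Counts are
template/cell counts and must be positive integers — the downstream
"highly represented" rule (≥ 10 cells) is only meaningful for integer
abundances, so fractional counts are rejected at parse time. Rows whose
CDR3 is empty or contains characters outside the 20-letter amino-acid
alphabet (stop `*`, frameshift `_`, ambiguity codes) are treated as
non-productive, dropped, and counted in a skip tally; productive-only
analysis is the field default and the two supported dialects (AIRR-style
and immunoSEQ-style TSV) behave identically after parsing.

## Normalized clonality

For frequencies f₁…fₙ over the n distinct clonotypes of a sample,

    H = −Σ fᵢ log₂ fᵢ / log₂ n,     C = 1 − H.

Log base 2 throughout. The statistic is scale-free in n and bounded in
[0, 1]: 0 for a uniform (perfectly polyclonal) repertoire, 1 in the
monoclonal limit. **Degenerate case n = 1:** the normalization divides
by log₂ 1 = 0; we define H = 0, C = 1 for monoclonal samples —
continuous with the statistic's interpretation — and flag the sample
(`monoclonal: true`) in output metadata. Frequencies must be strictly
positive and sum to 1 within 1e-9; tiny rounding excursions of H outside
[0, 1] are clamped.

## Bootstrap size normalization

Clonality depends on sample size, so repertoires sequenced at different
depths are compared after resampling each to a fixed size (default 1000
cells, configurable) with replacement. Each replicate is a multinomial
draw over the sample's clone frequencies; clonality is recomputed on the
resampled counts with n equal to the replicate's realized richness
(clonotypes that drop to zero leave the sample, as in a genuine
resequencing). The replicate count defaults to 100 (a reproducibility /
runtime compromise; the underlying study does not state one) and the RNG
is always explicitly seeded — identical inputs and seed give
bit-identical summaries. Reported: mean, sample SD and the 2.5/97.5
percentile interval over replicates.

## Clonotype sharing

Sharing is deliberately asymmetric and source-relative: the fraction of
distinct source clonotypes (exact CDR3 string match, no fuzzy matching)
present in the reference, regardless of reference abundance. "Highly
represented" clonotypes are those with ≥ `min_cells` cells in the
*source* repertoire (inclusive threshold, default 10; source-only
because the combined-donor alternative is not well defined for sorted
subsets). Because sharing can be weighted by clonotypes or by cells,
both are reported: the clonotype-weighted shared fraction of the highly
represented set, and the fraction of source *cell mass* that set holds.

`percentile_threshold` inverts the abundance rule: the smallest integer
t such that at most a given fraction of clonotypes have count ≥ t. With
heavily tied count distributions no threshold may select a non-empty set
within the fraction; the operation then returns the smallest t selecting
exactly the maximal-count clonotypes, and if *all* counts are tied there
is no defensible split at all — a sentinel (max count + 1) is returned
with a warning rather than an arbitrary tie-break.

## Constant-plus-variable composition model

Donor-level flow cytometry gives f_temra (TEMRA as a fraction of CD4
T cells) and f_dn (GPR56−Perforin− TEMRA as a fraction of CD4 T cells).
The model posits a single constant c — the absolute double-negative
frequency, shared by all donors — plus a variable GPR56+/Perforin+
component, so the double-negative proportion within TEMRA is

    p_dn(f_temra) = min(1, c / f_temra),

identically 1 below f_temra = c and strictly hyperbolically decreasing
above it (the decay is sometimes described loosely as "exponential"; the
constant-fraction model implies the c/f form, which is what is
implemented — the wording discrepancy is noted, not resolved). On the
unclipped branch f_temra · p_dn = c exactly (conservation of the
constant component).

c is estimated by bounded one-dimensional least squares
(`scipy.optimize.minimize_scalar`, bounds (1e-5, max f_temra), xatol
1e-10), by default on the proportion scale — what composition plots
show — with a log-frequency option that compares implied absolute
double-negative frequencies on the log scale instead. The verbal model
statement fixes no objective, so the scale is an exposed parameter
rather than a guess. Observations with f_dn > f_temra (measurement
noise) are clipped to p_dn = 1 with a warning. The fit is declared
degenerate (an error, not a number) with < 2 observations, < 2 distinct
f_temra values, or when every donor is clipped — any c ≥ max f_temra
then fits equally well.

## Synthetic cohorts

The generator emulates the structural features the analysis needs, not
the biology of VDJ recombination:

* **Clone sizes** follow a Zipf (power-law) distribution over a per-
  subset clonotype pool — probability ∝ rank^(−z) — the standard minimal
  model of clonal expansion; the exponent z is the single skew knob
  (z = 0 is uniform). Cells are a multinomial draw; pool members drawn
  zero times are absent from the realized repertoire.
* **Sharing**: a linked subset fills each clonotype-pool slot from a
  named source subset's *realized* repertoire with a set probability
  (several sources allowed, probabilities summing ≤ 1), else draws a de
  novo CDR3 (random 'C'…'F' string, rejection-sampled against
  collisions). Sharing copies identity only; abundances are re-drawn in
  the target, matching the observation that shared clonotypes are rare
  in the reference subset. Pools are shuffled before rank assignment so
  shared status is independent of clone size.
* **Composition**: per donor, f_dn = c · lognormal(0, sd) (frequencies
  are positive and span an order of magnitude, hence multiplicative
  noise; sd defaults to 0.2) and f_temra = f_dn + a variable component
  placing target totals geometrically over the configured range.

Defaults are the study-like conditions: c = 0.8%, f_temra over
0.4%–18%, 11 donors, 1000 cells per subset, GPR56+ TEMRA sharing 55%
of its clonotypes with TEM and 5% with TCM. The preset's pool sizes and
exponents (TN 4000/0.0, TCM 4000/0.1, TEM 1500/0.75, GPR56− TEMRA
1500/0.45, GPR56+ TEMRA 300/1.4) are package choices, set once so the
preset reproduces realistic clonality magnitudes (GPR56+ TEMRA ≈ 0.37,
TEM ≈ 0.07, TCM/TN ≈ 0.02 after 1000-cell bootstrap) and the qualitative
ordering GPR56+ TEMRA ≫ TEM > GPR56− TEMRA > TCM ≈ TN.

What a green test does *not* establish: the generator has no VDJ
recombination model, no sequence-dependent generation probabilities, no
convergent recombination (identical CDR3s arising independently), no
donor-level covariance between repertoire skew and cytometry
composition, and its clone-size law is exactly Zipf rather than the
heavier-tailed mixtures real expanded repertoires show. Tests against it
validate the *computations*, not any biological claim.

## Numerical choices and limitations

* Entropy sums are evaluated in double precision via vectorized numpy;
  the test oracle uses compensated summation (`math.fsum`) and agreement
  is required to 1e-12 up to 10⁴ clonotypes.
* Bootstrap SD uses ddof = 1 (sample SD over replicates); a single
  replicate reports SD 0.
* All randomness flows through `numpy.random.default_rng(seed)`;
  cohort generation, resampling and file emission are byte-reproducible
  under a fixed seed.
* Statistical subset comparisons (two-tailed Mann–Whitney U) delegate to
  scipy and are reported unadjusted, as is conventional for small
  pairwise subset panels; no bespoke multiple-testing machinery.
* Known limitations: no nucleotide-level clonotyping, no repertoire
  similarity indices beyond the sharing fractions (no Morisita–Horn or
  abundance-weighted Jaccard), no richness estimators or rarefaction
  beyond the single fixed-size bootstrap, and the composition model is a
  two-parameter-family-of-one: a single global c with no donor-level
  random effects.
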