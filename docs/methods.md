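# Methods

## The attribution model

The observable is a single categorical trait per archaeological find: the
prickle morphotype X ∈ {T1, T2, TO}. The parameter space is the discrete
set of candidate taxa θ ∈ {θ_1, …, θ_n} (in the bundled case study,
fifteen *Rosa* taxa plus *Rubus ulmifolius*, n = 16). Attribution is
Bayes' rule on this finite space:

    p(θ_i | x) = p(x | θ_i) p(θ_i) / p(x),
    p(x)       = Σ_i p(x | θ_i) p(θ_i).

Each find is attributed independently; there is no joint modelling of
assemblages, no hierarchy over taxa, and no continuous-trait likelihood —
the morphometric measurements enter only through the (deterministic)
morphotype classifier upstream. The reported identification is the MAP
taxon; exact ties are broken by taxon order and surfaced in an explicit
tie list.

### Likelihoods

p(x | θ) is estimated from a reference collection of modern stem and
leaf-rachis fragments of known taxa by pooling raw prickle counts across a
taxon's fragments:

    p(x_j | θ_i) = (n_ij + α) / (n_i· + 3α).

Pooling raw counts (rather than averaging per-fragment proportions)
implicitly weights fragments by length and is the multinomial MLE at
α = 0. The smoothing default is **α = 0**: structural zeros in the
reference counts (a taxon that never bears T1) should propagate to exact
posterior zeros, as in the bundled case-study table. Laplace smoothing
(α > 0) is available for robustness work. A taxon with zero prickles
overall has no defined row at α = 0 and is flagged `undefined` rather than
imputed; using such a table with a prior that puts mass on the undefined
taxon is an error rather than a silent NaN.

Both organs are pooled by default; an `organ_filter` restricts estimation
to stems or leaf rachises. An optional per-plant abundance weighting
rescales a taxon's effective counts by its estimated prickles-per-bush
relative to the mean; since rows are renormalized this does not change the
per-row probabilities, only the effective-count metadata, and it ships off
by default as an explicitly documented opt-in.

### Priors

A prior scenario is a named weight vector over the candidate taxa. Two
stances are bundled: uniform neutrality (1/n each), and weights elicited
from historical and biogeographical evidence, which legitimately assign
exact zero to taxa judged implausible. Published prior columns are rounded
to two decimals (sixteen uniform weights print as 0.06 and sum to 0.96),
so a scenario accepts raw weights summing to 1 within ±0.02 and
renormalizes internally, keeping the raw values for provenance. Report
rounding is half-up at two decimals, matching published-table convention;
full precision is retained internally.

### Inversion and consistency checking

Bayes' rule inverts algebraically: likelihood_i ∝ posterior_i / prior_i.
This makes a *pair* of published posterior columns under two known priors
over-determined — the uniform-prior column is itself the normalized
likelihood column, so the informed-scenario column must follow from it by
one forward application of Bayes' rule, and dividing the informed column
by its prior must recover the uniform one. `recon.reconstruct_posteriors`
runs both directions on the bundled table; agreement with the printed
values is limited only by input rounding.

Conditioning matters in the inverse direction: a printed cell's recovered
ratio carries relative error up to 0.005/posterior + 0.005/prior from
rounding alone (half a printed unit in each input). Cells where this bound
exceeds 50% (`recon.well_conditioned`) are excluded from whole-table
consistency checks; in the bundled table that is a single taxon with
prior = posterior = 0.01. Taxa with prior 0 *and* posterior 0 are
indeterminate (no information about their likelihood), not evidence; a
positive posterior on a zero prior raises an inconsistency error.

## Morphotype classification

The classifier compares measured length, base width and curvature class
against per-type prototypes: T1 = 2.5 × 3 mm, hooked; T2 = 5 × 2 mm,
slightly curved. A prickle matches a prototype when the curvature class
equals the prototype's and both dimensions fall within ±50% (relative) of
the prototype dimensions; no match means TO. Only the prototype dimensions
are externally given; the ±50% window is this package's decision boundary —
it separates the two prototypes cleanly (their windows do not overlap in
the width dimension, and curvature is categorical anyway) and is tunable
per prototype. T2 dimension reports vary between 5 × 2 mm and 4 × 2.5 mm
in the source descriptions; the defaults follow the former, and the latter
still classifies as T2 under the default window. A pre-assigned type
always overrides measurements; unknown curvature without an assigned type
yields TO with a `UserWarning`, never an exception.

Per-plant abundance extrapolates a linear density (prickles/cm of stem)
through an archetype bush of twenty 1.5 m stems: total = density × 150 cm
× 20. Densities of ~0.17–27 /cm map to ~500–80,000 prickles per plant.

## Synthetic data

The generator emulates the statistical structure of a modern reference
collection, per taxon profile (type-proportion 3-vector, density/cm,
stem fraction):

    length ~ Uniform(3, 9) cm
    total  ~ Poisson(length × density)
    counts ~ Multinomial(total, proportions)

Fragment lengths are continuous uniform because only the observed 3–9 cm
range is known; Poisson totals are the simplest count model consistent
with a per-cm density (no over-dispersion — a negative-binomial hook would
be the natural extension). Simulated archaeological finds draw a true
taxon from a prior scenario and a type from that taxon's proportions,
retaining the truth label. All generators are pure functions of
(config, seed) via `numpy.random.default_rng`.

What this does **not** emulate: taphonomy (charring, flotation recovery
bias), within-taxon heterogeneity between plants, correlation of types
along a stem, or measurement error in typing. Passing the synthetic
end-to-end checks therefore demonstrates the *inferential machinery* is
correct and well-calibrated under the stated sampling model — not that
real reference collections satisfy that model.

### Calibrated profiles

`datasets.calibrated_profiles` builds profiles whose T1 and T2 likelihood
columns are proportional to the bundled uniform-prior posterior columns
(the proportionality a flat prior guarantees), using one common scale
factor chosen so the taxon richest in T1+T2 mass keeps a TO fraction of
0.2; TO absorbs the per-taxon remainder. The TO fractions and the uniform
2.0/cm density are synthetic stand-ins — nothing published constrains
them — so only within-column ratios are meaningful. The reference data
behind the original likelihoods (97 modern samples) was not published;
every density in this package is a synthetic placeholder.

## Problem sizes and numerical choices

- Parameter-recovery check: 200 fragments/taxon at 2 prickles/cm
  (≈2,400 prickles/taxon; binomial SE bound ≈0.01, checked against a 0.05
  band).
- End-to-end calibrated pipeline: 2,000 fragments/taxon, chosen from the
  error budget — the deterministic reconstruction-vs-printed gap is up to
  0.007 per cell, leaving ~0.013 of the ±0.02 band for sampling noise,
  met at ≈24,000 prickles/taxon (posterior 3σ ≈ 0.009). Runs in seconds.
- Row-stochasticity is enforced at 1e-9 on construction; posterior
  normalization at 1e-9; inversion round-trips are exact to ≤1e-9 in
  floating point.
- Half-up decimal rounding (`round_half_up`) is used for all printed
  tables; Python's banker's rounding is never used for report output.

## Known limitations

- Single-trait likelihoods: dimensions and curvature inform attribution
  only through the three-way type, discarding within-type variation.
- The informed prior weights are an opaque elicitation — this package
  treats them as given inputs and can only test sensitivity to them, not
  derive them.
- The morphotype decision boundary (±50%) is a convention, not fitted to
  data; misclassification of borderline prickles propagates directly into
  the attribution.
- With α = 0, a taxon unseen bearing some type can never be attributed a
  find of that type, however strong the prior — the usual zero-count
  brittleness of unsmoothed categorical likelihoods.
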