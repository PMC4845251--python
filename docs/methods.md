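# Methods

`swardlab` analyses pot-scale (mesocosm) grassland diversity experiments in
which a small pool of grasses and one legume is grown in monocultures,
pairwise mixtures and a full-pool mixture under a repeated cutting regime.
This note documents the models and conventions the package implements, the
synthetic-data generator it is tested against, and the numerical choices
that matter.

## Diversity-effect partition

For a mixture with species *i = 1..N*, monoculture reference means *M_i*
(averaged over replicate monoculture pots per period) and expected
proportions *p_i*, the package computes

- expected biomass `E_i = M_i p_i`,
- relative-yield deviations `ΔRY_i = O_i / M_i − p_i`,
- net diversity effect `net = Σ (O_i − E_i)`,
- complementarity effect `CE = N · mean(ΔRY) · mean(M)`,
- selection effect `SE = N · cov(ΔRY, M)`,

with `cov` the population covariance (divisor *N*), which makes
`net = CE + SE` an algebraic identity rather than an approximation.
Proportional deviations `D = (O − E)/E` are reported per species and pooled
per functional group (all grasses vs. the legume), the pooled convention
being `D_group = (Σ O − Σ E)/Σ E`.

Conventions, all labeled in the outputs and switchable in config:

- `p_i` defaults to the **sown** proportion (equal shares at establishment),
  the standard additive-partition convention; a realized-proportion variant
  is available.
- Partition is computed per **composition** (replicate mixture pots averaged
  first) by default; a per-pot variant is available.
- Zero observed biomass of a species in mixture is valid (`ΔRY_i = −p_i`);
  a zero or missing monoculture mean is an error because relative yield is
  then undefined.
- Sward-type aggregates (2−, 2+, 5+) are plain means over compositions.

### Known estimator bias

On noisy data the plug-in estimator divides by estimated monoculture means,
and `E[1/M̂] > 1/M`, giving CE a positive and SE a matching negative
small-sample bias of order `cv² / n_mono` (≈ +2.5% of CE at biomass CV 0.15
with 4 monoculture replicates). The Monte-Carlo recovery test therefore
checks that this bias is small relative to the estimator's own
between-dataset standard error (within 3 SE), not that the estimator is
exactly unbiased; with 200 replicate datasets the measured bias is about
0.2 estimator-SE. Users comparing very precisely replicated designs should
be aware the partition inherits this ratio bias.

## Resource-use metrics

- **Daily ET** from pot weights: `ET_t = (W_{t−1} − W_t) + additions_t`.
  Negative corrected values (condensation, scale error) are clipped to 0
  and counted; the raw series is kept so period mass balances stay exact.
- **REW**: `(SM_t − SM_min)/(SM_max − SM_min)` with defaults 0.054 (drought
  minimum, from a companion drydown on the same soil) and 0.379
  (well-watered maximum). Because the bounds come from parallel
  measurements, observed moisture may fall slightly outside them; values
  are clipped into [0, 1] with a warning rather than rejected.
- **WUE** = biomass / ET (g kg⁻¹), exposed per period and per year; the
  per-period variant feeds the trait models.
- **Nyield** = (N% / 100) × biomass; **Nyield/ET** divides by the same
  period's ET.
- **Community leaf area** = Σ (biomass_i / 1000) × SLA_i (explicit g→kg).
- **Growth rates** (height, deep root length): Δvalue/Δdays between
  consecutive measurement dates; an interval is assigned to the period
  containing its **end** date (growth is realized by the time it is
  measured; the convention was open and is fixed here). Root-length
  decrements are floored at 0 before the rate is formed (the record is
  cumulative growth); height decrements are kept, but the reported
  statistic is the per-period maximum so they rarely matter. A period with
  no interval is a missing value, not an error.
- **Biom st1** = 100 × top-layer biomass / total biomass.

Internal units are fixed (biomass g, water kg, SLA m² kg⁻¹); conversions
happen only at documented points.

## Community-weighted means and functional diversity

`CWM = Σ p_i t_i` with trait-specific abundance weights: total biomass for
LDMC, green-leaf biomass for N, leaf area for δ¹³C. Height growth and
species-level top-layer share have no stated rule and default to
total-biomass weights; results carry a `weighting_is_default` flag.
Community-level variables (L.area, WUE, Nyield/ET, REW, R.growth, community
Biom st1) pass through unweighted.

`FD_Q = Σ_i Σ_j p_i p_j d_ij` (Rao's quadratic entropy) on the six
species-level traits (Biom st1, δ¹³C, H.growth, L.area, LDMC, N), with
total-biomass abundances. The default dissimilarity is Gower distance on
range-standardized traits (d ∈ [0, 1]); squared Euclidean on z-scores is
available, and the convention used is recorded in the output. Constant
trait columns carry no information and are dropped with a warning.
Monocultures have `FD_Q = 0` by construction.

## Trait models

Responses (community biomass, net effect, complementarity; per mixture
composition) are regressed on the ten community trait variables.
Whole-experiment scope averages each predictor over periods and sums the
responses; single-period scope uses that period only. Predictors are
z-standardized (constants recorded; a constant column is an error).

- **Best subset**: all C(10, k) OLS subsets for k ≤ 5 (cap configurable;
  five chosen because larger models stop improving the fit in this design),
  scored by leave-one-out CV mean squared prediction error via the exact
  identity `e_(i) = e_i / (1 − h_ii)`. Leverages within 1e-10 of 1 and
  rank-deficient subsets are skipped with a warning. Near-ties in CV error
  (within 1e-9 of the response variance) go to the smaller subset.
- **LMG**: Shapley decomposition of R² — the mean R² increment of each
  predictor over all k! orderings, computed by subset enumeration.
- **PMVD**: the proportional-marginal scheme; ordering weights
  `w(r) ∝ Π_{i<k} 1 / max(R²_full − R²(r_1..r_i), ε)` with ε = 1e-12, so a
  predictor with no partial contribution receives a vanishing share (LMG
  gives it a positive one). If every weight degenerates the code falls back
  to LMG with a warning. Both are limited to subsets of ≤ 8 predictors
  (exact enumeration); larger requests error rather than silently sample.
- Shares are reported raw (summing to the model R²) and normalized to 100%.
- Fits are ordinary least squares throughout; mixed-effect variants and
  coefficient-level significance tests are out of scope. An optional
  square-root/Box-Cox response pre-transform is deliberately not applied by
  default.

## Synthetic-data generator

The generator emulates the study design: 53 pots (5 monocultures × 4
replicates, 10 pairs × 3, one five-species mixture × 3), six cutting
periods on a (year, day-of-year) calendar including one winter-spanning
period, and a default pool of four grasses (tall/deep: `dg`, `fa`;
short/shallow: `pp`, `tf`) plus the legume `tr`.

- **Biomass**: species mean = monoculture yield × sown share × interaction
  multipliers × mean-1 lognormal noise. Baseline monoculture yields follow
  the seasonal course of a cut fertile sward, with the legume establishing
  slowly in its first spring. Multipliers: a symmetric complementarity
  surplus (default 0.12) for all mixtures; grass facilitation next to the
  legume ramping linearly from period 3 (0 → 0.4), matching the delayed
  onset of legume effects; legume relative yield suppressed (×0.35) in its
  establishment phase — two periods in pairs, stronger and longer (×0.35²
  for four periods) in the five-species mixture, where clover establishes
  slowest. Noise CV defaults to 0.15, a typical pot-to-pot biomass CV for
  replicated mesocosms; no variance components are published for this
  design, so it is an exposed free parameter, not a calibrated claim.
- **Ground truth** is computed from the noise-free means through the same
  partition code, so `net = CE + SE` holds to machine precision and the
  truth is the exact expectation of the realized tables.
- **Water**: a store-and-drawdown model. Daily ET ∝ current community leaf
  area (regrowing within each period after a cut), capped so moisture never
  falls below the drought minimum; every third day the pot is refilled to
  the 80%-of-field-capacity setpoint and the addition logged. Pot weight =
  tare + dry soil + water, making daily ET exactly recoverable by mass
  balance (to 1e-9 kg). Depth-resolved sensor moisture draws a larger share
  from the deep layer in legume pots, reproducing the deeper water use of
  clover mixtures. This is bookkeeping, not soil physics: no drainage,
  rainfall stochasticity, or root-water-uptake model.
- **Traits**: Gaussian draws around species means at instrument-specific
  dates (leaf traits twice; N at each harvest; δ¹³C at three harvests);
  height accumulates at a noisy species rate and resets to the 5 cm cutting
  height at cuts; pot-level root length accumulates at a biomass-weighted
  community rate (boosted by the facilitation ramp in legume pots) and
  never decreases.
- **Randomness**: one master seed; independent child streams per pot and
  per sub-model (biomass / water / traits) derived via `SeedSequence`
  spawning, so identical seeds give byte-identical output files.

What passing tests on this generator do **not** show: the generator has no
species×year weather interactions, no spatial structure, no measurement
drift, no missing data, and its interaction structure is exactly the
multiplicative form the partition decomposes — real data will violate all
of these, so recovery results bound estimator behavior under the model's
assumptions only.

## Problem sizes and runtime

Default test and acceptance runs use the full 53-pot design: the pipeline
completes in a few seconds; the recovery experiment uses 200 replicate
datasets and the planted-signal experiment 200 replicates at n = 30
communities, each under a minute on one CPU.

## Degenerate inputs and tie-breaks (summary)

- ET with < 2 weight records, unordered dates: error. Negative ET: clip +
  count.
- REW with inverted bounds: error; out-of-range moisture: clip + warn.
- Partition with N < 2 or any M ≤ 0: error. Weights not summing to 1
  (|Σp − 1| > 1e-6 for partitions, 1e-9 for CWM): error.
- FD on one species: 0 without computing distances.
- Best-subset ties: smaller subset, then lexicographic predictor order.
- LMG/PMVD with zero full-model R²: shares normalized to equal splits.
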