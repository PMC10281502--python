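# Methods

## Model structure and assumptions

The package partitions a polar bear's total body mass into structural
mass (bones, hide, viscera, structural muscle — assumed unavailable to
metabolism even under starvation) and storage mass, and splits storage
into adipose and storage-muscle compartments whose proportions vary with
body condition. Two assumptions of the classical single-storage approach
are relaxed: strong homeostasis of storage (here the energy density of a
kg of storage changes with condition, because the storage-muscle share
and the adipose lipid share are condition-dependent) and isomorphy of
structure (the fitted length exponents are free and in practice fall
below 3, so the shape-density K/L³ declines with length). Structure
itself is still assumed homeostatic, and only storage lipids and proteins
are counted as metabolizable energy (39.3 and 18.4 MJ/kg).

The condition covariate throughout is the scaled mass index
`SMI = M (L0/L)^b`: the mass an individual would have at the reference
length L0, sliding along the population's log-log allometry. The SMA
slope is estimated as sign(r)·sd(ln M)/sd(ln L) — the classical
standardized major axis, appropriate because both variables carry
measurement error — and L0 defaults to the mean training length and is
persisted with the parameters so fitting-time and prediction-time SMI
agree.

## Fitting processes

Four Bayesian fits parameterize the model:

1. **Combined fit** (dissection data): a lognormal regression of total
   muscle U on (ln L, ln A) jointly with a beta regression of the latent
   storage-muscle proportion on SMI. Within each posterior draw,
   structural muscle K_U = exp(α_lU0 + β_lU1 ln L) converts observed U
   into P_OU = (U − K_U)/(A + U − K_U), which enters a beta likelihood
   with mean logit⁻¹(α_POu + β_POu·SMI) and precision φ1 (shapes a = μφ,
   b = (1−μ)φ). Draws for which any latent proportion leaves (0, 1)
   receive −∞ log density; the sampler counts such support rejections. A
   sex-varying variant (sex-indexed α_POu, β_POu) is provided; its
   diagnostics are reported so the degradation expected at 31 records is
   visible. A two-stage fallback (regression first, beta regression on
   plug-in proportions) exists for debugging; the joint fit is canonical.
2. **Structure non-muscle** (dissection data): lognormal regression of
   hide+viscera+bones on length.
3. **Adipose lipid** (biopsy data): beta regression of the adipose lipid
   proportion on SMI with sex-specific intercepts. If one sex is absent
   the missing intercept is estimated under the proper Normal(0,2) prior
   only and the fit carries a `missing_sex` flag.
4. **Adipose protein** (chemistry data): beta regression of the protein
   proportion on the lipid proportion.

Two prior sets are available: *unrestricted* (improper flat priors, scale
parameters flat on (0,∞)) and *weakly informative* (Normal(0,2) on
coefficients; Uniform(0,1) on the lognormal residual sds; Normal(0,2) —
effectively half-normal — on the allocation precision φ1; Uniform(0,100)
on the adipose precisions φ2, φ3). Flat priors contribute no density;
their propriety in practice is assessed by comparing against the
proper-prior fit (the `prior_sensitivity` report).

## Sampler

No Hamiltonian Monte Carlo backend is used; the package ships its own
adaptive random-walk Metropolis engine: chains updated in lock-step with
the log posterior vectorized over chains, Haario-style proposal
covariance (2.38²/d times the empirical warmup covariance) with a
Robbins–Monro global scale tuned to an acceptance rate of 0.3, and
adaptation frozen at the end of warmup. Positive parameters are sampled
on the log scale with the Jacobian correction; predictors are centered
internally (a linear shear undone before reporting) to decorrelate
intercepts from slopes. The combined fit updates the regression and
allocation blocks alternately, which shortens autocorrelation times. An
optional parallel-tempering ladder (`SamplerConfig.betas`) is available
for difficult posteriors but defaults to a single temperature. Defaults:
4 chains, 3000 warmup + 8000 retained iterations, typically 1–7 s per
fit. Identical seed and configuration reproduce draws bit-for-bit.

Diagnostics are arviz rank-normalized split-R̂ and bulk ESS, with default
thresholds R̂ ≤ 1.01 and ESS ≥ 100. Random-walk Metropolis has no
divergent trajectories; the reported `divergences` count is the number of
proposals whose log density evaluated to NaN (numerical breakdown, zero
for a healthy fit), and support rejections are tallied separately. The
Bayesian energy-fraction diagnostic is undefined for this sampler and is
reported as None.

## Synthetic data

The generators emulate the four field datasets with known truth
parameters. Defaults emulate the study scales: 31 dissections, 140
biopsies, 25 adipose chemistry samples, 36 recaptures; lengths 0.9–2.6 m;
condition (SMI) span 130–240 kg; adipose lipid proportions inside the
observed 0.45–0.75 range; recapture intervals 8–200 days with mass
changes of 0.2–0.8 kg/day, a small fraction of animals gaining; isotopic
observation error 2.7% (one-sigma, proportional).

Default truth values were chosen once so that derived quantities land in
published descriptive ranges — structural length exponents slightly below
3 (2.90 / 2.85), a storage-muscle proportion declining from ~0.39 to
~0.11 across the condition span, female adipose-lipid intercept above the
male one, an exponential-decay-like protein–lipid relation, and adult
masses of hundreds of kg. The allocation precision is deliberately small
(φ1 = 2.5), matching the wide scatter of dissection-derived
storage-muscle proportions and the premise that a Normal(0,2) prior on
this precision is only weakly informative when the precision itself is
small.

Dissection records close exactly (total mass equals the sum of tissue
parts) and hit their target SMI exactly; the hide/viscera/bones split of
structure non-muscle uses fixed fractions (0.35/0.30/0.35), which nothing
downstream consumes beyond the sum. Structural muscle is generated as the
deterministic allometry prediction, so the latent proportion recovered by
the combined fit at the truth parameters equals the beta-distributed
proportion drawn by the generator and is always inside the fit's support
— a requirement for the generated data to be valid inputs for their
consumer. A consequence worth stating plainly: the combined fit's
regression term cannot be simultaneously exactly specified, because the
model uses the single observation U in two likelihood terms; under this
generator the residual scale sd_lU and the adipose exponent β_lU2 have no
generative truth (they absorb allocation-induced scatter), and recovery
checks therefore assess the five parameters that do (α_lU0, β_lU1,
α_POu, β_POu, φ1).

Recapture bears are adults measured at the same true length twice
(optional measurement jitter, default zero), with true storage lipid at
each timepoint computed through the full composition chain; with the
noise set to zero the validation round trip is exact to numerical
precision. The generators do not emulate seasonal feeding ecology,
demographic structure beyond age-class labels, or field measurement error
models (none is published), so passing tests demonstrate statistical
self-consistency of the pipeline, not field realism.

## A real degeneracy of the combined fit

At low allocation precision the beta shape a = μφ1 drops below 1 at the
high-condition end, and the beta density then diverges as a proportion
approaches 0. Because the latent proportions move with (α_lU0, β_lU1),
the joint likelihood is unbounded as the smallest latent proportion is
driven to 0, and the generator itself (drawing from that same beta law)
routinely produces bears with proportions of 1e−3 or smaller — data
essentially on the boundary. The posterior then carries an integrable
spike on the latent-support boundary; chains mix into and out of it
slowly, and split-R̂ ≤ 1.01 is not reliably attainable at n ≈ 31 for any
local sampler (a Hamiltonian sampler would report divergences in the same
geometry). This is a property of the model at these conditions, not of
the implementation: the three regular fitting processes converge cleanly
(R̂ ≤ 1.005, ESS in the thousands) under identical machinery. The
degeneracy also perturbs combined-fit recovery coverage and makes the
nominally weakly informative φ1 prior materially informative, which is
visible in the prior-sensitivity report for the combined block.

## Energy surfaces and validation

Surfaces evaluate the composition chain cell-wise on (length × mass)
grids, masking cells with mass below structural mass (infeasibility is
data, not an error; the boundary M = K is feasible with zero storage).
The conventional bound curves are the structural-mass minimum and, when
single-storage parameters are supplied, four times the single-storage
structural mass as an approximate maximum. The single-storage comparator
takes user-supplied parameters (structural coefficient and exponent,
fixed storage lipid/protein fractions, protein energy density 18.4
MJ/kg); this package does not derive them.

Validation uses paired captures of adults: because adults are
structurally grown, length differences between captures are treated as
measurement error (a paired t test is reported), the mean length is used
at both timepoints, structural mass cancels in the difference, and the
predicted change in storage lipid is compared to the isotopic change by
RMSE — overall, by subgroup (WH males, WH females, SB females), and with
caller-specified exclusions recomputed as a sensitivity block. Records
with an infeasible timepoint are excluded and listed, never imputed. The
±2.7% isotopic error band is reporting-only and does not enter RMSE. The
min/max storage-muscle lipid levels give uncertainty bounds on predicted
changes; the bound ordering follows the sign of the storage-muscle
change, which can oppose the total mass change because the allocation
declines with condition.

## Numerical choices

Mass conservation is checked to 1e−9 kg absolute (double precision at kg
scale). Inverse-logit outputs are mathematically inside (0,1) and are not
clamped; observed proportions exactly 0 or 1 are rejected, not nudged
(open beta support). Beta draws in the generators are redrawn in the rare
event a sample underflows to exactly 0 or 1. Lengths are meters
everywhere; regression coefficients are unit-dependent, so the parameter
bundle records the unit and readers reject non-meter bundles. Grid
convention for surfaces: inclusive endpoints, strictly ascending,
default 200 × 200.

## Problem sizes used in checks

Recovery coverage runs 20 seeded replicates per fitting process at
n = 200 dissections / 140 biopsies / 25 chemistry samples, pooling
coverage over replicates and parameters; convergence checks run each fit
once at the study scale (31/140/25); prior comparisons use n = 200 per
dataset; conservation sweeps 10,000 random feasible bears; validation
round trips use 36 recaptures.

## Known limitations

- The combined fit's two likelihood terms share one observation; no
  generator can make both exactly specified, and the boundary degeneracy
  above is real at low allocation precision.
- Parameter truth values are plausible, not the published posteriors
  (re-estimating those requires the original dissection data).
- The single-storage comparator is only as good as the parameters the
  user supplies.
- Young bears are poorly constrained in the source data; the synthetic
  cohorts inherit that caveat through their wide length span.
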