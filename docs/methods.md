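# Methods

## Model

`gridscr` implements a closed-population spatial capture-recapture (SCR)
model for opportunistic, spatially unstructured sampling. Because there are
no fixed trap stations, a regular lattice of square cells is imposed on the
study area and each habitat cell is treated as a detector ("conceptual
trap"); a capture anywhere in a cell is assigned to the cell center. The
state space *S* is the union of active cells; activity centers have a
Uniform(*S*) prior and are assumed fixed over the study (no drift, no
dispersal — the telemetry module exists to check this assumption
independently).

The encounter hazard of individual *i* in cell *j* on occasion *k* is

    lambda_ijk = exp(log lambda0
                     + beta_eff * effort_std_jk
                     + beta_sex * sex_i
                     + beta_size * size_std_i)
                 * exp(-d_ij^2 / (2 * sigma_i^2)),

and encounters are binary with p = 1 − exp(−lambda). Binarization per
(individual, cell, occasion) limits spatial autocorrelation between
neighbouring small cells; the complementary-log-log link is the standard
choice for a Gaussian hazard with binary detections and reduces to
p ≈ lambda for small hazards, which keeps lambda0 interpretable as "expected
captures per occasion at distance 0 and average effort". Cell-occasions with
zero fishing effort have p = 0 *exactly*, enforced both in the likelihood
and in data validation (a recorded capture there is an error, not a model
state).

Population size uses Bayesian data augmentation: M all-zero histories with
inclusion indicators z_i ~ Bernoulli(psi); N = sum(z) is derived. Sex enters
the hazard as a male offset and, optionally, the range as a log-linear
offset sigma_male = sigma0 * exp(beta_sigma_sex); the sex parameterization of
sigma is a package choice — the sex-specific activity spaces it produces are
reported by the estimators, and it can be switched off (`sex_sigma=False`).
Sex and size of uncaptured individuals (and unrecorded values of captured
ones) are latent. Main effects only enter the linear predictor; no
interactions, no behavioural (trap-response) effect, no open-population
dynamics.

## Parameters, units, defaults

| parameter | meaning | scale |
|---|---|---|
| `log_lambda0` | log baseline encounter hazard per occasion at average effort | log captures |
| `beta_effort` | effect per SD of days-fished among sampled cell-occasions | per SD |
| `beta_sex` | male offset on log hazard (F=0, M=1) | log ratio |
| `beta_size` | effect per SD of fork length among measured individuals | per SD |
| `log_sigma0` | log range of the bivariate-normal activity space (female) | log km |
| `beta_sigma_sex` | male offset on log sigma | log ratio |
| `psi` | augmentation inclusion probability | (0,1) |
| `psi_sex` | proportion of the population that is male | (0,1) |

Effort is z-scored over *sampled* cell-occasions only (unsampled slots are
structurally p = 0, not data); size over measured individuals. Sample
(ddof = 1) standard deviations are used. A zero-variance covariate is
centered only and its slope held at 0 with a warning.

Priors are deliberately weak: log lambda0 ~ N(0, 10²); each beta ~ N(0, 10²);
sigma0 ~ Uniform(0.05, 30) km (sampled on the log scale with the Jacobian
term); psi, psi_sex ~ Uniform(0, 1); latent standardized size ~ N(0, 1)
truncated to the observed range. These are package defaults chosen to be
uninformative at reef-shark scales, not a reproduction of any particular
study's prior file.

The augmented size defaults to M = 8 × (number observed) — comfortably above
the ~6:1 abundance-to-captures ratio such studies report — and the sampler
warns whenever ≥ 1% of posterior mass sits at N = M.

## Sampler

Metropolis-within-Gibbs with a numba-compiled core:

* exact conjugate/enumerable updates: psi (Beta), psi_sex (Beta over included
  individuals), inclusion z (Bernoulli with odds psi·exp(−E_i) : 1−psi, where
  E_i is the individual's total expected hazard over sampled cell-occasions),
  latent sex (exact two-point conditional);
* random-walk Metropolis: activity centers (bivariate normal proposals;
  proposals outside S are rejected because the prior is zero there),
  log lambda0, the betas, log sigma0, latent sizes. For excluded (z = 0)
  augmented individuals the activity center and latent covariates are drawn
  directly from their priors — their likelihood is flat.
* per-individual hazard totals, per-encounter hazards and log-likelihood
  contributions are cached; proposals that only rescale hazards
  (log lambda0, beta_sex, beta_size, latent size) cost O(M); kernel-changing
  proposals (sigma parameters, beta_effort) and the activity-center sweep
  cost one O(M·J) pass.

Proposal scales adapt toward 0.3 acceptance in windows of 50 iterations with
a Robbins-Monro (1/sqrt(window)) step, during burn-in only, so the
post-burn-in kernel is fixed and valid. Chain c uses seed `base_seed + c`;
runs are bit-reproducible. Initial states are overdispersed but
data-informed: sigma from the spread of multi-cell recaptures, lambda0 from
the mean encounter count, activity centers at the modal capture cell.

Numerical guards: log(1 − exp(−lambda)) is evaluated via expm1 with a
log(lambda) branch below 1e-10; hard proposal bounds (|beta| ≤ 20,
log lambda0 in [−30, 10]) keep exponentials finite without affecting any
realistic posterior.

Convergence is summarized by split Gelman-Rubin R-hat (each chain halved;
< 1.1 taken as converged, 1.0 returned by convention for constant chains)
plus a Geyer initial-positive-sequence effective sample size. Defaults:
3 chains × 12,000 iterations, 2,000 burn-in, no thinning of parameters;
activity centers are stored every 10th kept draw to bound memory.

## Derived estimators

* **Activity space.** A(q) = −2π σ² ln(1 − q); the squared radial
  displacement of a circular bivariate normal is σ²·chi²₂, giving the
  closed form directly (tested against Monte-Carlo integration).
* **Density.** The abundance denominator is the *area occupied*: per stored
  posterior draw, the union of q = 0.99 activity-space circles (sex-specific
  radius σ√(−2 ln(1−q))) around included activity centers, intersected with
  S and measured on a 100-m raster. Density draws are N / area, so
  density × area = N holds exactly per draw; the fixed area(S) denominator
  is also reported. The per-cell surface is the mean count of included
  activity centers per cell divided by cell area, and integrates to the
  posterior mean N by construction.
* **Trend.** The study design has no open-population component, so temporal
  stability is assessed by independent closed-population fits per occasion
  on a consistently sampled cell subset (shared prior specification, no
  shared parameters); the posterior slope of N over occasions is computed by
  regressing each draw's series on time, and "stable" means the 95% interval
  contains 0. Draws from the independent fits are paired by index.
* **Interaction fraction.** n_observed / N per draw.
* **Tag retention.** With x of n double-tagged recaptures showing a lost
  tag, the MLE is x/n and the one-sided upper bound is the exact
  Clopper-Pearson limit Beta⁻¹(conf; x+1, n−x), which for x = 0 solves
  (1 − p_U)ⁿ = 1 − conf.

## Telemetry

Acoustic detections are located at receiver coordinates (no interpolation or
detection-range model). Tags are retained when they have strictly more than
100 detections and a first-to-last span of at least 10 months (30.44-day
months; span-based, not months-with-data). The KUD is a *parametric*
bivariate normal fitted by the sample covariance, with q-quantile area
−2π ln(1−q) √det(Σ); this matches the model's own activity-space kernel and
makes the SCR-vs-KUD comparison exact in the isotropic case. A
smoothing-based kernel density estimate would differ in the tails; the
parametric choice is an assumption of this package. Collinear receiver
geometry (rank-deficient covariance) is an error, not a silent zero.

## Synthetic data

The generator produces exactly the structure the model assumes: activity
centers drawn per-cell (uniform by default; cell-weighted for hotspot
scenarios), truncated-normal sizes, Bernoulli sex, and forward simulation of
binary encounters under the Gaussian hazard with the same covariate
standardization the fitter uses.

The packaged paper-scale fixture emulates an eight-year atoll study: an
atoll-ring state space of 84 active 2 × 2 km cells (a 12 × 9 lattice with a
6 × 4 lagoon hole), 12 occasions at least 58 days apart totalling 88 fishing
days allocated opportunistically (one random cell per fishing day, so cells
accumulate 1–3 days), N_true = 8,000, 35% male, sigma chosen so the 99%
activity spaces are 25.2 km² (female) and 28.4 km² (male), and two 2 × 2-cell
density hotspots with 10× intensity on the east and west forereef. The
baseline hazard is calibrated by root-finding so the *expected* number of
distinct captured individuals is 1,356; the realized count then lands within
sampling error (a few percent). Everything is deterministic given the seed.

What the generator does **not** emulate: chum attraction and drift-path
autocorrelation of real fishing, tag loss and misreads, temporary emigration,
movement of activity centers between years, receiver detection-range decay.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness to these field
realities.

## Problem sizes used in the shipped checks

Parameter recovery uses 20 replicates at N = 300 on a 10 × 10 grid of 2-km
cells with K = 8 occasions and 3 chains × 3,000 iterations per fit, which
gives ample chain length for these small posteriors. The convergence check
runs the full 3 × 12,000 schedule on the paper-scale fixture with the
augmented size reduced to M = 1,500: with ~1,350 observed individuals this
truncates the abundance posterior (N pins at M and psi near 1), which is
intentional — the check targets mixing of the hazard and range parameters,
and those remain well identified by the spatial recapture pattern. The tiny
posterior oracle (M = 5, two cells, two occasions, sigma fixed) is compared
against dense two-dimensional quadrature over (log lambda0, psi) with the
activity-center integral on a 60 × 60 per-cell grid.

## Known limitations

* Closed-population only; no survival/recruitment or behavioural response.
* One shared sigma apart from the sex offset — individual heterogeneity in
  space use (which telemetry data show clearly) is not modelled, so the
  model's activity space is a population-typical value.
* The half-open cell convention assigns boundary points to the cell whose
  lower edge they touch; captures outside all active cells are dropped with
  a warning rather than snapped.
* The density denominator depends on the raster resolution (2% tolerance at
  100 m) and on the q = 0.99 convention.
* The equirectangular projection is adequate within ~20 km of the reference
  (< 0.1% distortion); it is not suitable for study areas spanning degrees.
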