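# Methods

## Binding models

### Steady-state isotherms

All equilibrium evaluators take concentrations and dissociation
constants in the same unit and are monotone non-decreasing in C and
bounded by the total Rmax:

* one-site: `R = Rmax·C/(KD + C)`;
* two-site: `R = Rmax1·C/(KD1 + C) + Rmax2·C/(KD2 + C)`. The two sites
  are independent; after fitting, sites are relabelled so KD1 ≤ KD2
  (KD1 is the high-affinity site). The two Rmax values are free by
  default; `shared_rmax=True` constrains Rmax1 = Rmax2;
* Hill: `R = Rmax·Cⁿ/(KDⁿ + Cⁿ)`; n = 1 reduces exactly to one-site.

Public interfaces accept and report concentrations and KDs in nM (the
customary unit at these affinities); internally everything is
converted to molar once at the interface.

### Fitting

`BindingCurveFitter` minimises the residual sum of squares in
log-parameter space (all parameters positive) with
`scipy.optimize.least_squares`, from 32 multi-starts by default:
dissociation constants drawn log-uniformly on `[max(C)/10⁴,
100·max(C)]`, Hill n on `[0.2, 4]`. Two-site fits have symmetric local
minima (site swap) and flat valleys when one site is unsaturated,
hence the multi-start. Each random draw is first improved by solving
the conditionally linear Rmax sub-problem with non-negative least
squares (variable projection), which makes convergence on noiseless
data essentially immediate. Standard errors come from the
forward-difference Jacobian at the optimum
(`cov = s²·(JᵀJ)⁻¹`, pseudo-inverse for near-singular cases).

A fitted KD above the largest tested concentration cannot be resolved
by the titration; it keeps its numerical value but is flagged censored
and rendered as `"> Cmax nM"`, matching how unsaturated low-affinity
sites are normally tabulated.

Model selection (`BindingModelSelector`) fits every candidate and
keeps the lowest small-sample-corrected Akaike score,
`AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with k = free parameters
+ 1 for the residual variance. The criterion penalises the extra Hill
or second-site parameters, so equal-likelihood nested models resolve
to the simpler one.

### Bivalent-analyte kinetics

One analyte molecule binds one surface ligand and may then engage a
second one:

    d[AL]/dt  = ka1·C·Lfree − kd1·AL − ka2·AL·Lfree + kd2·AL2
    d[AL2]/dt = ka2·AL·Lfree − kd2·AL2
    Lfree     = Lmax − AL − 2·AL2,      R(t) = AL + AL2

with C the injected concentration during association and 0 after
`t_assoc`. Two conventions are not fixed by instrument software
documentation and are therefore fixed here: each second-step event
consumes one additional ligand site (the −2·AL2 term), and the
response weights AL and AL2 equally. Units: ka1 [M⁻¹s⁻¹], kd1 and
kd2 [s⁻¹], ka2 [RU⁻¹s⁻¹] (the second step is a surface reaction),
Lmax [RU]. Integration uses `solve_ivp(method="LSODA")` with
rtol 1e−9 (1e−8 inside fitting loops) and atol scaled to Lmax; the
association solve also yields the exact state at `t_assoc` used as
the dissociation initial condition. With ka2 = 0 the simulated curve
matches the closed-form 1:1 Langmuir solution to better than 0.1%.

`SensorgramFitter` fits (ka1, kd1, ka2, kd2, Lmax) jointly to one or
more sensorgrams in log space. The first start is heuristic — kd1
from the log-linear early dissociation slope, the association rate
from the 63% crossing (kobs = ka1·C + kd1), Lmax = 2·max(R) — and the
remaining starts perturb it log-uniformly by ±1 decade. A practically
non-identifiable second step appears as very wide standard errors on
ka2/kd2 rather than a silent failure.

## AP distribution matrices

Spot coordinates are projected onto the anterior→posterior axis; u is
affinely scaled so the outline's projection spans [0, 1], and v is the
orthogonal coordinate scaled by the outline's extent in the rotated
frame (rotated bounding box, not per-column local width — simpler and
irrelevant for along-axis claims). Both coordinates are invariant
under rigid motions. Intensities are accumulated into cell
(⌊v·100⌋, ⌊u·100⌋) (u = 1, v = 1 map into the last cell) and the
matrix normalised to total 1, so each column holds the fraction of
signal under 1% of the AP extent. Points outside the outline are
excluded with a warning and a reported count. Internally cells are
0-indexed; external descriptions use columns 1–100
anterior→posterior.

Descriptors:

* **centre of mass** — Σ mᵢⱼ·(cell centres) − (0.5, 0.5), per axis in
  [−0.5, +0.5], AP component positive toward posterior;
* **posterior fraction** — the uniform expectation per column is 0.01;
  the posterior domain is the maximal contiguous run of columns ending
  at column 100 whose column sums all reach `enrichment × expected`
  (default 2-fold, uniform expectation; both configurable, e.g. an
  outline-geometry expectation can be passed per column). The
  descriptor is the summed signal of that domain, 0 if column 100
  itself is not enriched. This contiguous-run reading is one concrete
  formalisation of "minimum two-fold enrichment over expectation"; it
  is monotone under moving mass from anterior to posterior.

Group statistics: tie-corrected Kruskal–Wallis omnibus, then two-sided
Mann–Whitney U of every non-reference group against the reference.
`scipy.stats.mannwhitneyu(method="auto")` uses the exact null for
small tie-free samples and the tie/continuity-corrected normal
approximation otherwise. The Bonferroni divisor is the number of
pairwise tests actually performed (e.g. 5 groups at α = 0.05 →
corrected α = 0.01).

## Copy-number calibration

Components are estimated by EM (`sklearn.mixture.GaussianMixture`,
5 initialisations, seeded) with K selected by BIC over 1–5. By
default the Gaussians are fitted to **log** intensities, i.e. the
components are log-normal on the raw scale. This matches the
multiplicative nature of fluorescence intensity noise: on the raw
scale the single-molecule peak is right-skewed, and BIC then prefers
to split it into two Gaussians whose dominant member sits ~5–10%
below the true unit — a structural bias, not an estimation error
(it does not shrink with n). On the log scale the same peak is
symmetric, K resolves to the copy-number structure and the unit is
recovered to ~1% at n = 3000, CV = 0.2. `log_scale=False` restores
literal raw-scale Gaussians. Reported component locations are always
on the raw scale (median exp(µ) for log-scale fits).

The **unit intensity** is the mean of the component carrying the
largest weight. Empirically that component is also the lowest-mean
one; the calibration records this as a boolean consistency flag and
surfaces, rather than enforces, violations. Raw intensities divided
by the unit are clustered by `bin i = clamp(⌊log₂(max(x, 1))⌋, 0, 8)`
into the bins 1, 2:3, 4:7, …, 256:511; normalised intensities below
0.5 (configurable) are excluded as sub-unit background with a
reported count. Note that integer copy numbers sitting exactly on a
bin edge (2, 4, 8, …) are split ~50/50 by any multiplicative noise;
bin-recovery rates therefore depend on how single-copy-dominated the
population is.

Spot detection (for rendered or raw 2-D images) is a
scale-normalised Laplacian-of-Gaussian detector: peaks of
−σ²·LoG(image) above `threshold_sd` times the image background noise
(robust MAD) propagated through the filter's L2 norm, with minimum
peak spacing σ; each detection gets a background-subtracted
integrated intensity and intensity-weighted subpixel centroid within
a 3σ radius.

## Colocalization and scaling

Pairing is one-way nearest neighbour from each mRNP to the protein
channel (KD-tree, verified against exhaustive search), colocalized
when the distance is ≤ r. r defaults to 0.3 µm — a typical
chromatically-corrected registration tolerance at high NA; the
threshold is a required, explicit parameter rather than a hidden
constant. The randomization null redraws protein positions uniformly
inside the outline (particle counts preserved; optionally the RNA
too) n_rand times and reports per-bin mean and sd of the colocalized
fraction; under complete spatial randomness this converges to
1 − exp(−ρπr²). Enrichment is observed/expected; bins with fewer
than 5 mRNPs are flagged low-confidence.

Scaling: ordinary least squares of unit-normalised protein intensity
on mRNA copy number per genotype (slope, intercept, R²). Pairwise
slope differences are tested as interaction contrasts in a pooled
per-genotype-intercept-and-slope model — a transparent equivalent of
least-squares-means trend comparison — with HC3
heteroscedasticity-robust covariance, because multiplicative
intensity noise makes residual variance grow with copy number and
classical OLS covariance then anti-conservative. Pairwise p-values
are compared against α divided by the number of pairs.

## Synthetic-data generator

The generator defines the conditions under which everything above is
validated:

* **Oocyte**: a discretised ellipse (default 100 × 50 µm, ≥ 16
  vertices, optional inward jitter to mimic hand-drawn outlines); the
  AP axis is the major axis, poles exactly at its endpoints.
* **mRNP copy numbers**: geometric on {1, 2, …}, default p = 0.8 so
  that 80% of mRNPs are single-copy — mid-range of the single-unit
  fractions typical for calibration distributions in this system
  (~60% to >85% depending on the transcript); the law and p are
  parameters, not assumptions of the analysis.
* **Intensities**: copy × unit × exp(ε), ε ~ N(0, σ) with σ giving a
  target CV (default 0.2). Noise is multiplicative because intensities
  are positive and the CV is the natural control.
* **Localization**: a posterior/anterior fraction of spots placed at
  truncated-Gaussian distance `pole_spread` (default 2 µm) from the
  pole, the remainder uniform inside the outline (rejection sampling);
  every spot lies inside the outline.
* **Protein channel**: per mRNP, with bin-dependent probability
  `frac_bound`, one particle jittered by a Gaussian (default 0.1 µm)
  with intensity slope × copy under the same multiplicative noise,
  plus uniformly placed single-unit background particles.
* **Images**: spots rendered as isotropic Gaussians whose integral
  equals the spot intensity (exact per-pixel error-function
  quadrature), plus constant background and Gaussian camera noise,
  clipped to 16 bits with a saturation warning. Pixel (r, c) spans
  [c, c+1) × [r, r+1) with the origin at the lower left.
* **Binding data**: steady-state curves are closed-form evaluations
  plus Gaussian response noise; sensorgrams come from the bivalent
  ODE above.

What the generator does **not** emulate: 3-D stacks, optical
aberrations, nurse-cell/oocyte compartment structure, autofluorescent
background structure, chromatic shifts, or instrument drift and bulk
refractive-index jumps in SPR data. Recovery results therefore
demonstrate correctness of the estimators under the stated noise
model, not robustness to every artefact of real data.

## Problem sizes and numerical choices

Validation suites use 50 oocytes × 1000 spots for distribution
descriptors, n = 3000 spots at CV 0.2 for calibration, 800 mRNPs per
oocyte for colocalization recovery (spot density low enough that
hits on other spots' particles stay below the binomial error band),
n_rand = 200 for the CSR null, 12–24 concentrations for steady-state
fits and 301 time points × 2 concentrations for kinetic fits —
sizes chosen so each check is sharp at single-CPU, seconds-to-
minutes scale. All stochastic steps take explicit seeds; the
pipeline derives per-stage streams from one global seed via
`numpy.random.SeedSequence.spawn`, making full runs bit-reproducible.

Known limitations: two-site fits near-degenerate when KD1 ≈ KD2
(relabelling then arbitrary); the low-affinity KD of a two-site fit
has ~11–18% relative sampling error on a 12-point titration at 1%
response noise (use ≥ 24 points when it matters); nearest-neighbour
colocalization inflates observed fractions at high particle density
(crosstalk from non-partner particles); the posterior-domain rule is
threshold-based and not smoothed, so single noisy columns can
truncate the domain.
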