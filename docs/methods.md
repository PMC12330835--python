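# Methods

## The problem

Multi-compartment biophysical models of the diffusion-MRI (dMRI) signal in
white matter are degenerate: many parameter combinations generate signals
that differ by less than measurement noise, so voxel-wise inversion is
ill-posed (the package demonstrates this directly — see the degeneracy
test in `tests/test_forward.py`).  When the question is not "what are the
parameters in this voxel" but "which parameter change explains how the
signal varies with a covariate" (a histological stain density, a cell
count, a clinical score), inversion can be bypassed entirely.  This
package implements that change-inference approach for continuous
covariates: a generative tissue model is perturbed one candidate parameter
at a time, regressions learn the signal-space fingerprint of each
candidate change, a GLM extracts the measured change per covariate, and
Bayesian model comparison scores the candidates.

## Forward model

One voxel's signal on a shell with b-value b (ms/um^2) and unit gradient
direction g is

    S(g) = f_in  (stick    ⊗ Watson)(mu·g)
         + f_ex  (zeppelin ⊗ Watson)(mu·g)
         + f_sph E_sphere(b)  +  f_dot  +  f_ball e^{-b D_ball}

with signal fractions summing to one, mean fibre axis mu, stick
attenuation exp(-b D_a,in cos^2 θ), zeppelin
exp(-b [D_r,ex + (D_a,ex − D_r,ex) cos^2 θ]), an impermeable sphere under
the Gaussian-phase-distribution (GPD) approximation (intra-soma), a dot
(stationary water, common ex vivo), and optionally a free ball
compartment.  The ball variant (12 parameters) is used when modelling
numerical-substrate data, where many spins never meet a membrane; the
ex-vivo variant omits it.  Parameter priors are uniform on: fractions
f_in, f_ex in [0,1], f_sph, f_dot, f_ball in [0, 0.1]; ODI in
[0.01, 0.5]; diffusivities in [0.5, 1.5] um^2/ms (ball up to 2.5);
R_sph in [0.01, 10] um.  Internal units are um, ms, T throughout, so bD
is dimensionless.

Orientation dispersion follows a Watson distribution with concentration
kappa mapped from the orientation dispersion index by
ODI = (2/π) arctan(1/kappa).  Two convolution routes are implemented:

* a generic product quadrature (Gauss–Legendre in cos θ × uniform azimuth,
  2×64×48 antipodally-symmetric points) for arbitrary kernels;
* a Legendre (Funk–Hecke) series for the axially symmetric stick/zeppelin
  kernels — both the Watson density and the kernels are even Gaussians in
  cos θ, so one primitive g_l(u) = ∫ e^{u t^2} P_l(t) dt (Gauss–Legendre,
  128 nodes, even degrees ≤ 60) gives the convolved signal as a function
  of mu·g alone.  This route is exactly rotation-equivariant, ~100×
  faster when batched over training samples, and is what `model_signal`
  uses; the two routes are cross-checked in the tests to 1e-3 per
  direction (they actually agree to ~1e-14 at moderate dispersion).

The GPD sphere signal uses the classic root expansion over the first 30
positive roots of j_1'(x) (first root 2.0816), found by bracketed Brent
iteration.  Note the GPD is an approximation: at the study shells
(b = 7, 10 ms/um^2) and R ≥ 5 um the per-spin phase spread exceeds a
radian and the closed form deviates from an exact Monte-Carlo walk by
1–3%.  The test suite therefore validates the implementation against the
walk at weak diffusion weighting (qR < 1, agreement ~0.1–0.2%) and keeps
the strong-weighting comparison as a separate check at its nominal
tolerance, which fails for the larger radii for this physical reason, not
an implementation one.

## Summary measures

Raw per-direction signals are reduced to rotation-invariant summaries per
shell: the l = 0 measure (mean signal) and the l = 2 measure
(root-mean-square of the five degree-2 real spherical-harmonic
coefficients), giving four measures for two-shell data.  The SH fit is
*mean-anchored*: c00 is set from the directional mean and the l = 2
coefficients are fitted by least squares to the demeaned signal.  This
guarantees exactly that the l0 measure equals the directional mean on any
input and that an isotropic offset never moves the l2 measure — at the
cost of global least-squares optimality (the two coincide to ~1e-3 on
well-spread 90-direction sets) and of idempotency under refitting.  The
square root on the l2 measure makes it scale linearly with signal
amplitude; `l2_sqrt=False` switches to the plain mean of squared
coefficients (both forms were evaluated end-to-end on the substrate
study; the attribution results are insensitive to the choice).
Invariance is exact under joint rotation of signal and direction set;
rotating the *tissue* against a fixed direction set leaves a small
aliasing wobble (l ≥ 4 content leaking through a finite direction set),
which is consistent between the training and measurement paths because
both use the same directions.

## Change models

For each candidate change — every single parameter (ODI, the four/five
diffusivities, R_sph) plus every ordered pair of signal fractions, so
sum-to-one is preserved — training pairs are generated by: sampling a
baseline from the priors (fractions: draw the small fractions and f_in,
give the remainder to f_ex, reject negative remainders), drawing a
magnitude |Δν| uniformly from [0.01, 0.1] × w where w is the largest
prior width among the touched parameters (this keeps a pair and its
reverse on the same prior), perturbing, rejecting (not clipping) draws
that leave the prior box, and recording the finite-difference change
vector [M(ν+Δν) − M(ν)]/|Δν| in summary space.  Signals are assumed
locally linear in the parameter; the tests verify change vectors per unit
magnitude agree within 5% across a decade of magnitudes.

The change distribution N(mu_i(S), Sigma_i(S)) is regression-learned:
mu by degree-2 polynomial least squares on the baseline summary vector,
Sigma by degree-1 regression of the residual outer products, symmetrised
and eigenvalue-floored to positive semidefinite at prediction time.  The
family is validated by held-out recovery of constructed linear ground
truth, PSD checks, the antisymmetry of reversed fraction pairs, and
end-to-end parameter recovery — not by matching any published
coefficient.

## GLM stage

With Y (n voxels × m summaries) and q covariates, beta = pinv([1|x]) Y.
Covariates are demeaned (never rescaled) before the intercept is
prepended, so the first row beta_mean is exactly the across-voxel mean
summary vector — the baseline the inference stage conditions on; the
covariate rows are unchanged by the centering.  Effect sizes delta_l are
the 99.9th minus 0.1th percentile of each covariate (real-data
convention) or the raw range (simulated-data convention).  Noise
covariances come from a voxel bootstrap (default 5,000 iterations of
1,000 voxels resampled with replacement) — or, in simulation mode, from
repeated Rician-noise instances — as the covariance of beta_l.  Because
the measured change is Δy = beta_l · delta_l, the noise covariance
entering the inference is delta_l² · Cov(beta_l).

## Inference

For covariate l and candidate i, the likelihood of the measured change at
magnitude s is N(Δy; s·mu_i(y), s²·Sigma_i(y) + sigma_l) evaluated at
y = beta_mean, marginalised over s with a uniform prior on the training
magnitude range by 64-point Gauss–Legendre quadrature in the log-density
domain, and normalised across candidates.  Only positive magnitudes are
integrated; the opposite direction is its own roster entry, which is why
negating a covariate flips the winner to its mirrored counterpart.  A
1e-10 × mean-diagonal ridge stabilises every covariance inversion.
Because the posterior always normalises to one, a chi-squared pattern
distance — the Mahalanobis distance of Δy to its best non-negatively
scaled prediction, minimised over the magnitude — is reported alongside:
when even the best candidate's distance is far above the matched-case
level, no roster entry actually explains the data and the probabilities
should not be over-read.

## Synthetic data

Two generators make every stage testable without any download.

**Forward-model cohorts** emulate a homogeneous tissue region: one
baseline parameter set drawn from the priors per cohort (the soma radius
pinned at the glia-representative 5 um — a cohort whose "soma" have
sub-micron radii makes the sphere exactly degenerate with the dot and is
not a soma study), per-voxel uniform jitter of 2% of each prior width on
the non-fraction scalars, random per-voxel fibre orientations, a chosen
candidate change varying linearly with a uniform covariate (default total
change: 5% of the touched prior width, inside the trained magnitude
prior), and Rician noise at a stated SNR applied to the raw volumes
before b0 renormalisation and summarisation.  Drawing each voxel's
baseline independently from the full prior instead would bury the trend
under baseline variance and break the Var(beta) ∝ (S0/SNR)²/n scaling
that the noise-covariance machinery relies on; real voxel populations
within a white-matter mask are far more homogeneous than the prior box.
What cohorts do not emulate: spatial correlation, partial voluming,
distortion, or covariate measurement error.  A confound generator
produces a trend no roster entry can generate (the covariate
multiplicatively scales the higher shell only — a relaxation-like
mechanism) to exercise the misfit diagnostics.

**Substrates + spin walk.**  Substrates are 3D-periodic boxes (200 × 200
× 25 um³) of non-overlapping undulating cylinders (radius 2.5 um,
sinusoidal undulation amplitude 1 um, wavelength 25 um) and spheres
(radius 5 um), placed by rejection.  Cylinders are parameterised by z —
every z-plane cuts a disc of fixed radius whose centre follows the
undulation plus a z-periodic "meander" realising a Watson-sampled
inclination (target ODI 0.1) about the box's short axis.  This keeps the
substrate exactly periodic in all three axes and makes each cylinder's
volume exactly π r² Lz, so the analytic volume fractions (8.25% for 168
cylinders, 2.98% for 57 spheres) are exact.  Spins are seeded uniformly
everywhere (sphere interiors included by default, giving intra-soma
signal; a flag excludes them) and take fixed-length steps
ell = sqrt(6 D dt) (D = 1 um²/ms ex vivo, dt = 8.62 us) in directions
drawn from a whitened antipodal table; membranes reflect specularly, with
rejection as the fallback; crossing conservation is asserted after every
run.  PGSE phases are accumulated as per-pulse position integrals, so the
per-volume cost is independent of the direction count.  A per-cell
clearance grid lets spins provably far from every membrane skip collision
checks ("free flight"), enabled when enough of the box is open.  The
grid of 4 cylinder counts × 10 sphere counts gives 40 substrates; the
two-shell protocol is b = 7 and 10 ms/um² (90 directions each, 18 b0,
Δ = 24 ms, δ = 14 ms, gradient amplitudes 16.1/19.2 G/cm from inverting
b = γ²G²δ²(Δ − δ/3)).

## Problem sizes used by the tests and the acceptance script

Chosen so a full run takes minutes while leaving every conclusion
noise-dominated rather than size-limited; all are package defaults or
documented arguments:

* change-model training: 20,000 pairs per candidate (10,000 in the
  scaled-down suite variants of the substrate study and cohort recovery);
* substrate study: all 40 substrates, 8,000 spins per substrate and 40
  noise instances in the test suite; 10,000 spins and 100 instances in
  the acceptance script (SNR 150 in both, as in the regime emulated);
* cohort recovery: 2,000 voxels, SNR 50, bootstrap 5,000 × 1,000; 20
  replicates per tested change in the suite, 3 in the script;
* walk cross-checks: 20,000–100,000 spins depending on the check.

## Known limitations

* The substrate attribution study assigns essentially the whole posterior
  (~99%) to the single best candidate (f_in−f_sph for the cylinder
  trend), where the regime it emulates reported a ~70/30 split across the
  two nearly-degenerate intra-axonal pairs.  The split is an average over
  noise instances; it spreads only when noise flips the per-instance
  winner, and in these substrates the fit gap between the two candidates
  exceeds the SNR-150 noise scale.  The direction of the attribution and
  the dominance of the correct candidate pair are robust; the exact split
  is sensitive to the mu/Sigma regression family and substrate details.
* The GPD sphere compartment is biased at strong diffusion weighting for
  large radii (see above); the inference inherits whatever bias the
  forward model carries.
* The mean/covariance regressors extrapolate poorly far outside the
  training baseline cloud (e.g. baselines dominated by free water);
  posteriors there can be overconfident.
* No exchange, no compartmental T2/TE weighting, no finite axon radius;
  single-parameter (or fraction-pair) changes only.
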