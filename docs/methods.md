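# Methods

## The model class

`phasecoint` analyses systems of p coupled stochastic oscillators.  Each
oscillator k is a planar process z_k = (x_k, y_k)' that revolves around a
centre, written in polar coordinates as an unwrapped phase phi_k (monotone
in expectation) and a positive amplitude gamma_k:

    d phi_t   = f(phi_t, gamma_t) dt + Sigma_phi   dW^phi_t
    d gamma_t = g(gamma_t)        dt + Sigma_gamma dW^gamma_t

Interaction enters only through the phase drift, which is *linear* in the
phases:

    f_k = sum_j Pi_kj (phi_j - omega_j) + h(gamma_k).

Row k of the coupling matrix Pi says how oscillator k reacts to the phase
configuration; omega sets the attracting phase relation (0 by default: an
in-phase equilibrium).  When Pi has reduced rank r = rank(Pi) = rank(alpha
beta') the system sustains exactly r stationary linear phase relations
beta'phi — the phases are *cointegrated* — while each individual phase is
integrated (a drifting, nonstationary process).  The columns of beta encode
the coupling schemes (e.g. (1, -1, 0)' is a 1:1 phase lock between units 1
and 2), and the loadings alpha say which oscillators adjust to a
disequilibrium, hence the *direction* of coupling: a zero row of alpha is an
oscillator that receives no feedback.

Two concrete generators are implemented:

* **Noisy Winfree system** (`sim.simulate_winfree`): amplitudes follow
  d gamma_k = (kappa_k - gamma_k) gamma_k^2 dt + sigma_gamma dW, which
  fluctuate around the level kappa_k, and feed the phase drift through
  h(gamma_k) = gamma_k; so kappa_k is (approximately) the intrinsic angular
  frequency.  Integrated by Euler–Maruyama on a fine grid (default step
  2e-4) and recorded every dt_obs/dt_fine steps.
* **Degenerate-amplitude model** (`sim.simulate_ou_phase_exact`): gamma
  constant, h = mu; the phase vector is then a multivariate
  Ornstein–Uhlenbeck process whose exact discrete-time transition is the
  Gaussian VAR(1)  phi_n = exp(delta Pi) phi_{n-1} + delta mu + eps_n with
  innovation covariance Omega = int_0^delta e^{sPi} Sigma Sigma' e^{sPi'} ds.
  This is the correctly specified model for the inference machinery and is
  sampled exactly (no discretisation error).

The Kuramoto drift (1/p) sum K_kj sin(phi_j - phi_k) + mu_k is provided with
its linearisations around the in-phase state; it motivates the linear class
(the fully coupled reference network is its uniform linearisation) but
nonlinear cointegration itself is out of scope.

## Estimation and testing

Fitting works on the error-correction form of the observed phases,

    Delta phi_n = P phi_{n-1} + mu + eps_n,    P = alpha beta',

by classical reduced-rank regression: demean differences and lagged levels,
form S00, S01, S11, and solve det(lambda S11 - S10 S00^{-1} S01) = 0 as a
symmetrised generalized eigenproblem (Cholesky whitening of S11, `eigh`,
eigenvalues clipped to [0, 1)).  beta is the matrix of the r leading
eigenvectors normalized so its top r x r block is the identity (a row
permutation is substituted, and flagged, if that block is singular); alpha,
mu, Omega follow by least squares given beta.  Standard errors for alpha and
mu come from the conditional regression of Delta phi on (beta'phi_{lag}, 1)
with the ML covariance; none are reported for beta.  The trace statistic for
rank(P) <= r is -T sum_{i>r} log(1 - lambda_i) with T = N - 1 (one
observation lost to differencing); it equals twice the log-likelihood gap to
the full-rank model, an identity the tests verify to 1e-8.

Because the asymptotic law of the trace statistic is nonstandard, p-values
come from a residual bootstrap: the rank-r fit generates M recursive paths
phi*_n = (I + alpha beta') phi*_{n-1} + mu + eps*_n from the observed
initial level, with eps* resampled i.i.d. with replacement from the centred
residuals; the p-value is (1 + #{LRT* >= LRT_obs})/(M + 1), so it is never
exactly zero.  Replicate m draws from an RNG stream derived from (seed, m),
making results independent of execution order.  The sequential procedure
tests r = 0, 1, ... at the chosen level (default 5%, M = 500) and stops at
the first non-rejection.  The bootstrap imposes the H_r-restricted mu-hat
(not the unrestricted one), and a fitted H_r model that violates the I(1)
conditions — spectral radius of I_r + beta'alpha below one and
det(alpha_perp' beta_perp) != 0 — triggers a warning but still runs.

Linear restrictions alpha = A psi and/or beta = B xi are estimated exactly
when one-sided (reduced-rank regression on B-transformed levels; for the
A-side, conditioning the A-directions of the differences on the
A-perpendicular directions, whose mean is zero under the hypothesis) and by
an alternating switching algorithm when combined.  Each half-step of the
switching scheme is the exact conditional MLE given the other side, so the
log-likelihood is monotonically non-decreasing (exposed as
`loglik_history`); iteration stops when the change drops below 1e-10 or
after 1000 iterations, with a warning on non-convergence.  The LRT is
2 (loglik_unres - loglik_res), clipped at 0 within round-off, and is
referred to a chi-squared distribution with r(p-m), r(p-s) or
r(p-m) + r(p-s) degrees of freedom.  For the one-sided hypotheses this
equals T sum_{i<=r} log((1 - lambda*_i)/(1 - lambda_i)) with lambda* the
restricted eigenvalues; the equality is a regression test.

## Continuous time

The continuous-time drift is recovered from the discrete estimate by the
principal matrix logarithm, Pi = log(delta P + I)/delta.  This *embedding*
step is valid only when delta P + I is nonsingular with no eigenvalue on the
closed negative real axis; `ctime.pi_from_p` always returns the principal
branch together with diagnostics and an `ok` flag (non-real residues above
1e-10 also flag failure).  The innovation covariance integral is evaluated
exactly by the Van Loan augmented-matrix-exponential identity rather than
quadrature; adaptive quadrature is kept as the independent oracle in the
tests.  Rank, sp(alpha) and sp(beta) are shared between the time scales:
exp(delta Pi) - I = alpha xi beta' with xi = (beta'alpha)^{-1}
(exp(delta beta'alpha) - I_r).  Note the widely quoted form of this
decomposition equates alpha xi beta' with P itself; with
P = (exp(delta Pi) - I)/delta the two sides differ by the factor delta, and
the identity implemented (and tested) here is the delta P version.  Only
subspaces are identified across time scales — the r x r scaling xi is
absorbed — so reported alpha/beta are discrete-time estimates and Pi-hat is
the object to interpret for continuous time.

On reporting scales: the fitted constant estimates delta*mu, and the fitted
loadings estimate delta*alpha; `experiments.analyze_signals` and the
recovery tests therefore divide both by delta before comparing with
generator-level parameters (e.g. kappa, or the coupling strength 0.5).

## Phase extraction and mean phase coherence

For raw signals the instantaneous phase is the argument of the analytic
signal x + i H(x) (Hilbert transform), unwrapped by cumulative 2 pi
corrections.  The transform is unreliable near the series boundaries, so
slope fits in tests exclude 5% of samples at each end; a linear detrend
option exists and is off by default.  Pairwise synchronization is summarised
by the mean phase coherence R = |mean exp(i (phi_i - phi_j))| in [0, 1],
which is blind to coupling direction.  Its null distribution (independent
oscillators) is simulated parametrically: M independent realizations of a
configured Pi = 0 system, empirical 95% quantile of R.  The reference
configuration for pairs is kappa = (0.75, 1), sigma_phi = 1,
sigma_gamma = 0.1, N = 2000, delta = 0.1, which yields a critical value of
about 0.16–0.17.

## Numerical and design choices

* **Fine-step integration.**  The Winfree simulator subsamples every
  dt_obs/dt_fine fine steps (500 at the default 0.1/2e-4); noise for phases
  and amplitudes is drawn jointly from one seeded generator so polar and
  Cartesian integrations can share a Wiener path.  The two inner loops
  (Euler integration, recursive bootstrap paths) are numba-compiled with
  fastmath; trajectories are bit-reproducible for a fixed seed within one
  build.
* **Cartesian drift form.**  `sim.plane_drift` evaluates the standard
  printed form of the Cartesian dynamics of this oscillator class, whose
  drift carries a radial (sigma_gamma sigma_phi)/|z| correction.  Our own
  Ito computation of the Cartesian image under *independent* phase and
  amplitude Wiener processes produces no such cross term (the quadratic
  covariation of phi and gamma vanishes), and numerically the plane Euler
  path converges pathwise to the polar path only when the term is dropped
  (`cross_correction=False`); with it, the discrepancy plateaus at about
  sigma_gamma sigma_phi T.  The default keeps the printed form; the
  convergence oracle test uses the consistent variant.
* **Amplitude positivity.**  The amplitude SDE can reach gamma <= 0: the
  restoring drift is quadratic near zero, so at kappa = 0.75,
  sigma_gamma = 0.1 a small but non-negligible fraction of study-length
  trajectories makes at least one excursion through zero (the stationary
  density at 0 is only about exp(-5.3) below the mode for that channel).
  The default policy records the event count on the trajectory and
  continues; a "reflect" mode substitutes |gamma|.
  Excursions stall the affected oscillator and bias its frequency estimate
  low in those replicates, a feature inherited by any analysis of this DGP.
* **Eigenvector conventions.**  Eigenvalues sorted descending; each
  eigenvector's first non-negligible component is made positive before
  normalization, so fits are reproducible across platforms.
* **Desk-scale defaults.**  The replication drivers default to 100
  repetitions with M = 200 bootstrap samples (the reference studies used
  1000 and 500); both are configurable.  The acceptance script uses the
  desk-scale sizes, and a 600-replicate null for the mean-phase-coherence
  critical value.

## What the synthetic data does and does not emulate

The simulators generate exactly the processes the inference machinery is
designed for: linearly phase-coupled oscillators with Gaussian diagonal
noise, constant coupling and a single attracting phase relation per
cointegration column.  Passing tests therefore demonstrate internal
correctness and recovery of coupling structure *under this class*, including
the intended misspecification of fitting a constant-amplitude model to
Winfree data.  They say nothing about regime switching or time-varying
coupling, nonlinear (sine) coupling at large phase dispersion, non-Gaussian
or correlated noise, unequal sampling, or measurement noise on raw signals
before phase extraction — all of which occur in real electrophysiological
data.  The raw-signal pipeline additionally depends on the Hilbert phase
being meaningful, which requires a narrowband oscillatory signal and low
phase noise.

## Known limitations

* Only VAR(1) dynamics (no lagged-difference terms), an unrestricted
  constant, and I(1) processes; no trend deterministics or I(2) analysis.
* Bootstrap p-values only for the rank test; restriction tests use the
  asymptotic chi-squared reference.
* Noise matrices are diagonal throughout the simulators.
* The matrix logarithm uses the principal branch only; an embedding-flagged
  result means the continuous-time drift is not identified from the sampled
  process at this delta.
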