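# Methods

## The buildup model and its three fitting modes

Under amide-proton saturation the longitudinal ¹⁵N polarization relaxes
from its equilibrium value toward the steady-state NOE value with the
nitrogen longitudinal rate, so the cross-peak intensity as a function of
the saturation period t follows

    S(t) = S0 [ε + (1 − ε) exp(−R1 t)]

with S(0) = S0 and S(∞) = S0·ε.  `relax_fit` fits this curve per
residue in three data-reduction modes:

* **A (sequential)** — R1 is taken from a dedicated decay experiment and
  held fixed; (S0, ε) are fitted.  The sensitivity of the NOE error to
  the fixed rate is probed by two extra fits at R1 ± σ(R1)
  (`mode_a_sensitivity`), reporting the largest change in dε.
* **B (simultaneous)** — the buildup series and the dedicated decay
  series A·exp(−R1 t) are fitted jointly with one shared R1.
* **C (standalone)** — (S0, ε, R1) all come from the buildup series.
  ε is essentially as good as in A/B; R1 is roughly an order of
  magnitude less precise than a dedicated decay fit, which
  `compare_modes` quantifies as the mean-error ratio between result
  lists.

Optimizer: `scipy.optimize.least_squares` (Levenberg–Marquardt) with
ftol = xtol = gtol = 1e-14 and a budget of 200·(n_par+1) evaluations;
non-convergence raises rather than returning silently.
Initialization is data-driven and sign-robust: S0 from the intensity at
the smallest delay, ε from the ratio of the largest-delay intensity to
S0, R1 from the reciprocal median positive delay.  Duplicate delays are
treated as independent replicate observations — never averaged — so
residual statistics keep their degrees of freedom.

### Error convention

When every point carries a noise RMS (the normal situation: spectral
noise is measured from signal-free regions), residuals are weighted by
1/noise_rms and parameter errors come from the **unscaled** covariance
(JᵀJ)⁻¹ of the weighted problem — known-noise chi-square fitting.  This
ties fitted dε to the measured noise floor, the same basis as the
SNR propagation used for steady-state NOEs, and makes dε a smooth
function of the design rather than of the per-fit residual draw (with
~8 degrees of freedom a residual-variance estimate of the noise
fluctuates by ~25% from fit to fit, which would dominate quantities
like the mode-A sensitivity).  Without noise information the fit falls
back to unweighted least squares with the covariance scaled by the
residual variance.  The ε–R1 correlation is taken from the unscaled
covariance, where the overall error scale cancels; it is therefore
defined even for noiseless data.

The reported `reduced_chi2` is the weighted SSR per degree of freedom
(≈1 when the noise model is correct) or, unweighted, the residual
variance.

## Steady-state NOEs and their errors

ε = S_sat/S_ref, with thermal-noise propagation
dε = |ε|·√(SNR_sat⁻² + SNR_ref⁻²).  Because of the |ε| factor this
formula underestimates errors for near-zero NOEs; results with
|ε| < 0.1 (configurable) carry a `near_zero_noe` flag.  Replicate
statistics use the sample standard deviation (n−1); comparing the grand
means of replicate SDs and SNR-based errors is the standard reliability
check for the propagation formula, and on synthetic replicates the two
converge as the series grows.

Noise RMS is computed about zero, not about the sample mean: spectra
are baseline-corrected and the estimator must be the plain RMS a user
can verify by hand (automatically derived SNR values are known to be
overestimated in practice).  At least 32 baseline samples are required.

## Delay adequacy and grid design

The reference spectrum must start from equilibrium, which the slow
water-proton rate bottlenecks: `exp(−RD1·R1W) ≤ threshold` (default
0.02, admittedly arbitrary and configurable).  The saturation period
must cover the slowest nitrogen: `exp(−D_sat·R1N) ≤ threshold` per
residue.  Dynamic NOE additionally requires `exp(−RD2·R1W) ≤ threshold`
because every buildup point restarts from equilibrium; steady-state NOE
accepts RD2 = 0.  The boundary counts as a pass: published setups sit
essentially on it (RD1 = 10 s at R1W = 0.389 s⁻¹ gives a factor of
0.0203), so a strict inequality would reject working schedules.

Recommended saturation grids place the first delay at 0, the last at
the adequacy boundary −ln(threshold)/R1N, and interior delays where the
model intensities are equally spaced — uniform sampling in signal, not
in time.  Four delays is the smallest accepted design.  At ε ≈ 1 the
curve is flat and the recommendation degrades gracefully to uniform
time spacing with a warning.

## The three-pool simulator

`noesim` evolves the longitudinal magnetizations of amide ¹⁵N, amide ¹H
and water protons as a linear system d′ = −L d in
deviation-from-equilibrium coordinates,

        | R1N     λ        0       |
    L = | λ       R1H+k   −k/p     |
        | 0       −k       R1W+k/p |

with λ = σ_NH·sign(γH/γN), exchange rate k, and water:amide pool ratio
p (default 10⁴ for a dilute protein; its appearance on both exchange
off-diagonals enforces detailed balance, making L symmetrizable with
real, positive decay eigenvalues).  Equilibrium magnetizations are kept
positive (M_N = 1, M_H = |γH/γN| = 9.866, M_W = 9.866·p); the negative
nitrogen magnetogyric ratio is carried by the coupling sign.  The
cross-relaxation rate is implied by the target NOE through the
saturation steady state ε = 1 + (γH/γN)·σ_NH/R1N; couplings violating
σ² < R1N·R1H are flagged non-physical but still usable in parameter
scans.  Homonuclear water–amide NOE is folded into k; transverse
relaxation, CSA and DD/CSA cross-correlation are not modelled.

Saturation clamps the proton pool (optionally water) to zero and
removes it from the evolving subsystem; its equilibrium pull becomes a
constant forcing that shifts the fixed point of the remaining pools.
Propagation is exact via eigen-decomposition of the free-pool block,
with a `scipy.linalg.expm` fallback if the eigenbasis is
ill-conditioned.  Two structural limits anchor the model:

* with k = 0 the saturated N pool reduces *exactly* to the buildup
  model with rate R1N (verified to 1e-9);
* unsaturated evolution from equilibrium stays there (fixed point).

Steady-state measurements are simulated with both branches starting
from the all-zero post-acquisition state — the worst case, configurable
— the reference branch recovering for RD1, the saturation branch
recovering for RD2 and then saturated for D_sat.  This reproduces the
characteristic systematic errors: a short D_sat leaves the apparent
saturated intensity too positive (ε_app > ε for ε < 0), a short RD1
attenuates the reference and drives ε_app < ε for negative NOEs, and
both biases vanish monotonically as their delay grows.  One caveat
discovered in testing: for strongly negative NOEs with fast exchange,
the nitrogen pool can transiently undershoot zero during unsaturated
recovery (cross-relaxation against a still-depressed proton pool), so
no global no-overshoot property is claimed for that regime.

## Corrections for mis-set delays

Recovery-type corrections (water, amide-proton, joint R1H/R1N) use the
rational form ε = (1−X)ε_app/(1−X·ε_app); the saturation-truncation
correction uses the linear form ε = (ε_app − X)/(1−X), which exactly
inverts an equilibrium-start buildup cut off at D_sat.  The joint
factor's removable singularity at R1N = R1H is evaluated by its
analytic limit X = R1N·RD·e^(−R1N·RD)/(1−e^(−R1N·RD)) when the rates
agree to 1e-6 relative.  Corrected values keep the original dε (errors
are not re-propagated through the correction — a documented limitation)
and are always labelled `corrected` with the factor kind in their
flags: no correction is ever applied implicitly, and none substitutes
for a properly designed experiment.  Compensation efficiency is
100·(1 − mean|ε_corr − ε_ref| / mean|ε_app − ε_ref|) over residues,
using means of absolute differences; the package reports efficiencies
for all kinds and leaves the choice to the user.

## Synthetic study conditions

The generator defaults emulate the reference measurement conditions:
the 11-delay saturation grid {0, 0.11, 0.22, 0.35, 0.55, 0.66, 0.79,
1.10, 1.30, 3.00, 4.00} s with validated 7- and 4-delay reductions;
70 residues; NOE values uniform in (−0.9, 0.9) spanning rigid backbone
to mobile termini; R1N uniform in (1.0, 1.6) s⁻¹; S0 = 100 with
Gaussian noise of RMS max|S|/SNR at SNR 150, constant across delays
(a fixed spectral noise floor); sample rates R1W = 0.412 s⁻¹ and
R1H = 0.85 s⁻¹ (22.3 T values).  The dedicated R1 experiment is
emulated with 10 log-spaced delays on 0.02–3 s.  For mis-set-delay
scenarios the amide–water exchange rate is k = 5 s⁻¹ — exchange
dominates the amide-proton rate, a realistic choice for exposed amides
near neutral pH — which makes incomplete water recovery the dominant
systematic error, and the water-recovery correction correspondingly the
most effective one.  The mode-A sensitivity scenario perturbs the fixed
R1 by σ = 0.008 s⁻¹, the precision of a dedicated R1 measurement.

What the generator does **not** emulate: peak overlap, baseline and
phase artifacts, temperature drift, field-dependent rate variation
within one dataset, DD/CSA cross-correlation and incomplete proton
saturation.  Passing tests therefore demonstrate correctness of the
estimators and of the coupled-relaxation logic under the stated noise
model, not robustness to spectral artifacts.

Problem sizes (70 residues, 500 replicate fits, 1e-4-step brute-force
integration over 1 s) are chosen so the whole suite and the acceptance
script each run in well under a minute on one CPU while keeping
Monte-Carlo statements statistically meaningful.

## Numerical choices and edge cases

* Convergence: relative objective change below ~1e-12 (tight scipy
  tolerances), 200·(n_par+1) evaluation budget; exceeding it raises a
  convergence error with the last iterate.
* Singular normal equations (all delays equal) and under-determined
  series (<2 distinct delays for mode A, <3 for C and for R1 decay)
  raise typed errors; a constant decay series returns a flagged
  non-decaying result (R1 = 0), never a clamped rate.
* The rational correction and its inverse raise a singular-correction
  error when the denominator is within 1e-12 of zero (the inverse map
  has true poles at ε = 1 − 1/X).
* Result tables are written atomically (temp file + rename) with no
  forced float format, so numeric fields round-trip bit for bit.
* All generators are driven by `numpy.random.Generator` seeds; a fixed
  seed reproduces every synthetic table byte for byte.

## Known limitations

* Corrected NOE values carry the uncorrected dε.
* The pool model is longitudinal-only and three pools; aliphatic
  protons, spin diffusion and saturation-train details are out of
  scope, so simulated systematic-error *magnitudes* are
  scenario-dependent — signs and orderings are the robust predictions.
* SNR-based dε near ε ≈ 0 is flagged, not repaired; replicate series
  are the recommended remedy.
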