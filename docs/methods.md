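# Methods

This note documents the models, numerical choices and synthetic-data design
behind `petkin`, and what the test suite does and does not establish.

## Input function

Total plasma and whole blood are modelled piecewise: an exact linear
interpolation from zero through the pre-peak samples, then a sum of
`n` (1–3, default 3) decaying exponentials from the peak on. The tail is
fitted by variable projection — amplitudes solved by non-negative least
squares given the rates, log-rates optimized by bounded least squares from
four deterministic starts — which is robust for the ill-conditioned
multi-exponential problem. The last pre-peak node is set to the tail's value
at the peak, so the model is continuous there by construction; the measured
peak sample still enters the tail fit. Whether the pre-peak rise should enter
the exponential fit at all is a genuine design choice; we interpolate it
exactly and fit only from the peak, which is the common practice when early
samples are sparse. With `n_exponentials="auto"` the tail order is chosen by
AIC with the RSS floored at the numerical precision of the data
(`(1e-8·max)²` per point), so noiseless nested fits resolve by parsimony
rather than rounding noise.

The unchanged parent fraction is PF(t) = 1 − a·G(t; α, β), G the gamma CDF
with shape α and rate β (1/min), a ∈ [0, 1] the asymptotic metabolized
fraction. This family satisfies PF(0) = 1, is monotone non-increasing, and
has a free asymptote 1 − a; it is fitted by bounded least squares from four
starts. Three free parameters set the minimum sample count at three. Blood
samples are weighted uniformly (sample-level variances are not available).

The metabolite-corrected input is the pointwise product of the plasma fit and
PF; the plasma free fraction f_p is carried as metadata (it enters the Guo
analysis, not the compartment fit). All activities are assumed
decay-corrected to injection time; no dispersion or cross-calibration
correction is applied.

## Compartment models

The tissue impulse response is K1·e^(−k2 t) (1TCM) or the standard
bi-exponential K1·[φ1 e^(−α1 t) + φ2 e^(−α2 t)] with
α1,2 = ½[(k2+k3+k4) ∓ √((k2+k3+k4)² − 4 k2 k4)] (2TCM; 2TiCM is the same
with k4 = 0, giving a trapping component α1 = 0). Predictions convolve this
response with the input *analytically*: the input is sampled on a 0.05-min
grid, treated as piecewise linear, and the convolution with each exponential
term is computed by the exact per-step recursion (evaluated with `expm1` for
small rates and propagated by a linear IIR filter). This is exact for the
model family given the piecewise-linear input, stable near the bolus peak,
and fast enough for multistart fitting. Frame values are interval averages
via a cumulative trapezoid. Against a brute-force RK4 integration of the
ODEs on a 0.01-min grid the predictions agree to ~10⁻⁴ relative, an order
below the 0.1% acceptance band.

The measured signal adds a vascular term: C = (1 − V_b)·C_T + V_b·C_wb(t−Δt),
with the *fitted* whole-blood model used inside the fit. The whole-blood term
is shifted by the same delay as plasma. Positive Δt means the tissue lags the
blood sampling site; Δt is bounded to [−3, +3] min and estimated per scan
from the frames ending within 10 min of injection, using the 3-parameter
irreversible uptake model (K1, V_b, Δt; k2 = 0 — washout over 10 min is
negligible for these kinetics, e^(−k2·10) ≈ 0.96 at the default clearance).
The small model mismatch this approximation introduces is visible as a
sub-0.01-min delay bias in noiseless round trips, well inside the ±0.1-min
tolerance used in the tests.

Fitting is weighted nonlinear least squares (trust-region reflective, bounded:
K1 ∈ [0, 0.5] mL·min⁻¹·cm⁻³, rate constants ∈ [0, 1] min⁻¹, V_b ∈ [0, 0.2])
from 8 deterministic log-spaced starts; ties resolve to the lowest WRSS, then
the smallest parameter norm. Frame weights default to duration-proportional
(uniform and duration²/activity are available) and are normalized to mean 1,
which makes estimates, rSEs *and* AICs invariant to overall weight scale.
The covariance is the Gauss–Newton inverse Hessian × WRSS/(N − p); rSE =
100·SE/|estimate|; macroparameter (V_T, K_i) rSEs use the delta method with a
central-difference gradient. A fit whose best start sits at a boundary where
the macroparameter degenerates (e.g. k4 → 0 in the 2TCM) reports the value
as infinite and the rSE as unavailable rather than NaN.

## Model selection

AIC = n·ln(WRSS/n) + 2p (no small-sample correction; an AICc variant is
provided). A two-tissue model is preferred over the 1TCM only when the
F-test against the 1TCM is significant (p ≤ α = 0.05) *and* it has the lowest
AIC of all fitted models; otherwise the 1TCM is kept. The 2TiCM is not nested
in the 1TCM (k4 = 0 vs k3 = 0), so that comparison uses AIC alone; F-tests
are computed for the nested pairs 1TCM ⊂ 2TCM and 2TiCM ⊂ 2TCM. An
F statistic that would be negative (complex fit worse, possible with bounded
multistart) is clipped to 0 with p = 1. Reliability (primary-parameter
rSE ≤ 10%) is a separate flag, not a veto — selection and reliability are
reported independently, mirroring how such studies count "better fits" and
"reliable fits" separately.

## Binding metrics

Lassen plot: OLS of ΔV_T on baseline V_T (statsmodels); slope = r,
V_ND = −intercept/slope, SEs by the delta method from the OLS covariance.
OLS is the standard convention although both axes carry error; an orthogonal
(total least squares) option is provided for sensitivity checks. A slope
numerically at zero flags V_ND as undefined instead of propagating NaN, and
negative occupancies are reported, never clipped. BP_ND tables use the mean
of the per-animal V_ND estimates. Guo plot: OLS of tracer A's regional
baseline V_T on tracer B's; K_D^B/K_D^A = slope·f_p^B/f_p^A. Because the
standard derivation leaves open whether the axes were normalized by V_ND,
both the raw intercept and intercept/mean(V_ND^A) are reported, and the
BP_ND ratio slope·mean(V_ND^B)/mean(V_ND^A) is computed when V_ND estimates
are supplied.

## Stability analysis

Truncation endpoints default to 180→60 min in 30-min steps; a rest period
removes every frame overlapping the gap. The full-scan delay is reused (early
frames are always retained), V_b is refit freely, and percent differences are
taken against the full-scan estimate. On noiseless data truncation and
gapping are bias-free (the refit recovers the generating parameters exactly),
so the degradation the tests quantify is driven by noise interacting with
non-equilibrium kinetics: with a 175-min clearance half-life, equilibrium is
far beyond 180 min and V_T from a 120-min scan is markedly less stable than
for fast (k2 = 0.05 min⁻¹) kinetics — the package reproduces that contrast as
a property, not the study-specific regional percentages, which depend on the
real animal data.

## Synthetic data

The generator emulates the study conditions end to end: the 45-frame/180-min
schedule (6×30 s, 3×1 min, 2×2 min, 34×5 min); 11 gray-matter ROIs whose
baseline V_T values (1.96–4.55 mL/cm³) match the reported regional table;
1TCM kinetics with k2 = ln 2/175 min⁻¹ and K1 = V_T·k2 (so K1 ≈ 8–18
µL·min⁻¹·cm⁻³, the slow-uptake regime); V_b = 0.036; a plasma curve rising
linearly to a bolus peak at 1 min then decaying tri-exponentially; whole
blood at 0.85× plasma; parent fraction solved to pass through 0.88/0.83/0.79
at 30/90/180 min; and baseline/blocking pairs sharing one occupancy
(default 0.68) and one V_ND (0.88 mL/cm³) per animal, with
V_T,block = V_ND + (1−r)(V_T,base − V_ND) and K1 held fixed (blocking changes
binding, not delivery). The blocking-scan plasma is scaled by 1.3× — the
elevation is real but its magnitude is not published, so the factor is an
explicit configurable choice. Default f_p = 0.135, dose 182 MBq, body weight
5.5 kg (typical adult rhesus).

TAC noise is zero-mean Gaussian with SD ∝ √(prediction/frame duration) — the
usual count-statistics surrogate — scaled to a 5% CV at the peak frame;
blood samples get 2% multiplicative noise and parent fractions 1% additive
noise (clipped to [0, 1]). One top-level seed spawns named `SeedSequence`
child streams (blood, parent fraction, then one stream per ROI) in a fixed
order; the ground-truth JSON plus the seed regenerates every curve
bit-exactly.

What the generator does *not* emulate: attenuation/scatter residuals,
motion, partial-volume effects, inter-animal kinetic variability, dispersion
in the arterial line, and non-Gaussian count noise at very low rates. Passing
tests therefore demonstrate the correctness and calibration of the
estimation chain under the stated noise model, not performance on real
scanner data.

## Problem sizes in the test suite

The suite favours the smallest sizes that still exercise each property:
parameter-recovery and rSE-calibration checks use 200 noisy replicates of one
ROI; the model-selection rate uses 220 TACs (20 simulated scans × 11 ROIs);
the ODE-oracle comparison uses 20 random parameter draws; stability contrasts
use 10 noise replicates per kinetic regime. End-to-end pipeline checks run a
single noiseless animal.

## Known limitations

- No voxelwise/parametric imaging, reference-tissue models or graphical
  (Logan/Patlak) estimators — the Patlak limit appears only as a test oracle.
- The parent-fraction family is one documented choice within the
  integrated-gamma model family; other parameterizations exist.
- The optimizer's bounds and weighting are defaults, all configurable; rSEs
  assume the weighted-Gaussian error model.
- Occupancy assumes a region-invariant r and V_ND; regional violations show
  up as Lassen-plot scatter, not as a model error.
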