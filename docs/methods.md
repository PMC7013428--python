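# Methods

## Models and conventions

Effects are signed fractions throughout the library (0.5 = 50 %
inhibition, −0.2 = 20 % stimulation); percent appears only in file headers
and rendered reports. Concentrations are molar and enter every sigmoid
*linearly* — the slope parameters b and q of the biphasic model carry
units of 1/(mol/L), which is why fitted values of order 10⁴–10⁶ are
normal for micromolar-active chemicals. The luminescence readout maps to
effect as E = 1 − L/L₀ with L₀ the mean control signal.

The five-parameter biphasic (BP) model describes the whole J-curve:

    E(C) = m − m/(1 + 10^(b(C−a))) + (1−m)/(1 + 10^(q(p−C)))

m is the bottom parameter (the stimulation magnitude the left sigmoid
alone would reach, typically negative), a/b the left-phase median and
slope, p/q the right-phase median and slope. Two segment sub-models
follow by construction, BPL (left sigmoid only) and BPR (right sigmoid
plus the floor m), and satisfy the exact identity
f_BP = f_BPL + f_BPR − m. Both sub-models have closed-form inverses.

Two asymmetries of the BP family drive the whole design:

* **BPR transfer works.** Re-using the fitted (m, p, q) in BPR reproduces
  the right segment of the BP curve wherever the left sigmoid is
  saturated. The residual −m/(1+10^(b(C−a))) decays rapidly past the
  minimum; for the nine shipped reference parameter sets it is below
  0.005 effect units everywhere beyond twice EC_m (it can still be a few
  percent *at* the minimum for fits with extreme bottom parameters such
  as m ≈ −80, where the two phases overlap strongly).
* **BPL transfer does not.** Plugging the fitted (m, a, b) into BPL gives
  a left branch that deviates grossly from the BP curve's own left branch
  (tens of percent in concentration at matched effect; for the
  overlapping-phase fits the closed-form inverse can even turn negative).
  The left branch of the BP curve is shaped by *both* sigmoids, so the
  library inverts it numerically (Brent, machine-precision tolerance on a
  bracket (0, EC_m]) and never uses BPL for analysis — BPL exists to
  state the identity and to demonstrate the failure.

The left segment of a *component* curve is therefore described for
prediction purposes by a separately fitted Hill model E = dC/(k+C)
(d < 0, k > 0), whose inverse is closed-form and monotone, with the
observed lowest point included in both the Hill and the BP/BPR fits so
the two segment descriptions agree near the minimum.

The hormetic minimum (EC_m, E_m) of a BP curve is located numerically: a
512-point log-spaced grid scan brackets the minimum (this guards against
the nearly flat plateaus of extreme-m fits), then bounded scalar
minimisation in log-concentration refines it to ~1e−8 relative
precision. A curve that is monotone over the bracket returns a flagged,
non-interior result instead of raising. Reported EC_m/E_m always refer
to the fitted-curve minimum, not the lowest observed point; the observed
minimum is used only to split data into segments (the two conventions
agree within replicate noise on well-behaved plates).

## Fitting

BP parameters are estimated by unweighted nonlinear least squares on the
pooled replicates (scipy `least_squares`, trust-region reflective, slopes
bounded positive). The least-squares surface is multi-modal — very
different parameter regimes describe the same J-curve almost equally
well — so the fitter multi-starts over a fixed deterministic grid: bottom
parameter m ∈ {−0.2, −0.5, −1, −5, −50}, medians seeded from the observed
minimum and the log-interpolated 50 %-inhibition crossing, slopes from
the 2/width heuristic at two scales. No RNG is involved: a given dataset
always yields the same fit. At least five distinct concentrations are
required (one per parameter); datasets whose blank-control CV exceeds
15 % are rejected at ingestion, mirroring the assay acceptance gate.
Goodness of fit is reported as R² about the observed mean (undefined and
reported absent for zero-variance data) and RMSE.

The Hill left-segment fit uses the observations at concentrations up to
and including the observed lowest point (≥3 distinct concentrations) with
its own small deterministic start grid. A flat left segment yields d ≈ 0,
and the segmented prediction refuses such a component rather than
inventing a stimulatory branch.

### Effect-concentration confidence intervals

The replicate design supports an observation-based band: at each tested
concentration, mean ± t(0.975, n−1)·SE. For EC_x intervals the band
offsets are carried along the fitted curve (fitted effect ± interpolated
half-widths), the resulting envelopes monotonised within each branch,
and intersected with the requested level; each envelope that never
attains the level on its branch produces an absent bound — the "NA"
pattern typical of steep or noisy segments, which the downstream
interaction rules consume explicitly. Carrying the offsets along the
fitted curve rather than chord-interpolating between tested wells
matters on coarse dilution grids: a factor-2 series puts adjacent wells
far apart on a steep sigmoid, and chords bias both bounds toward higher
concentrations. This band construction is an interpretation — the
underlying assay literature does not pin down a unique "observation-based
CI" — and is the package's documented choice; parameter-level CIs
(bootstrap, profile likelihood) are deliberately out of scope.

## Mixture prediction

Rays follow the direct equipartition-ray design: molar ratios converted
to concentration proportions P_i = r_i/Σr. Plain CA inverts each
component at the requested level (BPR inverse on the right branch,
numerical BP left-branch inverse on the left) and combines harmonically;
levels deeper than the shallowest component minimum form the predictive
blind zone and are skipped, with the PBZ interval (spanning the component
minima) reported whenever stimulatory levels were requested.

SCA builds two branch functions, L(e) = CA over the Hill inverses and
R(e) = CA over the BPR inverses, on the common domain
e ∈ (max_i max(d_i, m_i), 0) that keeps every inverse defined. The
docking effect e\* is the root of L − R, bracketed by a 2048-point scan
and polished by Brent to machine precision; if several sign changes
exist the shallowest is taken with a warning, and if none exists the
curve is returned undocked with a diagnostic. The docking root itself is
reported as (EC_m,SCA, E_m,SCA). The predicted curve is continuous but
not differentiable at the docking point; no smoothing is applied. Sham
additivity holds by construction: a chemical "mixed" with itself at any
proportions reproduces its own segmented curve, and component order
never affects a prediction.

## Interaction diagnosis

CTC = 100·EC_CA/EC_obs is carried at full precision and rounded half
away from zero only for display. Because CTC is monotone decreasing in
the observed EC, the EC confidence bounds map to CTC bounds with the
roles swapped, and absent EC bounds propagate. The CTCICI cascade then
classifies: (i) two-sided CI — by the position of 100, boundaries
inclusive; (ii) one bound — the interval [min(bound, CTC),
max(bound, CTC)] is tested for 100, and on failure the rule falls
through; (iii) the classical thresholds 80 ≤ CTC ≤ 120 additive,
below antagonistic, above synergistic, again inclusive. Boundary
inclusivity is a deliberate choice (a CI bound of exactly 100 counts as
additive), matching how the published reference judgments treat such
cells.

Isoboles are built for binary mixtures only: observed points are
P_i·EC_obs with CI scaled along the ray, the CA reference is the straight
segment between the single-component intercepts, and the per-ray call
compares the CI segment against the line's radial intersection — computed
by solving the 2×2 ray/line system, an independent geometric route that
agrees with the CTCICI call whenever a two-sided CI exists.

Cross points between an observed BP curve and a sampled predicted curve
are located by scanning (observed − predicted) on a 4096-point log grid
and refining each sign change by Brent, each root labelled left/right of
the observed minimum. Predicted curves must be sampled finely enough
that their interpolation error stays below the coincidence tolerance
(10⁻³ effect units by default); curves agreeing within that tolerance
report no crossing.

The toxicity–composition profile tabulates pEC_x = −log₁₀ EC_x against
the molar proportion of one component, with the single components as the
boundary rows. On the shipped reference values the EC₅₀ profile is
strictly monotone in the CTCC share across the seven mixture rays; the
boundary components themselves do not extend the monotone ordering (the
most OTCC-rich ray is slightly less toxic than pure OTCC), so the
monotonicity claim is asserted across rays only.

## Synthetic data

The generators emulate the microplate assay: 16-step factor-2 geometric
dilution from the stock, 4 replicates, 24 controls, additive Gaussian
noise on the effect scale (σ = 0.02 by default — chosen as a realistic
replicate scatter for a luminescence endpoint, and one that lands fits
inside an R² > 0.91 / RMSE < 0.12 envelope), effects clipped at 1 (full
light loss), and an optional RLU mode with multiplicative lognormal
control scatter at a stated CV ≤ 15 %. Mixture truth curves are the SCA
prediction itself, so additivity holds by construction and fitted CTCs
centre on 100; interactive truths scale the concentration axis by a
deviation factor (CTC ≈ 100/deviation). All randomness flows from the
design seed; identical seeds give byte-identical datasets.

What the generators do *not* model: plate-position effects, quenching,
time-course kinetics (only the single endpoint), concentration-dependent
error variance, and correlated replicate errors. Passing recovery and
operating-characteristic tests therefore demonstrate the estimators'
behaviour under clean assay assumptions, not robustness to systematic
plate artefacts.

Problem sizes used by the test suite were chosen to make the statistical
claims stable: 50 seeded plates for parameter recovery (median EC₅₀
error < 5 %), 100 for the additive CTC centring check (mean in
[95, 105]), and 200 for the classification operating characteristics
(detection power ≥ 90 % at deviation 1.4; additive false-call rate
≤ 10 %).

## Numerical choices and edge cases

* Exponents are clipped to ±300 before every `10**z`; the clip never
  binds within realistic concentration ranges and only prevents overflow
  on absurd input.
* All closed-form inverses validate their open domains and raise a
  domain error outside them; the numerical left-branch inverse
  additionally requires an interior minimum and a bracketing sign change.
* Docking and root refinement use Brent's method at machine-precision
  tolerances, so the docked branches agree to better than 1e−6 relative.
* Ties in the observed minimum (exactly equal mean effects) resolve to
  the lowest concentration; real replicate data never tie exactly.
* Reference-value regressions use ±2 % relative tolerance on
  concentrations (±0.3 percentage points on effects) because the shipped
  parameters are printed to four significant digits; cross-point
  locations get ±5 % / ±1 pp for the same reason.

## Limitations

Only two-segment, single-minimum J-curves are supported; independent
action, curvature-parameterised isoboles, interpolation-based surface
methods and ≥3-component isobole geometry are out of scope. The CI
construction for EC_x is an interpretation (see above), so CI-dependent
quantities are reproduced qualitatively (presence/absence pattern of
bounds, classification behaviour) rather than digit-for-digit. The
left-segment Hill description is a pragmatic choice, not a mechanistic
claim: any monotone model with a closed-form inverse could replace it
segment-wise.
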