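# Methods

## Model

The material is a thin, flow-aligned network of crosslinked extensile
microtubule bundles, treated as a 2D active nematic *elastomer* (the
material points are the nematogens, so director fluctuations are slaved to
the displacement field).  Small deformations u = (u_x, u_y, h) varying only
along the alignment direction x feel a destabilising extensile active force
ζ∂ₓ²u on the transverse components, elastic restoring forces from the
deformation free energy

F = ½ ∫ dx dy [ ν(∂ₓuₓ)² + μ(∂ₓu_y)² + κ(∂ₓ²h)² + K((∂ₓ²u_y)² + (∂ₓ²h)²) ],

and friction γ∂ₜu (overdamped, quasistatic).  The resulting dispersion
relations per Fourier mode e^{iqx} are

* in-plane bend:   σ_y(q) = [(ζ − μ)q² − Kq⁴]/γ,
* out-of-plane:    σ_h(q) = [ζq² − (K + κ)q⁴]/γ,
* axial (passive): σ_x(q) = −νq²/γ (always stable; ν is carried only for
  the free energy).

Consequences implemented and tested:

* the in-plane branch is unstable only for ζ > ζ\* = μ — the critical
  activity is elastic in origin (distinct from confinement- or
  friction-induced thresholds, which are out of scope);
* the out-of-plane branch is unstable at any ζ > 0;
* fastest modes: q\*_y = √((ζ−μ)/2K), σ\*_y = (ζ−μ)²/4γK and
  q\*_h = √(ζ/2(K+κ)), σ\*_h = ζ²/4γ(K+κ);
* three regimes: (i) 0 < ζ/μ ≤ 1 only out-of-plane unstable;
  (ii) in-plane unstable but slower; (iii) in-plane faster, for
  ζ/μ > R(κ/K) = 1/(1 − (1 + κ/K)^−½).  Exactly on the boundary the label
  is out-of-plane (regime ii closure, matching the strict inequality of
  regime iii).  μ = 0 raises a fluid-limit error: the elastomer
  classification does not apply to a fluid.

Degenerate stiffness (K = 0 on an unstable in-plane branch, or
K + κ = 0 out-of-plane) is reported as an error rather than λ\* = 0: the
continuum model has lost its short-wavelength cutoff there.

## Kinetics

Motor stepping follows Michaelis–Menten kinetics in ATP with
f = [ATP]/(K_M + [ATP]).  The package takes the stepping motor fraction to
*be* f (occupancy), so

ζ = ζ₀·[motors]·f,  [XL] = p₀[PRC1] + [motors](1 − f),
μ = μ₀[XL]², κ = κ₀[XL]², K = K₀·L^a.

Choices made where the design was open:

* the stepping-fraction sub-model (occupancy) is the simplest law
  consistent with the saturating activity and the low-ATP crosslinking
  picture; processivity/duty-ratio corrections are not modelled;
* K_M defaults to 30 µM (typical kinesin ATP half-saturation), configurable;
* the filament-length exponent a defaults to 2 but is exposed as a
  parameter, because the proper scaling of the nematic elasticity of a
  bundle network is genuinely ambiguous;
* the crosslinker exponent is fixed at 2 (the crosslinked-gel scaling law
  μ ∝ [XL]², κ ∝ [XL]²) and deliberately not configurable.

An exact consequence used as a test oracle: ζ/μ at fixed ATP and PRC1 is
unimodal in the motor concentration with maximiser m\* = p₀[PRC1]/(1 − f),
which produces the re-entrant out → in → out sequence at limiting ATP.
Instability *directions* depend only on ζ₀/μ₀, K₀/κ₀, κ₀/ζ₀ and p₀; a
common rescaling of the four prefactors cancels.

## Phase diagrams

`predict_grid` classifies each cell of a 2D composition grid through the
kinetics and stability layers (cells with ζ = 0 are labelled `stable`, a
state the instability assays cannot show but zero ATP implies).
`boundary_trace` locates the in/out boundary by per-scan-line bracketing and
Brent refinement of the sign of σ\*_y − σ\*_h, up to two crossings per line
(re-entrance); contouring was rejected as fragile for multi-crossing lines.
Every returned point satisfies ζ/μ = R(κ/K) to the requested tolerance.

## Spectral simulator

The linear dynamics are diagonal in q, so `evolve` advances each mode with
the exact propagator exp(σ(q)Δt) — no time-discretisation error — making
the simulator a trustworthy oracle for mode selection.  Periodic boundary
conditions (the experimental channel walls are not modelled; the stability
analysis is wall-free).  Defaults: 1024 points on 512 µm, noise amplitude
1e−4 µm, mandatory seed.  Growth is unbounded in the linear theory; runs
are capped by an overflow guard (max σΔt ≤ 700), not by ad-hoc saturation.
The dominant wavelength is read from the amplitude-spectrum peak with
parabolic log-interpolation; amplitudes rather than powers are used so
strongly amplified fields stay within double precision.  The spectral
selectivity of a run grows like √(|σ''(q\*)|t), so wavelength-selection
tests evolve to σ\*t ≈ 600 with the probed branch fastest.

## Blurriness

The focus score is the local (15 px window) variance of the Laplacian of
the contrast-normalised, lightly pre-smoothed (Gaussian σ = 1.5 px) image.
Contrast normalisation (1st–99th percentile span) makes B exactly invariant
to global intensity rescaling; the pre-smoothing suppresses shot noise that
would otherwise masquerade as sharpness inside defocused regions.  Pixels
are classified by thresholding the log₁₀ score histogram with Otsu's
method, clamped to ±0.6 around an absolute sharp/blur reference score of
−3.9 calibrated on the synthetic fixtures (sharp texture stays above
≈ −3.7, defocused texture below ≈ −4.1 across seeds).  Images whose scores
lie entirely on one side of the reference (unimodal histograms: all-sharp
or all-blurred) are assigned B = 0 or 1 directly and flagged low
confidence.  For time series one threshold is computed from the pooled
score histogram of all frames so B(t) trends are comparable.
Classification: in-plane for B ≤ 0.05 (a noise floor standing in for
"B = 0"), out-of-plane for B > 0.5, mixed between.  Known limitation:
images with a very rare minority class (≈ 2–5 % blurred area) can be over-
segmented by several percent; the accuracy guarantee (±0.05) is established
on fractions 0–1 in steps of 0.2.

## Inference

Only four quantities are identifiable from directions and wavelengths:
ζ₀/μ₀, K₀/κ₀, κ₀/ζ₀ and p₀ (the overall stress scale cancels from
directions; wavelengths pin κ₀/ζ₀).  Sampling runs in transformed space
(log ratios, logit p₀).  The likelihood is this package's construction —
the published analyses of such data state the channels but not a
likelihood:

* direction: Bernoulli with P(out) = logistic(s·log(σ\*_h/σ\*_y)), s = 5;
  P(out) = 1 − ε when the in-plane branch is stable (ε = 1e−6).  B > 0.5
  reads out-of-plane, B ≤ 0.05 in-plane; mixed rows are down-weighted to ½
  with the label of the nearer threshold (they are superpositions of both
  modes);
* wavelength: Gaussian on log λ around the model wavelength of the branch
  indicated by the *observed* label (robust near the boundary), σ_λ = 0.2.
  A labelled-in-plane row whose parameters render that branch stable is
  penalised through a clamped, astronomically long model wavelength.

s and σ_λ are fixed hyperparameters, keeping the four-parameter structure.
Priors: log-uniform over six decades per ratio (ζ₀/μ₀ and K₀/κ₀ in
[1e−1, 1e5], κ₀/ζ₀ in [1e−3, 1e3]), uniform(0, 1) for p₀.  The sampler is
an adaptive random-walk Metropolis per chain (Haario-style empirical
covariance, global scale tuned to ≈ 30 % acceptance during the burn-in =
first half, then frozen), with each chain started from the best of 128 of
its own prior draws — the prior box is mostly likelihood plateau, and a
cold-started random walk may not reach the mode within the burn-in.
Diagnostics: split R-hat across chains (warn above 1.1) and the acceptance
rate (warn outside [0.05, 0.8]).  Four diagrams are pooled into one
likelihood (a hierarchical treatment was considered out of scope).  The
whole machinery is validated by parameter recovery: on 20 independently
seeded synthetic four-panel datasets (4 × 5000 steps each) the 95 %
credible intervals cover every planted component in ≥ 90 % of repetitions,
and the posterior agrees with an independent affine-invariant ensemble
sampler on the identical posterior.

## Synthetic data

The planted kinetic constants are ζ₀ = 1 Pa/nM, μ₀ = 6.25e−4 Pa/nM²,
κ₀ = 0.3 Pa·µm²/nM², K₀ = 300 Pa·µm²/µm², p₀ = 0.6, K_M = 30 µM, a = 2
(ratios 1600, 1000, 0.3).  They were chosen once so that the generated
diagrams reproduce the qualitative experimental anchors: a sharp
out-to-in transition at a few µM ATP for lightly crosslinked networks, a
boundary that shifts to higher ATP with more PRC1, a re-entrant
out/in/out band along the motor axis near limiting ATP with the in-plane
nose around 50–80 nM, activities of tens of Pa, and winning wavelengths of
tens of µm at high ATP.  With these constants the upper (in → out)
re-entrant crossing at 8 µM ATP sits near 270 nM motors, so re-entrance
demonstrations scan motors up to 400 nM while the default grid ranges
mirror the experimental panels (ATP 1–1500 µM log, motors 5–200 nM,
PRC1 10–500 nM, length 0.5–10 µm).

Observation noise: clearly classified cells draw B from Beta distributions
centred at 0.02 (in-plane) and 0.65 (out-of-plane); near-boundary cells
(|log σ-ratio| < 0.5) draw from the mixed band (0.05, 0.5] with a mean
that slides with the logistic of the growth-rate contrast — the same
information structure the likelihood assumes, chosen so that parameter
recovery tests the estimator rather than an arbitrary noise mismatch.
Wavelengths carry lognormal noise (σ = 0.2) and are attached to
clearly-classified cells.  Friction γ never enters labels or wavelengths.

Images are wavy oriented stripes (period 12 px, emulating aligned bundles)
plus two scales of cloud noise and Poisson shot noise at 500
photons/pixel; the defocused region is a randomly placed ellipse (or
complement) of analytically exact area, composited from the
Gaussian-blurred (σ = 8 px) copy with a 2 px feathered edge.  What the
generators do *not* emulate: optics (PSF anisotropy, depth-dependent
blur), photobleaching, bundle coarsening, advection of texture during the
instability, or correlated replicate noise — so passing tests demonstrate
the correctness and calibration of the pipeline on data matching the
stated noise model, not performance on raw experimental micrographs.

## Problem sizes and numerics

Default analysis sizes: 10 × 10 grids per panel (400 observations), 4
chains × 5000 steps for recovery runs, 1024-point spectral fields, 512²
images.  Boundary bisection refines to machine precision (Brent,
xtol 1e−14) and is verified against the closed form at 1e−8 relative;
closed-form modes are verified against two-stage grid argmax at 1e−4
relative.  Tie-breaks: growth-rate ties classify out-of-plane; B exactly at
a threshold goes to the lower class (in-plane at 0.05, mixed at 0.5).

## Known limitations

* Linear theory only: no post-instability chaos, defect nucleation,
  nonlinear saturation, or 2D sheet simulation.
* The quasistatic map cannot describe pulsed-activation dynamics whose
  period competes with motor binding kinetics.
* Load-dependent motor stepping, depletant-bundled networks and
  non-processive motor variants are not modelled.
* γ (friction) is a free timescale parameter: nothing in the direction or
  wavelength data constrains it, and no value is shipped.
* Absolute stresses require an external μ₀ calibration (e.g. bulk
  rheology); the fitted quantities are ratios plus p₀.
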