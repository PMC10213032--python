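# Methods

## Model

The thallus is a set of hyphae in continuous 2-D space (µm); time runs
in hours.  Each hypha is a polyline with a single growing apex; apexes
never die and hyphae never fuse (no anastomosis — where hyphae overlap
the crossing is a purely geometric V3i, computed on demand and never
stored as a graph node).  All random laws are base-2 exponentials where
a rate k means survival 2^(−kx); conversions to the natural base occur
only inside closed forms.

**Elongation.**  Every apex advances at the shared velocity
v(t) = v_asym(1 − 2^(−t/τ)), v_asym = 4.5 µm min⁻¹ = 270 µm h⁻¹.  The
ramp satisfies v(0) = 0, monotone saturation, and a cumulative length
of 500 µm at 7 h — the constraint that times the onset of lateral
branching — which pins τ ≈ 7.5 h (solved numerically once per
parameter set).  Any monotone ramp satisfying those three constraints
would be admissible; the base-2 saturating form keeps the model's
exponential vocabulary.

**Apical (subapical) branching.**  Each apex carries a pre-drawn
distance-to-next-branching L₀ + X, L₀ = 180 µm, X ~ Exp₂(10.4×10⁻³
µm⁻¹).  At the trigger the junction vertex is placed L_api ~ N(41, 11)
µm (truncated at zero) behind the tip.  The *operating* daughter — the
one making the widest angle with the mother's projection — starts a new
hypha there; the *exploratory* daughter (smallest angle) continues the
mother's identity.  This continuation matters: without it almost no
hypha would outgrow the 480 µm lateral dominance length (mean apical
spacing ≈ 319 µm) and lateral branching would starve.  Angle magnitudes
are **calibration knobs, not measured values**: operating 70°,
exploratory 20°, lateral 90°, each with Gaussian jitter (sd 10°).

**Lateral branching.**  Only the region of a hypha at least 480 µm
behind its apex is eligible.  Events are the superposition of
(i) *isolated* seeds, Poisson with 6×10⁻³ events per µm of newly
eligible length, fired at a uniform position within the new strip and a
uniform delay inside the 90-min aging window; and (ii) *bursts*: each
event spawns a follow-up on the same hypha with probability
1 − uniform_fraction = 0.78, at a signed offset ΔL ~ Exp₂(2.3×10⁻³
µm⁻¹) clamped into the eligible region and a delay Δt ~ Exp₂(41×10⁻³
min⁻¹).  The geometric-series chain makes the isolated share exactly
0.22 by construction.  This superposition is statistically equivalent
to a curvature-memory nucleation mechanism at the level of the
measurable ΔL/Δt laws, which is how it is validated.

**Spontaneous curvature.**  Per 20 µm of advance (independent of the
integration step dt, so curvature statistics are dt-invariant) the
heading turns by θ drawn from a density ∝ (θ₀−θ)ᵃ(θ+θ₀)ᵇ on (−θ₀, θ₀).
Substituting u = (θ+θ₀)/2θ₀ makes this a Beta(b+1, a+1), so sampling is
exact; the mean is θ₀(b−a)/(a+b+2) — zero for a = b (unbroken
chirality).  A literal reading of the printed law with (θ−θ₀)ᵃ would be
negative on the support for non-integer a, so the Beta-like form is
used.  The shape values are not measured: a = b = 2 enforces zero mean
and θ₀ = 40° was calibrated once against the measured arc-chord
tortuosity α = (L_tot − L_p)/(L_tot + L_p) ≈ 0.038 of a grown thallus
(θ₀ = 25° gives 0.017).  Tortuosity compares total polyline length with
the length of the network pruned to straight chords between degree-1/3
vertices; it is invariant under rigid motions.

**Branching side.**  Positive curvature bends the hypha rightward; a
new branch (the operating daughter for apical events) lands on the
opposite side of the local bend with probability 0.82 (apical) / 0.72
(lateral), on the same side otherwise.  Because the curvature law is
symmetric, clockwise and counterclockwise branches are equiprobable
globally — chirality is local, not global.

**Germination.**  Six germ tubes leave the ascospore at evenly spaced,
jittered headings, each from its own point on a 15 µm spore-boundary
circle (so base vertices stay degree 1).  Two tubes per spore is the
other defensible reading of the observations; it was rejected because
two opposite tubes give an exactly collinear apex cloud — λ₂ = 0 — for
the whole first growth phase, leaving the density observable undefined
there and the sphericity near zero, whereas the apex-cloud sphericity
is observed to hold near 0.88 throughout growth.  With six tubes the
simulated late-time sphericity is 0.85–0.95 without further tuning.

**Integration.**  dt = 0.1 h; apexes advance with mid-step velocity;
snapshots of all apex positions are taken every 18 min, matching the
experimental imaging cadence.  A single seeded generator drives
everything; replicate k of an ensemble uses seed + k.

## The density observable

The inertia tensor of the apex cloud is the matrix of second moments of
the centered coordinates **divided by the number of points**.  The
printed form of the tensor is the raw sum; normalizing is the single
most consequential reading made here, and it is forced by three facts:
the eigenvalues are stated to have the dimension of a squared length,
the r_i = √λ_i grow linearly while the apex count grows exponentially
(a raw sum would mix the two), and ρ = N₁/(r₁r₂) only follows
D·2^(ωt)/t² if λ is a per-point dispersion.  Eigenvalues come from the
closed-form 2×2 symmetric decomposition; sphericity is 2λ₂/(λ₁+λ₂).

ρ_o(t) = N₁/(r₁r₂) is computed per snapshot; clouds with fewer than two
distinct points or λ₂/λ₁ < 10⁻⁹ are dropped with a warning.
Uncertainties: bootstrap over apex locations (B = 500 by default)
combined with a Poisson-resampled count, per the counting hypothesis.
The minimum is the argmin of a Savitzky–Golay local-quadratic smooth
(window 5) of log ρ — the noise is multiplicative — refined by the
vertex of a parabola through the three surrounding points; a monotone
series returns a no-minimum flag.  On exact curves D·2^(ωt)/tⁿ the
detector recovers n/(ω ln 2) to within the sampling grid.

## Fitting conventions

Counts and survival curves are linearized with log₂ and fitted by least
squares; R² = 1 − SS_res/SS_tot is reported on the linearized scale and
parameter uncertainties come from the diagonal covariance.  The
branching-length fit bins the empirical CDF at 10 µm, locates the
apical-dominance transition at the maximum slope, and fits the tail
survival with weights n·S/(1−S) (the binomial variance of log-survival),
which keeps the deep tail from dominating the residual.  The
two-step lateral mixture fit performs step 1 (Γ₁·2^(−γ₁ΔL)) on the
non-empty bins below the 0.75 sample quantile: the sparse far tail
belongs to the uniform component and provably flattens an unrestricted
log-linear slope by ~40 % on any exponential-plus-uniform mixture with
these parameters.  Step 2 fixes γ₁ and fits amplitude plus floor r over
the full range; the uniform share is r·n_bins/n, and a fitted decay
shallower than one half-life across the range is classified as all
uniform.  The printed amplitude/floor pair (≈28.2 vs ≈1) together with
the ≈22 % uniform share imply a uniform support of roughly 5 mm —
thallus scale — which is the default spatial range of the synthetic
mixture generator.

The early-time density decay is fitted log-log as β·t^(−α) on
(0, 0.9·t_min], optionally with α pinned at 2 (the value implied by a
constant apex count spreading linearly); the pinned fit's R² can never
exceed the free fit's.  Orientation tests are exact two-sided binomial
with Bonferroni adjustment; the media comparison uses one-way ANOVA on
the per-replicate D values and a mean-centered Levene test (mean
centering reproduces the published p; median centering does not).

## What the synthetic generator does and does not emulate

The fixture generator produces apex-count series C·2^(ωt) with Poisson
noise, branching lengths L₀ + Exp₂(α), lateral-spacing mixtures, and
point clouds with prescribed eigenvalues — the distributions the
measurement half is validated against.  It does not emulate imaging
artifacts (segmentation gaps, overlap/fusion ambiguity, finite
resolution), nutrient fields, septation, or 3-D aerial growth, so
passing tests demonstrate correctness of the algorithms under the
stated laws, not robustness to microscopy noise.  Image-derived
quantities (per-replicate ω, the ≈100 µm h⁻¹ eigen-root slopes,
tortuosity 0.038, sphericity 0.88) enter as defaults and qualitative
bands only; they are not reproducible without the raw images.

## Problem sizes and known limitations

Reference runs last 15 h of model time (a few hundred to ~2000 apexes,
fractions of a second each); ensembles use 10 seeds.  Test-suite
simulations use 7–15 h runs.

- Measured inter-apical spacings are survivorship-censored: in an
  exponentially growing tip population the completed spacings are
  biased below the law's mean (≈270 vs ≈319 µm), so distributional
  identity with the generating law holds at the sampler level, not on
  trajectory output.
- Under the slow velocity ramp the apex-cloud radii grow super-linearly
  early and the measured density minimum of the reference ensemble
  (≈6.9 ± 0.4 h) sits somewhat above the closed-form t_min from the
  fitted growth rate (≈5 h); the two bracket the broad, flat basin of
  ρ_o.  The variant ordering t_min(dense-lateral) < t_min(reference) <
  t_min(no-lateral) is robust across seeds.
- Hyphal diameter, septation and anastomosis are out of scope; graphs
  are strictly planar overlays.
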