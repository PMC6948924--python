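# Methods

`tilt3d` models an eight-alternative forced-choice (8AFC) tilt-discrimination
paradigm: an observer fixates a target at 57 cm and reports which side of a
slanted, random-dot plane is nearest, choosing among eight tilts spaced 45°
apart.  The package covers the full analysis chain — stimulus geometry,
synthetic choice behavior, circular psychometrics, optimal cue integration,
estimation of a prior over tilt, and Poisson population-code simulations of
how neural architecture constrains combined-cue precision.  This note
documents the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Stimulus geometry

Surface pose is (tilt T, slant S, distance D): tilt is the direction the
plane is oriented in depth (0° right-near, 90° top-near, 270° bottom-near),
slant the magnitude of that orientation, distance the position along the
line of sight.  The coordinate frame places the cyclopean eye at the origin
with +z toward fixation.

*Disparity pedestals.*  The pedestal of a stimulus at distance D is
`vergence(57 cm) − vergence(D)` with `vergence(d) = 2·atan(iod/2 / d)` —
exact arctangent geometry, not the small-angle approximation.  The
interocular distance is not a measured quantity here; the default 3.0 cm
reproduces all eight standard pedestals (−1.63° at 37 cm through +1.76° at
137 cm) to two decimals and is exposed in `ViewingGeometry`.  Pedestals are
negative for near stimuli; the near-side pedestal magnitude grows faster
than the far-side one (|−1.63| at 37 cm vs 0.78 at 77 cm), which matters for
the asymmetric precision falloff below.

*Dot projection.*  A ray at signed eccentricity e along the tilt direction
(positive toward the near side) meets the plane at depth
`z = D / (1 + tan e · tan S)`.  Projected dot axes scale the 0.35° baseline
by `57 / (z / cos e)` — fixation distance over the Euclidean distance to the
intersection — and the minor axis is additionally foreshortened by
`cos(S − e)`, the local slant relative to that line of sight.  This
convention reproduces the standard printed sizes at slant 60°
(0.35°×0.18° on-axis, 0.45°×0.29° near edge, 0.24°×0.08° far edge); scaling
by the z-depth instead of the ray range does not (it gives 0.46° at the
near edge).  Distance-dependence of dot size is removed (screen size depends
only on slant), keeping perspective-cue reliability constant across
distance.  Dot fields: combined-cue stimuli place dots uniformly on the
plane in the world and project each eye's view; stereo-cue stimuli place
dots uniformly on the screen, ray-trace them onto the plane, and render all
dots circular at baseline size (no usable perspective information);
perspective-cue stimuli are combined-cue renderings shown to one eye.
Rejection sampling inside the circular 20° envelope; a seed is mandatory.

## Synthetic behavior

No behavioral data accompany this package, so sessions are synthesized with
the statistical structure the analyses assume.  The percept model specifies
a likelihood concentration κ per pose and cue:

- stereo: `κ_S(S,D) = floor + κ_max_s·(S/60)^a · exp(−(ped(D) − p0)²/2w²)`
  with separate near/far widths (defaults: κ_max_s = 9, a = 1.8, peak
  pedestal p0 = 0.3°, w_near = 1.1°, w_far = 1.0°, floor = 0.15) —
  monotone in slant, inverted-U in distance peaking just behind fixation,
  steeper toward the observer because the near pedestal grows faster;
- perspective: `κ_P(S) = floor + κ_max_p·(S/60)^b` (κ_max_p = 5, b = 1.5),
  distance-independent by construction;
- combined: the vector-sum prediction with zero biases, κ_S + κ_P.

These parametric forms are stand-ins chosen once to reproduce the
qualitative wedge-shaped slant-distance precision landscapes of the task
(near-chance stereo performance at small slant / large distance, peak
precision at the largest slant near fixation); they are not fits to any
subject.  A reported tilt is a draw from the posterior — von Mises
likelihood centered on the true tilt times the tilt prior — binned to the
nearest choice (±22.5° bins; exact-edge draws go to the lower bin, a
measure-zero convention).  Sessions follow a block design: every condition
of the factorial grid (8 tilts × 4 slants × 6 or 8 distances × 3 cue
conditions = 576 or 768 conditions) appears once per block in pseudo-random
order, with the stimulated eye of perspective trials chosen pseudo-randomly;
per-block substreams derive deterministically from one master seed.
Aborted trials are not modeled.

## Circular psychometrics

Errors ΔTilt = reported − presented are wrapped into (−180°, 180°] and
binned at the eight 45° offsets (the half-turn bin sits at +180°).  Each
distribution is fit with a von Mises density `exp(κ·cos(ΔT − μ))/(2π I₀(κ))`
by maximum likelihood under a multinomial whose cell probabilities are the
von Mises mass integrated over each bin.  MLE was chosen over density
least-squares because it handles the 8-bin support exactly and weights bins
by their information; the least-squares variant is provided for comparison.
κ is box-bounded at 18 inside the optimizer: with a 45° sampling interval,
concentrations above ≈18 place ≥90% of the mass within half an interval of
the mean and are mutually indistinguishable (`kappa_identifiability_bound`
recomputes this bound; it is 18.03, i.e. 18 at printed precision, and the
mass at exactly κ = 18 is 0.8997).  Chance performance is tested with the
Rayleigh statistic (via pingouin) with Bonferroni correction across
slant-distance conditions.  Cardinal/oblique comparisons use Fisher-style
sign-based circular median tests (hand-written; no installed library
provides them) for biases and Mann-Whitney U for concentrations.  Gaussian
refits of binned error mass (least squares on bin masses) provide the
1/σ² precision used when comparing behavior with decoded posteriors; σ is
reported in degrees, precision in rad⁻².

## Optimal cue integration

Treating each cue's (κ, μ) as a polar vector, the optimal combined estimate
is the vector sum: μ̂_C from the four-quadrant arctangent of the summed
components and `κ̂_C = sqrt(κ_S² + κ_P² + 2κ_Sκ_P cos(μ_S − μ_P))`.
Consequences asserted by tests: aligned cues add concentrations, opposed
equal cues cancel, one-cue limits hold, and the triangle inequality bounds
κ̂_C.  Observed-vs-predicted comparisons use Pearson correlation and
standardized-major-axis regression (the Type-II flavor chosen; no variant
was mandated) after excluding cap-saturated (κ = 18) fits whose true
precision is unknown.

## Prior over tilt

The prior is the mean of four von Mises densities at the cardinal tilts with
the 0°/180° lobes sharing a concentration — three parameters (κ_0&180, κ_90,
κ_270) reflecting natural-scene tilt statistics (cardinal excess, left/right
symmetry, ground-plane preponderance).  Perception of tilt T̂ follows
`p(T|T̂) ∝ L(T̂|T)·p(T)` with unbiased von Mises likelihoods.  Because a
prior expresses itself only at low precision, it is fit on the
lowest-precision quartile of conditions, minimizing the RMSE between
observed and model choice proportions jointly over the three lobes and the
per-condition likelihood κ's.

Numerical choices: model proportions are exact posterior bin masses on a
0.5° tilt grid offset by 0.25° (no grid point on a bin edge) — the limit of
binning arbitrarily many posterior samples — so the objective is noise-free;
a sampled mode (50,000 inverse-CDF draws, common random numbers) is
available and agrees within Monte-Carlo error.  Given a prior, conditions
decouple, so each κ_L is profiled out on a dense grid (step 0.05, bounds
[0, 18]); the outer problem is multi-start Nelder-Mead (16 deterministic
starts, lobe bounds [0, 20]).  One genuine identifiability limit: an
equal-concentration component shared by all four lobes moves the 45°-binned
choice probabilities by far less than realistic sampling noise, so that
direction is resolved toward the least-informative prior with a small ridge
(2·10⁻⁴·Σκ²); genuine lobe asymmetries affect the objective an order of
magnitude more strongly.  Confidence intervals come from a percentile
bootstrap that resamples each condition's trials (multinomial at the
observed proportions) and refits, warm-started at the point estimate.
Combined-cue predictions multiply both cue likelihoods with the prior and
fit the binned result with a von Mises; with a uniform prior this reduces
exactly to the vector-sum prediction, which the tests exploit as a
consistency check.

## Population-code simulations

72 model neurons with preferred tilts on a 5° grid share a von Mises tuning
width κ_SD per slant-distance and a gain g per cue condition:
`f_i(T) = g·exp(κ_SD[cos(T − μ_i) − 1])`.  Spike counts are independent
Poisson.  Decoding assumes a uniform prior (the prior's behavioral effect is
small, and the focus is cue combination); the log-posterior is
`λ·Σ r_i log f_i(T) − Σ f_i(T)`, with factorial terms constant in T — this
also lets the decoder accept the real-valued "counts" produced by divisive
normalization.  For this homogeneous population the posterior is exactly von
Mises with concentration `K = λ·κ_SD·|Z|`, `Z = Σ r_i e^{iμ_i}`.

The Gaussian summary of the posterior matches its mode and log-curvature
(Laplace): precision 1/σ² = K.  This choice makes decoded precision exactly
proportional to gain at fixed width and makes the linear-summation
architecture exactly optimal (precisions add), which is the property the
architecture comparison is built on.  Moment-based and least-squares
Gaussian summaries are implemented as options; both carry small constant
offsets (≈0.52 and ≈0.25 respectively) that would otherwise bias the
separate-decode-then-sum comparison.

λ(κ_SD) maps population gain to behavioral precision: for each calibration
condition the required λ is the behavioral precision divided by the
unit-λ decoded precision, and four families (linear, exponential
`DC + G·exp(−ακ)`, double exponential, two-phase exponential) are fit by
least squares with AIC selection.  Per-condition gains are then calibrated
by a bracketed 1-D root find so decoded precision matches each cue-isolated
behavioral target (round-trip within 2%); tuning widths are shared across
cue conditions.

Per-condition response amplitudes and tuning widths of 3D-orientation-
selective cortical populations are not published, so a synthetic generator
(`synthetic_cip_table`, clearly labeled synthetic) produces plausible
values — amplitudes of a few tens of spikes growing modestly with slant and
shrinking away from fixation, tuning concentrations 0.6–2.4 sharpening with
slant — at four tested distances, with linear interpolation to untested
distances.

Three architectures combine stereo (r_S) and monocular perspective (r_PL,
r_PR) responses: linear sum of three independent populations; stereo plus
the divisively normalized sum of squared monocular perspective responses
(two populations); and a single population normalizing all three.
Normalization operates on trial-wise counts so noise propagates through the
nonlinearity (an expected-rate variant of the perspective term equals the
monocular rate identically).  The trial-wise quadratic term exceeds the
monocular rate by `normalization_bias(m) = E[(X²+Y²)/(X+Y)] − m`, which
saturates at ½ within a few spikes — a nearly uniform offset that cancels
in decoding (Σe^{iμ_i} = 0) — but at sub-spike rates it becomes tuned and
inflates two-population precision; this is why architecture comparisons are
run at realistic spike counts, and why `expected_combined_precision`
propagates the bias analytically as the noise-free reference for the
simulated precisions.  Simulations present T = 180° only; homogeneity makes
precision tilt-invariant (asserted by test at other tilts).  Conditions
whose cue-isolated behavioral targets sit below κ = 1 (near-chance) are
excluded from the architecture comparison: an unmeasurable behavioral
precision cannot anchor a gain, mirroring the exclusion of chance-level
conditions from behavioral fits.

## Pipeline, problem sizes, and limitations

`run_pipeline` chains simulate → fit → integrate → prior → neurons behind a
YAML-configured CLI, writing CSV/JSON artifacts and a manifest of all seeds;
rerunning with the same seeds reproduces every file byte-for-byte.  Default
problem sizes (20 blocks, 100 bootstrap replicates, 100 decoding trials per
condition) run the full pipeline in minutes on one core; tests use smaller
sizes (2–60 blocks, 30 bootstrap replicates, 80–300 decoding trials) chosen
so Monte-Carlo error stays well below the tolerances they assert.

What the synthetic generator does not emulate: sequential dependencies,
lapses, motivation drifts, aborted trials, vergence noise, heterogeneous
tuning, or correlated neural variability.  Passing tests therefore certify
the correctness and internal consistency of the estimation and simulation
machinery under the stated generative assumptions — not claims about any
particular subject's data.  Subject-specific summary statistics from real
experiments are deliberately out of reach (no deposited data) and are
covered instead by parameter-recovery and closure properties.
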