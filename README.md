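# tilt3d

Analysis toolkit for 3D surface-tilt psychophysics with an
eight-alternative forced-choice (8AFC) design, written for vision
scientists studying how stereoscopic and perspective cues are combined
into 3D percepts — and how neural population codes constrain that
combination.

A planar surface's orientation in depth is described by tilt T (the
direction the plane is oriented in depth: 0° right-near, 90° top-near,
270° bottom-near), slant S (how much it is oriented in depth), and viewing
distance D.  An observer fixating at 57 cm reports the near side of a
random-dot plane by choosing one of eight tilts spaced 45° apart.  The
package implements the full analysis chain for this paradigm:

- **Stimulus geometry** — vergence-based disparity pedestals, ray-plane
  intersection, perspective dot foreshortening/scaling, and construction of
  combined-cue, stereo-only, and perspective-only dot fields.
- **Synthetic behavior** — seed-controlled 8AFC block-design sessions whose
  precision landscapes carry the structure the analyses assume (stereo
  precision monotone in slant and inverted-U in distance; perspective
  precision distance-independent).
- **Circular psychometrics** — tilt-error distributions ΔT = reported −
  presented, summarized by von Mises fits VM(ΔT) ∝ exp(κ·cos(ΔT − μ)):
  μ is the bias (accuracy) and κ the concentration (precision, the
  circular analog of 1/σ²), capped at 18 because 45°-quantized responses
  cannot distinguish higher concentrations.  Rayleigh chance tests and
  cardinal-vs-oblique ("oblique effect") summaries included.
- **Optimal cue integration** — the vector-sum prediction
  κ̂_C = √(κ_S² + κ_P² + 2κ_Sκ_P·cos(μ_S − μ_P)) with the corresponding
  combined bias, plus observed-vs-optimal correlation and Type-II
  regression.
- **Prior over tilt** — a four-lobed cardinal mixture prior (shared 0°/180°
  lobe, free 90° and 270° lobes) estimated from low-precision conditions by
  RMSE between observed and posterior-model choice proportions, with
  bootstrap confidence intervals and Bayes-rule combined-cue predictions.
- **Population models** — 72 Poisson neurons with von Mises tuning
  f_i(T) = g·exp(κ_SD[cos(T − μ_i) − 1]); Bayesian decoding of combined
  representations built by three architectures (linear three-population
  sum; stereo + divisively normalized squared monocular perspective
  responses; one fully normalized population), with a λ(κ_SD) calibration
  mapping population gain to behavioral precision.

See `docs/methods.md` for the models, assumptions, and design choices.

## Worked example

Simulate a session for the 576-condition grid, fit one slant-distance
condition per cue, and compare the combined-cue precision with the optimal
prediction:

```python
from tilt3d import (ConditionGrid, PerceptModel, TiltPrior, simulate_session,
                    tilt_errors, fit_von_mises, CuePair, optimal_combined)

model = PerceptModel(prior=TiltPrior(0, 0, 2))   # ground-plane (270 deg) prior
trials = simulate_session(ConditionGrid.monkey_l(), model, n_blocks=20, seed=42)

sub = trials[(trials.slant == 45) & (trials.distance_cm == 77)]
fits = {cue: fit_von_mises(tilt_errors(t)[0]) for cue, t in sub.groupby("cue")}
for cue, f in fits.items():
    print(f"{cue:12s} mu = {f.mu:6.2f} deg   kappa = {f.kappa:5.2f}   (n = {f.n})")

pred = optimal_combined(CuePair(fits["stereo"].mu, fits["stereo"].kappa,
                                fits["perspective"].mu, fits["perspective"].kappa))
print(f"optimal      mu = {pred.mu_c:6.2f} deg   kappa = {pred.kappa_c:5.2f}")
```

Output:

```
combined     mu =   0.58 deg   kappa =  7.32   (n = 160)
perspective  mu =  -2.33 deg   kappa =  3.67   (n = 160)
stereo       mu =   1.32 deg   kappa =  3.92   (n = 160)
optimal      mu =  -0.45 deg   kappa =  7.59
```

The two cue-isolated precisions (κ ≈ 3.7 and 3.9) predict a combined
precision of 7.59 under optimal integration; the simulated combined-cue
fit (7.32) lands on that prediction within sampling error, and the small
biases reflect 160 trials per condition plus the weak pull of the
bottom-near prior.

The full pipeline — simulate → fit → integrate → prior → neurons — runs
from the command line:

```bash
tilt3d all --out results_dir          # default configuration
tilt3d fit --trials my_trials.csv --out fits_dir
```

Each run writes CSV/JSON artifacts and a `manifest.json` recording every
seed, so outputs are byte-for-byte reproducible.

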