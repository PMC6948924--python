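"""Optimal cue integration for circular estimates.

Each cue's tilt estimate is summarized by a bias μ (deg) and a concentration
κ; treating (κ, μ) as a polar vector, the optimal combined estimate is the
vector sum:

    μ̂_C = atan2(κ_S sin μ_S + κ_P sin μ_P, κ_S cos μ_S + κ_P cos μ_P)
    κ̂_C = sqrt(κ_S² + κ_P² + 2 κ_S κ_P cos(μ_S − μ_P))

so aligned cues add their concentrations, opposed equal cues cancel, and a
cue with κ = 0 contributes nothing.  Observed-versus-optimal comparisons use
Pearson correlation and standardized-major-axis (Type II) regression, with
cap-saturated fits (κ = 18) excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psychometrics import KAPPA_CAP, wrap_degrees

__all__ = ["CuePair", "CombinedPrediction", "optimal_combined", "integration_comparison"]


@dataclass(frozen=True)
class CuePair:
    """Stereo and (pooled) perspective bias/precision for one condition."""

    mu_s: float
    kappa_s: float
    mu_p: float
    kappa_p: float

    def __post_init__(self) -> None:
        if self.kappa_s < 0 or self.kappa_p < 0:
            raise ValueError("concentrations must be nonnegative")
        if not (np.isfinite(self.kappa_s) and np.isfinite(self.kappa_p)):
            raise ValueError("concentrations must be finite")


@dataclass(frozen=True)
class CombinedPrediction:
    mu_c: float
    kappa_c: float
    mu_defined: bool = True


def optimal_combined(pair: CuePair) -> CombinedPrediction:
    """Optimal combined-cue (μ̂_C, κ̂_C) from a pair of cue-isolated fits."""
    ms, mp = np.radians(pair.mu_s), np.radians(pair.mu_p)
    ks, kp = pair.kappa_s, pair.kappa_p
    y = ks * np.sin(ms) + kp * np.sin(mp)
    x = ks * np.cos(ms) + kp * np.cos(mp)
    kappa_c = float(
        np.sqrt(max(ks**2 + kp**2 + 2 * ks * kp * np.cos(ms - mp), 0.0))
    )
    if kappa_c < 1e-12:
        return CombinedPrediction(mu_c=0.0, kappa_c=0.0, mu_defined=False)
    mu_c = wrap_degrees(np.degrees(np.arctan2(y, x)))
    return CombinedPrediction(mu_c=mu_c, kappa_c=kappa_c)


def sma_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Standardized major axis slope and intercept (Type II regression)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0:
        raise ValueError("x has zero variance")
    r = np.corrcoef(x, y)[0, 1]
    slope = np.sign(r if r != 0 else 1.0) * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


def integration_comparison(
    observed_kappa: np.ndarray,
    predicted_kappa: np.ndarray,
    exclude_capped: bool = True,
) -> dict:
    """Correlate observed with optimally predicted combined-cue precision.

    Returns Pearson r and the SMA regression of predicted on observed.
    Conditions where either κ saturates the estimation cap are excluded
    (their true precision is unknown); fewer than 3 remaining pairs is an
    error.
    """
    obs = np.asarray(observed_kappa, dtype=float)
    pred = np.asarray(predicted_kappa, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must align")
    keep = np.ones(len(obs), dtype=bool)
    if exclude_capped:
        keep = (obs < KAPPA_CAP - 1e-6) & (pred < KAPPA_CAP - 1e-6)
    obs, pred = obs[keep], pred[keep]
    if len(obs) < 3:
        raise ValueError("need at least 3 uncapped condition pairs")
    if np.allclose(obs, pred):
        # Degenerate perfect agreement: correlation is 1 by construction.
        return {"r": 1.0, "slope": 1.0, "intercept": 0.0, "n": int(len(obs))}
    r = float(np.corrcoef(obs, pred)[0, 1])
    slope, intercept = sma_regression(obs, pred)
    return {"r": r, "slope": slope, "intercept": intercept, "n": int(len(obs))}
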