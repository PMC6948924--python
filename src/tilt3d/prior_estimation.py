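"""Estimating a cardinal prior over surface tilt from 8AFC choices.

Natural scenes contain more cardinal than oblique surface tilts, equal
left-near and right-near frequencies, and a preponderance of ground planes
(bottom-near, 270°).  The prior over tilt is accordingly modeled as the mean
of four von Mises densities centered on the cardinal tilts, with the 0° and
180° lobes sharing a concentration — three free parameters in all:
κ_0°&180°, κ_90°, and κ_270°.

Perception of a presented tilt T is modeled as a draw from the posterior

    p(T | T̂) ∝ L(T̂ | T) · p(T),

with an unbiased von Mises likelihood of concentration κ_L, binned into the
eight 45°-spaced choice options.  Because a prior only reveals itself when
the likelihood is broad, the prior is fit on the lowest-precision quartile of
conditions, by minimizing the RMSE between observed and model choice
proportions jointly over the three lobes and the per-condition κ_L's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .psychometrics import ErrorDistribution, VonMisesFit, fit_von_mises, wrap_degrees

__all__ = [
    "TiltPrior",
    "CHOICE_TILTS",
    "prior_density",
    "posterior_choice_probs",
    "choice_table_from_trials",
    "fit_prior",
    "PriorFitResult",
    "bootstrap_prior_ci",
    "predict_combined_bayes",
]

#: The eight response options (deg).
CHOICE_TILTS = np.arange(0.0, 360.0, 45.0)

_CARDINALS = np.array([0.0, 90.0, 180.0, 270.0])

# Tilt grid for quadrature/sampling: 0.5° steps offset by 0.25° so no grid
# point falls on a choice-bin edge (odd multiples of 22.5°).
_GRID = np.arange(0.0, 360.0, 0.5) + 0.25
_GRID_RAD = np.radians(_GRID)
_GRID_BIN = (np.round(_GRID / 45.0).astype(int)) % 8
_BIN_MATRIX = np.eye(8)[_GRID_BIN]  # (n_grid, 8)

_PRIOR_LOBE_BOUND = 20.0
_LIK_BOUND = 18.0


@dataclass(frozen=True)
class TiltPrior:
    """Four-lobed cardinal mixture prior; lobes at 0/180° share kappa_0_180."""

    kappa_0_180: float = 0.0
    kappa_90: float = 0.0
    kappa_270: float = 0.0

    def __post_init__(self) -> None:
        if min(self.kappa_0_180, self.kappa_90, self.kappa_270) < 0:
            raise ValueError("lobe concentrations must be nonnegative")

    @property
    def lobe_kappas(self) -> np.ndarray:
        """Concentrations for the lobes at (0, 90, 180, 270) degrees."""
        return np.array(
            [self.kappa_0_180, self.kappa_90, self.kappa_0_180, self.kappa_270]
        )

    def is_uniform(self, tol: float = 1e-9) -> bool:
        return bool(np.all(self.lobe_kappas < tol))


def prior_density(tilt_deg, prior: TiltPrior) -> np.ndarray | float:
    """Normalized circular density of the cardinal-mixture prior (per radian).

    The mean of four unit-area von Mises densities integrates to one by
    construction; a zero-concentration lobe contributes a uniform 1/(2π).
    p(T) = p(180° − T) holds because the 0° and 180° lobes share their
    concentration and the 90°/270° lobes sit on the mirror axis.
    """
    t = np.radians(np.asarray(tilt_deg, dtype=float))
    dens = np.zeros_like(t)
    from scipy.special import i0

    for center, kappa in zip(np.radians(_CARDINALS), prior.lobe_kappas):
        dens += np.exp(kappa * np.cos(t - center)) / (2 * np.pi * i0(kappa))
    dens /= 4.0
    return dens if np.ndim(tilt_deg) else float(dens)


def _posterior_on_grid(true_tilt: float, kappa_l: float, prior_grid: np.ndarray) -> np.ndarray:
    """Unnormalized posterior over the tilt grid."""
    like = np.exp(kappa_l * np.cos(_GRID_RAD - np.radians(true_tilt)))
    return like * prior_grid


def posterior_choice_probs(
    true_tilt: float,
    kappa_l: float,
    prior: TiltPrior,
    n_samples: int = 50_000,
    seed: Optional[int] = None,
    method: Literal["sample", "exact"] = "sample",
) -> np.ndarray:
    """Probability of each of the eight choices under the tilt posterior.

    ``method="sample"`` draws `n_samples` from the posterior (inverse-CDF on
    a 0.5° grid, deterministic given `seed`) and bins them into the 45°
    choice bins, as in fitting the prior from behavioral proportions;
    ``method="exact"`` integrates the posterior over each bin instead.
    """
    if kappa_l < 0:
        raise ValueError("likelihood concentration must be nonnegative")
    prior_grid = prior_density(_GRID, prior)
    post = _posterior_on_grid(true_tilt, kappa_l, prior_grid)
    if method == "exact":
        mass = post @ _BIN_MATRIX
        return mass / mass.sum()
    if seed is None:
        raise ValueError("sampling requires a seed")
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(post)
    u = rng.uniform(0.0, cdf[-1], size=n_samples)
    idx = np.searchsorted(cdf, u, side="left")
    counts = np.bincount(_GRID_BIN[idx], minlength=8)
    return counts / counts.sum()


def choice_table_from_trials(
    trials: pd.DataFrame,
    grouping: Sequence[str] = ("tilt", "slant", "distance_cm", "cue"),
) -> pd.DataFrame:
    """Per-condition choice proportions from a trial table.

    Returns one row per condition with the grouping keys, the trial count
    `n`, and columns ``p0 ... p315`` holding the proportion of each reported
    tilt.
    """
    rows = []
    for key, sub in trials.groupby(list(grouping), sort=True, observed=True):
        props = np.zeros(8)
        rep = sub["reported_tilt"].to_numpy() % 360.0
        for j, c in enumerate(CHOICE_TILTS):
            props[j] = np.mean(np.isclose(rep, c))
        row = dict(zip(grouping, key if isinstance(key, tuple) else (key,)))
        row["n"] = len(sub)
        row.update({f"p{int(c)}": props[j] for j, c in enumerate(CHOICE_TILTS)})
        rows.append(row)
    return pd.DataFrame(rows)


def _prop_matrix(choice_table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = [f"p{int(c)}" for c in CHOICE_TILTS]
    props = choice_table[cols].to_numpy(dtype=float)
    tilts = choice_table["tilt"].to_numpy(dtype=float) % 360.0
    return tilts, props


_KAPPA_GRID = np.arange(0.0, _LIK_BOUND + 1e-9, 0.05)
_LIKE_CACHE: dict[str, np.ndarray] = {}


def _likelihood_bases() -> np.ndarray:
    """Cached von Mises likelihood grids, (8 tilts, nk, ng); prior-free."""
    if "bases" not in _LIKE_CACHE:
        base = np.exp(np.outer(_KAPPA_GRID, np.cos(_GRID_RAD)))  # T = 0
        step = int(round(45.0 / 0.5))
        _LIKE_CACHE["bases"] = np.stack(
            [np.roll(base, ti * step, axis=1) for ti in range(8)]
        )
    return _LIKE_CACHE["bases"]


def _model_prob_tensor(prior: TiltPrior) -> np.ndarray:
    """Choice-probability tensor P[tilt_idx, kappa_idx, choice] for a prior.

    tilt_idx indexes the eight presentable tilts; kappa_idx the dense κ_L
    grid used to profile out the per-condition likelihood concentrations.
    """
    prior_grid = prior_density(_GRID, prior)
    bases = _likelihood_bases()
    out = np.empty((8, len(_KAPPA_GRID), 8))
    for ti in range(8):
        mass = (bases[ti] * prior_grid) @ _BIN_MATRIX
        out[ti] = mass / mass.sum(axis=1, keepdims=True)
    return out


def _profile_objective(
    lobes: np.ndarray, tilts: np.ndarray, props: np.ndarray
) -> tuple[float, np.ndarray]:
    """RMSE over all conditions' choice proportions, profiling out κ_L.

    For a fixed prior the conditions decouple: each condition's best κ_L is
    found on the dense grid independently.  Returns (rmse, per-condition
    κ_L).
    """
    prior = TiltPrior(*np.clip(lobes, 0.0, _PRIOR_LOBE_BOUND))
    tensor = _model_prob_tensor(prior)
    tilt_idx = (np.round(tilts / 45.0).astype(int)) % 8
    n_cond = len(tilts)
    sse_total = 0.0
    kappas = np.empty(n_cond)
    for i in range(n_cond):
        model = tensor[tilt_idx[i]]  # (nk, 8)
        sse = np.sum((model - props[i]) ** 2, axis=1)
        j = int(np.argmin(sse))
        kappas[i] = _KAPPA_GRID[j]
        sse_total += sse[j]
    rmse = float(np.sqrt(sse_total / (n_cond * 8)))
    return rmse, kappas


@dataclass
class PriorFitResult:
    prior: TiltPrior
    likelihood_kappas: np.ndarray
    rmse: float
    converged: bool
    n_conditions: int

    def to_dict(self) -> dict:
        return {
            "kappa_0_180": self.prior.kappa_0_180,
            "kappa_90": self.prior.kappa_90,
            "kappa_270": self.prior.kappa_270,
            "rmse": self.rmse,
            "converged": self.converged,
            "n_conditions": self.n_conditions,
            "likelihood_kappas": self.likelihood_kappas.tolist(),
        }


def _multi_starts(n_starts: int) -> np.ndarray:
    """Deterministic spread of starting lobes over [0, 10]^3."""
    rng = np.random.default_rng(20231107)
    starts = rng.uniform(0.0, 10.0, size=(max(n_starts - 2, 0), 3))
    fixed = np.array([[0.1, 0.1, 0.1], [2.0, 2.0, 6.0]])
    return np.vstack([fixed, starts])[:n_starts]


def fit_prior(
    choice_table: pd.DataFrame,
    n_starts: int = 16,
    x0: Optional[np.ndarray] = None,
    ridge: float = 2e-4,
) -> PriorFitResult:
    """Jointly estimate the cardinal prior and per-condition likelihood κ's.

    `choice_table` holds one row per low-precision condition (the first
    quartile of previously fitted κ's) with its presented tilt and observed
    choice proportions (see :func:`choice_table_from_trials`).  The RMSE
    between observed and model proportions is minimized over the three prior
    lobes by multi-start Nelder-Mead, with each condition's κ_L profiled out
    on a dense grid.  Model proportions are exact bin masses of the
    posterior on a 0.5° tilt grid (the limit of binning arbitrarily many
    posterior samples), so the objective is noise-free.

    An equal-concentration component shared by all four lobes is almost
    invisible to 45°-binned choices (it moves the bin masses by well under
    the sampling noise of realistic condition counts), so that direction of
    parameter space is resolved toward the least-informative prior by a
    small ridge penalty `ridge`·Σκ² on the lobes; genuine lobe asymmetries
    change the objective by an order of magnitude more than the penalty.
    """
    if choice_table.empty:
        raise ValueError("prior estimation requires a non-empty condition subset")
    tilts, props = _prop_matrix(choice_table)

    def objective(lobes: np.ndarray) -> float:
        rmse = _profile_objective(lobes, tilts, props)[0]
        return rmse + ridge * float(np.sum(np.clip(lobes, 0, None) ** 2))

    starts = _multi_starts(n_starts) if x0 is None else np.atleast_2d(x0)
    best = None
    converged = False
    for s in starts:
        res = optimize.minimize(
            objective,
            x0=s,
            method="Nelder-Mead",
            options={"xatol": 1e-2, "fatol": 1e-7, "maxiter": 250},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    lobes = np.clip(best.x, 0.0, _PRIOR_LOBE_BOUND)
    rmse, kappas = _profile_objective(lobes, tilts, props)
    return PriorFitResult(
        prior=TiltPrior(*lobes),
        likelihood_kappas=kappas,
        rmse=rmse,
        converged=converged,
        n_conditions=len(tilts),
    )


def bootstrap_prior_ci(
    choice_table: pd.DataFrame,
    n_rep: int = 1000,
    seed: Optional[int] = None,
    ci: float = 0.95,
    n_starts: int = 2,
) -> dict:
    """Percentile bootstrap CI for the three prior lobes.

    Each replicate resamples every condition's trials with replacement
    (multinomial draws at the observed proportions and trial counts) and
    refits the prior, warm-started at the full-data estimate.  Returns the
    point estimate, per-lobe CIs, and the replicate matrix.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    point = fit_prior(choice_table)
    tilts, props = _prop_matrix(choice_table)
    ns = choice_table["n"].to_numpy(dtype=int)
    cols = [f"p{int(c)}" for c in CHOICE_TILTS]
    reps = np.empty((n_rep, 3))
    warm = np.array(
        [point.prior.kappa_0_180, point.prior.kappa_90, point.prior.kappa_270]
    )
    for b in range(n_rep):
        boot = choice_table.copy()
        for i in range(len(boot)):
            counts = rng.multinomial(ns[i], props[i])
            boot.loc[boot.index[i], cols] = counts / counts.sum()
        starts = np.vstack([warm, _multi_starts(n_starts)])[: max(n_starts, 1)]
        best = None
        for s in starts:
            fit = fit_prior(boot, x0=s)
            if best is None or fit.rmse < best.rmse:
                best = fit
        reps[b] = [best.prior.kappa_0_180, best.prior.kappa_90, best.prior.kappa_270]
    alpha = (1.0 - ci) / 2.0
    lo = np.percentile(reps, 100 * alpha, axis=0)
    hi = np.percentile(reps, 100 * (1 - alpha), axis=0)
    degenerate = n_rep < 2
    names = ["kappa_0_180", "kappa_90", "kappa_270"]
    return {
        "point": point,
        "ci": {nm: (float(l), float(h)) for nm, l, h in zip(names, lo, hi)},
        "replicates": reps,
        "degenerate": degenerate,
    }


def predict_combined_bayes(
    kappa_l_stereo: float,
    kappa_l_persp: float,
    prior: TiltPrior,
    true_tilt: float = 180.0,
    n_samples: int = 50_000,
    seed: Optional[int] = None,
    method: Literal["sample", "exact"] = "exact",
) -> tuple[ErrorDistribution, VonMisesFit]:
    """Predicted combined-cue error distribution and its von Mises summary.

    The combined-cue posterior is the product of the stereo and perspective
    likelihoods (both unbiased von Mises centered on the presented tilt) and
    the prior; its mass in each choice bin gives the predicted 8AFC error
    distribution, which is then fit with a von Mises.  With a uniform prior
    the two likelihoods collapse to a single von Mises of concentration
    κ_S + κ_P, reproducing the vector-sum prediction of
    :func:`tilt3d.cue_integration.optimal_combined`.
    """
    if kappa_l_stereo < 0 or kappa_l_persp < 0:
        raise ValueError("likelihood concentrations must be nonnegative")
    prior_grid = prior_density(_GRID, prior)
    t0 = np.radians(true_tilt)
    post = (
        np.exp(kappa_l_stereo * np.cos(_GRID_RAD - t0))
        * np.exp(kappa_l_persp * np.cos(_GRID_RAD - t0))
        * prior_grid
    )
    if method == "exact":
        probs = post @ _BIN_MATRIX
        probs = probs / probs.sum()
        n_eff = n_samples
    else:
        if seed is None:
            raise ValueError("sampling requires a seed")
        rng = np.random.default_rng(seed)
        cdf = np.cumsum(post)
        u = rng.uniform(0.0, cdf[-1], size=n_samples)
        counts = np.bincount(_GRID_BIN[np.searchsorted(cdf, u)], minlength=8)
        probs = counts / counts.sum()
        n_eff = n_samples
    # Re-express choice probabilities as ΔTilt probabilities around true_tilt.
    if not np.any(np.isclose(true_tilt % 45.0, [0.0, 45.0])):
        raise ValueError("true_tilt must be one of the eight 45-degree choices")
    deltas = wrap_degrees(CHOICE_TILTS - true_tilt)
    from .psychometrics import DELTA_BINS

    delta_probs = np.zeros(8)
    for j, d in enumerate(deltas):
        k = int(np.where(np.isclose(DELTA_BINS, d))[0][0])
        delta_probs[k] = probs[j]
    errdist = ErrorDistribution(
        probs=delta_probs, n=n_eff, keys={"true_tilt": float(true_tilt)}
    )
    return errdist, fit_von_mises(errdist)
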