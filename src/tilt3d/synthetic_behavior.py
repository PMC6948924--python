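"""Seed-controlled synthetic 8AFC tilt-discrimination sessions.

No behavioral data are deposited for this task, so analyses are exercised on
synthetic sessions that carry the statistical structure the method assumes:

* a full factorial condition grid — 8 tilts × 4 slants × several distances ×
  3 cue conditions — presented one repetition per block in pseudo-random
  order;
* a perceptual precision landscape in which stereoscopic concentration rises
  monotonically with slant and falls off (inverted-U, steeper on the near
  side) with distance from fixation, perspective concentration rises with
  slant but is distance-independent, and the combined-cue concentration is
  the vector sum of the two;
* choices drawn from the posterior of an unbiased von Mises likelihood times
  a cardinal tilt prior, binned to the nearest of the eight response options.

The parametric forms of the precision landscapes are stand-ins chosen to
reproduce the qualitative wedge-shaped slant-distance precision maps of the
task; they are not estimates of any particular subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cue_integration import CuePair, optimal_combined
from .prior_estimation import CHOICE_TILTS, TiltPrior, _GRID, _GRID_BIN, prior_density
from .stimulus_geometry import CueCondition, Eye, SurfacePose, ViewingGeometry, disparity_pedestal

__all__ = [
    "ConditionGrid",
    "MONKEY_L_DISTANCES",
    "MONKEY_F_DISTANCES",
    "PerceptModel",
    "kappa_landscape",
    "sample_reported_tilt",
    "simulate_session",
    "TRIAL_COLUMNS",
]

MONKEY_L_DISTANCES = (37.0, 57.0, 77.0, 87.0, 107.0, 137.0)
MONKEY_F_DISTANCES = (37.0, 57.0, 77.0, 87.0, 97.0, 107.0, 117.0, 137.0)

TRIAL_COLUMNS = ["block", "tilt", "slant", "distance_cm", "cue", "eye", "reported_tilt"]


@dataclass(frozen=True)
class ConditionGrid:
    """Factorial stimulus grid (tilt × slant × distance × cue)."""

    tilts: tuple[float, ...] = tuple(np.arange(0.0, 360.0, 45.0))
    slants: tuple[float, ...] = (15.0, 30.0, 45.0, 60.0)
    distances: tuple[float, ...] = MONKEY_L_DISTANCES
    cues: tuple[CueCondition, ...] = (
        CueCondition.COMBINED,
        CueCondition.STEREO,
        CueCondition.PERSPECTIVE,
    )

    @classmethod
    def monkey_l(cls) -> "ConditionGrid":
        """6-distance preset: 576 conditions."""
        return cls(distances=MONKEY_L_DISTANCES)

    @classmethod
    def monkey_f(cls) -> "ConditionGrid":
        """8-distance preset: 768 conditions."""
        return cls(distances=MONKEY_F_DISTANCES)

    @classmethod
    def preset(cls, name: str) -> "ConditionGrid":
        try:
            return {"monkey_l": cls.monkey_l, "monkey_f": cls.monkey_f}[name.lower()]()
        except KeyError:
            raise ValueError(f"unknown grid preset {name!r}") from None

    @property
    def size(self) -> int:
        return len(self.tilts) * len(self.slants) * len(self.distances) * len(self.cues)

    def conditions(self) -> pd.DataFrame:
        """One row per condition, in canonical (tilt, slant, distance, cue) order."""
        rows = [
            {"tilt": t, "slant": s, "distance_cm": d, "cue": c.value}
            for t in self.tilts
            for s in self.slants
            for d in self.distances
            for c in self.cues
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PerceptModel:
    """Parametric stand-in for the perceptual precision landscapes.

    Stereo concentration:
        κ_S(S, D) = floor + κ_max_s · (S/60)^a · exp(−(ped(D) − p0)² / 2w²)
    with separate near-side (ped < p0) and far-side falloff widths, where
    ped(D) is the disparity pedestal in degrees — so the falloff is governed
    by disparity content, peaking at/just behind fixation and dropping more
    steeply toward the observer (the near pedestal at 37 cm is larger in
    magnitude than the far pedestal at 77 cm).

    Perspective concentration:
        κ_P(S) = floor + κ_max_p · (S/60)^b,   independent of distance.

    Combined concentration is the vector-sum prediction with zero biases,
    i.e. κ_S + κ_P.  Choices are modulated by a cardinal tilt `prior`.
    """

    kappa_max_s: float = 9.0
    slant_exp_s: float = 1.8
    peak_pedestal: float = 0.3  # deg; precision peaks just behind fixation
    width_near: float = 1.1  # deg of pedestal, toward the observer
    width_far: float = 1.0  # deg of pedestal, away from the observer
    kappa_max_p: float = 5.0
    slant_exp_p: float = 1.5
    kappa_floor: float = 0.15
    prior: TiltPrior = field(default_factory=TiltPrior)
    geom: ViewingGeometry = field(default_factory=ViewingGeometry)

    def __post_init__(self) -> None:
        if min(self.kappa_max_s, self.kappa_max_p, self.kappa_floor) < 0:
            raise ValueError("concentration parameters must be nonnegative")
        if self.width_near <= 0 or self.width_far <= 0:
            raise ValueError("falloff widths must be positive")


def kappa_landscape(
    pose: SurfacePose, cue: CueCondition | str, model: PerceptModel
) -> float:
    """Likelihood concentration κ for one pose and cue condition."""
    cue = CueCondition(cue)
    slant_term_s = (pose.slant / 60.0) ** model.slant_exp_s
    slant_term_p = (pose.slant / 60.0) ** model.slant_exp_p
    ped = disparity_pedestal(pose.distance, model.geom)
    width = model.width_near if ped < model.peak_pedestal else model.width_far
    dist_term = np.exp(-((ped - model.peak_pedestal) ** 2) / (2.0 * width**2))
    kappa_s = model.kappa_floor + model.kappa_max_s * slant_term_s * dist_term
    kappa_p = model.kappa_floor + model.kappa_max_p * slant_term_p
    if cue is CueCondition.STEREO:
        return float(kappa_s)
    if cue is CueCondition.PERSPECTIVE:
        return float(kappa_p)
    combined = optimal_combined(
        CuePair(mu_s=0.0, kappa_s=kappa_s, mu_p=0.0, kappa_p=kappa_p)
    )
    return float(combined.kappa_c)


def sample_reported_tilt(
    true_tilt: float,
    kappa_lik: float,
    prior: TiltPrior,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    size: int = 1,
) -> np.ndarray:
    """Reported tilt(s): posterior draws binned to the nearest choice.

    A percept is a sample from the posterior (von Mises likelihood of
    concentration `kappa_lik` centered on `true_tilt`, times the tilt
    prior), drawn by inverse-CDF on a 0.5° grid and assigned to the choice
    whose ±22.5° bin contains it.
    """
    if not np.isfinite(kappa_lik) or kappa_lik < 0:
        raise ValueError("kappa_lik must be finite and nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)
    post = np.exp(kappa_lik * np.cos(np.radians(_GRID - true_tilt))) * prior_density(
        _GRID, prior
    )
    cdf = np.cumsum(post)
    u = rng.uniform(0.0, cdf[-1], size=size)
    idx = np.searchsorted(cdf, u, side="left")
    return CHOICE_TILTS[_GRID_BIN[idx]]


def simulate_session(
    grid: ConditionGrid,
    model: PerceptModel,
    n_blocks: int = 1,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate a block-design session; one response per condition per block.

    Within each block every condition appears exactly once in pseudo-random
    order; perspective trials are delivered to a pseudo-randomly chosen eye.
    Per-block random substreams are derived deterministically from the
    master seed, so the same seed always yields an identical table.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if seed is None:
        raise ValueError("simulate_session requires a master seed")
    conditions = grid.conditions()
    # Precompute per-condition likelihood concentrations (tilt-independent).
    kappas = np.array(
        [
            kappa_landscape(
                SurfacePose(row.tilt, row.slant, row.distance_cm), row.cue, model
            )
            for row in conditions.itertuples()
        ]
    )
    master = np.random.SeedSequence(seed)
    block_seeds = master.spawn(n_blocks)
    tables = []
    for b, bs in enumerate(block_seeds):
        rng = np.random.default_rng(bs)
        order = rng.permutation(len(conditions))
        block = conditions.iloc[order].reset_index(drop=True)
        block_kappas = kappas[order]
        eyes = np.where(
            block["cue"].to_numpy() == CueCondition.PERSPECTIVE.value,
            np.where(rng.random(len(block)) < 0.5, Eye.LEFT.value, Eye.RIGHT.value),
            Eye.BOTH.value,
        )
        reported = np.empty(len(block))
        for i, row in enumerate(block.itertuples()):
            reported[i] = sample_reported_tilt(
                row.tilt, block_kappas[i], model.prior, rng=rng
            )[0]
        block = block.assign(block=b, eye=eyes, reported_tilt=reported)
        tables.append(block[TRIAL_COLUMNS])
    return pd.concat(tables, ignore_index=True)
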