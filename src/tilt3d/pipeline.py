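"""End-to-end analysis pipeline and command-line interface.

Orchestrates: synthetic session generation → psychometric fitting → optimal
cue-integration comparison → prior estimation → population-model
simulation, writing CSV/JSON artifacts and a manifest of seeds so any
output can be regenerated exactly.  The CLI is a thin layer over the
library; every stage is callable directly in Python.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cue_integration import CuePair, integration_comparison, optimal_combined
from .population_models import (
    architecture_experiment,
    expected_decoded_precision,
    fit_lambda,
    interpolate_cip_table,
    synthetic_cip_table,
)
from .prior_estimation import (
    TiltPrior,
    bootstrap_prior_ci,
    choice_table_from_trials,
    fit_prior,
)
from .psychometrics import (
    fit_von_mises,
    fits_to_frame,
    rayleigh_chance_test,
    tilt_errors,
)
from .stimulus_geometry import SurfacePose
from .synthetic_behavior import ConditionGrid, PerceptModel, kappa_landscape, simulate_session

__all__ = ["RunConfig", "run_pipeline", "cli"]

log = logging.getLogger("tilt3d")


@dataclass
class RunConfig:
    """Schema-validated pipeline configuration.

    Every stochastic stage has an explicit seed; the percept-model and
    prior parameters default to the package's standard synthetic study
    conditions.
    """

    grid_preset: str = "monkey_l"
    n_blocks: int = 20
    prior: dict = field(
        default_factory=lambda: {"kappa_0_180": 0.0, "kappa_90": 0.0, "kappa_270": 2.0}
    )
    percept_model: dict = field(default_factory=dict)
    seeds: dict = field(
        default_factory=lambda: {
            "session": 1,
            "cip": 2,
            "architecture": 3,
            "bootstrap": 4,
        }
    )
    bootstrap_reps: int = 100
    architecture_trials: int = 100
    output_dir: str = "tilt3d_output"

    def validate(self) -> None:
        if self.grid_preset.lower() not in {"monkey_l", "monkey_f"}:
            raise ValueError(f"unknown grid preset {self.grid_preset!r}")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        required = {"session", "cip", "architecture", "bootstrap"}
        if not required <= set(self.seeds):
            raise ValueError(f"seeds must define {sorted(required)}")
        for k, v in self.seeds.items():
            if not isinstance(v, int):
                raise ValueError(f"seed {k!r} must be an integer")
        for k in self.prior:
            if k not in {"kappa_0_180", "kappa_90", "kappa_270"}:
                raise ValueError(f"unknown prior parameter {k!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def build_model(self) -> PerceptModel:
        return PerceptModel(prior=TiltPrior(**self.prior), **self.percept_model)

    def build_grid(self) -> ConditionGrid:
        return ConditionGrid.preset(self.grid_preset)


def _stage_simulate(cfg: RunConfig, out: Path) -> pd.DataFrame:
    trials = simulate_session(
        cfg.build_grid(), cfg.build_model(), n_blocks=cfg.n_blocks,
        seed=cfg.seeds["session"],
    )
    trials.to_csv(out / "trials.csv", index=False)
    return trials


def _stage_fit(cfg: RunConfig, out: Path, trials: pd.DataFrame) -> pd.DataFrame:
    """Pooled-tilt von Mises fits per slant × distance × cue, with chance tests."""
    dists = tilt_errors(trials, ["slant", "distance_cm", "cue"])
    n_cmp = trials.groupby(["slant", "distance_cm"]).ngroups
    fits = []
    for ed in dists:
        f = fit_von_mises(ed)
        p = rayleigh_chance_test(ed, n_comparisons=n_cmp)
        f.keys["p_rayleigh"] = p
        f.keys["chance"] = p >= 0.05
        fits.append(f)
    frame = fits_to_frame(fits)
    frame.to_csv(out / "fits.csv", index=False)
    return frame


def _stage_integrate(cfg: RunConfig, out: Path, fits: pd.DataFrame) -> dict:
    """Observed vs optimally predicted combined-cue precision per condition."""
    wide = fits.pivot_table(
        index=["slant", "distance_cm"], columns="cue", values=["mu", "kappa"]
    )
    rows = []
    for (s, d), row in wide.iterrows():
        pred = optimal_combined(
            CuePair(
                mu_s=row[("mu", "stereo")],
                kappa_s=row[("kappa", "stereo")],
                mu_p=row[("mu", "perspective")],
                kappa_p=row[("kappa", "perspective")],
            )
        )
        rows.append(
            {
                "slant": s,
                "distance_cm": d,
                "observed_kappa": row[("kappa", "combined")],
                "predicted_kappa": pred.kappa_c,
                "observed_mu": row[("mu", "combined")],
                "predicted_mu": pred.mu_c,
            }
        )
    comp = pd.DataFrame(rows)
    comp.to_csv(out / "integration.csv", index=False)
    stats = integration_comparison(
        comp["observed_kappa"].to_numpy(), comp["predicted_kappa"].to_numpy()
    )
    with open(out / "integration_summary.json", "w") as fh:
        json.dump(stats, fh, indent=2)
    return stats


def _stage_prior(cfg: RunConfig, out: Path, trials: pd.DataFrame, fits: pd.DataFrame) -> dict:
    """Estimate the tilt prior from the lowest-precision quartile of conditions."""
    cutoff = fits["kappa"].quantile(0.25)
    low = fits[fits["kappa"] <= cutoff]
    keys = set(map(tuple, low[["slant", "distance_cm", "cue"]].to_numpy()))
    mask = trials.apply(
        lambda r: (r["slant"], r["distance_cm"], r["cue"]) in keys, axis=1
    )
    table = choice_table_from_trials(trials[mask])
    boot = bootstrap_prior_ci(
        table, n_rep=cfg.bootstrap_reps, seed=cfg.seeds["bootstrap"]
    )
    result = {
        "kappa_quartile_cutoff": float(cutoff),
        "fit": boot["point"].to_dict(),
        "ci95": boot["ci"],
    }
    with open(out / "prior.json", "w") as fh:
        json.dump(result, fh, indent=2)
    _plot_prior(boot, out / "prior_polar.png")
    return result


def _plot_prior(boot: dict, path: Path) -> None:
    """Polar plot of the fitted prior with its bootstrap band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .prior_estimation import prior_density

    theta = np.linspace(0, 2 * np.pi, 361)
    fit = boot["point"].prior
    dens = prior_density(np.degrees(theta), fit)
    reps = boot["replicates"]
    band = np.array(
        [prior_density(np.degrees(theta), TiltPrior(*r)) for r in reps]
    )
    lo, hi = np.percentile(band, [2.5, 97.5], axis=0)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(theta, dens, color="k")
    ax.fill_between(theta, lo, hi, alpha=0.3)
    ax.set_title("Tilt prior (bootstrap 95% band)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stage_neurons(cfg: RunConfig, out: Path, fits: pd.DataFrame) -> pd.DataFrame:
    """Calibrate the population model to the fits and compare architectures."""
    model = cfg.build_model()
    grid = cfg.build_grid()
    cip = synthetic_cip_table(
        slants=grid.slants, distances=(37.0, 57.0, 97.0, 137.0),
        seed=cfg.seeds["cip"],
    )
    full = interpolate_cip_table(cip, grid.distances)
    rows = []
    for _, r in full.iterrows():
        pose = SurfacePose(180.0, r["slant"], r["distance_cm"])
        rows.append(
            {
                **r,
                "t_comb": kappa_landscape(pose, "combined", model),
                "t_s": kappa_landscape(pose, "stereo", model),
                "t_p": kappa_landscape(pose, "perspective", model),
            }
        )
    df = pd.DataFrame(rows)
    unit = np.array(
        [
            expected_decoded_precision(a, k, lam=1.0)
            for a, k in zip(df["amplitude"], df["kappa_sd"])
        ]
    )
    cal = fit_lambda(df["kappa_sd"].to_numpy(), df["t_comb"].to_numpy(), unit)
    with open(out / "lambda_calibration.json", "w") as fh:
        json.dump(cal.to_dict(), fh, indent=2)
    keep = (df["t_s"] >= 1.0) & (df["t_p"] >= 1.0)
    conds = df[keep].rename(columns={"t_s": "target_s", "t_p": "target_p"})
    res = architecture_experiment(
        conds[["kappa_sd", "target_s", "target_p"]],
        cal,
        n_trials=cfg.architecture_trials,
        seed=cfg.seeds["architecture"],
    )
    res = pd.concat(
        [conds[["slant", "distance_cm"]].reset_index(drop=True), res], axis=1
    )
    res.to_csv(out / "architectures.csv", index=False)
    return res


def run_pipeline(
    cfg: RunConfig, stages: Optional[Sequence[str]] = None, trials_csv=None
) -> dict:
    """Run the requested stages (default: all) and write a seed manifest.

    ``stages`` is an ordered subset of {"simulate", "fit", "integrate",
    "prior", "neurons"}; later stages load earlier artifacts from the
    output directory when not run in the same invocation (e.g. fitting a
    user-provided trial CSV via `trials_csv`).
    """
    cfg.validate()
    all_stages = ["simulate", "fit", "integrate", "prior", "neurons"]
    stages = list(stages or all_stages)
    unknown = set(stages) - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "stages": stages,
        "timing_s": {},
    }
    trials = fits = None
    if trials_csv is not None:
        trials = pd.read_csv(trials_csv)
    for stage in all_stages:
        if stage not in stages:
            continue
        t0 = time.monotonic()
        log.info("stage %s started", stage)
        if stage == "simulate":
            trials = _stage_simulate(cfg, out)
        elif stage == "fit":
            if trials is None:
                trials = pd.read_csv(out / "trials.csv")
            fits = _stage_fit(cfg, out, trials)
        elif stage == "integrate":
            if fits is None:
                fits = pd.read_csv(out / "fits.csv")
            manifest["integration"] = _stage_integrate(cfg, out, fits)
        elif stage == "prior":
            if trials is None:
                trials = pd.read_csv(out / "trials.csv")
            if fits is None:
                fits = pd.read_csv(out / "fits.csv")
            manifest["prior"] = _stage_prior(cfg, out, trials, fits)
        elif stage == "neurons":
            if fits is None:
                fits = pd.read_csv(out / "fits.csv")
            _stage_neurons(cfg, out, fits)
        manifest["timing_s"][stage] = round(time.monotonic() - t0, 3)
        log.info("stage %s finished in %.2fs", stage, manifest["timing_s"][stage])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _load_config(config_path: Optional[str]) -> RunConfig:
    if config_path is None:
        cfg = RunConfig()
        cfg.validate()
        return cfg
    return RunConfig.from_yaml(config_path)


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Enable info-level logging.")
def cli(verbose: bool) -> None:
    """Tilt-perception analysis pipeline."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _stage_command(name: str, help_text: str):
    @cli.command(name=name, help=help_text)
    @click.option("--config", "config_path", type=click.Path(exists=True), default=None)
    @click.option("--out", "output_dir", default=None, help="Output directory override.")
    @click.option(
        "--trials", "trials_csv", type=click.Path(exists=True), default=None,
        help="Run on an existing trial-table CSV instead of simulating.",
    )
    def _cmd(config_path, output_dir, trials_csv):
        cfg = _load_config(config_path)
        if output_dir:
            cfg.output_dir = output_dir
        stages = None if name == "all" else [name]
        run_pipeline(cfg, stages=stages, trials_csv=trials_csv)

    return _cmd


_stage_command("simulate", "Generate a synthetic 8AFC session.")
_stage_command("fit", "Fit per-condition tilt-error distributions.")
_stage_command("integrate", "Compare observed and optimal combined-cue precision.")
_stage_command("prior", "Estimate the cardinal tilt prior with a bootstrap CI.")
_stage_command("neurons", "Run the population-code architecture comparison.")
_stage_command("all", "Run the full pipeline.")


if __name__ == "__main__":  # pragma: no cover
    cli()
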