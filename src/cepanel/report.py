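"""Run orchestration and result assembly.

Glues the estimation strategies together: one dataset in, one summary
table out, with a row per method (observed, bootstrapped, adjusted,
predictive) in the layout of a standard cost-effectiveness results
table.  Group differences are always low - high.  All randomness derives
from a single master seed via named substreams, so a rerun with an
identical configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .imputation import ImputationSettings, single_impute_for_bootstrap
from .margins import adjusted_ce, bootstrap_adjusted
from .outcomes import CEEstimate, bootstrap_unadjusted, ce_summary
from .panel import PanelDataset, build_design, dichotomize_group, read_panel
from .simulate import ScenarioConfig, default_scenario, simulate_scenario
from .twopart import MCMCSettings, bayes_margins, sample_posterior

__all__ = ["RunConfig", "run", "ce_plane_export", "summary_table",
           "derive_rng"]


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    input_path: str | None = None          # CSV; None -> synthetic scenario
    scenario: ScenarioConfig | None = None
    methods: tuple = ("observed", "bootstrapped", "adjusted", "predictive")
    confounders: list = field(default_factory=lambda: [
        "gender", "diagnosis", "iip", "soc", "sas"])
    categorical: list = field(default_factory=lambda: ["gender", "diagnosis"])
    group_threshold: float = 4.0
    bootstrap_B: int = 500
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    imputation: ImputationSettings = field(default_factory=ImputationSettings)
    seed: int = 0
    out_dir: str | None = None

    def digest(self) -> str:
        blob = json.dumps(_plain(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _plain(o):
    if isinstance(o, dict):
        return {k: _plain(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_plain(v) for v in o]
    if isinstance(o, np.generic):
        return o.item()
    return o


def derive_rng(master_seed: int, stream: str) -> np.random.Generator:
    """Named substream of the master seed (documented derivation)."""
    h = hashlib.sha256(f"{master_seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big"))


def summary_table(estimates: list[CEEstimate]) -> pd.DataFrame:
    """One row per method: means, differences (low - high), ICER, spread."""
    rows = []
    for e in estimates:
        rows.append({
            "method": e.method,
            "cost_low": e.mean_cost["low"],
            "cost_high": e.mean_cost["high"],
            "delta_cost": e.delta_cost,
            "eff_low": e.mean_eff["low"],
            "eff_high": e.mean_eff["high"],
            "delta_eff": e.delta_eff,
            "icer": np.nan if e.icer_undefined else e.icer,
            "icer_undefined": e.icer_undefined,
            "se_delta_cost": e.se.get("delta_cost", np.nan),
            "se_delta_eff": e.se.get("delta_eff", np.nan),
            "ci_delta_cost_lo": e.ci.get("delta_cost", (np.nan, np.nan))[0],
            "ci_delta_cost_hi": e.ci.get("delta_cost", (np.nan, np.nan))[1],
            "ci_delta_eff_lo": e.ci.get("delta_eff", (np.nan, np.nan))[0],
            "ci_delta_eff_hi": e.ci.get("delta_eff", (np.nan, np.nan))[1],
            "p_delta_cost": e.p_value.get("delta_cost", np.nan),
            "p_delta_eff": e.p_value.get("delta_eff", np.nan),
        })
    return pd.DataFrame(rows)


def _complete_group_subset(ds: PanelDataset) -> PanelDataset:
    keep = ~np.isnan(ds.group)
    return ds if keep.all() else ds.subset(np.flatnonzero(keep))


def run(config: RunConfig) -> dict:
    """Execute the requested methods on one dataset.

    Returns a bundle: ``table`` (summary DataFrame), ``estimates``
    (method -> CEEstimate), ``provenance`` and, when the Bayesian method
    ran, ``draws``.  If ``out_dir`` is set, the table, a provenance
    header and the CE-plane exports are written there as CSV/JSON;
    partial results of completed stages are still written if a later
    stage fails.
    """
    if config.input_path is not None:
        ds = read_panel(config.input_path,
                        {"categorical": config.categorical})
        ds = dichotomize_group(ds, config.group_threshold)
    else:
        scen = config.scenario or default_scenario()
        sim = simulate_scenario(scen, derive_rng(config.seed, "simulate"))
        ds = sim.data

    imp_settings = config.imputation

    def impute_hook(d, rng):
        return single_impute_for_bootstrap(d, imp_settings, rng)

    estimates: dict[str, CEEstimate] = {}
    bundle: dict = {"estimates": estimates}
    failure: Exception | None = None
    failed_stage = None
    try:
        obs_ds = _complete_group_subset(ds)
        if "observed" in config.methods:
            estimates["observed"] = ce_summary(_complete_cases(obs_ds))
        if "bootstrapped" in config.methods:
            estimates["bootstrapped"] = bootstrap_unadjusted(
                obs_ds, B=config.bootstrap_B,
                rng=derive_rng(config.seed, "bootstrap-unadjusted"),
                impute=impute_hook)
        if "adjusted" in config.methods:
            est = bootstrap_adjusted(
                _complete_covariates(obs_ds, config.confounders),
                config.confounders, B=config.bootstrap_B,
                rng=derive_rng(config.seed, "bootstrap-adjusted"),
                impute=impute_hook, categorical=config.categorical)
            estimates["adjusted"] = est
        if "predictive" in config.methods:
            design = build_design(ds, config.confounders,
                                  categorical=config.categorical)
            draws = sample_posterior(
                ds, design, mcmc=config.mcmc,
                rng=derive_rng(config.seed, "mcmc"))
            bundle["draws"] = draws
            estimates["predictive"] = bayes_margins(
                draws, design, ds,
                rng=derive_rng(config.seed, "predictive"))
    except Exception as err:                      # noqa: BLE001
        failed_stage = _next_stage(config.methods, estimates)
        failure = err

    order = [m for m in ("observed", "bootstrapped", "adjusted", "predictive")
             if m in estimates]
    bundle["table"] = summary_table([estimates[m] for m in order])
    bundle["provenance"] = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "direction": "differences are low - high",
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["table"].to_csv(out / "summary.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(bundle["provenance"], indent=2))
    if failure is not None:
        raise RuntimeError(f"stage {failed_stage!r} failed: {failure}"
                           ) from failure
    return bundle


def _next_stage(methods, estimates):
    for m in ("observed", "bootstrapped", "adjusted", "predictive"):
        if m in methods and m not in estimates:
            return m
    return "unknown"


def _complete_cases(ds: PanelDataset) -> PanelDataset:
    """Patients with fully observed outcomes (for the observed row)."""
    ok = (~np.isnan(ds.effectiveness).any(axis=1)
          & ~np.isnan(ds.interval_costs).any(axis=1))
    if ok.all():
        return ds
    return ds.subset(np.flatnonzero(ok))


def _complete_covariates(ds: PanelDataset, confounders) -> PanelDataset:
    cols = [c for c in confounders if c in ds.covariates.columns]
    ok = ~ds.covariates[cols].isna().any(axis=1).to_numpy()
    if ok.all():
        return ds
    return ds.subset(np.flatnonzero(ok))


def ce_plane_export(delta_eff: np.ndarray, delta_cost: np.ndarray,
                    path=None) -> pd.DataFrame:
    """Cost-effectiveness plane point cloud with quadrant fractions.

    Takes replicate or posterior-draw (delta effectiveness, delta cost)
    pairs (low - high).  Quadrant fractions are attached as attrs.  When
    effectiveness is harm-scaled (larger = worse symptoms) the usual
    quadrant interpretation is reversed with respect to the vertical
    axis; the export notes this.
    """
    de = np.asarray(delta_eff, float)
    dc = np.asarray(delta_cost, float)
    if de.size == 0 or de.shape != dc.shape:
        raise ValueError("need at least one (delta_eff, delta_cost) pair")
    df = pd.DataFrame({"delta_eff": de, "delta_cost": dc})
    quad = {
        "eff>0,cost>0": float(np.mean((de > 0) & (dc > 0))),
        "eff<0,cost>0": float(np.mean((de < 0) & (dc > 0))),
        "eff<0,cost<0": float(np.mean((de < 0) & (dc < 0))),
        "eff>0,cost<0": float(np.mean((de > 0) & (dc < 0))),
    }
    df.attrs["quadrants"] = quad
    df.attrs["note"] = ("for a harm-scaled effectiveness outcome the usual "
                        "quadrant interpretation is reversed about the "
                        "vertical axis")
    if path is not None:
        df.to_csv(path, index=False)
    return df
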