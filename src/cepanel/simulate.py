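"""Synthetic panel generator mirroring the study's generative structure.

A scenario draws baseline confounders from configurable marginals,
assigns the binary group through a logistic mechanism in the (partially
standardized) confounders — so group and confounders are dependent and
any group contrast is confounded by construction — and then generates
outcomes from the hierarchical two-part model itself: logistic zero/
positive cost indicator, gamma positive costs with group-and-interval
specific dispersion, and a linear effectiveness trajectory with
correlated patient-level random intercept/slope plus a cost random
effect.  Missingness is superimposed afterwards (MCAR, or MAR driven by
the always-observed baseline covariates so ignorability holds by
construction), and the complete data are kept alongside as ground truth
for recovery experiments.

The default scenario emulates a one-year psychotherapy panel: n = 200
patients, five measurement points at months 0/3/7/9/12, near-zero
prevalence of zero cost in the first two intervals and roughly 35-40%
afterwards, positive-cost dispersion descending from about 12 to about 2
over the intervals, cumulative mean costs around 1,900 euros, declining
symptom scores, and a true random-effect correlation of 0.5 between the
effectiveness level and the cost level.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .panel import PanelDataset, build_design, dichotomize_group
from .twopart import TwoPartParams

__all__ = [
    "ScenarioConfig", "SimulatedPanel", "generate_covariates",
    "generate_outcomes", "apply_missingness", "simulate_scenario",
    "default_scenario", "null_effect_scenario", "spe_scenario",
    "spe_misspecified_scenario",
]


@dataclass
class ScenarioConfig:
    """Everything needed to generate one synthetic study."""

    n: int
    nominal_times: list            # K months, first 0
    confounders: dict              # name -> ("normal", m, s) | ("bernoulli", p)
                                   #         | ("categorical", {level: prob})
    assignment: dict               # standardized logistic coefs + "intercept"
    group_score_threshold: float
    group_score_spread: float      # |score - threshold| scale
    beta_z: dict                   # coefficient maps, design-column names
    beta_p: dict
    beta_e: dict
    tau: list                      # (2, K-1) nested lists [low, high]
    sigma2_e: list
    sigma_u: list                  # (3, 3)
    confounder_columns: list       # design confounder order
    categorical: list
    missing: dict = field(default_factory=dict)
    clamp_effectiveness: bool = False
    baseline_eff_column: str = "baseline_gsi"
    #: lognormal shape of the effectiveness noise at the last two
    #: measurement points (0 = normal noise; >0 injects right skew while
    #: keeping the configured mean and variance) — a controlled
    #: misspecification for predictive-error experiments
    eff_noise_skew: float = 0.0

    @property
    def K(self) -> int:
        return len(self.nominal_times)

    def validate(self) -> None:
        t = np.asarray(self.nominal_times, float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("nominal_times must increase from 0")
        tau = np.asarray(self.tau, float)
        s2 = np.asarray(self.sigma2_e, float)
        if tau.shape != (2, self.K - 1) or np.any(tau <= 0):
            raise ValueError("tau must be positive with shape (2, K-1)")
        if s2.shape != (2, self.K - 1) or np.any(s2 <= 0):
            raise ValueError("sigma2_e must be positive with shape (2, K-1)")
        su = np.asarray(self.sigma_u, float)
        if not np.allclose(su, su.T) or np.any(
                np.linalg.eigvalsh(su) < -1e-10):
            raise ValueError(
                "sigma_u must be symmetric positive semidefinite")
        def _flat(o):
            if isinstance(o, dict):
                for v in o.values():
                    yield from _flat(v)
            elif isinstance(o, (list, tuple, np.ndarray)):
                for v in o:
                    yield from _flat(v)
            else:
                yield float(o)

        for v in _flat(self.missing.get("rates", {})):
            if not 0 <= v <= 1:
                raise ValueError("missingness rates must be in [0, 1]")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("confounders", "assignment"):
            d[key] = {k: (tuple(v) if isinstance(v, (list, tuple)) else v)
                      for k, v in d[key].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        def _plain(o):
            if isinstance(o, dict):
                return {k: _plain(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_plain(v) for v in o]
            if isinstance(o, np.generic):
                return o.item()
            return o
        with open(path, "w") as fh:
            # keep insertion order: generation consumes the RNG in
            # confounder-dict order, so order is part of the scenario
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def true_params(self, cols_z: list[str], cols_e: list[str]
                    ) -> TwoPartParams:
        return TwoPartParams.from_dicts(
            self.beta_z, self.beta_p, self.beta_e, cols_z, cols_e,
            tau=np.asarray(self.tau, float),
            sigma2_e=np.asarray(self.sigma2_e, float),
            sigma_u=np.asarray(self.sigma_u, float))


@dataclass
class SimulatedPanel:
    """Generated study: observed data plus the complete-data ground truth."""

    data: PanelDataset             # with missingness applied
    complete: PanelDataset         # no missing values
    config: ScenarioConfig
    params: TwoPartParams          # the generating parameter values


# ---------------------------------------------------------------------------
# Covariates and group assignment
# ---------------------------------------------------------------------------

def generate_covariates(cfg: ScenarioConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Baseline confounders, group score and binary group for n patients.

    Continuous/binary confounders are drawn from the configured marginals;
    the group is assigned by a logistic model in the standardized
    continuous (and raw binary) confounders, and a continuous group score
    consistent with the assignment is synthesized around the threshold.
    """
    cfg.validate()
    n = cfg.n
    cols = {}
    for name, spec in cfg.confounders.items():
        kind = spec[0]
        if kind == "normal":
            cols[name] = rng.normal(spec[1], spec[2], n)
        elif kind == "bernoulli":
            cols[name] = (rng.random(n) < spec[1]).astype(float)
        elif kind == "categorical":
            levels = list(spec[1])
            probs = np.array([spec[1][lv] for lv in levels], float)
            cols[name] = rng.choice(levels, size=n, p=probs / probs.sum())
        else:
            raise ValueError(f"unknown confounder kind {kind!r}")
    df = pd.DataFrame(cols)

    logit = np.full(n, float(cfg.assignment.get("intercept", 0.0)))
    for name, coef in cfg.assignment.items():
        if name == "intercept" or coef == 0:
            continue
        spec = cfg.confounders[name]
        x = df[name].to_numpy(float)
        if spec[0] == "normal":
            x = (x - spec[1]) / spec[2]
        logit += coef * x
    group = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(float)

    thr, spread = cfg.group_score_threshold, cfg.group_score_spread
    offset = 0.05 + np.abs(rng.normal(0.0, spread, n))
    score = np.where(group == 1.0, thr + offset, thr - offset)
    df["group"] = group
    df["group_score"] = np.clip(score, 0.5, 9.0)
    return df


# ---------------------------------------------------------------------------
# Outcome generation
# ---------------------------------------------------------------------------

def generate_outcomes(covariates: pd.DataFrame, cfg: ScenarioConfig,
                      rng: np.random.Generator) -> PanelDataset:
    """Complete panel dataset drawn from the two-part hierarchical model."""
    cfg.validate()
    n = len(covariates)
    times = np.asarray(cfg.nominal_times, float)
    K = len(times)
    nmp = K - 1

    base_eff = covariates[cfg.baseline_eff_column].to_numpy(float)
    eff = np.full((n, K), np.nan)
    eff[:, 0] = np.maximum(base_eff, 0.0)
    ds = PanelDataset(
        patient_ids=np.arange(1, n + 1),
        nominal_times=times,
        effectiveness=eff,
        interval_costs=np.full((n, nmp), np.nan),
        group_score=covariates["group_score"].to_numpy(float),
        group=covariates["group"].to_numpy(float),
        covariates=covariates.drop(columns=["group", "group_score"]),
        strict=cfg.clamp_effectiveness,
    )
    design = build_design(ds, cfg.confounder_columns,
                          categorical=cfg.categorical)
    params = cfg.true_params(design.cols_z, design.cols_e)
    params.validate(allow_semidefinite=True)

    # random effects via eigen square root (Sigma_U may be singular)
    su = np.asarray(cfg.sigma_u, float)
    ev, V = np.linalg.eigh(su)
    u = rng.standard_normal((n, 3)) @ (V * np.sqrt(np.maximum(ev, 0))).T

    g = ds.group.astype(int)
    gk = g[:, None] * nmp + np.arange(nmp)[None, :]
    tau = params.tau.ravel()[gk]
    sig2 = params.sigma2_e.ravel()[gk]

    eta_z = design.z @ params.beta_z
    pz = 1.0 / (1.0 + np.exp(-eta_z))
    Z = (rng.random((n, nmp)) < pz).astype(float)
    m = np.exp(design.p @ params.beta_p + u[:, 2][:, None])
    P = rng.gamma(np.maximum(m * tau, 1e-12)) / tau
    ds.interval_costs = Z * P

    mu = design.e @ params.beta_e + u[:, 0][:, None] \
        + u[:, 1][:, None] * times[1:][None, :]
    eps = rng.standard_normal((n, nmp))
    if cfg.eff_noise_skew > 0:
        s = cfg.eff_noise_skew
        z = rng.standard_normal((n, 2))
        skewed = (np.exp(s * z) - np.exp(s * s / 2)) \
            / np.sqrt((np.exp(s * s) - 1) * np.exp(s * s))
        eps[:, -2:] = skewed
    E = mu + np.sqrt(sig2) * eps
    if cfg.clamp_effectiveness:
        E = np.maximum(E, 0.0)
    ds.effectiveness[:, 1:] = E
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def _missing_mask(rate, driver_z, coef, n, rng):
    """Bernoulli mask at marginal ~rate; MAR tilts the logit by coef*z."""
    if rate <= 0:
        return np.zeros(n, bool)
    if rate >= 1:
        return np.ones(n, bool)
    logit = np.log(rate / (1 - rate)) + coef * driver_z
    return rng.random(n) < 1.0 / (1.0 + np.exp(-logit))


def apply_missingness(ds: PanelDataset, cfg: ScenarioConfig,
                      rng: np.random.Generator) -> PanelDataset:
    """Superimpose the configured missingness on a complete dataset.

    ``cfg.missing`` blocks: ``mechanism`` ("MCAR" | "MAR"), ``driver``
    (baseline covariate column for MAR), ``coef`` (logit tilt per driver
    SD) and ``rates`` with per-variable entries: ``effectiveness`` (K,),
    ``cost`` (K-1,), ``group_score`` scalar, ``covariates`` {col: rate}.
    """
    cfg.validate()
    spec = cfg.missing
    if not spec:
        return ds.copy()
    out = ds.copy()
    n = ds.n
    mech = spec.get("mechanism", "MCAR")
    coef = float(spec.get("coef", 0.0)) if mech == "MAR" else 0.0
    if mech == "MAR":
        drv = ds.covariates[spec.get("driver",
                                     cfg.baseline_eff_column)].to_numpy(float)
        z = (drv - drv.mean()) / max(drv.std(), 1e-12)
    else:
        z = np.zeros(n)
    rates = spec.get("rates", {})
    for k, r in enumerate(np.asarray(rates.get("effectiveness",
                                               np.zeros(ds.K)), float)):
        out.effectiveness[_missing_mask(r, z, coef, n, rng), k] = np.nan
    for k, r in enumerate(np.asarray(rates.get("cost",
                                               np.zeros(ds.K - 1)), float)):
        out.interval_costs[_missing_mask(r, z, coef, n, rng), k] = np.nan
    r = float(rates.get("group_score", 0.0))
    gm = _missing_mask(r, z, coef, n, rng)
    out.group_score[gm] = np.nan
    out.group[gm] = np.nan
    for col, r in rates.get("covariates", {}).items():
        mask = _missing_mask(float(r), z, coef, n, rng)
        vals = out.covariates[col].astype(float).to_numpy()
        vals[mask] = np.nan
        out.covariates[col] = vals
    return out


def simulate_scenario(cfg: ScenarioConfig,
                      rng: np.random.Generator | int | None = None
                      ) -> SimulatedPanel:
    """Full pipeline: covariates -> outcomes -> missingness, with truth."""
    rng = np.random.default_rng(rng)
    cov = generate_covariates(cfg, rng)
    complete = generate_outcomes(cov, cfg, rng)
    complete = dichotomize_group(complete, cfg.group_score_threshold)
    data = apply_missingness(complete, cfg, rng)
    design = build_design(complete, cfg.confounder_columns,
                          categorical=cfg.categorical)
    return SimulatedPanel(data=data, complete=complete, config=cfg,
                          params=cfg.true_params(design.cols_z,
                                                 design.cols_e))


# ---------------------------------------------------------------------------
# Stock scenarios
# ---------------------------------------------------------------------------

def default_scenario(n: int = 200) -> ScenarioConfig:
    """The reference one-year psychotherapy-like panel (see module docs)."""
    return ScenarioConfig(
        n=n,
        nominal_times=[0.0, 3.0, 7.0, 9.0, 12.0],
        confounders={
            "baseline_gsi": ("normal", 1.27, 0.52),
            "gender": ("categorical", {"woman": 0.74, "man": 0.26}),
            "diagnosis": ("categorical",
                          {"mood": 0.51, "anxiety": 0.18, "comorbid": 0.31}),
            "iip": ("normal", 8.86, 3.1),
            "soc": ("normal", 11.25, 2.0),
            "sas": ("normal", 2.16, 0.56),
        },
        assignment={"intercept": 0.0, "baseline_gsi": 1.1, "iip": 0.55,
                    "soc": -0.6, "sas": 0.4},
        group_score_threshold=4.0,
        group_score_spread=0.6,
        beta_z={"intercept": 4.3, "gender[man]": 0.1, "iip": 0.02,
                "soc": -0.02, "sas": 0.1, "mp3": -0.1, "mp4": -4.0,
                "mp5": -4.0, "group": 0.15},
        beta_p={"intercept": 6.46, "gender[man]": 0.05, "iip": 0.01,
                "soc": -0.01, "sas": 0.05, "mp3": -0.05, "mp4": -0.84,
                "mp5": -0.85, "group": 0.08},
        beta_e={"intercept": 0.12, "gender[man]": 0.02,
                "diagnosis[anxiety]": -0.05, "diagnosis[comorbid]": 0.06,
                "iip": 0.012, "soc": -0.02, "sas": 0.08,
                "baseline_eff": 0.65, "mp3": -0.13, "mp4": -0.19,
                "mp5": -0.20, "group": 0.05},
        tau=[[12.0, 6.0, 4.0, 2.0], [8.0, 4.5, 3.5, 2.0]],
        sigma2_e=[[0.10, 0.09, 0.07, 0.10], [0.13, 0.12, 0.09, 0.17]],
        sigma_u=[[0.15, -0.00155, 0.075],
                 [-0.00155, 0.0004, 0.0],
                 [0.075, 0.0, 0.15]],
        confounder_columns=["gender", "diagnosis", "iip", "soc", "sas"],
        categorical=["gender", "diagnosis"],
        missing={
            "mechanism": "MAR",
            "driver": "baseline_gsi",
            "coef": 0.5,
            "rates": {
                "effectiveness": [0.01, 0.09, 0.17, 0.17, 0.18],
                "cost": [0.12, 0.12, 0.145, 0.15],
                "group_score": 0.025,
                "covariates": {"iip": 0.01, "soc": 0.01, "sas": 0.01},
            },
        },
    )


def null_effect_scenario(n: int = 200, missing: bool = False
                         ) -> ScenarioConfig:
    """Confounded scenario with a true null group effect in every model.

    The group still depends on the confounders (so unadjusted contrasts
    are biased), but the group coefficient is zero in the zero-cost,
    positive-cost and effectiveness models: the adjusted contrasts'
    estimand is exactly zero.
    """
    cfg = default_scenario(n)
    for b in (cfg.beta_z, cfg.beta_p, cfg.beta_e):
        b["group"] = 0.0
    if not missing:
        cfg.missing = {}
    return cfg


def spe_scenario(n: int = 400) -> ScenarioConfig:
    """Well-specified scenario for predictive-error calibration.

    Random-effect variances are kept small relative to the residual
    variance: the standardized predictive error divides by the residual
    SD only, so its cross-subject spread approaches N(0, 1) only when the
    random effects contribute little — the regime in which the
    calibration of the Q-Q check is meaningful.
    """
    cfg = default_scenario(n)
    cfg.sigma_u = [[0.012, 0.0, 0.01],
                   [0.0, 5e-5, 0.0],
                   [0.01, 0.0, 0.12]]
    cfg.sigma2_e = [[0.16, 0.15, 0.15, 0.16], [0.18, 0.17, 0.16, 0.18]]
    cfg.missing = {}
    return cfg


def spe_misspecified_scenario(n: int = 400, skew: float = 1.8
                              ) -> ScenarioConfig:
    """The calibration scenario with right-skewed noise at late MPs.

    The fitted model still assumes normal residuals, so holdout
    standardized predictive errors should depart from N(0, 1) in the
    upper tail at the last two measurement points.
    """
    cfg = spe_scenario(n)
    cfg.eff_noise_skew = skew
    return cfg
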