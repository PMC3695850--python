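"""Hierarchical Bayesian two-part model for panel cost-effectiveness data.

The model factors each interval cost into a zero/positive indicator and a
positive magnitude, and models the repeated effectiveness score with a
random linear trend:

* ``Z_ik ~ Bernoulli(logit^-1(X_ik b_z))`` — any cost incurred in
  interval k;
* ``P_ik ~ Gamma(shape = exp(X_ik b_p + U_i3) * tau_gk, rate = tau_gk)``
  — the positive cost, so its conditional mean is ``exp(X b_p + U_i3)``
  and its conditional variance is mean / tau (tau is the inverse
  variance-to-mean ratio, free per group x interval to capture
  heteroscedasticity);
* ``E_ik ~ N(X_ik b_e + U_i1 + U_i2 * t_k, sigma2_gk)`` — the symptom
  score at month ``t_k``, with a patient-level random intercept and slope.

The three random effects ``U_i = (U_i1, U_i2, U_i3)`` share a covariance
matrix ``Sigma_U``; its correlations measure the association between
costs and effectiveness left unexplained by the covariates.  Priors:
coefficients N(0, 100) (variance convention, configurable to the
precision convention), sigma2 ~ InverseGamma(3, 1), tau ~ Gamma(3, 1),
Sigma_U ~ InverseWishart_10(I_3).  Missing outcomes, missing continuous
baseline covariates (modelled N(mu_j, 1/tau_j) with weak hyperpriors) and
missing group indicators (Bernoulli(p) with a uniform hyperprior) are
augmented as extra unknowns during sampling.

Posterior sampling is Metropolis-within-Gibbs: conjugate updates for
``b_e``, ``sigma2``, ``Sigma_U``, ``(U_i1, U_i2)`` and the hyperparameters,
adaptive random-walk Metropolis for ``b_z``, ``b_p``, ``tau`` and ``U_i3``,
and exact conditional draws for every augmented quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .outcomes import auc as _auc
from .outcomes import icer as _icer
from .outcomes import CEEstimate
from .panel import DesignMatrices, PanelDataset

__all__ = [
    "TwoPartParams", "Priors", "MCMCSettings", "PosteriorDraws",
    "log_joint", "sample_posterior", "predictive_outcomes", "bayes_margins",
    "random_effect_summary",
]


# ---------------------------------------------------------------------------
# Parameters and priors
# ---------------------------------------------------------------------------

@dataclass
class TwoPartParams:
    """All parameters of the hierarchical two-part model."""

    beta_z: np.ndarray          # logistic coefficients (log-odds)
    beta_p: np.ndarray          # gamma log-scale coefficients
    beta_e: np.ndarray          # effectiveness coefficients (score units)
    cols_z: list[str]           # shared by the two cost parts
    cols_e: list[str]
    tau: np.ndarray             # (2, K-1) positive-cost dispersion
    sigma2_e: np.ndarray        # (2, K-1) effectiveness residual variance
    sigma_u: np.ndarray         # (3, 3) random-effects covariance
    p_group: float | None = None
    cov_mu: dict = field(default_factory=dict)    # covariate-model means
    cov_tau: dict = field(default_factory=dict)   # covariate-model precisions

    def __post_init__(self):
        self.beta_z = np.asarray(self.beta_z, float)
        self.beta_p = np.asarray(self.beta_p, float)
        self.beta_e = np.asarray(self.beta_e, float)
        self.tau = np.asarray(self.tau, float)
        self.sigma2_e = np.asarray(self.sigma2_e, float)
        self.sigma_u = np.asarray(self.sigma_u, float)

    def validate(self, allow_semidefinite: bool = False) -> None:
        if np.any(self.tau <= 0):
            raise ValueError("tau must be positive")
        if np.any(self.sigma2_e <= 0):
            raise ValueError("sigma2_e must be positive")
        if not np.allclose(self.sigma_u, self.sigma_u.T):
            raise ValueError("Sigma_U must be symmetric")
        ev = np.linalg.eigvalsh(self.sigma_u)
        lo = -1e-10 if allow_semidefinite else 1e-12
        if np.any(ev < lo):
            raise ValueError("Sigma_U must be positive (semi)definite")

    def rho(self, i: int, j: int) -> float:
        s = self.sigma_u
        return float(s[i, j] / np.sqrt(s[i, i] * s[j, j]))

    @classmethod
    def from_dicts(cls, beta_z: dict, beta_p: dict, beta_e: dict,
                   cols_z: list[str], cols_e: list[str], **kw):
        """Build from name->value coefficient maps (missing names -> 0)."""
        bz = np.array([beta_z.get(c, 0.0) for c in cols_z])
        bp = np.array([beta_p.get(c, 0.0) for c in cols_z])
        be = np.array([beta_e.get(c, 0.0) for c in cols_e])
        return cls(beta_z=bz, beta_p=bp, beta_e=be,
                   cols_z=list(cols_z), cols_e=list(cols_e), **kw)


@dataclass
class Priors:
    """Prior specification.

    ``N(0, 100)`` for coefficients is read on the variance scale by
    default; set ``convention="precision"`` for the BUGS reading.
    """

    beta_param: float = 100.0
    cov_mu_param: float = 1000.0
    convention: str = "variance"          # or "precision"
    sigma2_shape: float = 3.0
    sigma2_rate: float = 1.0              # InverseGamma(3, 1)
    tau_shape: float = 3.0
    tau_rate: float = 1.0                 # Gamma(3, 1)
    wishart_df: float = 10.0
    wishart_scale: np.ndarray = field(default_factory=lambda: np.eye(3))
    cov_tau_shape: float = 2.0
    cov_tau_rate: float = 1.0

    @property
    def beta_var(self) -> float:
        return self.beta_param if self.convention == "variance" \
            else 1.0 / self.beta_param

    @property
    def cov_mu_var(self) -> float:
        return self.cov_mu_param if self.convention == "variance" \
            else 1.0 / self.cov_mu_param


@dataclass
class MCMCSettings:
    """Chain settings; defaults are a reduced run, ``paper_scale`` restores
    the reference configuration (2 chains, 60,000 kept iterations after
    10,000 burn-in, thinned by 15)."""

    chains: int = 2
    iterations: int = 4000     # post-burn-in iterations per chain
    burn_in: int = 1000
    thin: int = 1

    @classmethod
    def paper_scale(cls) -> "MCMCSettings":
        return cls(chains=2, iterations=60000, burn_in=10000, thin=15)

    @property
    def kept_per_chain(self) -> int:
        return self.iterations // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of parameters, random effects and augmented data."""

    beta_z: np.ndarray          # (S, p_z)
    beta_p: np.ndarray
    beta_e: np.ndarray          # (S, p_e)
    tau: np.ndarray             # (S, 2, K-1)
    sigma2_e: np.ndarray        # (S, 2, K-1)
    sigma_u: np.ndarray         # (S, 3, 3)
    p_group: np.ndarray         # (S,)
    u: np.ndarray               # (S, n, 3)
    chain: np.ndarray           # (S,) chain id
    iteration: np.ndarray       # (S,) post-burn-in iteration index
    cols_z: list[str]
    cols_e: list[str]
    times: np.ndarray           # (K-1,) months of post-baseline MPs
    aug_e: np.ndarray           # (S, #missing E cells)
    aug_z: np.ndarray           # (S, #missing C cells)
    aug_p: np.ndarray
    aug_group: np.ndarray       # (S, #missing group)
    aug_cov: dict               # col name -> (S, #missing) values
    miss_e_idx: np.ndarray      # (2, #missing E) patient, interval indices
    miss_c_idx: np.ndarray
    miss_g_idx: np.ndarray      # (#missing group,) patient indices
    miss_cov_idx: dict          # col name -> patient indices

    @property
    def S(self) -> int:
        return len(self.chain)

    def rho_draws(self, i: int, j: int) -> np.ndarray:
        s = self.sigma_u
        return s[:, i, j] / np.sqrt(s[:, i, i] * s[:, j, j])

    def scalar_params(self) -> dict:
        """Flatten to named scalar traces (for convergence diagnostics)."""
        out = {}
        for name, arr, cols in (("beta_z", self.beta_z, self.cols_z),
                                ("beta_p", self.beta_p, self.cols_z),
                                ("beta_e", self.beta_e, self.cols_e)):
            for j, c in enumerate(cols):
                out[f"{name}[{c}]"] = arr[:, j]
        for g in range(2):
            for k in range(self.tau.shape[2]):
                out[f"tau[{g},{k + 2}]"] = self.tau[:, g, k]
                out[f"sigma2_e[{g},{k + 2}]"] = self.sigma2_e[:, g, k]
        for i in range(3):
            for j in range(i, 3):
                out[f"sigma_u[{i + 1},{j + 1}]"] = self.sigma_u[:, i, j]
        return out


# ---------------------------------------------------------------------------
# Model data: flattened internal representation
# ---------------------------------------------------------------------------

class _ModelData:
    """Mutable sampler state for one dataset: current augmented values and
    the design matrices they live in."""

    def __init__(self, ds: PanelDataset, design: DesignMatrices):
        self.n = ds.n
        self.nmp = ds.K - 1
        self.t = design.times.astype(float)            # (nmp,)
        self.Xz = design.z.copy()
        self.Xp = design.p.copy()
        self.Xe = design.e.copy()
        self.cols_z = list(design.cols_z)
        self.cols_e = list(design.cols_e)
        self.gz = design.group_col("z")
        self.ge = design.group_col("e")

        E = ds.effectiveness[:, 1:]                    # outcomes: k = 2..K
        C = ds.interval_costs
        self.miss_e = np.isnan(E)
        self.miss_c = np.isnan(C)
        self.E = np.where(self.miss_e, 0.0, E)
        self.Z = np.where(self.miss_c, 0.0, (C > 0)).astype(float)
        self.P = np.where((C > 0) & ~self.miss_c, C, np.nan)

        self.miss_g = np.isnan(ds.group)
        self.g = np.where(self.miss_g, 0.0, ds.group)

        # continuous design columns with missing entries get augmented
        self.aug_cols: dict[str, dict] = {}
        for name in self.cols_z + self.cols_e:
            if name in ("intercept", "group") or name.startswith("mp") \
                    or name in self.aug_cols:
                continue
            jz = self.cols_z.index(name) if name in self.cols_z else None
            je = self.cols_e.index(name) if name in self.cols_e else None
            col = (self.Xz[:, 0, jz] if jz is not None
                   else self.Xe[:, 0, je])
            mis = np.isnan(col)
            if mis.any():
                self.aug_cols[name] = {
                    "jz": jz, "je": je, "idx": np.flatnonzero(mis),
                    "values": np.zeros(mis.sum()),
                }
        bad = [c for c in self.cols_z + self.cols_e
               if "[" in c and (np.isnan(self._col(c)).any())]
        if bad:
            raise ValueError(
                f"missing categorical covariate(s) {bad} cannot be augmented")

        self.u = np.zeros((self.n, 3))
        self._write_group()

    def _col(self, name):
        if name in self.cols_z:
            return self.Xz[:, 0, self.cols_z.index(name)]
        return self.Xe[:, 0, self.cols_e.index(name)]

    def _write_group(self):
        self.Xz[:, :, self.gz] = self.g[:, None]
        self.Xp[:, :, self.gz] = self.g[:, None]
        self.Xe[:, :, self.ge] = self.g[:, None]

    def set_group(self, idx, values):
        self.g[idx] = values
        self.Xz[idx, :, self.gz] = np.asarray(values)[:, None]
        self.Xp[idx, :, self.gz] = np.asarray(values)[:, None]
        self.Xe[idx, :, self.ge] = np.asarray(values)[:, None]

    def set_cov(self, name, values):
        info = self.aug_cols[name]
        info["values"] = np.asarray(values, float)
        idx = info["idx"]
        if info["jz"] is not None:
            self.Xz[idx, :, info["jz"]] = info["values"][:, None]
            self.Xp[idx, :, info["jz"]] = info["values"][:, None]
        if info["je"] is not None:
            self.Xe[idx, :, info["je"]] = info["values"][:, None]

    # linear predictors ---------------------------------------------------
    def eta_z(self, beta):
        return self.Xz @ beta

    def eta_p(self, beta):
        return self.Xp @ beta

    def eta_e(self, beta):
        return self.Xe @ beta

    def cell_gk(self):
        """(n, nmp) flat index into (group, interval) tables."""
        g = self.g.astype(int)
        return g[:, None] * self.nmp + np.arange(self.nmp)[None, :]


# ---------------------------------------------------------------------------
# Log joint density
# ---------------------------------------------------------------------------

def _gamma_cost_logpdf(P, mean, tau):
    """log Gamma(shape = mean * tau, rate = tau) density at P."""
    a = mean * tau
    return a * np.log(tau) - special.gammaln(a) + (a - 1) * np.log(P) - tau * P


def log_joint(params: TwoPartParams, md: _ModelData,
              priors: Priors | None = None) -> float:
    """Full log posterior density (likelihood x priors, all constants kept)
    at the given parameters and the augmented data currently held in ``md``.

    Returns ``-inf`` (never raises) when a constraint is violated, so the
    sampler can treat invalid proposals as rejections.
    """
    priors = priors or Priors()
    try:
        params.validate()
    except ValueError:
        return -np.inf

    gk = md.cell_gk()
    tau = params.tau.ravel()[gk]
    sig2 = params.sigma2_e.ravel()[gk]

    # two-part cost likelihood
    ez = md.eta_z(params.beta_z)
    lp = float(np.sum(md.Z * ez - np.logaddexp(0.0, ez)))
    pos = md.Z == 1.0
    if pos.any():
        mean = np.exp(md.eta_p(params.beta_p) + md.u[:, 2][:, None])
        lp += float(np.sum(_gamma_cost_logpdf(md.P[pos], mean[pos], tau[pos])))

    # effectiveness likelihood
    mu = md.eta_e(params.beta_e) + md.u[:, 0][:, None] \
        + md.u[:, 1][:, None] * md.t[None, :]
    lp += float(np.sum(-0.5 * np.log(2 * np.pi * sig2)
                       - 0.5 * (md.E - mu) ** 2 / sig2))

    # random effects
    lp += float(np.sum(stats.multivariate_normal.logpdf(
        md.u, mean=np.zeros(3), cov=params.sigma_u)))

    # priors
    bv = priors.beta_var
    for b in (params.beta_z, params.beta_p, params.beta_e):
        lp += float(np.sum(stats.norm.logpdf(b, 0.0, np.sqrt(bv))))
    lp += float(np.sum(stats.gamma.logpdf(
        params.tau, priors.tau_shape, scale=1.0 / priors.tau_rate)))
    lp += float(np.sum(stats.invgamma.logpdf(
        params.sigma2_e, priors.sigma2_shape, scale=priors.sigma2_rate)))
    lp += float(stats.invwishart.logpdf(
        params.sigma_u, priors.wishart_df, priors.wishart_scale))

    # missing-group model: Bernoulli(p) over all group indicators,
    # p ~ Uniform(0, 1); only active when any group value is augmented
    if md.miss_g.any():
        p = params.p_group
        if p is None or not (0 < p < 1):
            return -np.inf
        lp += float(np.sum(md.g * np.log(p) + (1 - md.g) * np.log1p(-p)))

    # covariate model for augmented continuous columns
    for name, info in md.aug_cols.items():
        mu_j = params.cov_mu.get(name)
        tau_j = params.cov_tau.get(name)
        if mu_j is None or tau_j is None or tau_j <= 0:
            return -np.inf
        col = md._col(name)
        lp += float(np.sum(stats.norm.logpdf(col, mu_j, 1 / np.sqrt(tau_j))))
        lp += float(stats.norm.logpdf(mu_j, 0.0, np.sqrt(priors.cov_mu_var)))
        lp += float(stats.gamma.logpdf(
            tau_j, priors.cov_tau_shape, scale=1.0 / priors.cov_tau_rate))
    return lp


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _chol2_solve_draw(A11, A12, A22, b1, b2, rng):
    """Vectorized draw from N(A^-1 b, A^-1) for 2x2 precision matrices."""
    L11 = np.sqrt(A11)
    L21 = A12 / L11
    L22 = np.sqrt(A22 - L21 ** 2)
    # solve L y = b
    y1 = b1 / L11
    y2 = (b2 - L21 * y1) / L22
    # solve L' m = y
    m2 = y2 / L22
    m1 = (y1 - L21 * m2) / L11
    # x = m + L'^-1 z  (back-substitution on the upper-triangular L')
    z1 = rng.standard_normal(len(np.atleast_1d(A11)))
    z2 = rng.standard_normal(len(np.atleast_1d(A11)))
    e2 = z2 / L22
    e1 = (z1 - L21 * e2) / L11
    return m1 + e1, m2 + e2


class _Sampler:
    def __init__(self, md: _ModelData, priors: Priors,
                 rng: np.random.Generator):
        self.md = md
        self.pr = priors
        self.rng = rng
        self.p = self._init_params()
        self._init_proposals()

    # -- initialization ---------------------------------------------------
    def _init_params(self) -> TwoPartParams:
        md, rng = self.md, self.rng
        # fill augmented data with simple starting values
        obs_e = np.where(md.miss_e, np.nan, md.E)
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(obs_e, axis=0)
            p_pos = np.nanmean(np.where(md.miss_c, np.nan, md.Z), axis=0)
            logmean = np.nanmean(np.where(md.P > 0, np.log(md.P), np.nan),
                                 axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        md.E[md.miss_e] = np.broadcast_to(col_mean, md.E.shape)[md.miss_e]
        p_pos = np.where(np.isnan(p_pos), 0.5, p_pos)
        zinit = (np.broadcast_to(p_pos, md.Z.shape) > 0.5).astype(float)
        md.Z[md.miss_c] = zinit[md.miss_c]
        logmean = np.where(np.isnan(logmean), 0.0, logmean)
        pinit = np.exp(np.broadcast_to(logmean, md.P.shape))
        need_p = md.miss_c | np.isnan(md.P)
        md.P[need_p] = pinit[need_p]
        for name, info in md.aug_cols.items():
            col = md._col(name)
            fill = np.nanmean(col)
            if np.isnan(fill):
                fill = 0.0
            md.set_cov(name, np.full(len(info["idx"]), fill))
        if md.miss_g.any():
            md.set_group(np.flatnonzero(md.miss_g),
                         np.full(md.miss_g.sum(),
                                 float(np.round(np.mean(md.g[~md.miss_g])))))

        beta_z = self._fit_logit()
        beta_p = self._fit_gamma()
        beta_e = self._fit_wls()
        params = TwoPartParams(
            beta_z=beta_z, beta_p=beta_p, beta_e=beta_e,
            cols_z=md.cols_z, cols_e=md.cols_e,
            tau=np.ones((2, md.nmp)), sigma2_e=np.ones((2, md.nmp)),
            sigma_u=np.eye(3),
            p_group=float(np.clip(np.mean(md.g), 0.05, 0.95)),
            cov_mu={c: float(np.mean(md._col(c))) for c in md.aug_cols},
            cov_tau={c: float(1.0 / max(np.var(md._col(c)), 1e-6))
                     for c in md.aug_cols},
        )
        lp = log_joint(params, md, self.pr)
        if not np.isfinite(lp):
            raise RuntimeError("non-finite log density at initialization")
        return params

    def _flat(self, X):
        return X.reshape(-1, X.shape[-1])

    def _fit_logit(self):
        md = self.md
        X = self._flat(md.Xz)
        y = md.Z.ravel()
        try:
            import statsmodels.api as sm
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=50)
            self._cov_z = np.asarray(fit.cov_params())
            beta = np.asarray(fit.params)
            if np.all(np.isfinite(beta)) and np.all(np.abs(beta) < 20):
                return beta
        except Exception:
            pass
        self._cov_z = None
        return np.zeros(X.shape[1])

    def _fit_gamma(self):
        md = self.md
        pos = md.Z.ravel() == 1.0
        X = self._flat(md.Xp)[pos]
        y = md.P.ravel()[pos]
        try:
            import statsmodels.api as sm
            fit = sm.GLM(y, X, family=sm.families.Gamma(
                sm.families.links.Log())).fit(maxiter=100)
            self._cov_p = np.asarray(fit.cov_params())
            beta = np.asarray(fit.params)
            if np.all(np.isfinite(beta)):
                return beta
        except Exception:
            pass
        self._cov_p = None
        return np.zeros(X.shape[1])

    def _fit_wls(self):
        md = self.md
        X = self._flat(md.Xe)
        y = md.E.ravel()
        XtX = X.T @ X + 1e-8 * np.eye(X.shape[1])
        return np.linalg.solve(XtX, X.T @ y)

    def _init_proposals(self):
        pz = len(self.p.beta_z)
        covz = self._cov_z if self._cov_z is not None else np.eye(pz) * 1e-2
        covp = self._cov_p if self._cov_p is not None else np.eye(pz) * 1e-2
        covz = covz + 1e-10 * np.eye(pz)
        covp = covp + 1e-10 * np.eye(pz)
        self._Lz = np.linalg.cholesky((2.4 ** 2 / pz) * covz)
        self._Lp = np.linalg.cholesky((2.4 ** 2 / pz) * covp)
        self._sc_z = 1.0
        self._sc_p = 1.0
        self._sc_tau = np.full((2, self.md.nmp), 0.3)
        self._sc_u3 = 0.5
        self._sc_cov = {c: max(np.std(self.md._col(c)), 0.1)
                        for c in self.md.aug_cols}
        self._const_cols_p = [j for j, c in enumerate(self.md.cols_z)
                              if not c.startswith("mp")]
        self._sc_shift = {j: 0.05 for j in self._const_cols_p}
        self._hist_z: list = []
        self._hist_p: list = []

    def refresh_proposals(self):
        """Mid-burn-in proposal refresh.

        beta_z: adaptive-Metropolis empirical covariance of the burn-in
        history (no random effect, so marginal = conditional shape).
        beta_p: conditional Fisher information (X' diag(m tau) X)^-1 at
        the current state — the block update conditions on U3 and the
        gamma part is far tighter than the marginal GLM covariance used
        at initialization.
        """
        if len(self._hist_z) >= 50:
            H = np.array(self._hist_z[-2000:])
            d = H.shape[1]
            cov = np.cov(H, rowvar=False) * (2.4 ** 2 / d) \
                + 1e-12 * np.eye(d)
            try:
                self._Lz = np.linalg.cholesky(cov)
                self._sc_z = 1.0
            except np.linalg.LinAlgError:
                pass
        self._hist_z.clear()
        self._hist_p.clear()
        md = self.md
        gk = md.cell_gk()
        w = (np.exp(md.eta_p(self.p.beta_p) + md.u[:, 2][:, None])
             * self.p.tau.ravel()[gk]) * (md.Z == 1.0)
        X = self._flat(md.Xp)
        info = (X * w.ravel()[:, None]).T @ X
        d = X.shape[1]
        info += np.eye(d) / self.pr.beta_var
        try:
            cov = np.linalg.inv(info) * (2.4 ** 2 / d)
            self._Lp = np.linalg.cholesky(cov)
            self._sc_p = 1.0
        except np.linalg.LinAlgError:
            pass

    # -- likelihood helpers ----------------------------------------------
    def _loglik_z(self, beta):
        ez = self.md.eta_z(beta)
        return np.sum(self.md.Z * ez - np.logaddexp(0.0, ez))

    def _loglik_p_cells(self, beta):
        """Per-cell gamma log-likelihood terms depending on beta_p / U3."""
        md = self.md
        gk = md.cell_gk()
        tau = self.p.tau.ravel()[gk]
        a = np.exp(md.eta_p(beta) + md.u[:, 2][:, None]) * tau
        pos = md.Z == 1.0
        out = np.zeros_like(a)
        out[pos] = (a[pos] * (np.log(tau[pos]) + np.log(md.P[pos]))
                    - special.gammaln(a[pos]))
        return out

    # -- individual updates ----------------------------------------------
    def update_beta_e(self):
        md, pr, rng = self.md, self.pr, self.rng
        gk = md.cell_gk()
        w = 1.0 / self.p.sigma2_e.ravel()[gk]
        r = md.E - md.u[:, 0][:, None] - md.u[:, 1][:, None] * md.t[None, :]
        X = self._flat(md.Xe)
        wf = w.ravel()
        A = (X * wf[:, None]).T @ X + np.eye(X.shape[1]) / pr.beta_var
        b = X.T @ (wf * r.ravel())
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        z = rng.standard_normal(len(b))
        self.p.beta_e = mean + np.linalg.solve(L.T, z)

    def update_u12(self):
        md, rng = self.md, self.rng
        gk = md.cell_gk()
        w = 1.0 / self.p.sigma2_e.ravel()[gk]          # (n, nmp)
        r = md.E - md.eta_e(self.p.beta_e)             # (n, nmp)
        t = md.t
        A11 = w.sum(axis=1)
        A12 = (w * t).sum(axis=1)
        A22 = (w * t ** 2).sum(axis=1)
        b1 = (w * r).sum(axis=1)
        b2 = (w * r * t).sum(axis=1)
        S = self.p.sigma_u
        Saa = S[:2, :2]
        Sab = S[:2, 2]
        V = Saa - np.outer(Sab, Sab) / S[2, 2]
        Vinv = np.linalg.inv(V)
        m = (Sab / S[2, 2])[None, :] * md.u[:, 2][:, None]   # (n, 2)
        P11 = A11 + Vinv[0, 0]
        P12 = A12 + Vinv[0, 1]
        P22 = A22 + Vinv[1, 1]
        c1 = b1 + Vinv[0, 0] * m[:, 0] + Vinv[0, 1] * m[:, 1]
        c2 = b2 + Vinv[0, 1] * m[:, 0] + Vinv[1, 1] * m[:, 1]
        u1, u2 = _chol2_solve_draw(P11, P12, P22, c1, c2, rng)
        md.u[:, 0] = u1
        md.u[:, 1] = u2

    def update_u3(self, adapt=False):
        md, rng = self.md, self.rng
        S = self.p.sigma_u
        Saa_inv = np.linalg.inv(S[:2, :2])
        w = S[:2, 2] @ Saa_inv
        m3 = md.u[:, :2] @ w
        v3 = S[2, 2] - w @ S[:2, 2]
        gk = md.cell_gk()
        tau = self.p.tau.ravel()[gk]
        pos = md.Z == 1.0
        etap = md.eta_p(self.p.beta_p)
        log_tau_p = np.log(tau) + np.log(np.where(pos, md.P, 1.0))

        def loglik(u3):
            a = np.exp(etap + u3[:, None]) * tau
            terms = np.where(pos, a * log_tau_p
                             - special.gammaln(np.where(pos, a, 1.0)), 0.0)
            return terms.sum(axis=1)

        cur = md.u[:, 2]
        prop = cur + self._sc_u3 * rng.standard_normal(md.n)
        ll_cur = loglik(cur)
        ll_prop = loglik(prop)
        lp_cur = -0.5 * (cur - m3) ** 2 / v3
        lp_prop = -0.5 * (prop - m3) ** 2 / v3
        acc = np.log(rng.random(md.n)) < (ll_prop + lp_prop - ll_cur - lp_cur)
        md.u[:, 2] = np.where(acc, prop, cur)
        if adapt:
            rate = acc.mean()
            self._sc_u3 *= np.exp(0.3 * (rate - 0.44))

    def update_sigma_u(self):
        from .imputation import _invwishart_bartlett
        pr, md = self.pr, self.md
        df = pr.wishart_df + md.n
        scale = pr.wishart_scale + md.u.T @ md.u
        self.p.sigma_u = _invwishart_bartlett(df, scale, self.rng)

    def update_sigma2(self):
        md, pr, rng = self.md, self.pr, self.rng
        gk = md.cell_gk().ravel()
        mu = md.eta_e(self.p.beta_e) + md.u[:, 0][:, None] \
            + md.u[:, 1][:, None] * md.t[None, :]
        r2 = ((md.E - mu) ** 2).ravel()
        ncell = np.bincount(gk, minlength=2 * md.nmp)
        ssr = np.bincount(gk, weights=r2, minlength=2 * md.nmp)
        shape = pr.sigma2_shape + ncell / 2
        rate = pr.sigma2_rate + ssr / 2
        draw = rate / rng.gamma(shape)
        self.p.sigma2_e = draw.reshape(2, md.nmp)

    def update_tau(self, adapt=False):
        md, pr, rng = self.md, self.pr, self.rng
        gk = md.cell_gk()
        pos = md.Z == 1.0
        m = np.exp(md.eta_p(self.p.beta_p) + md.u[:, 2][:, None])
        idx = gk[pos]
        mpos = m[pos]
        Ppos = md.P[pos]
        logP = np.log(Ppos)
        ncat = 2 * md.nmp

        def loglik(tau_flat):
            tc = tau_flat[idx]
            a = mpos * tc
            terms = a * np.log(tc) - special.gammaln(a) + a * logP - tc * Ppos
            return np.bincount(idx, weights=terms, minlength=ncat)

        cur = self.p.tau.ravel()
        prop = cur * np.exp(self._sc_tau.ravel() *
                            rng.standard_normal(ncat))
        lp_cur = (loglik(cur) + pr.tau_shape * np.log(cur)
                  - pr.tau_rate * cur)
        lp_prop = (loglik(prop) + pr.tau_shape * np.log(prop)
                   - pr.tau_rate * prop)
        acc = np.log(rng.random(ncat)) < (lp_prop - lp_cur)
        new = np.where(acc, prop, cur)
        self.p.tau = new.reshape(2, md.nmp)
        if adapt:
            self._sc_tau *= np.exp(
                0.05 * (acc.astype(float) - 0.44)).reshape(2, md.nmp)

    def update_beta_z(self, adapt=False):
        rng = self.rng
        cur = self.p.beta_z
        prop = cur + self._sc_z * (self._Lz @
                                   rng.standard_normal(len(cur)))
        pr_var = self.pr.beta_var
        d = (self._loglik_z(prop) - self._loglik_z(cur)
             - 0.5 * (prop @ prop - cur @ cur) / pr_var)
        ok = np.log(rng.random()) < d
        if ok:
            self.p.beta_z = prop
        if adapt:
            self._sc_z *= np.exp(0.05 * (float(ok) - 0.23))
            self._hist_z.append(self.p.beta_z.copy())

    def update_beta_p(self, adapt=False):
        rng = self.rng
        cur = self.p.beta_p
        prop = cur + self._sc_p * (self._Lp @
                                   rng.standard_normal(len(cur)))
        pr_var = self.pr.beta_var
        d = (self._loglik_p_cells(prop).sum()
             - self._loglik_p_cells(cur).sum()
             - 0.5 * (prop @ prop - cur @ cur) / pr_var)
        ok = np.log(rng.random()) < d
        if ok:
            self.p.beta_p = prop
        if adapt:
            self._sc_p *= np.exp(0.05 * (float(ok) - 0.23))
            self._hist_p.append(self.p.beta_p.copy())

    def update_shift_p(self, adapt=False):
        """Reparameterization moves along the (beta_p, U3) ridges.

        Every column of the positive-cost design that is constant over
        the measurement points (intercept, baseline confounders, group)
        can be traded against the cost random effect: beta_j -> beta_j + d
        with U3_i -> U3_i - d * x_ij leaves the likelihood unchanged, so
        acceptance involves only the random-effects and coefficient
        priors.  These directions are identified solely by the
        random-effects prior; without explicit moves along them the tight
        gamma likelihood makes the sampler diffuse extremely slowly.
        """
        md, rng = self.md, self.rng
        Lam = np.linalg.inv(self.p.sigma_u)
        pr_var = self.pr.beta_var
        lu3 = md.u @ Lam[:, 2]                # (Lambda u_i)_3, (n,)
        for j in self._const_cols_p:
            x = md.Xp[:, 0, j]                # k-constant column values
            d = self._sc_shift[j] * rng.standard_normal()
            b = self.p.beta_p[j]
            # joint prior change for u3 -= d*x:  d*sum(x*lu3)
            #   - d^2/2 * Lam33 * sum(x^2), plus the beta prior change
            dlp = (d * np.dot(x, lu3)
                   - 0.5 * d * d * Lam[2, 2] * np.dot(x, x)
                   - ((b + d) ** 2 - b ** 2) / (2 * pr_var))
            if np.log(rng.random()) < dlp:
                self.p.beta_p = self.p.beta_p.copy()
                self.p.beta_p[j] = b + d
                md.u[:, 2] = md.u[:, 2] - d * x
                lu3 = lu3 - d * x * Lam[2, 2]
                ok = 1.0
            else:
                ok = 0.0
            if adapt:
                self._sc_shift[j] *= np.exp(0.05 * (ok - 0.35))

    # -- augmentation updates --------------------------------------------
    def update_missing_e(self):
        md, rng = self.md, self.rng
        if not md.miss_e.any():
            return
        gk = md.cell_gk()
        mu = md.eta_e(self.p.beta_e) + md.u[:, 0][:, None] \
            + md.u[:, 1][:, None] * md.t[None, :]
        sd = np.sqrt(self.p.sigma2_e.ravel()[gk])
        draw = mu + sd * rng.standard_normal(mu.shape)
        md.E[md.miss_e] = draw[md.miss_e]

    def update_missing_c(self):
        md, rng = self.md, self.rng
        if not md.miss_c.any():
            return
        gk = md.cell_gk()
        tau = self.p.tau.ravel()[gk]
        pz = special.expit(md.eta_z(self.p.beta_z))
        m = np.exp(md.eta_p(self.p.beta_p) + md.u[:, 2][:, None])
        z = (rng.random(md.Z.shape) < pz).astype(float)
        pdraw = rng.gamma(np.maximum(m * tau, 1e-12)) / tau
        md.Z[md.miss_c] = z[md.miss_c]
        md.P[md.miss_c] = np.maximum(pdraw[md.miss_c], 1e-8)

    def _patient_loglik(self, rows):
        """Log-likelihood of the listed patients' cells under the current
        state (used by the group-flip update)."""
        md = self.md
        gk = md.cell_gk()[rows]
        tau = self.p.tau.ravel()[gk]
        sig2 = self.p.sigma2_e.ravel()[gk]
        ez = md.Xz[rows] @ self.p.beta_z
        ll = np.sum(md.Z[rows] * ez - np.logaddexp(0.0, ez), axis=1)
        pos = md.Z[rows] == 1.0
        m = np.exp(md.Xp[rows] @ self.p.beta_p + md.u[rows, 2][:, None])
        a = m * tau
        gterm = np.where(pos,
                         a * np.log(tau) - special.gammaln(np.where(pos, a, 1.0))
                         + (a - 1) * np.log(np.where(pos, md.P[rows], 1.0))
                         - tau * md.P[rows], 0.0)
        ll += gterm.sum(axis=1)
        mu = md.Xe[rows] @ self.p.beta_e + md.u[rows, 0][:, None] \
            + md.u[rows, 1][:, None] * md.t[None, :]
        ll += np.sum(-0.5 * np.log(2 * np.pi * sig2)
                     - 0.5 * (md.E[rows] - mu) ** 2 / sig2, axis=1)
        return ll

    def update_missing_group(self):
        md, rng = self.md, self.rng
        if not md.miss_g.any():
            return
        rows = np.flatnonzero(md.miss_g)
        md.set_group(rows, np.zeros(len(rows)))
        ll0 = self._patient_loglik(rows)
        md.set_group(rows, np.ones(len(rows)))
        ll1 = self._patient_loglik(rows)
        p = self.p.p_group
        logit = (ll1 - ll0) + np.log(p) - np.log1p(-p)
        prob1 = special.expit(logit)
        md.set_group(rows, (rng.random(len(rows)) < prob1).astype(float))

    def update_p_group(self):
        md, rng = self.md, self.rng
        s = md.g.sum()
        self.p.p_group = float(rng.beta(1 + s, 1 + md.n - s))

    def update_missing_cov(self):
        md, rng = self.md, self.rng
        for name, info in md.aug_cols.items():
            rows = info["idx"]
            cur = info["values"].copy()
            prop = cur + 0.5 * self._sc_cov[name] * \
                rng.standard_normal(len(rows))
            mu_j = self.p.cov_mu[name]
            tau_j = self.p.cov_tau[name]
            ll_cur = self._patient_loglik(rows) \
                - 0.5 * tau_j * (cur - mu_j) ** 2
            md.set_cov(name, prop)
            ll_prop = self._patient_loglik(rows) \
                - 0.5 * tau_j * (prop - mu_j) ** 2
            acc = np.log(rng.random(len(rows))) < (ll_prop - ll_cur)
            md.set_cov(name, np.where(acc, prop, cur))

    def update_cov_hyper(self):
        md, pr, rng = self.md, self.pr, self.rng
        for name in md.aug_cols:
            x = md._col(name)
            n = len(x)
            mu = self.p.cov_mu[name]
            shape = pr.cov_tau_shape + n / 2
            rate = pr.cov_tau_rate + 0.5 * np.sum((x - mu) ** 2)
            tau_j = rng.gamma(shape) / rate
            prec = n * tau_j + 1.0 / pr.cov_mu_var
            mean = tau_j * x.sum() / prec
            self.p.cov_mu[name] = float(mean + rng.standard_normal()
                                        / np.sqrt(prec))
            self.p.cov_tau[name] = float(tau_j)

    # -- one full sweep ---------------------------------------------------
    def sweep(self, adapt=False):
        self.update_missing_e()
        self.update_missing_c()
        self.update_missing_group()
        self.update_missing_cov()
        self.update_cov_hyper()
        self.update_p_group()
        self.update_beta_e()
        self.update_u12()
        self.update_u3(adapt)
        self.update_sigma_u()
        self.update_sigma2()
        self.update_beta_z(adapt)
        self.update_beta_p(adapt)
        self.update_shift_p(adapt)
        self.update_tau(adapt)


def sample_posterior(
    ds: PanelDataset,
    design: DesignMatrices,
    priors: Priors | None = None,
    mcmc: MCMCSettings | None = None,
    rng: np.random.Generator | int | None = None,
) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler and return retained draws.

    Parameters, per-patient random effects and all augmented values
    (missing outcomes, missing continuous covariates, missing group
    indicators) are updated jointly; see the module docstring for the
    update scheme.  Chains are independent restarts sharing the data.
    """
    priors = priors or Priors()
    mcmc = mcmc or MCMCSettings()
    if mcmc.chains < 1:
        raise ValueError("need at least one chain")
    rng = np.random.default_rng(rng)

    store: dict[str, list] = {k: [] for k in (
        "beta_z", "beta_p", "beta_e", "tau", "sigma2_e", "sigma_u",
        "p_group", "u", "chain", "iteration", "aug_e", "aug_z", "aug_p",
        "aug_group")}
    aug_cov_store: dict[str, list] = {}
    md0 = _ModelData(ds, design)
    miss_e_idx = np.array(np.nonzero(md0.miss_e))
    miss_c_idx = np.array(np.nonzero(md0.miss_c))
    miss_g_idx = np.flatnonzero(md0.miss_g)
    miss_cov_idx = {c: info["idx"] for c, info in md0.aug_cols.items()}
    for c in miss_cov_idx:
        aug_cov_store[c] = []

    for chain in range(mcmc.chains):
        md = _ModelData(ds, design)
        smp = _Sampler(md, priors, rng)
        refresh_at = {mcmc.burn_in // 2, (3 * mcmc.burn_in) // 4}
        for it in range(mcmc.burn_in):
            smp.sweep(adapt=True)
            if it + 1 in refresh_at:
                smp.refresh_proposals()
        for it in range(mcmc.iterations):
            smp.sweep(adapt=False)
            if (it + 1) % mcmc.thin:
                continue
            store["beta_z"].append(smp.p.beta_z.copy())
            store["beta_p"].append(smp.p.beta_p.copy())
            store["beta_e"].append(smp.p.beta_e.copy())
            store["tau"].append(smp.p.tau.copy())
            store["sigma2_e"].append(smp.p.sigma2_e.copy())
            store["sigma_u"].append(smp.p.sigma_u.copy())
            store["p_group"].append(smp.p.p_group)
            store["u"].append(md.u.copy())
            store["chain"].append(chain)
            store["iteration"].append(it)
            store["aug_e"].append(md.E[md.miss_e].copy())
            store["aug_z"].append(md.Z[md.miss_c].copy())
            store["aug_p"].append(md.P[md.miss_c].copy())
            store["aug_group"].append(md.g[miss_g_idx].copy())
            for c, info in md.aug_cols.items():
                aug_cov_store[c].append(info["values"].copy())

    draws = PosteriorDraws(
        beta_z=np.array(store["beta_z"]), beta_p=np.array(store["beta_p"]),
        beta_e=np.array(store["beta_e"]), tau=np.array(store["tau"]),
        sigma2_e=np.array(store["sigma2_e"]),
        sigma_u=np.array(store["sigma_u"]),
        p_group=np.array(store["p_group"]), u=np.array(store["u"]),
        chain=np.array(store["chain"]), iteration=np.array(store["iteration"]),
        cols_z=md0.cols_z, cols_e=md0.cols_e, times=md0.t,
        aug_e=np.array(store["aug_e"]), aug_z=np.array(store["aug_z"]),
        aug_p=np.array(store["aug_p"]),
        aug_group=np.array(store["aug_group"]),
        aug_cov={c: np.array(v) for c, v in aug_cov_store.items()},
        miss_e_idx=miss_e_idx, miss_c_idx=miss_c_idx, miss_g_idx=miss_g_idx,
        miss_cov_idx=miss_cov_idx,
    )
    return draws


# ---------------------------------------------------------------------------
# Posterior predictive machinery
# ---------------------------------------------------------------------------

def _draw_params(draws: PosteriorDraws, s: int):
    return (draws.beta_z[s], draws.beta_p[s], draws.beta_e[s],
            draws.tau[s], draws.sigma2_e[s], draws.sigma_u[s])


def _sample_u(sigma_u, n, rng):
    ev, V = np.linalg.eigh(sigma_u)
    root = V * np.sqrt(np.maximum(ev, 0.0))
    return rng.standard_normal((n, 3)) @ root.T


def predictive_outcomes(draws: PosteriorDraws, cohort: dict,
                        rng: np.random.Generator | int | None = None,
                        max_draws: int | None = None):
    """Posterior predictive outcome draws for a hypothetical cohort.

    ``cohort`` holds design matrices ``{"z", "p", "e"}`` of shape
    (n*, nmp, p) and the per-patient group values ``"group"`` used to
    index the dispersion and variance tables.  For each retained
    parameter draw a fresh random-effect vector is sampled per cohort
    member and outcomes are drawn from the model.  Returns arrays
    ``(C_Z, C_P, E)`` of shape (S, n*, nmp); an empty cohort yields empty
    arrays.
    """
    rng = np.random.default_rng(rng)
    Xz, Xp, Xe = cohort["z"], cohort["p"], cohort["e"]
    nstar = Xz.shape[0]
    nmp = Xz.shape[1]
    t = np.asarray(cohort["times"], float)
    g = np.asarray(cohort["group"], float).astype(int)
    gk = g[:, None] * nmp + np.arange(nmp)[None, :]
    S = draws.S if max_draws is None else min(draws.S, max_draws)
    sel = (np.arange(draws.S) if S == draws.S else
           np.linspace(0, draws.S - 1, S).astype(int))
    CZ = np.empty((S, nstar, nmp))
    CP = np.empty((S, nstar, nmp))
    E = np.empty((S, nstar, nmp))
    if nstar == 0:
        return CZ, CP, E
    for out_s, s in enumerate(sel):
        bz, bp, be, tau, sig2, su = _draw_params(draws, s)
        u = _sample_u(su, nstar, rng)
        ez = Xz @ bz
        pz = special.expit(ez)
        CZ[out_s] = (rng.random((nstar, nmp)) < pz).astype(float)
        m = np.exp(Xp @ bp + u[:, 2][:, None])
        tcell = tau.ravel()[gk]
        CP[out_s] = rng.gamma(np.maximum(m * tcell, 1e-12)) / tcell
        mu = Xe @ be + u[:, 0][:, None] + u[:, 1][:, None] * t[None, :]
        E[out_s] = mu + np.sqrt(sig2.ravel()[gk]) * \
            rng.standard_normal((nstar, nmp))
    return CZ, CP, E


def _cohort_from_design(design: DesignMatrices, draws: PosteriorDraws,
                        s: int, level: float, baseline_eff: np.ndarray):
    """Design matrices for the observed patients with augmented covariate
    cells filled from draw ``s`` and the group forced to ``level``."""
    Xz = design.z.copy()
    Xp = design.p.copy()
    Xe = design.e.copy()
    be = baseline_eff.copy()
    for c, idx in draws.miss_cov_idx.items():
        vals = draws.aug_cov[c][s]
        if c in design.cols_z:
            j = design.cols_z.index(c)
            Xz[idx, :, j] = vals[:, None]
            Xp[idx, :, j] = vals[:, None]
        if c in design.cols_e:
            j = design.cols_e.index(c)
            Xe[idx, :, j] = vals[:, None]
        if c == "baseline_eff":
            be[idx] = vals
    gz = design.group_col("z")
    ge = design.group_col("e")
    Xz[:, :, gz] = level
    Xp[:, :, gz] = level
    Xe[:, :, ge] = level
    return Xz, Xp, Xe, be


def bayes_margins(
    draws: PosteriorDraws,
    design: DesignMatrices,
    ds: PanelDataset,
    rng: np.random.Generator | int | None = None,
    level: float = 0.95,
    tolerance: float = 1e-6,
    max_draws: int | None = None,
) -> CEEstimate:
    """Posterior predictive margins: group-standardized cost/effectiveness.

    For every retained draw the observed patients form a hypothetical
    cohort twice — group forced to low, then high — with fresh random
    effects; the cohort means of cumulative cost and effectiveness AUC
    under each level, their differences (low - high) and the ICER are
    computed per draw and summarized by posterior means, SDs and central
    credible intervals.  Draws with an ICER-undefined denominator are
    excluded from the ICER quantiles and their fraction reported.
    """
    rng = np.random.default_rng(rng)
    n, nmp = design.z.shape[0], design.z.shape[1]
    t_full = ds.nominal_times
    base_eff_obs = ds.effectiveness[:, 0]
    S = draws.S if max_draws is None else min(draws.S, max_draws)
    sel = (np.arange(draws.S) if S == draws.S else
           np.linspace(0, draws.S - 1, S).astype(int))
    res = {("cost", 0.0): np.empty(S), ("cost", 1.0): np.empty(S),
           ("eff", 0.0): np.empty(S), ("eff", 1.0): np.empty(S)}
    gk_tab = {lv: np.full((n, nmp), 0, int) for lv in (0.0, 1.0)}
    for lv in (0.0, 1.0):
        gk_tab[lv] = int(lv) * nmp + np.tile(np.arange(nmp), (n, 1))
    for out_s, s in enumerate(sel):
        bz, bp, be, tau, sig2, su = _draw_params(draws, s)
        for lv in (0.0, 1.0):
            Xz, Xp, Xe, b0 = _cohort_from_design(design, draws, s, lv,
                                                 base_eff_obs)
            u = _sample_u(su, n, rng)
            gk = gk_tab[lv]
            pz = special.expit(Xz @ bz)
            Z = (rng.random((n, nmp)) < pz).astype(float)
            m = np.exp(Xp @ bp + u[:, 2][:, None])
            tcell = tau.ravel()[gk]
            P = rng.gamma(np.maximum(m * tcell, 1e-12)) / tcell
            cost = (Z * P).sum(axis=1)
            mu = Xe @ be + u[:, 0][:, None] \
                + u[:, 1][:, None] * draws.times[None, :]
            E = mu + np.sqrt(sig2.ravel()[gk]) * \
                rng.standard_normal((n, nmp))
            Efull = np.column_stack([b0, E])
            res[("cost", lv)][out_s] = cost.mean()
            res[("eff", lv)][out_s] = _auc(Efull, t_full).mean()

    dcost = res[("cost", 0.0)] - res[("cost", 1.0)]
    deff = res[("eff", 0.0)] - res[("eff", 1.0)]
    defined = np.abs(deff) > tolerance
    icers = np.where(defined, dcost / np.where(defined, deff, 1.0), np.nan)
    alpha = (1 - level) / 2
    qs = (100 * alpha, 100 * (1 - alpha))
    mean_cost = {g: float(res[("cost", v)].mean())
                 for g, v in (("low", 0.0), ("high", 1.0))}
    mean_eff = {g: float(res[("eff", v)].mean())
                for g, v in (("low", 0.0), ("high", 1.0))}
    se, ci = {}, {}
    for key, arr in (("cost_low", res[("cost", 0.0)]),
                     ("cost_high", res[("cost", 1.0)]),
                     ("eff_low", res[("eff", 0.0)]),
                     ("eff_high", res[("eff", 1.0)]),
                     ("delta_cost", dcost), ("delta_eff", deff)):
        se[key] = float(arr.std(ddof=1))
        ci[key] = tuple(np.percentile(arr, qs))
    d_eff_mean = float(deff.mean())
    ratio, undef = _icer(float(dcost.mean()), d_eff_mean, tolerance)
    extra = {"S": S,
             "icer_undefined_fraction": float(1 - defined.mean())}
    if defined.any():
        se["icer"] = float(np.nanstd(icers, ddof=1))
        ci["icer"] = tuple(np.nanpercentile(icers, qs))
    return CEEstimate(
        method="predictive", mean_cost=mean_cost, mean_eff=mean_eff,
        delta_cost=float(dcost.mean()), delta_eff=d_eff_mean,
        icer=ratio, icer_undefined=undef, se=se, ci=ci, level=level,
        extra=extra)


def random_effect_summary(draws: PosteriorDraws, level: float = 0.95):
    """Posterior summaries of the random-effect correlations and of the
    dispersion/variance tables (the variance-parameter table layout)."""
    import pandas as pd
    alpha = (1 - level) / 2
    qs = (100 * alpha, 100 * (1 - alpha))
    rows = []
    for (i, j), name in (((0, 1), "rho12"), ((0, 2), "rho13"),
                         ((1, 2), "rho23")):
        r = draws.rho_draws(i, j)
        lo, hi = np.percentile(r, qs)
        rows.append({"parameter": name, "group": "", "interval": "",
                     "mean": float(r.mean()), "lo": lo, "hi": hi})
    for g, gname in ((0, "low"), (1, "high")):
        for k in range(draws.tau.shape[2]):
            for pname, arr in (("sigma2_e", draws.sigma2_e),
                               ("tau", draws.tau)):
                x = arr[:, g, k]
                lo, hi = np.percentile(x, qs)
                rows.append({"parameter": pname, "group": gname,
                             "interval": k + 2, "mean": float(x.mean()),
                             "lo": lo, "hi": hi})
    return pd.DataFrame(rows)
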