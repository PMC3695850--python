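"""Multivariate-normal data-augmentation imputation of repeated outcomes.

Missing effectiveness scores and interval costs are imputed jointly under
a multivariate normal model fitted separately within each group, using
the classic data-augmentation chain for nonmonotone missingness: the
I-step draws each patient's missing coordinates from their conditional
normal given the observed coordinates and the current (mu, Sigma); the
P-step draws (mu, Sigma) from the complete-data posterior under the
Jeffreys prior, Sigma | Y ~ InvWishart(n - 1, S) and mu | Sigma, Y ~
N(ybar, Sigma / n).

Interval costs enter the normal model on the raw euro scale by default
and imputed values are clamped at zero, so imputed costs are always
nonnegative.  A conditional-normal draw has a linear conditional mean, so
raw-scale imputation is approximately mean-unbiased even though interval
costs are semicontinuous (a point mass at zero plus a skewed positive
part); a log1p/expm1 variant is available but inflates imputed costs by
the exponential of half the (large, zero-spike-driven) conditional
variance and is therefore not the default.  Auxiliary covariates are not
part of the imputation model.  Observed cells are never altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .panel import PanelDataset

__all__ = ["ImputationSettings", "fit_and_impute",
           "single_impute_for_bootstrap"]


@dataclass
class ImputationSettings:
    """Chain settings for the data-augmentation imputer.

    ``burn_in`` iterations precede the first imputation and ``thin``
    iterations separate successive ones; the bootstrap path uses the
    shorter ``bootstrap_burn_in`` since each replicate needs one draw and
    the chain starts at observed-moment estimates.  ``ridge`` keeps the
    working covariance invertible for near-degenerate patterns.
    """

    burn_in: int = 200
    thin: int = 100
    bootstrap_burn_in: int = 40
    ridge: float = 1e-6
    cost_scale: str = "raw"        # "raw" or "log1p"


def _chain_matrices(ds: PanelDataset, cost_scale: str):
    """Stack the imputation-model variables: all K scores then the K-1
    interval costs (raw or log1p scale)."""
    C = ds.interval_costs
    if cost_scale == "log1p":
        C = np.log1p(C)
    elif cost_scale != "raw":
        raise ValueError(f"unknown cost_scale {cost_scale!r}")
    return np.column_stack([ds.effectiveness, C]), ds.K


def _unstack(ds: PanelDataset, Y: np.ndarray, rows: np.ndarray,
             cost_scale: str) -> None:
    K = ds.K
    eff = Y[:, :K]
    cost = Y[:, K:]
    if cost_scale == "log1p":
        cost = np.expm1(cost)
    cost = np.maximum(cost, 0.0)
    mis_e = np.isnan(ds.effectiveness[rows])
    mis_c = np.isnan(ds.interval_costs[rows])
    e_block = ds.effectiveness[rows]
    c_block = ds.interval_costs[rows]
    e_block[mis_e] = np.maximum(eff, 0.0)[mis_e]
    c_block[mis_c] = cost[mis_c]
    ds.effectiveness[rows] = e_block
    ds.interval_costs[rows] = c_block


_TRIL_CACHE: dict = {}


def _invwishart_bartlett(df: float, S: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw from InvWishart(df, S) via the Bartlett decomposition."""
    q = S.shape[0]
    if q not in _TRIL_CACHE:
        _TRIL_CACHE[q] = (np.tril_indices(q, -1), np.diag_indices(q))
    tril, diag = _TRIL_CACHE[q]
    L = np.linalg.cholesky(S)
    A = np.zeros((q, q))
    A[tril] = rng.standard_normal(q * (q - 1) // 2)
    A[diag] = np.sqrt(rng.chisquare(df - np.arange(q)))
    # with U = L^-T (UU' = S^-1), W = (UA)(UA)' ~ Wishart(df, S^-1) and
    # W^-1 = L A^-T A^-1 L' = B'B with B = A^-1 L'
    B = solve_triangular(A, L.T, lower=True, check_finite=False)
    return B.T @ B


class _DAChain:
    """Data-augmentation chain over both groups at once.

    Group-specific (mu, Sigma) are stacked so each iteration is a fixed,
    small number of (partly batched) numpy calls: one stacked Cholesky
    and inverse, two matmuls per group, and one batched solve per
    missing-block size.
    """

    def __init__(self, Y: np.ndarray, group: np.ndarray, ridge: float):
        self.n, self.q = Y.shape
        self.obs = ~np.isnan(Y)
        self.obs_f = self.obs.astype(float)
        self.ridge = ridge
        self.gidx = [np.flatnonzero(group == g) for g in (0.0, 1.0)]
        for g, idx in enumerate(self.gidx):
            if len(idx) < self.q + 2:
                raise ValueError(
                    f"group {g} too small for the imputation model: "
                    f"{len(idx)} rows < {self.q} variables + 2")
        # starting values: group-wise observed means / filled covariance
        self.Y = Y.copy()
        self.mu = np.zeros((2, self.q))
        self.Sigma = np.zeros((2, self.q, self.q))
        for g, idx in enumerate(self.gidx):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cm = np.nanmean(np.where(self.obs[idx], Y[idx], np.nan),
                                axis=0)
            cm = np.where(np.isnan(cm), 0.0, cm)
            block = np.where(self.obs[idx], Y[idx], cm)
            self.Y[idx] = block
            self.mu[g] = block.mean(axis=0)
            self.Sigma[g] = np.cov(block, rowvar=False) \
                + ridge * np.eye(self.q)
        self.y_filled = np.where(self.obs, self.Y, 0.0)
        self.group_of = group.astype(int)
        # missing blocks grouped by size for batched solves
        self.size_groups = {}
        miss = ~self.obs
        rows_any = np.flatnonzero(miss.any(axis=1))
        sizes = miss[rows_any].sum(axis=1)
        for s in np.unique(sizes):
            rows = rows_any[sizes == s]
            mi = np.array([np.flatnonzero(miss[r]) for r in rows])
            self.size_groups[int(s)] = (rows, self.group_of[rows], mi)

    def istep(self, rng):
        # conditioning by kriging: draw W ~ N(mu_g, Sigma_g) jointly, then
        # shift each missing block by -Lam_mm^-1 (Lam d)_m with d the
        # observed residual zero-filled at missing cells
        L = np.linalg.cholesky(self.Sigma)
        Lam = np.linalg.inv(self.Sigma)
        Z = rng.standard_normal((self.n, self.q))
        W = np.empty_like(Z)
        G = np.empty_like(Z)
        for g, idx in enumerate(self.gidx):
            W[idx] = self.mu[g] + Z[idx] @ L[g].T
            G[idx] = ((self.y_filled[idx] - W[idx]) * self.obs_f[idx]) \
                @ Lam[g]
        for s, (rows, gid, mi) in self.size_groups.items():
            if s == 1:
                j = mi[:, 0]
                corr = G[rows, j] / Lam[gid, j, j]
                self.Y[rows, j] = W[rows, j] - corr
            else:
                A = Lam[gid[:, None, None], mi[:, :, None], mi[:, None, :]]
                Gm = G[rows[:, None], mi]
                corr = np.linalg.solve(A, Gm[..., None])[..., 0]
                self.Y[rows[:, None], mi] = W[rows[:, None], mi] - corr

    def pstep(self, rng):
        for g, idx in enumerate(self.gidx):
            block = self.Y[idx]
            ybar = block.mean(axis=0)
            D = block - ybar
            S = D.T @ D + self.ridge * np.eye(self.q)
            if not np.isfinite(S).all():
                raise RuntimeError("chain divergence: non-finite draws")
            n = len(idx)
            self.Sigma[g] = _invwishart_bartlett(n - 1, S, rng)
            L = np.linalg.cholesky(self.Sigma[g] / n)
            self.mu[g] = ybar + L @ rng.standard_normal(self.q)

    def run(self, iters, rng):
        for it in range(iters):
            self.istep(rng)
            try:
                self.pstep(rng)
            except RuntimeError as err:
                raise RuntimeError(f"{err} at iteration {it}") from None


def fit_and_impute(
    ds: PanelDataset,
    m: int = 20,
    settings: ImputationSettings | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[PanelDataset]:
    """Draw ``m`` completed datasets from group-wise normal augmentation.

    Patients must carry an observed group (the frequentist paths exclude
    missing-group patients before imputation).  With no missing outcome
    cells the input is returned unchanged ``m`` times.
    """
    settings = settings or ImputationSettings()
    rng = np.random.default_rng(rng)
    if np.isnan(ds.group).any():
        raise ValueError("imputation requires observed group for every "
                         "patient; subset first")
    Y, _ = _chain_matrices(ds, settings.cost_scale)
    if not np.isnan(Y).any():
        return [ds.copy() for _ in range(m)]
    chain = _DAChain(Y, ds.group, settings.ridge)

    out = []
    all_rows = np.arange(ds.n)
    for j in range(m):
        chain.run(settings.burn_in if j == 0 else settings.thin, rng)
        comp = ds.copy()
        _unstack(comp, chain.Y, all_rows, settings.cost_scale)
        out.append(comp)
    return out


def single_impute_for_bootstrap(
    ds: PanelDataset,
    settings: ImputationSettings | None = None,
    rng: np.random.Generator | int | None = None,
) -> PanelDataset:
    """One completed dataset (the per-bootstrap-replicate imputation)."""
    settings = settings or ImputationSettings()
    short = ImputationSettings(burn_in=settings.bootstrap_burn_in,
                               thin=settings.thin,
                               bootstrap_burn_in=settings.bootstrap_burn_in,
                               ridge=settings.ridge,
                               cost_scale=settings.cost_scale)
    return fit_and_impute(ds, m=1, settings=short, rng=rng)[0]
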