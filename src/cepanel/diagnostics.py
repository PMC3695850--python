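"""Holdout predictive checks and MCMC convergence summaries.

Model assessment follows the holdout standardized-predictive-error (SPE)
scheme: a random subset of patients is excluded from estimation; for
each held-out patient the posterior fitted on the remaining patients
yields a predictive distribution of every outcome from baseline
information alone (fresh random effects per draw), and the SPE is the
posterior expectation of (prediction - observation) / residual SD.
Under a well-specified model (and random-effect variation small relative
to the residual) the SPE values behave approximately like N(0, 1)
samples, so Q-Q coordinates against the standard normal and a per-MP
Kolmogorov-Smirnov statistic summarize the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import DesignMatrices, PanelDataset
from .twopart import PosteriorDraws, _sample_u

__all__ = ["SPEResult", "holdout_split", "spe", "convergence_report"]


@dataclass
class SPEResult:
    """Standardized predictive errors for a holdout set."""

    holdout_ids: np.ndarray
    eff_spe: np.ndarray          # (n*, nmp), NaN where unobserved
    cost_spe: np.ndarray         # (n*, nmp), NaN where cost not positive/obs
    qq: dict                     # (variable, mp) -> (theoretical, empirical)
    ks: dict                     # (variable, mp) -> (statistic, p-value)


def holdout_split(ds: PanelDataset, n_holdout: int,
                  rng: np.random.Generator | int | None = None
                  ) -> tuple[PanelDataset, PanelDataset]:
    """Random train/holdout split of patients (without replacement)."""
    if n_holdout >= ds.n:
        raise ValueError("holdout size must be smaller than the sample")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(ds.n)
    hold = np.sort(perm[:n_holdout])
    train = np.sort(perm[n_holdout:])
    return ds.subset(train), ds.subset(hold)


def _qq_coords(x: np.ndarray):
    x = np.sort(x[~np.isnan(x)])
    m = len(x)
    if m == 0:
        return np.empty(0), np.empty(0)
    theo = stats.norm.ppf((np.arange(1, m + 1) - 0.5) / m)
    return theo, x


def spe(
    draws: PosteriorDraws,
    holdout: PanelDataset,
    design: DesignMatrices,
    rng: np.random.Generator | int | None = None,
    max_draws: int | None = None,
) -> SPEResult:
    """Standardized predictive errors for observed holdout outcomes.

    ``draws`` must come from a posterior fitted on the training patients
    only; ``design`` is the holdout patients' design (their baseline
    information).  Holdout patients with a missing group or missing
    design entries contribute nothing.  Effectiveness SPE per draw is
    (predicted mean with fresh random effects - observed) / residual SD.
    Cost SPE (positive observed costs only) standardizes the observation
    against the draw's full predictive mean and SD of the positive cost
    with the cost random effect integrated out; standardizing by the
    gamma's conditional SD alone would be degenerate, since that SD is a
    tiny fraction of the random-effect variation (the conditional CV is
    1/sqrt(shape) with shapes in the thousands) and every SPE would be
    tens of units wide even under the true model.  Values are averaged
    over draws.
    """
    rng = np.random.default_rng(rng)
    nstar, nmp = design.e.shape[0], design.e.shape[1]
    obs_e = holdout.effectiveness[:, 1:]
    obs_c = holdout.interval_costs
    usable = ~np.isnan(holdout.group)
    usable &= ~np.isnan(design.z).reshape(nstar, -1).any(axis=1)
    usable &= ~np.isnan(design.e).reshape(nstar, -1).any(axis=1)
    if not (np.isfinite(obs_e[usable]).any()
            or np.isfinite(obs_c[usable]).any()):
        raise ValueError("holdout has no observed outcomes")

    g = np.where(usable, holdout.group, 0.0).astype(int)
    gk = g[:, None] * nmp + np.arange(nmp)[None, :]
    S = draws.S if max_draws is None else min(draws.S, max_draws)
    sel = (np.arange(draws.S) if S == draws.S
           else np.linspace(0, draws.S - 1, S).astype(int))

    eff_acc = np.zeros((nstar, nmp))
    cost_acc = np.zeros((nstar, nmp))
    for s in sel:
        u = _sample_u(draws.sigma_u[s], nstar, rng)
        mu = design.e @ draws.beta_e[s] + u[:, 0][:, None] \
            + u[:, 1][:, None] * draws.times[None, :]
        sd = np.sqrt(draws.sigma2_e[s].ravel()[gk])
        eff_acc += (mu - obs_e) / sd
        # positive-cost predictive moments with U3 integrated out:
        # C = m e^U (1 + gamma noise), U ~ N(0, s33)
        m = np.exp(design.p @ draws.beta_p[s])
        s33 = draws.sigma_u[s][2, 2]
        cmean = m * np.exp(s33 / 2)
        cvar = (m ** 2 * (np.exp(2 * s33) - np.exp(s33))
                + (m / draws.tau[s].ravel()[gk]) * np.exp(s33 / 2))
        cost_acc += (obs_c - cmean) / np.sqrt(cvar)
    eff_spe = eff_acc / S
    cost_spe = cost_acc / S
    eff_spe[~usable] = np.nan
    cost_spe[~usable] = np.nan
    cost_spe[~(obs_c > 0)] = np.nan     # zero or missing cost cells excluded

    qq, ks = {}, {}
    for k in range(nmp):
        for var, arr in (("effectiveness", eff_spe), ("cost", cost_spe)):
            theo, emp = _qq_coords(arr[:, k])
            qq[(var, k + 2)] = (theo, emp)
            if len(emp) >= 3:
                stat, p = stats.kstest(emp, "norm")
                ks[(var, k + 2)] = (float(stat), float(p))
    return SPEResult(holdout_ids=holdout.patient_ids.copy(),
                     eff_spe=eff_spe, cost_spe=cost_spe, qq=qq, ks=ks)


# ---------------------------------------------------------------------------
# Convergence
# ---------------------------------------------------------------------------

def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction (rank-free, classic form)."""
    half = chains.shape[1] // 2
    parts = np.concatenate([chains[:, :half], chains[:, half:2 * half]])
    m, n = parts.shape
    means = parts.mean(axis=1)
    W = parts.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return np.inf if B > 0 else 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _autocorr(x: np.ndarray, lag: int) -> float:
    x = x - x.mean()
    v = np.dot(x, x)
    if v == 0 or lag >= len(x):
        return 0.0
    return float(np.dot(x[:-lag], x[lag:]) / v)


def convergence_report(draws_or_traces, threshold: float = 1.05):
    """Per-parameter split-chain scale reduction and autocorrelations.

    Accepts a :class:`PosteriorDraws` or a ``{name: (chains, iters)}``
    dict of traces.  Returns a DataFrame with lag-1 / lag-10
    autocorrelation (averaged over chains), the split-chain
    scale-reduction factor, and a flag for parameters exceeding
    ``threshold``.  With a single chain the scale reduction is omitted
    with a warning column instead of an error.
    """
    import pandas as pd
    if isinstance(draws_or_traces, PosteriorDraws):
        d = draws_or_traces
        ids = np.unique(d.chain)
        traces = {}
        for name, x in d.scalar_params().items():
            traces[name] = np.stack([x[d.chain == c] for c in ids])
    else:
        traces = {k: np.atleast_2d(np.asarray(v, float))
                  for k, v in draws_or_traces.items()}
    rows = []
    single = next(iter(traces.values())).shape[0] < 2
    for name, tr in traces.items():
        row = {"parameter": name,
               "lag1": float(np.mean([_autocorr(c, 1) for c in tr])),
               "lag10": float(np.mean([_autocorr(c, 10) for c in tr]))}
        if single:
            row["rhat"] = np.nan
            row["flagged"] = False
        else:
            row["rhat"] = _split_rhat(tr)
            row["flagged"] = bool(row["rhat"] > threshold)
        rows.append(row)
    out = pd.DataFrame(rows)
    if single:
        out.attrs["warning"] = ("single chain: scale reduction omitted; "
                                "run at least two chains")
    return out
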