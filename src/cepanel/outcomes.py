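"""Cumulative outcomes, ICER and the unadjusted bootstrap.

The repeated measurements are compressed into two per-patient scalars:

* the cumulative cost ``C_i = sum_k C_ik`` over the K-1 intervals, and
* the effectiveness AUC, the trapezoid-rule area of the score over the
  follow-up divided by its length, so the AUC lives on the score scale
  (a time-average).

Group contrasts are always reported as low - high.  The incremental
cost-effectiveness ratio (ICER) is the cost difference over the
effectiveness difference, undefined when the denominator is numerically
zero.  The unadjusted strategy quantifies uncertainty by a stratified
patient bootstrap with one fresh imputation of missing outcomes inside
every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel import GROUP_HIGH, GROUP_LOW, PanelDataset

__all__ = [
    "CumulativeOutcomes", "CEEstimate", "auc", "cumulative_cost", "icer",
    "ce_summary", "bootstrap_unadjusted",
]

#: |delta effectiveness| below this makes the ICER undefined.
ICER_TOLERANCE = 1e-6


@dataclass
class CumulativeOutcomes:
    """Per-patient cumulative cost and effectiveness AUC."""

    cum_cost: np.ndarray       # (n,) euros, NaN where incomplete
    auc: np.ndarray            # (n,) score units, NaN where incomplete
    complete: np.ndarray       # (n,) bool: both outcomes computable


@dataclass
class CEEstimate:
    """One method's cost-effectiveness summary (a results-table row)."""

    method: str
    mean_cost: dict            # {"low": ..., "high": ...}
    mean_eff: dict
    delta_cost: float          # low - high
    delta_eff: float
    icer: float | None
    icer_undefined: bool
    sd_cost: dict = field(default_factory=dict)
    sd_eff: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)       # keyed quantity -> SE/SD
    ci: dict = field(default_factory=dict)       # keyed quantity -> (lo, hi)
    p_value: dict = field(default_factory=dict)
    level: float = 0.95
    extra: dict = field(default_factory=dict)


def auc(effectiveness, times) -> np.ndarray:
    """Trapezoid-rule time-average of repeated scores over the follow-up.

    ``effectiveness`` is (K,) or (n, K); ``times`` is (K,) with
    ``times[0] == 0`` and strictly increasing.  Every score must be
    present — impute first.  The area is divided by ``times[-1]`` so a
    constant series returns that constant.
    """
    E = np.atleast_2d(np.asarray(effectiveness, dtype=float))
    t = np.asarray(times, dtype=float)
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing from 0")
    if E.shape[1] != len(t):
        raise ValueError("effectiveness and times length mismatch")
    if np.isnan(E).any():
        raise ValueError("missing effectiveness values; impute before AUC")
    dt = np.diff(t)
    area = 0.5 * (E[:, :-1] + E[:, 1:]) @ dt
    out = area / t[-1]
    return out[0] if np.ndim(effectiveness) == 1 else out


def cumulative_cost(interval_costs) -> np.ndarray:
    """Sum of interval costs; every interval must be present."""
    C = np.atleast_2d(np.asarray(interval_costs, dtype=float))
    if np.isnan(C).any():
        raise ValueError("missing interval costs; impute before summing")
    out = C.sum(axis=1)
    return out[0] if np.ndim(interval_costs) == 1 else out


def cumulative_outcomes(ds: PanelDataset) -> CumulativeOutcomes:
    """Per-patient cumulative outcomes, NaN where any component is missing."""
    cum = np.full(ds.n, np.nan)
    av = np.full(ds.n, np.nan)
    cost_ok = ~np.isnan(ds.interval_costs).any(axis=1)
    eff_ok = ~np.isnan(ds.effectiveness).any(axis=1)
    if cost_ok.any():
        cum[cost_ok] = ds.interval_costs[cost_ok].sum(axis=1)
    if eff_ok.any():
        av[eff_ok] = auc(ds.effectiveness[eff_ok], ds.nominal_times)
    return CumulativeOutcomes(cum_cost=cum, auc=av,
                              complete=cost_ok & eff_ok)


def icer(delta_cost: float, delta_eff: float,
         tolerance: float = ICER_TOLERANCE) -> tuple[float | None, bool]:
    """ICER = delta_cost / delta_eff, undefined when |delta_eff| <= tolerance.

    Returns ``(value, undefined_flag)``; undefined is a value, not an
    error.
    """
    if abs(delta_eff) <= tolerance:
        return None, True
    return delta_cost / delta_eff, False


def _group_arrays(cum_cost, av, group):
    out = {}
    for gval, gname in ((GROUP_LOW, "low"), (GROUP_HIGH, "high")):
        sel = group == gval
        if not sel.any():
            raise ValueError(f"group {gname!r} is empty")
        out[gname] = (cum_cost[sel], av[sel])
    return out


def _welch(x, y, level):
    """Welch t CI and p-value for mean(x) - mean(y)."""
    nx, ny = len(x), len(y)
    d = x.mean() - y.mean()
    vx, vy = x.var(ddof=1) / nx, y.var(ddof=1) / ny
    se = np.sqrt(vx + vy)
    if se == 0:
        return d, (d, d), (0.0 if d != 0 else 1.0)
    df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    tcrit = stats.t.ppf(0.5 + level / 2, df)
    p = 2 * stats.t.sf(abs(d) / se, df)
    return d, (d - tcrit * se, d + tcrit * se), p


def ce_summary(ds: PanelDataset, level: float = 0.95,
               tolerance: float = ICER_TOLERANCE) -> CEEstimate:
    """Observed (complete-case or post-imputation) group summary.

    Means/SDs per group, differences low - high with t-based (Welch)
    confidence intervals and p-values, and the ICER.
    """
    co = cumulative_outcomes(ds)
    mean_cost, mean_eff, sd_cost, sd_eff, ci, pv = {}, {}, {}, {}, {}, {}
    arrs = {}
    for gval, gname in ((GROUP_LOW, "low"), (GROUP_HIGH, "high")):
        sel = ds.group == gval
        if not sel.any():
            raise ValueError(f"group {gname!r} is empty")
        cc = co.cum_cost[sel]
        aa = co.auc[sel]
        cc, aa = cc[~np.isnan(cc)], aa[~np.isnan(aa)]
        if cc.size == 0 or aa.size == 0:
            raise ValueError(f"group {gname!r} has no complete outcomes")
        arrs[gname] = (cc, aa)
        mean_cost[gname], mean_eff[gname] = float(cc.mean()), float(aa.mean())
        sd_cost[gname] = float(cc.std(ddof=1)) if cc.size > 1 else 0.0
        sd_eff[gname] = float(aa.std(ddof=1)) if aa.size > 1 else 0.0
        for lab, x in ((f"cost_{gname}", cc), (f"eff_{gname}", aa)):
            m = x.mean()
            se = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
            tcrit = stats.t.ppf(0.5 + level / 2, max(len(x) - 1, 1))
            ci[lab] = (m - tcrit * se, m + tcrit * se)

    dcost, ci["delta_cost"], pv["delta_cost"] = _welch(
        arrs["low"][0], arrs["high"][0], level)
    deff, ci["delta_eff"], pv["delta_eff"] = _welch(
        arrs["low"][1], arrs["high"][1], level)
    ratio, undef = icer(dcost, deff, tolerance)
    return CEEstimate(
        method="observed", mean_cost=mean_cost, mean_eff=mean_eff,
        delta_cost=float(dcost), delta_eff=float(deff), icer=ratio,
        icer_undefined=undef, sd_cost=sd_cost, sd_eff=sd_eff,
        ci=ci, p_value=pv, level=level,
        extra={"n_low": len(arrs["low"][0]), "n_high": len(arrs["high"][0])})


def stratified_resample(group: np.ndarray, rng: np.random.Generator
                        ) -> np.ndarray:
    """Patient indices resampled with replacement within each group.

    Preserves the two group sizes exactly; patients with missing group are
    never drawn.
    """
    parts = []
    for gval in (GROUP_LOW, GROUP_HIGH):
        idx = np.flatnonzero(group == gval)
        if idx.size == 0:
            raise ValueError("cannot resample an empty group")
        parts.append(rng.choice(idx, size=idx.size, replace=True))
    return np.concatenate(parts)


def bootstrap_p(deltas: np.ndarray) -> float:
    """Two-sided bootstrap sign-inversion p-value, 2*min(#<=0, #>=0)/B."""
    B = len(deltas)
    return min(1.0, 2 * min((deltas <= 0).sum(), (deltas >= 0).sum()) / B)


def _summarize_bootstrap(method, reps, level, tolerance):
    """Common bootstrap summary: reps is a dict of replicate arrays."""
    alpha = (1 - level) / 2
    qs = (100 * alpha, 100 * (1 - alpha))
    mean_cost = {g: float(np.mean(reps[f"cost_{g}"])) for g in ("low", "high")}
    mean_eff = {g: float(np.mean(reps[f"eff_{g}"])) for g in ("low", "high")}
    se, ci, pv = {}, {}, {}
    for key in ("cost_low", "cost_high", "eff_low", "eff_high",
                "delta_cost", "delta_eff"):
        x = reps[key]
        se[key] = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        ci[key] = tuple(np.percentile(x, qs))
    pv["delta_cost"] = bootstrap_p(reps["delta_cost"])
    pv["delta_eff"] = bootstrap_p(reps["delta_eff"])

    dcost = float(np.mean(reps["delta_cost"]))
    deff = float(np.mean(reps["delta_eff"]))
    ratio, undef = icer(dcost, deff, tolerance)
    icers = reps["icer"]
    defined = icers[~np.isnan(icers)]
    n_undef = int(np.isnan(icers).sum())
    extra = {"B": len(reps["delta_cost"]), "icer_undefined_replicates": n_undef}
    if defined.size and n_undef <= 0.5 * len(icers):
        se["icer"] = float(np.std(defined, ddof=1))
        ci["icer"] = tuple(np.percentile(defined, qs))
        pv["icer"] = bootstrap_p(defined)
    else:
        extra["icer_summaries_unusable"] = True
    return CEEstimate(
        method=method, mean_cost=mean_cost, mean_eff=mean_eff,
        delta_cost=dcost, delta_eff=deff, icer=ratio, icer_undefined=undef,
        se=se, ci=ci, p_value=pv, level=level, extra=extra)


def bootstrap_unadjusted(
    ds: PanelDataset,
    B: int = 500,
    rng: np.random.Generator | None = None,
    impute=None,
    level: float = 0.95,
    tolerance: float = ICER_TOLERANCE,
) -> CEEstimate:
    """Unadjusted bootstrap of group means, differences and the ICER.

    Patients are resampled with replacement stratified by group; each
    replicate is completed by one call of ``impute(ds_rep, rng)`` (a
    single-imputation hook; ``None`` requires complete data) before the
    cumulative outcomes and their group means are computed.  Summaries are
    the replicate means' average, their SD as the standard error, the
    percentile interval, and the sign-inversion p-value.  Replicates with
    an undefined ICER are excluded from the ICER summaries and counted.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(rng)
    keep = ~np.isnan(ds.group)
    base = ds.subset(np.flatnonzero(keep)) if not keep.all() else ds
    reps = {k: np.empty(B) for k in
            ("cost_low", "cost_high", "eff_low", "eff_high",
             "delta_cost", "delta_eff", "icer")}
    for b in range(B):
        rep = base.subset(stratified_resample(base.group, rng))
        if impute is not None:
            rep = impute(rep, rng)
        co = cumulative_outcomes(rep)
        if not co.complete.all():
            raise ValueError("incomplete outcomes in a bootstrap replicate; "
                             "provide an imputation hook")
        for gval, g in ((GROUP_LOW, "low"), (GROUP_HIGH, "high")):
            sel = rep.group == gval
            reps[f"cost_{g}"][b] = co.cum_cost[sel].mean()
            reps[f"eff_{g}"][b] = co.auc[sel].mean()
        reps["delta_cost"][b] = reps["cost_low"][b] - reps["cost_high"][b]
        reps["delta_eff"][b] = reps["eff_low"][b] - reps["eff_high"][b]
        val, undef = icer(reps["delta_cost"][b], reps["delta_eff"][b],
                          tolerance)
        reps["icer"][b] = np.nan if undef else val
    return _summarize_bootstrap("bootstrapped", reps, level, tolerance)
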