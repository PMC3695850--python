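"""Panel data model for longitudinal cost-effectiveness studies.

The study design is a repeated-measures panel: each patient is measured at
``K`` time points (months since baseline), yielding an effectiveness score
(a symptom severity index, larger = worse) at every measurement point and a
nonnegative interval cost (euros) for each of the ``K - 1`` intervals
between consecutive measurement points.  Patients are compared in two
groups obtained by dichotomizing a continuous baseline score at a
threshold, and carry a set of baseline confounders.

Missing values are allowed everywhere and are represented as NaN; they are
never silently dropped.  Downstream modules decide how to handle them
(imputation, Bayesian augmentation, or complete-case exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "DesignMatrices",
    "read_panel",
    "write_panel",
    "dichotomize_group",
    "build_design",
    "missingness_table",
]

GROUP_LOW = 0.0
GROUP_HIGH = 1.0


@dataclass
class PanelDataset:
    """A repeated-measures cost-effectiveness study table.

    Attributes
    ----------
    patient_ids : (n,) array of patient identifiers (ints or strings).
    nominal_times : (K,) strictly increasing months, first element 0.
    effectiveness : (n, K) float array, NaN = missing, observed values >= 0.
    interval_costs : (n, K-1) float array for intervals between consecutive
        measurement points (column j covers ``nominal_times[j]`` to
        ``nominal_times[j+1]``); NaN = missing, observed values >= 0.
    group_score : (n,) continuous grouping score, NaN allowed.
    group : (n,) float; 0.0 = low, 1.0 = high, NaN = missing / not yet set.
    covariates : DataFrame with one row per patient (baseline confounders).
        Categorical columns carry pandas ``category`` or object dtype.
    actual_times : optional (n, K) per-patient measurement months.
    strict : enforce nonnegative effectiveness (real scores are >= 0; the
        synthetic generator relaxes this when no floor is requested, since
        its effectiveness model is normal and unbounded).
    """

    patient_ids: np.ndarray
    nominal_times: np.ndarray
    effectiveness: np.ndarray
    interval_costs: np.ndarray
    group_score: np.ndarray
    group: np.ndarray
    covariates: pd.DataFrame
    actual_times: np.ndarray | None = None
    strict: bool = True

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids)
        self.nominal_times = np.asarray(self.nominal_times, dtype=float)
        self.effectiveness = np.asarray(self.effectiveness, dtype=float)
        self.interval_costs = np.asarray(self.interval_costs, dtype=float)
        self.group_score = np.asarray(self.group_score, dtype=float)
        self.group = np.asarray(self.group, dtype=float)
        self.validate()

    # -- basic shape accessors -------------------------------------------
    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def K(self) -> int:
        return len(self.nominal_times)

    def validate(self) -> None:
        n, K = self.n, self.K
        if K < 2:
            raise ValueError("need at least two measurement points")
        if self.nominal_times[0] != 0.0:
            raise ValueError("first nominal time must be 0")
        if np.any(np.diff(self.nominal_times) <= 0):
            raise ValueError("nominal_times must be strictly increasing")
        if self.effectiveness.shape != (n, K):
            raise ValueError(
                f"effectiveness shape {self.effectiveness.shape} != {(n, K)}")
        if self.interval_costs.shape != (n, K - 1):
            raise ValueError(
                f"interval_costs shape {self.interval_costs.shape} != {(n, K - 1)}")
        if self.group_score.shape != (n,) or self.group.shape != (n,):
            raise ValueError("group arrays must have shape (n,)")
        if len(self.covariates) != n:
            raise ValueError("covariates must have one row per patient")
        if self.strict:
            bad = np.argwhere(self.effectiveness < 0)
            if bad.size:
                i, k = bad[0]
                raise ValueError(
                    f"negative effectiveness for patient "
                    f"{self.patient_ids[i]!r} at measurement point {k + 1}")
        bad = np.argwhere(self.interval_costs < 0)
        if bad.size:
            i, k = bad[0]
            raise ValueError(
                f"negative cost for patient {self.patient_ids[i]!r} "
                f"in interval {k + 2}")
        obs = ~np.isnan(self.group)
        if np.any((self.group[obs] != GROUP_LOW) & (self.group[obs] != GROUP_HIGH)):
            raise ValueError("group must be 0 (low), 1 (high) or NaN")

    def subset(self, idx: np.ndarray) -> "PanelDataset":
        """Row-subset (or resample: indices may repeat) by patient index."""
        idx = np.asarray(idx)
        return PanelDataset(
            patient_ids=self.patient_ids[idx],
            nominal_times=self.nominal_times.copy(),
            effectiveness=self.effectiveness[idx],
            interval_costs=self.interval_costs[idx],
            group_score=self.group_score[idx],
            group=self.group[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            actual_times=None if self.actual_times is None
            else self.actual_times[idx],
            strict=self.strict,
        )

    def copy(self) -> "PanelDataset":
        return self.subset(np.arange(self.n))

    def equals(self, other: "PanelDataset") -> bool:
        def _eq(a, b):
            return np.array_equal(np.asarray(a), np.asarray(b), equal_nan=True)

        return (
            np.array_equal(self.patient_ids.astype(str),
                           other.patient_ids.astype(str))
            and _eq(self.nominal_times, other.nominal_times)
            and _eq(self.effectiveness, other.effectiveness)
            and _eq(self.interval_costs, other.interval_costs)
            and _eq(self.group_score, other.group_score)
            and _eq(self.group, other.group)
            and self.covariates.reset_index(drop=True).equals(
                other.covariates.reset_index(drop=True))
        )


@dataclass
class DesignMatrices:
    """Design matrices for the repeated-measures and cumulative models.

    Repeated-measures rows exist for each patient x post-baseline
    measurement point (k = 2..K).  Column order is always: intercept,
    confounders (continuous as-is, categoricals dummy-coded against the
    reference level), measurement-point dummies (reference = first
    post-baseline point), group indicator; the effectiveness design
    additionally appends the baseline effectiveness column right after the
    confounders.  Cumulative rows (one per patient) omit the MP dummies.

    Missing covariate or group values propagate as NaN entries; consumers
    either drop or augment those rows.
    """

    z: np.ndarray            # (n, K-1, p_z) zero/positive cost part
    p: np.ndarray            # (n, K-1, p_z) positive cost magnitude part
    e: np.ndarray            # (n, K-1, p_e) effectiveness part
    cum_cost: np.ndarray     # (n, p_c)
    cum_eff: np.ndarray      # (n, p_ec)
    cols_z: list[str]
    cols_e: list[str]
    cols_cum_cost: list[str]
    cols_cum_eff: list[str]
    times: np.ndarray        # (K-1,) months of the post-baseline MPs

    @property
    def cols_p(self) -> list[str]:
        return self.cols_z

    def group_col(self, which: str) -> int:
        cols = {"z": self.cols_z, "p": self.cols_z, "e": self.cols_e,
                "cum_cost": self.cols_cum_cost,
                "cum_eff": self.cols_cum_eff}[which]
        return cols.index("group")


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

#: Canonical long-format column names.
LONG_COLUMNS = ("patient_id", "mp", "time", "effectiveness", "cost")

_NA = ["", "NA"]


def _default_schema(schema: dict | None) -> dict:
    out = {
        "format": "long",
        "patient_id": "patient_id",
        "mp": "mp",
        "time": "time",
        "effectiveness": "effectiveness",
        "cost": "cost",
        "group_score": "group_score",
        "covariates": None,       # None = every remaining column
        "categorical": (),
        "strict": True,           # reject negative effectiveness on read
    }
    if schema:
        out.update(schema)
    return out


def read_panel(path, schema: dict | None = None) -> PanelDataset:
    """Read a panel CSV in the canonical long dialect or the wide dialect.

    Long format (canonical): one row per patient x measurement point with
    columns ``patient_id, mp, time, effectiveness, cost`` (cost refers to
    the interval ending at ``mp``; empty at mp 1) plus per-patient columns
    (group score, confounders) repeated on every row or filled only on the
    mp-1 row.  Wide format: one row per patient with ``eff_1..eff_K``,
    ``cost_2..cost_K`` and a ``time_k`` header mapping.

    Missing cells are empty or the literal ``NA``.
    """
    sch = _default_schema(schema)
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False)
    if sch["format"] == "long":
        return _from_long(df, sch)
    if sch["format"] == "wide":
        return _from_wide(df, sch)
    raise ValueError(f"unknown panel format {sch['format']!r}")


def _covariate_frame(base: pd.DataFrame, sch: dict) -> pd.DataFrame:
    reserved = {sch["patient_id"], sch["mp"], sch["time"],
                sch["effectiveness"], sch["cost"], sch["group_score"]}
    names = sch["covariates"]
    if names is None:
        names = [c for c in base.columns if c not in reserved]
    missing = [c for c in names if c not in base.columns]
    if missing:
        raise ValueError(f"unknown covariate column(s): {missing}")
    cov = base[list(names)].reset_index(drop=True)
    for c in sch["categorical"]:
        if c in cov.columns:
            cov[c] = cov[c].astype(object)
    return cov


def _from_long(df: pd.DataFrame, sch: dict) -> PanelDataset:
    for role in ("patient_id", "mp", "effectiveness"):
        if sch[role] not in df.columns:
            raise ValueError(f"missing required column {sch[role]!r}")
    pid_col, mp_col = sch["patient_id"], sch["mp"]
    mps = np.sort(df[mp_col].unique())
    K = len(mps)
    if not np.array_equal(mps, np.arange(1, K + 1)):
        raise ValueError("measurement points must be labelled 1..K")
    # preserve first-appearance patient order
    pids = df[pid_col].drop_duplicates().to_numpy()
    index = {p: i for i, p in enumerate(pids)}
    n = len(pids)

    eff = np.full((n, K), np.nan)
    cost = np.full((n, K - 1), np.nan)
    times = np.full(K, np.nan)
    rows_i = df[pid_col].map(index).to_numpy()
    rows_k = df[mp_col].to_numpy(int) - 1
    if sch["time"] in df.columns:
        for k, t in zip(rows_k, df[sch["time"]].to_numpy(float)):
            if not np.isnan(t):
                times[k] = t
    else:
        times = np.arange(K, dtype=float)
    eff[rows_i, rows_k] = df[sch["effectiveness"]].to_numpy(float)
    if sch["cost"] in df.columns:
        cvals = df[sch["cost"]].to_numpy(float)
        post = rows_k >= 1
        cost[rows_i[post], rows_k[post] - 1] = cvals[post]

    base = df.sort_values(mp_col).groupby(pid_col, sort=False).first()
    base = base.loc[pids].reset_index()
    gs = (base[sch["group_score"]].to_numpy(float)
          if sch["group_score"] in base.columns else np.full(n, np.nan))
    _check_nonneg(eff, cost, pids, sch["strict"])
    return PanelDataset(
        patient_ids=pids, nominal_times=times, effectiveness=eff,
        interval_costs=cost, group_score=gs, group=np.full(n, np.nan),
        covariates=_covariate_frame(base, sch), strict=sch["strict"])


def _from_wide(df: pd.DataFrame, sch: dict) -> PanelDataset:
    pid_col = sch["patient_id"]
    eff_cols = sorted([c for c in df.columns if c.startswith("eff_")],
                      key=lambda c: int(c.split("_")[1]))
    cost_cols = sorted([c for c in df.columns if c.startswith("cost_")],
                       key=lambda c: int(c.split("_")[1]))
    K = len(eff_cols)
    if K < 2 or len(cost_cols) != K - 1:
        raise ValueError("wide format needs eff_1..eff_K and cost_2..cost_K")
    times = np.asarray(sch.get("times", np.arange(K)), dtype=float)
    pids = df[pid_col].to_numpy()
    eff = df[eff_cols].to_numpy(float)
    cost = df[cost_cols].to_numpy(float)
    gs = (df[sch["group_score"]].to_numpy(float)
          if sch["group_score"] in df.columns else np.full(len(df), np.nan))
    sch2 = dict(sch)
    if sch2["covariates"] is None:
        reserved = {pid_col, sch["group_score"]} | set(eff_cols) | set(cost_cols)
        sch2["covariates"] = [c for c in df.columns if c not in reserved]
    _check_nonneg(eff, cost, pids, sch["strict"])
    return PanelDataset(
        patient_ids=pids, nominal_times=times, effectiveness=eff,
        interval_costs=cost, group_score=gs,
        group=np.full(len(df), np.nan),
        covariates=_covariate_frame(df, sch2), strict=sch["strict"])


def _check_nonneg(eff, cost, pids, strict=True):
    if strict:
        bad = np.argwhere(eff < 0)
        if bad.size:
            i, k = bad[0]
            raise ValueError(f"negative effectiveness for patient {pids[i]!r} "
                             f"at measurement point {k + 1}")
    bad = np.argwhere(cost < 0)
    if bad.size:
        i, k = bad[0]
        raise ValueError(f"negative cost for patient {pids[i]!r} "
                         f"in interval {k + 2}")


def write_panel(ds: PanelDataset, path) -> None:
    """Write the canonical long-format CSV (inverse of :func:`read_panel`)."""
    rows = []
    for i in range(ds.n):
        for k in range(ds.K):
            row = {
                "patient_id": ds.patient_ids[i],
                "mp": k + 1,
                "time": ds.nominal_times[k],
                "effectiveness": ds.effectiveness[i, k],
                "cost": np.nan if k == 0 else ds.interval_costs[i, k - 1],
                "group_score": ds.group_score[i],
            }
            for c in ds.covariates.columns:
                row[c] = ds.covariates.iloc[i][c]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Grouping and design construction
# ---------------------------------------------------------------------------

def dichotomize_group(ds: PanelDataset, threshold: float = 4.0) -> PanelDataset:
    """Split patients at ``threshold`` on the continuous grouping score.

    ``group_score >= threshold`` maps to high (1), ``< threshold`` to low
    (0); missing scores stay missing.  Returns a new dataset.
    """
    group = np.where(np.isnan(ds.group_score), np.nan,
                     (ds.group_score >= threshold).astype(float))
    out = ds.copy()
    out.group = group
    return out


def group_counts(ds: PanelDataset) -> dict:
    return {
        "low": int(np.nansum(ds.group == GROUP_LOW)),
        "high": int(np.nansum(ds.group == GROUP_HIGH)),
        "missing": int(np.isnan(ds.group).sum()),
    }


def _dummy_code(cov: pd.DataFrame, categorical: list[str],
                reference: dict[str, object]) -> tuple[np.ndarray, list[str]]:
    blocks, names = [], []
    for c in cov.columns:
        col = cov[c]
        if c in categorical or col.dtype == object or isinstance(
                col.dtype, pd.CategoricalDtype):
            levels = [v for v in pd.unique(col.dropna())]
            ref = reference.get(c)
            if ref is None:
                ref = col.value_counts().idxmax()  # most frequent = reference
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} absent from column {c!r}")
            for lev in levels:
                if lev == ref:
                    continue
                blocks.append((col == lev).astype(float).to_numpy())
                names.append(f"{c}[{lev}]")
        else:
            blocks.append(col.to_numpy(float))
            names.append(c)
    if not blocks:
        return np.empty((len(cov), 0)), []
    return np.column_stack(blocks), names


def build_design(
    ds: PanelDataset,
    confounders: list[str],
    categorical: list[str] | None = None,
    reference: dict[str, object] | None = None,
    baseline_adjustment: bool = True,
) -> DesignMatrices:
    """Build all design matrices used by the three analysis strategies.

    ``confounders`` are baseline covariate columns entering every model;
    the baseline effectiveness score enters the effectiveness designs only
    (``baseline_adjustment``).  Categorical confounders are dummy-coded
    against ``reference`` (default: the most frequent level).
    """
    categorical = list(categorical or ())
    reference = dict(reference or {})
    missing_cols = [c for c in confounders if c not in ds.covariates.columns]
    if missing_cols:
        raise ValueError(f"unknown confounder column(s): {missing_cols}")
    cov = ds.covariates[list(confounders)]
    conf_mat, conf_names = _dummy_code(cov, categorical, reference)

    n, K = ds.n, ds.K
    nmp = K - 1
    intercept = np.ones((n, 1))
    group = ds.group[:, None]
    base_eff = ds.effectiveness[:, [0]]

    # cumulative rows: intercept + confounders (+ baseline eff) + group
    cum_cost = np.hstack([intercept, conf_mat, group])
    cols_cum_cost = ["intercept", *conf_names, "group"]
    if baseline_adjustment:
        cum_eff = np.hstack([intercept, conf_mat, base_eff, group])
        cols_cum_eff = ["intercept", *conf_names, "baseline_eff", "group"]
    else:
        cum_eff = cum_cost.copy()
        cols_cum_eff = list(cols_cum_cost)

    # repeated-measures rows: add MP dummies (reference = first
    # post-baseline measurement point)
    mp_names = [f"mp{k + 2}" for k in range(1, nmp)]
    cols_z = ["intercept", *conf_names, *mp_names, "group"]
    cols_e = ["intercept", *conf_names]
    if baseline_adjustment:
        cols_e.append("baseline_eff")
    cols_e += [*mp_names, "group"]

    z = np.empty((n, nmp, len(cols_z)))
    e = np.empty((n, nmp, len(cols_e)))
    for j in range(nmp):
        mp_dum = np.zeros((n, nmp - 1))
        if j >= 1:
            mp_dum[:, j - 1] = 1.0
        z[:, j, :] = np.hstack([intercept, conf_mat, mp_dum, group])
        blocks = [intercept, conf_mat]
        if baseline_adjustment:
            blocks.append(base_eff)
        blocks += [mp_dum, group]
        e[:, j, :] = np.hstack(blocks)

    return DesignMatrices(
        z=z, p=z.copy(), e=e, cum_cost=cum_cost, cum_eff=cum_eff,
        cols_z=cols_z, cols_e=cols_e, cols_cum_cost=cols_cum_cost,
        cols_cum_eff=cols_cum_eff, times=ds.nominal_times[1:].copy())


# ---------------------------------------------------------------------------
# Descriptive table
# ---------------------------------------------------------------------------

def missingness_table(ds: PanelDataset) -> pd.DataFrame:
    """Per-variable x measurement-point x group descriptive statistics.

    One row per cell with the observed mean and SD, the count of observed
    zeros (``n_zero``, costs only) and the count of missing values
    (``n_missing``) — the layout of a standard panel descriptive table.
    Requires the dichotomized group; patients with missing group are
    excluded (their count is reported in the attrs).
    """
    if np.all(np.isnan(ds.group)):
        raise ValueError("dichotomized group required; run dichotomize_group")
    rows = []
    for gval, gname in ((GROUP_LOW, "low"), (GROUP_HIGH, "high")):
        sel = ds.group == gval
        for k in range(1, ds.K):
            x = ds.effectiveness[sel, k]
            rows.append(_cell("effectiveness", f"{ds.nominal_times[k]:g}",
                              gname, x, count_zeros=False))
        for k in range(ds.K - 1):
            lab = f"{ds.nominal_times[k]:g}-{ds.nominal_times[k + 1]:g}"
            rows.append(_cell("cost", lab, gname, ds.interval_costs[sel, k],
                              count_zeros=True))
    out = pd.DataFrame(rows)
    out.attrs["n_missing_group"] = int(np.isnan(ds.group).sum())
    return out


def _cell(var, month, group, x, count_zeros):
    obs = x[~np.isnan(x)]
    return {
        "variable": var,
        "month": month,
        "group": group,
        "mean": float(np.mean(obs)) if obs.size else np.nan,
        "sd": float(np.std(obs, ddof=1)) if obs.size > 1 else np.nan,
        "n_zero": int((obs == 0).sum()) if count_zeros else 0,
        "n_missing": int(np.isnan(x).sum()),
        "n_obs": int(obs.size),
    }
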