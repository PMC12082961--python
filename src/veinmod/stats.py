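"""Cohort aggregation and inferential statistics.

Per-participant means over the three repetitions feed a paired t-test on the
band log-powers (PB10 vs PB3), a one-way repeated-measures ANOVA on the
50-s baselines across the three breathing conditions, and Bonferroni-
adjusted pairwise paired t-tests.  Sphericity is assumed (no
Greenhouse-Geisser correction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DegenerateTestError, MissingCellError
from .types import Condition

__all__ = ["TestResult", "make_cohort_table", "aggregate_repetitions",
           "paired_t", "rm_anova", "bonferroni_pairwise", "report",
           "write_report"]

#: Canonical condition order for matrices and pairwise labels.
CONDITION_ORDER = [Condition.SB, Condition.PB3, Condition.PB10]


@dataclass
class TestResult:
    """A single test outcome; ``df`` is a tuple for the ANOVA F-test."""

    statistic: float
    df: float | tuple[int, int]
    p_value: float
    adjusted_p: float | None = None
    comparison: str = ""

    def as_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["df"], tuple):
            d["df"] = list(d["df"])
        return d


def make_cohort_table(rows) -> pd.DataFrame:
    """Build the long-format cohort table.

    ``rows``: iterable of dicts with keys participant, condition, repetition,
    baseline_mm and (for paced conditions) log_power.
    """
    df = pd.DataFrame(rows)
    required = {"participant", "condition", "repetition", "baseline_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"cohort table missing columns: {sorted(missing)}")
    if "log_power" not in df.columns:
        df["log_power"] = np.nan
    df["condition"] = [Condition.coerce(c).value for c in df["condition"]]
    counts = df.groupby(["participant", "condition"])["repetition"].count()
    if (counts > 3).any():
        raise ConfigError("more than 3 repetitions in a (participant, condition) cell")
    return df


def aggregate_repetitions(table: pd.DataFrame,
                          measures=("baseline_mm", "log_power")) -> pd.DataFrame:
    """Average the repetitions within each (participant, condition) cell.

    Every participant must have at least one repetition of every condition
    present in the table; empty cells raise ``MissingCellError`` naming them.
    """
    participants = sorted(table["participant"].unique())
    conditions = [c.value for c in CONDITION_ORDER
                  if c.value in set(table["condition"])]
    present = set(zip(table["participant"], table["condition"]))
    empty = [(p, c) for p in participants for c in conditions
             if (p, c) not in present]
    if empty:
        raise MissingCellError(empty)
    keep = [m for m in measures if m in table.columns]
    agg = (table.groupby(["participant", "condition"], as_index=False)[keep]
           .mean())
    agg["condition"] = pd.Categorical(agg["condition"], categories=conditions,
                                      ordered=True)
    return agg.sort_values(["participant", "condition"]).reset_index(drop=True)


def _condition_matrix(agg: pd.DataFrame, measure: str, conditions) -> np.ndarray:
    wide = agg.pivot(index="participant", columns="condition", values=measure)
    wide = wide[[c for c in conditions]]
    if wide.isna().any().any():
        cells = [(p, c) for p, c in zip(*np.where(wide.isna().to_numpy()))]
        raise MissingCellError(cells)
    return wide.to_numpy(dtype=float)


def paired_t(x, y, comparison: str = "") -> TestResult:
    """Two-sided paired t-test on per-participant values.

    t = mean(d) / (sd(d)/sqrt(n)) on the differences d = x - y with the
    n-1-denominator SD; p from the t distribution with n-1 df.  Differences
    with zero variance leave the statistic undefined and raise
    ``DegenerateTestError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("paired samples must be equal-length vectors")
    n = x.size
    if n < 2:
        raise ConfigError("need at least 2 pairs")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateTestError("zero-variance differences: t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return TestResult(t, n - 1, p, comparison=comparison)


def rm_anova(matrix) -> TestResult:
    """One-way repeated-measures ANOVA on an n x k within-subject matrix.

    SS_total decomposes into SS_subjects + SS_conditions + SS_error;
    F = MS_conditions / MS_error with df (k-1, (n-1)(k-1)).  If the error
    mean square is exactly zero, F = 0 when there is no condition effect,
    otherwise the test is degenerate.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ConfigError("matrix must be n>=2 participants x k>=2 conditions")
    if np.isnan(X).any():
        cells = [tuple(map(int, rc)) for rc in np.argwhere(np.isnan(X))]
        raise MissingCellError(cells)
    n, k = X.shape
    grand = X.mean()
    ss_total = float(((X - grand) ** 2).sum())
    ss_subj = float(k * ((X.mean(axis=1) - grand) ** 2).sum())
    ss_cond = float(n * ((X.mean(axis=0) - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_cond
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0.0:
        if ss_cond <= 1e-300:
            return TestResult(0.0, (df_cond, df_err), 1.0, comparison="rm_anova")
        raise DegenerateTestError("zero error mean square with non-zero effect")
    f = (ss_cond / df_cond) / ms_err
    p = float(sps.f.sf(f, df_cond, df_err))
    return TestResult(float(f), (df_cond, df_err), p, comparison="rm_anova")


def bonferroni_pairwise(matrix, labels=None) -> list[TestResult]:
    """All pairwise paired t-tests with Bonferroni-adjusted p-values.

    For k conditions there are m = k(k-1)/2 comparisons and
    adjusted_p = min(1, m * p).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ConfigError("matrix must be n x k with k >= 2")
    k = X.shape[1]
    labels = labels or [f"c{j}" for j in range(k)]
    m = k * (k - 1) // 2
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            res = paired_t(X[:, i], X[:, j],
                           comparison=f"{labels[i]} vs {labels[j]}")
            res.adjusted_p = min(1.0, m * res.p_value)
            results.append(res)
    return results


def report(table: pd.DataFrame, ensembles: dict | None = None) -> dict:
    """Full study report from a long-format cohort table.

    Repetitions are averaged per cell first.  Baselines are summarised as
    mean +/- standard error per condition (the figure convention for the
    baseline comparison) and tested with the repeated-measures ANOVA plus
    Bonferroni pairwise tests; band log-powers are summarised as mean +/- SD
    and the paced conditions compared with a paired t-test.  ``ensembles``
    may supply per-condition ensemble mean traces; their linear-trend r^2 is
    then included.
    """
    from .timeseries import linear_trend_r2   # local import to avoid a cycle

    table = make_cohort_table(table.to_dict("records")) \
        if isinstance(table, pd.DataFrame) else make_cohort_table(table)
    agg = aggregate_repetitions(table)
    conditions = [c for c in agg["condition"].cat.categories]

    out: dict = {"n_participants": int(agg["participant"].nunique()),
                 "conditions": conditions}

    base = {}
    for cond in conditions:
        v = agg.loc[agg["condition"] == cond, "baseline_mm"].to_numpy(float)
        base[cond] = {"mean_mm": float(v.mean()),
                      "se_mm": float(v.std(ddof=1) / np.sqrt(v.size)),
                      "sd_mm": float(v.std(ddof=1)),
                      "n": int(v.size)}
    out["baseline"] = base

    logp = {}
    for cond in conditions:
        v = agg.loc[agg["condition"] == cond, "log_power"].to_numpy(float)
        if np.isnan(v).all():
            continue
        logp[cond] = {"mean": float(np.nanmean(v)),
                      "sd": float(np.nanstd(v, ddof=1)),
                      "n": int(np.sum(~np.isnan(v)))}
    out["band_log_power"] = logp

    def _safe(callable_, *args, **kw):
        try:
            return callable_(*args, **kw)
        except DegenerateTestError as exc:
            return str(exc)

    Xb = _condition_matrix(agg, "baseline_mm", conditions)
    anova = _safe(rm_anova, Xb)
    out["rm_anova_baseline"] = (anova.as_dict()
                                if isinstance(anova, TestResult)
                                else {"degenerate": anova})
    try:
        pairwise = bonferroni_pairwise(Xb, labels=conditions)
        out["bonferroni_baseline"] = [r.as_dict() for r in pairwise]
    except DegenerateTestError as exc:
        out["bonferroni_baseline"] = {"degenerate": str(exc)}

    paced = [c for c in (Condition.PB10.value, Condition.PB3.value) if c in logp]
    if len(paced) == 2:
        wide = agg.pivot(index="participant", columns="condition",
                         values="log_power")
        tt = _safe(paired_t, wide[paced[0]].to_numpy(float),
                   wide[paced[1]].to_numpy(float),
                   comparison=f"{paced[0]} vs {paced[1]} log power")
        out["paired_t_log_power"] = (tt.as_dict() if isinstance(tt, TestResult)
                                     else {"degenerate": tt})

    if ensembles:
        trend = {}
        for cond, ens in ensembles.items():
            mean_trace = getattr(ens, "mean_trace", ens)
            tr = linear_trend_r2(mean_trace)
            trend[str(cond)] = {"slope_mm_s": tr.slope,
                                "intercept_mm": tr.intercept,
                                "r2": tr.r2}
        out["ensemble_trend"] = trend
    return out


def write_report(rep: dict, table: pd.DataFrame, out_dir,
                 ensembles: dict | None = None) -> Path:
    """Persist the report bundle: report.json, cohort.csv, ensemble CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(json.dumps(rep, indent=2, sort_keys=True))
    table.to_csv(out_dir / "cohort.csv", index=False)
    if ensembles:
        for cond, ens in ensembles.items():
            if hasattr(ens, "to_csv"):
                ens.to_csv(out_dir / f"ensemble_{cond}.csv")
    return path
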