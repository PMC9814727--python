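"""Benchmark statistics: accuracy metrics, bootstrap errors, bias traces.

Calculated ΔG values are compared against a reference (typically
experiment) with AUE, RMSE and rank/linear correlations. Metric
uncertainties combine non-parametric resampling of the systems with
parametric perturbation of each calculated ΔG by its own standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BenchmarkTable",
    "accuracy_metrics",
    "bootstrap_metric_se",
    "bias_trace",
    "method_matrix",
]

METRICS = ("aue", "rmse", "pearson", "spearman", "kendall")


@dataclass(frozen=True)
class BenchmarkTable:
    """Per-system calculated ΔG, uncertainty and reference value.

    ``data`` must have columns ``system``, ``dg_calc``, ``dg_ref`` and
    optionally ``se_calc``; extra numeric columns may hold time-resolved
    estimates for :func:`bias_trace`. Units are uniform within a table.
    """

    data: pd.DataFrame
    unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        df = self.data
        for col in ("system", "dg_calc", "dg_ref"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if df["system"].duplicated().any():
            dupes = sorted(df.loc[df["system"].duplicated(), "system"].unique().tolist())
            raise ValueError(f"duplicate system ids: {dupes}")
        if "se_calc" in df.columns and (df["se_calc"] < 0).any():
            raise ValueError("se_calc must be non-negative")

    @classmethod
    def from_arrays(cls, systems, dg_calc, dg_ref, se_calc=None, unit="kcal/mol"):
        df = pd.DataFrame({"system": systems, "dg_calc": dg_calc, "dg_ref": dg_ref})
        if se_calc is not None:
            df["se_calc"] = se_calc
        return cls(df, unit=unit)

    def __len__(self) -> int:
        return len(self.data)


def _metrics_from_vectors(calc: np.ndarray, ref: np.ndarray) -> dict:
    diff = calc - ref
    out = {
        "n": int(calc.size),
        "aue": float(np.mean(np.abs(diff))),
        "rmse": float(np.sqrt(np.mean(diff**2))),
    }
    degenerate = calc.size < 2 or np.all(calc == calc[0]) or np.all(ref == ref[0])
    out["correlations_defined"] = not degenerate
    if degenerate:
        out["pearson"] = out["spearman"] = out["kendall"] = float("nan")
    else:
        out["pearson"] = float(stats.pearsonr(calc, ref).statistic)
        out["spearman"] = float(stats.spearmanr(calc, ref).statistic)
        # variant="b" is scipy's default tau: tie-corrected
        out["kendall"] = float(stats.kendalltau(calc, ref, variant="b").statistic)
    return out


def accuracy_metrics(table: BenchmarkTable) -> dict:
    """AUE, RMSE and Pearson/Spearman/Kendall τ-b of calc vs reference.

    Spearman uses average ranks for ties; Kendall is the tie-corrected
    τ-b. When either vector is constant the correlations are undefined and
    reported as NaN with ``correlations_defined=False`` (not an exception).
    """
    if len(table) < 1:
        raise ValueError("at least one row required")
    calc = table.data["dg_calc"].to_numpy(dtype=float)
    ref = table.data["dg_ref"].to_numpy(dtype=float)
    out = _metrics_from_vectors(calc, ref)
    out["unit"] = table.unit
    return out


def bootstrap_metric_se(
    table: BenchmarkTable,
    metric: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Combined parametric + non-parametric bootstrap error of a metric.

    Each iteration resamples systems with replacement, then perturbs every
    drawn dg_calc by a normal draw centred on it with sd equal to its
    se_calc, and recomputes the metric. Returns the point estimate on the
    original table and the sd (ddof=1) across iterations. Iterations where
    a correlation is undefined (constant resample) are discarded; more than
    20% discards is an error.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    df = table.data
    if "se_calc" not in df.columns:
        raise ValueError("se_calc column required for parametric bootstrap")
    calc = df["dg_calc"].to_numpy(dtype=float)
    ref = df["dg_ref"].to_numpy(dtype=float)
    se = df["se_calc"].to_numpy(dtype=float)
    n = calc.size
    point = accuracy_metrics(table)[metric]

    rng = np.random.default_rng(seed)
    values = []
    discarded = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        c = rng.normal(calc[idx], se[idx])
        r = ref[idx]
        m = _metrics_from_vectors(c, r)
        v = m[metric]
        if np.isnan(v):
            discarded += 1
            continue
        values.append(v)
    if discarded > 0.2 * n_boot:
        raise RuntimeError(
            f"{discarded}/{n_boot} bootstrap iterations produced an undefined metric"
        )
    return float(point), float(np.std(values, ddof=1))


def bias_trace(
    table: pd.DataFrame,
    time_columns: list | None = None,
) -> list[tuple[float, float]]:
    """Mean unsigned deviation of time-resolved ΔG from the final estimate.

    *table* is indexed (or keyed by a ``system`` column) with one numeric
    column per sampling time; ``time_columns`` defaults to all numeric
    column labels sorted ascending. Returns ``[(time, bias)]`` with

        bias(τ) = mean over systems of |ΔG(τ) − ΔG(T_final)|

    so the final point is exactly 0. Missing values are an error naming the
    offending cell.
    """
    df = table
    if "system" in df.columns:
        df = df.set_index("system")
    if time_columns is None:
        time_columns = sorted((c for c in df.columns), key=float)
    if len(time_columns) < 2:
        raise ValueError("at least two time points required")
    for col in time_columns:
        bad = df.index[df[col].isna()].tolist()
        if bad:
            raise ValueError(f"missing value at (system={bad[0]!r}, time={col!r})")
    final = df[time_columns[-1]].to_numpy(dtype=float)
    trace = []
    for col in time_columns:
        bias = float(np.mean(np.abs(df[col].to_numpy(dtype=float) - final)))
        trace.append((float(col), bias))
    return trace


def method_matrix(tables: dict[str, BenchmarkTable]) -> dict[str, pd.DataFrame]:
    """Pairwise AUE and Pearson matrices across methods sharing system ids.

    ``tables`` maps method name → BenchmarkTable; all tables must cover the
    same system ids. Returns ``{"aue": DataFrame, "pearson": DataFrame}``
    symmetric matrices (diagonal AUE 0, Pearson 1).
    """
    if len(tables) < 2:
        raise ValueError("at least two methods required")
    names = list(tables)
    id_sets = {name: set(t.data["system"]) for name, t in tables.items()}
    common = set.intersection(*id_sets.values())
    union = set.union(*id_sets.values())
    if common != union:
        missing = sorted(str(s) for s in union - common)
        raise ValueError(f"system ids not shared by all methods: {missing}")
    vectors = {}
    for name, t in tables.items():
        df = t.data.set_index("system").loc[sorted(common, key=str)]
        vectors[name] = df["dg_calc"].to_numpy(dtype=float)
    aue = pd.DataFrame(0.0, index=names, columns=names)
    pearson = pd.DataFrame(1.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            m = _metrics_from_vectors(vectors[a], vectors[b])
            aue.loc[a, b] = aue.loc[b, a] = m["aue"]
            pearson.loc[a, b] = pearson.loc[b, a] = m["pearson"]
    return {"aue": aue, "pearson": pearson}
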