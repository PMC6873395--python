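"""Real-vs-simulated fidelity protocol.

Three families of metrics are compared between a real and a simulated table:

* sparsity — percentage of exact zeros, overall, per feature, per sample and
  per group submatrix;
* intensity — normalised counts averaged over the replicates of each group;
* variability — within-group variance and relative variance (variance/mean).

For each group and metric the per-feature value distributions of the two
tables are compared with a two-sided Mann-Whitney U test, its rank-biserial
effect size r = 1 - 2U/(n1*n2), and a bootstrap procedure that repeats the
test on many small random feature subsets (by default 10000 subsets of 5% of
the features) and reports the fraction of significant outcomes. The bootstrap
decouples the verdict from the huge number of features, where even trivial
differences reach significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, TableFormatError
from .estimation import EstimatorConfig, GroupedCountTable, normalize_counts

__all__ = [
    "SparsitySummary",
    "EvalReport",
    "sparsity_metrics",
    "intensity_metrics",
    "variability_metrics",
    "rank_biserial",
    "compare_tables",
    "effect_size_label",
]

METRICS = ("intensity", "variance")


@dataclass(frozen=True)
class SparsitySummary:
    """Zero-count percentages at every granularity; all values in [0, 100]."""

    total: float
    per_row: np.ndarray
    per_col: np.ndarray
    per_group: dict[str, float]


def sparsity_metrics(table: GroupedCountTable) -> SparsitySummary:
    """Percentage of exactly-zero entries overall, per row/column and per group."""
    zeros = table.counts == 0
    per_group = {
        g: 100.0 * zeros[:, table.columns_of(g)].mean() for g in table.group_labels
    }
    return SparsitySummary(
        total=100.0 * zeros.mean(),
        per_row=100.0 * zeros.mean(axis=1),
        per_col=100.0 * zeros.mean(axis=0),
        per_group=per_group,
    )


def intensity_metrics(
    table: GroupedCountTable, config: EstimatorConfig | None = None
) -> pd.DataFrame:
    """Per-feature mean of normalised counts within each group.

    Zero-mean features are legitimate entries (value 0); distribution-level
    summaries exclude them downstream.
    """
    config = config or EstimatorConfig()
    normalized = normalize_counts(table, config)
    data = {
        g: normalized[:, table.columns_of(g)].mean(axis=1) for g in table.group_labels
    }
    return pd.DataFrame(data, index=list(table.feature_ids))


def variability_metrics(
    table: GroupedCountTable, config: EstimatorConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-group variance and relative variance of normalised counts.

    Returns ``(variance, relative_variance)`` frames (features x groups).
    Groups with a single replicate have undefined variance (NaN, never 0);
    relative variance is NaN wherever the group mean is zero.
    """
    config = config or EstimatorConfig()
    normalized = normalize_counts(table, config)
    var = {}
    rv = {}
    for g in table.group_labels:
        cols = table.columns_of(g)
        sub = normalized[:, cols]
        if cols.size < 2:
            v = np.full(table.n_features, np.nan)
        else:
            v = sub.var(axis=1, ddof=1)
        mean = sub.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(mean > 0, v / mean, np.nan)
        var[g] = v
        rv[g] = r
    index = list(table.feature_ids)
    return pd.DataFrame(var, index=index), pd.DataFrame(rv, index=index)


def rank_biserial(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U p-value and rank-biserial r = 1 - 2U/(n1*n2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return np.nan, np.nan
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    r = 1.0 - 2.0 * float(res.statistic) / (x.size * y.size)
    return float(res.pvalue), r


def effect_size_label(r: float) -> str:
    a = abs(r)
    if np.isnan(a):
        return "undefined"
    if a < 0.1:
        return "negligible"
    if a < 0.3:
        return "small"
    if a < 0.5:
        return "medium"
    return "large"


def _tie_term(row: np.ndarray) -> float:
    _, counts = np.unique(row, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def _bootstrap_mwu(
    x: np.ndarray,
    y: np.ndarray,
    n_iter: int,
    subset_size: int,
    alpha: float,
    rng: np.random.Generator,
) -> float:
    """Fraction of MWU tests significant over random paired feature subsets.

    Each iteration draws ``subset_size`` feature indices without replacement,
    takes the corresponding values from both tables and runs a two-sided MWU
    (normal approximation with tie correction and continuity correction —
    standard at these subset sizes). Vectorised across iterations.
    """
    n = x.size
    k = min(subset_size, n)
    if k < 2:
        return np.nan
    idx = np.empty((n_iter, k), dtype=np.intp)
    for b in range(n_iter):
        idx[b] = rng.choice(n, size=k, replace=False)
    xy = np.concatenate([x[idx], y[idx]], axis=1)  # (n_iter, 2k)
    ranks = stats.rankdata(xy, axis=1)
    u1 = ranks[:, :k].sum(axis=1) - k * (k + 1) / 2.0
    n_tot = 2 * k
    mean_u = k * k / 2.0
    base_var = k * k * (n_tot + 1) / 12.0
    # tie correction only where ties actually occur
    s = np.sort(xy, axis=1)
    has_ties = np.any(s[:, 1:] == s[:, :-1], axis=1)
    tie = np.zeros(n_iter)
    if np.any(has_ties):
        for b in np.flatnonzero(has_ties):
            tie[b] = _tie_term(xy[b])
    var_u = base_var - k * k * tie / (12.0 * n_tot * (n_tot - 1))
    sd = np.sqrt(var_u)
    z = np.zeros(n_iter)
    ok = sd > 0
    z[ok] = (np.abs(u1[ok] - mean_u) - 0.5) / sd[ok]
    z = np.maximum(z, 0.0)
    p = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    p[~ok] = 1.0
    return float(np.mean(p < alpha))


def _qq_r_squared(a: np.ndarray, b: np.ndarray, n_quantiles: int = 101) -> float:
    """R^2 of the quantile-quantile relation between two value sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    q = np.linspace(0.0, 1.0, n_quantiles)
    qa = np.quantile(a, q)
    qb = np.quantile(b, q)
    if np.std(qa) == 0 or np.std(qb) == 0:
        return np.nan
    return float(np.corrcoef(qa, qb)[0, 1] ** 2)


@dataclass
class EvalReport:
    """Aggregated output of :func:`compare_tables`.

    ``tests`` is a tidy frame with one row per (group, metric): MWU p-value,
    rank-biserial effect size, its magnitude label and the bootstrap fraction
    of significant subsets. Metric frames are keyed ``"real"``/``"sim"``.
    """

    total_sparsity: dict[str, float]
    group_sparsity: pd.DataFrame
    row_sparsity: dict[str, np.ndarray]
    col_sparsity: dict[str, np.ndarray]
    group_mean_intensity: dict[str, pd.DataFrame]
    group_variance: dict[str, pd.DataFrame]
    group_rv: dict[str, pd.DataFrame]
    tests: pd.DataFrame
    r_squared: dict[str, float]


def compare_tables(
    real: GroupedCountTable,
    sim: GroupedCountTable,
    config: EstimatorConfig | None = None,
    *,
    seed: int = 0,
    n_bootstrap: int = 10_000,
    bootstrap_fraction: float = 0.05,
    alpha: float = 0.05,
) -> EvalReport:
    """Run the full real-vs-simulated comparison protocol.

    The two tables must have the same number of features and the same set of
    group labels (replicate counts may differ). Zero-mean features are
    excluded from the intensity/variability distributions, mirroring the
    usual presentation of such comparisons; the bootstrap draws from features
    with a positive mean in both tables, with the subset size fixed at
    ``bootstrap_fraction`` of the *total* feature number.
    """
    config = config or EstimatorConfig()
    if real.n_features != sim.n_features:
        raise TableFormatError(
            f"feature count mismatch: real has {real.n_features}, "
            f"simulated has {sim.n_features}"
        )
    if set(real.group_labels) != set(sim.group_labels):
        raise TableFormatError(
            f"group labels differ: {sorted(real.group_labels)} vs "
            f"{sorted(sim.group_labels)}"
        )
    if not 0.0 < bootstrap_fraction <= 1.0:
        raise InvalidParameterError("bootstrap_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)

    sp_real = sparsity_metrics(real)
    sp_sim = sparsity_metrics(sim)
    groups = list(real.group_labels)
    group_sparsity = pd.DataFrame(
        {
            "real": [sp_real.per_group[g] for g in groups],
            "sim": [sp_sim.per_group[g] for g in groups],
        },
        index=groups,
    )

    intensity = {"real": intensity_metrics(real, config), "sim": intensity_metrics(sim, config)}
    var_real, rv_real = variability_metrics(real, config)
    var_sim, rv_sim = variability_metrics(sim, config)
    variance = {"real": var_real, "sim": var_sim}
    rv = {"real": rv_real, "sim": rv_sim}

    subset_size = max(2, int(round(bootstrap_fraction * real.n_features)))
    rows = []
    for g in groups:
        mean_r = intensity["real"][g].to_numpy()
        mean_s = intensity["sim"][g].to_numpy()
        for metric in METRICS:
            if metric == "intensity":
                vals_r, vals_s = mean_r, mean_s
            else:
                vals_r = variance["real"][g].to_numpy()
                vals_s = variance["sim"][g].to_numpy()
            ok_r = (mean_r > 0) & ~np.isnan(vals_r)
            ok_s = (mean_s > 0) & ~np.isnan(vals_s)
            p, r = rank_biserial(vals_r[ok_r], vals_s[ok_s])
            both = ok_r & ok_s
            if both.sum() >= 2 and not np.isnan(p):
                frac = _bootstrap_mwu(
                    vals_r[both], vals_s[both], n_bootstrap, subset_size, alpha, rng
                )
            else:
                frac = np.nan
            rows.append(
                {
                    "group": g,
                    "metric": metric,
                    "n_real": int(ok_r.sum()),
                    "n_sim": int(ok_s.sum()),
                    "mwu_pvalue": p,
                    "effect_size": r,
                    "effect_magnitude": effect_size_label(r),
                    "bootstrap_significant_fraction": frac,
                }
            )
    tests = pd.DataFrame(rows)

    gs = group_sparsity
    if len(groups) >= 2 and gs["real"].std() > 0 and gs["sim"].std() > 0:
        r2_group = float(np.corrcoef(gs["real"], gs["sim"])[0, 1] ** 2)
    else:
        r2_group = np.nan
    r_squared = {
        "group_sparsity": r2_group,
        "row_sparsity_qq": _qq_r_squared(sp_real.per_row, sp_sim.per_row),
        "col_sparsity_qq": _qq_r_squared(sp_real.per_col, sp_sim.per_col),
    }

    return EvalReport(
        total_sparsity={"real": sp_real.total, "sim": sp_sim.total},
        group_sparsity=group_sparsity,
        row_sparsity={"real": sp_real.per_row, "sim": sp_sim.per_row},
        col_sparsity={"real": sp_real.per_col, "sim": sp_sim.per_col},
        group_mean_intensity=intensity,
        group_variance=variance,
        group_rv=rv,
        tests=tests,
        r_squared=r_squared,
    )
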