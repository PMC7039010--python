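"""Pairwise association statistics and streaming association scans.

Pearson measures linear association, Spearman (Pearson on mean ranks)
monotone association. All pairwise statistics use pairwise-complete
observations: positions missing in either vector are dropped and the
reported ``n`` is the complete count. A correlation is undefined (error,
not r = 0) when fewer than 3 complete pairs remain or either vector is
constant on the complete subset.

Feature-vs-all scans stream the data file one row at a time through the
byte-offset index, so memory stays O(1) in the number of features.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import StatisticError
from .mi import mutual_information
from .project import ExpressionVector, GroupSelection, Project


@dataclass
class CorrelationResult:
    feature_a: str
    feature_b: str
    method: str
    r: float
    n: int
    p_raw: float
    p_adj: float | None = None


def _pair_values(x, y, name_a="x", name_b="y"):
    if isinstance(x, ExpressionVector):
        name_a = x.feature_id
        x = x.values
    if isinstance(y, ExpressionVector):
        name_b = y.feature_id
        y = y.values
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok], name_a, name_b


def _check_defined(x: np.ndarray, y: np.ndarray) -> None:
    if x.size < 3:
        raise StatisticError(f"need >= 3 pairwise-complete observations, have {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatisticError("correlation undefined for a constant vector")


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson r with the parametric two-sided p (t with n-2 df)."""
    xc, yc, na, nb = _pair_values(x, y)
    _check_defined(xc, yc)
    res = stats.pearsonr(xc, yc)
    return CorrelationResult(na, nb, "pearson", float(res.statistic), xc.size, float(res.pvalue))


def spearman(x, y) -> CorrelationResult:
    """Spearman r: Pearson on average-ranked data (ties get mean ranks)."""
    xc, yc, na, nb = _pair_values(x, y)
    _check_defined(xc, yc)
    rx = stats.rankdata(xc)
    ry = stats.rankdata(yc)
    _check_defined(rx, ry)  # ranks can be constant when all values tie
    res = stats.pearsonr(rx, ry)
    return CorrelationResult(na, nb, "spearman", float(res.statistic), xc.size, float(res.pvalue))


def _stat_for(method: str, x: np.ndarray, y: np.ndarray, mi_M: int, mi_k: int):
    """(statistic, n, p) for one pair; NaNs when undefined (< 3 complete pairs)."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if method == "mi":
        if n == 0:
            return np.nan, 0, np.nan
        res = mutual_information(x[ok], y[ok], mi_M, mi_k)
        return res.mi, n, np.nan
    if n < 3 or np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
        return np.nan, n, np.nan
    if method == "pearson":
        r = stats.pearsonr(x[ok], y[ok])
    else:
        r = stats.pearsonr(stats.rankdata(x[ok]), stats.rankdata(y[ok]))
    return float(r.statistic), n, float(r.pvalue)


def feature_vs_all(
    project: Project,
    feature_id: str,
    method: str = "pearson",
    samples: GroupSelection | None = None,
    mi_M: int = 10,
    mi_k: int = 3,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Associate one feature with every other feature, streaming rows.

    Returns a table (feature_a, feature_b, statistic, n, p_raw) sorted by
    descending statistic with ties broken by feature ID; the query feature
    itself is excluded. Features with fewer than 3 complete pairs are
    reported with a missing statistic, not dropped. Results are identical
    for any ``n_workers``; NaN statistics sort last.
    """
    if method not in ("pearson", "spearman", "mi"):
        raise ValueError(f"unknown method {method!r}")
    target = project.get_feature(feature_id)
    if samples is not None:
        tvals = target.subset(samples)
        sample_ids = samples.sample_ids
    else:
        tvals = target.values
        sample_ids = None
    others = [f for f in project.feature_ids if f != feature_id]

    def run_chunk(chunk: list[str]) -> list[tuple]:
        rows = []
        for vec in project.iter_features(chunk):
            vals = vec.subset(sample_ids) if sample_ids is not None else vec.values
            s, n, p = _stat_for(method, tvals, vals, mi_M, mi_k)
            rows.append((feature_id, vec.feature_id, s, n, p))
        return rows

    rows = _run_partitioned(others, run_chunk, n_workers)
    df = pd.DataFrame(rows, columns=["feature_a", "feature_b", "statistic", "n", "p_raw"])
    df = df.sort_values(
        ["statistic", "feature_b"], ascending=[False, True], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return df


def _run_partitioned(items: list, run_chunk, n_workers: int) -> list:
    """Partition items into chunks, run (possibly threaded), reduce in fixed order."""
    if n_workers <= 1 or len(items) < 2:
        return run_chunk(items)
    chunks = [list(c) for c in np.array_split(np.asarray(items, dtype=object), n_workers) if len(c)]
    with ThreadPoolExecutor(max_workers=n_workers) as pool:
        parts = list(pool.map(run_chunk, chunks))
    out: list = []
    for p in parts:  # fixed reduction order == chunk order
        out.extend(p)
    return out


def all_pairs(
    project: Project,
    feature_ids: list[str],
    method: str = "pearson",
    samples: GroupSelection | None = None,
    mi_M: int = 10,
    mi_k: int = 3,
) -> pd.DataFrame:
    """All-pairs association among a (modest) list of features.

    The selected rows are read once via the index; pairs are emitted in
    lexicographic order with each undirected pair listed once.
    """
    vecs = {}
    for vec in project.iter_features(sorted(feature_ids)):
        vecs[vec.feature_id] = vec.subset(samples) if samples is not None else vec.values
    ids = sorted(vecs)
    rows = []
    for i, fa in enumerate(ids):
        for fb in ids[i + 1 :]:
            s, n, p = _stat_for(method, vecs[fa], vecs[fb], mi_M, mi_k)
            rows.append((fa, fb, s, n, p))
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "statistic", "n", "p_raw"])


def sample_correlation_screen(
    project: Project, group: GroupSelection, threshold: float = 0.70
) -> pd.DataFrame:
    """Quality screen: pairwise Pearson among group samples over all features.

    Streams rows once, accumulating pairwise-complete sufficient statistics.
    A sample is flagged when *all* of its within-group correlations fall
    below ``threshold`` (samples from the same condition are expected to
    correlate highly, > 0.70 by default).
    """
    ids = group.sample_ids
    m = len(ids)
    if m < 2:
        raise StatisticError("sample correlation screen needs a group of >= 2 samples")
    N = np.zeros((m, m))
    Sx = np.zeros((m, m))  # sum of row values over jointly-observed positions
    Sxx = np.zeros((m, m))
    Sxy = np.zeros((m, m))
    for vec in project.iter_features():
        v = vec.subset(ids)
        f = np.isfinite(v).astype(float)
        v0 = np.where(np.isfinite(v), v, 0.0)
        N += np.outer(f, f)
        Sx += np.outer(v0, f)
        Sxx += np.outer(v0 * v0, f)
        Sxy += np.outer(v0, v0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = N * Sxy - Sx * Sx.T
        var = N * Sxx - Sx * Sx
        r = cov / np.sqrt(var * var.T)
    np.fill_diagonal(r, np.nan)
    max_r = np.nanmax(r, axis=1)
    mean_r = np.nanmean(r, axis=1)
    flag = max_r < threshold
    return pd.DataFrame({"sample": ids, "max_r": max_r, "mean_r": mean_r, "flag": flag})


def export_edges(results: pd.DataFrame, statistic_threshold: float, path: str) -> int:
    """Write a thresholded, deduplicated undirected edge list as TSV.

    Keeps rows with ``statistic >= statistic_threshold``; each undirected
    pair appears once (endpoints ordered lexicographically). Returns the
    number of edges written.
    """
    df = results.copy()
    df = df[np.isfinite(df["statistic"]) & (df["statistic"] >= statistic_threshold)]
    a = df["feature_a"].astype(str)
    b = df["feature_b"].astype(str)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    df = df.assign(feature_a=lo, feature_b=hi)
    df = df.drop_duplicates(subset=["feature_a", "feature_b"])
    df = df.sort_values(["feature_a", "feature_b"], kind="mergesort")
    out = df[["feature_a", "feature_b", "statistic"]].copy()
    out["p_value"] = df["p_raw"] if "p_raw" in df.columns else np.nan
    out.to_csv(path, sep="\t", index=False)
    return len(out)
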