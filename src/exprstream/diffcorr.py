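"""Differential correlation: does a feature's co-expression with a chosen
target differ between two sample groups?

The parametric route Fisher-transforms each group's Pearson correlation,
z = atanh(r), whose sampling variance is approximately 1/(n - 3); the
standardized difference

    Z = (z1 - z2) / sqrt(1/(n1 - 3) + 1/(n2 - 3))

is approximately standard normal under equality of the two population
correlations, giving a two-sided p-value. The distribution-free route
permutes group labels and uses the raw difference r1 - r2 as the test
statistic with an empirical p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import StatisticError
from .multitest import adjust as mt_adjust
from .project import GroupSelection, Project


def fisher_z(r: float) -> float:
    """Fisher transformation z = atanh(r); requires |r| < 1."""
    r = float(r)
    if abs(r) >= 1:
        raise StatisticError(f"|r| = {abs(r)} >= 1: Fisher z is infinite")
    return float(np.arctanh(r))


def fisher_z_inverse(z: float) -> float:
    return float(np.tanh(z))


def diffcorr_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Z statistic and two-sided normal p for equality of two correlations."""
    if n1 <= 3 or n2 <= 3:
        raise StatisticError("both groups need n >= 4 (variance 1/(n-3) undefined)")
    z1 = fisher_z(r1)
    z2 = fisher_z(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    Z = (z1 - z2) / se
    return float(Z), float(2 * stats.norm.sf(abs(Z)))


@dataclass
class DiffCorrResult:
    target_feature: str
    other_feature: str
    r1: float
    n1: int
    r2: float
    n2: int
    z1: float
    z2: float
    Z: float
    p_raw: float
    p_adj: float | None
    mode: str


def _pairwise_r(tv: np.ndarray, ov: np.ndarray) -> tuple[float, int]:
    """Pearson r and complete-n; (nan, n) when undefined."""
    ok = np.isfinite(tv) & np.isfinite(ov)
    n = int(ok.sum())
    if n < 4:
        return np.nan, n
    x, y = tv[ok], ov[ok]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, n
    return float(stats.pearsonr(x, y).statistic), n


def diffcorr_scan(
    project: Project,
    target_feature: str,
    group_1: GroupSelection,
    group_2: GroupSelection,
    mode: str = "fisher_z",
    B: int = 999,
    seed: int = 0,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Scan all other features for differential correlation with the target.

    ``fisher_z`` mode applies :func:`diffcorr_test` per feature;
    ``raw_permutation`` permutes the pooled group labels B times and uses
    T = r1 - r2 with the +1/(B+1) empirical p. p-values are BH-adjusted
    across features (features with insufficient complete pairs are
    reported with missing statistics, not dropped). Output is sorted by
    feature ID; per-permutation RNG is counter-based so results do not
    depend on execution order.
    """
    if mode not in ("fisher_z", "raw_permutation"):
        raise ValueError(f"unknown mode {mode!r}")
    ids1, ids2 = group_1.sample_ids, group_2.sample_ids
    if set(ids1) & set(ids2):
        raise StatisticError("groups overlap")
    if len(ids1) < 4 or len(ids2) < 4:
        raise StatisticError("each group needs >= 4 samples")

    target = project.get_feature(target_feature)
    t1 = target.subset(ids1)
    t2 = target.subset(ids2)
    pooled_ids = ids1 + ids2
    t_pooled = target.subset(pooled_ids)
    n1_lab = len(ids1)

    perms = None
    if mode == "raw_permutation":
        perms = [
            np.random.Generator(np.random.Philox(key=[seed, b])).permutation(len(pooled_ids))
            for b in range(B)
        ]

    rows = []
    others = sorted(f for f in project.feature_ids if f != target_feature)
    for vec in project.iter_features(others):
        o1 = vec.subset(ids1)
        o2 = vec.subset(ids2)
        r1, n1 = _pairwise_r(t1, o1)
        r2, n2 = _pairwise_r(t2, o2)
        if not (np.isfinite(r1) and np.isfinite(r2)):
            rows.append((vec.feature_id, r1, n1, r2, n2, np.nan, np.nan, np.nan, np.nan))
            continue
        if mode == "fisher_z":
            try:
                Z, p = diffcorr_test(r1, n1, r2, n2)
                z1, z2 = fisher_z(r1), fisher_z(r2)
            except StatisticError:
                Z = p = z1 = z2 = np.nan
            rows.append((vec.feature_id, r1, n1, r2, n2, z1, z2, Z, p))
        else:
            o_pooled = vec.subset(pooled_ids)
            t_obs = r1 - r2
            null = np.empty(B)
            for b, perm in enumerate(perms):
                lab1 = perm[:n1_lab]
                lab2 = perm[n1_lab:]
                pr1, _ = _pairwise_r(t_pooled[lab1], o_pooled[lab1])
                pr2, _ = _pairwise_r(t_pooled[lab2], o_pooled[lab2])
                null[b] = pr1 - pr2 if np.isfinite(pr1) and np.isfinite(pr2) else 0.0
            from .multitest import empirical_pvalue

            p = empirical_pvalue(t_obs, null)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                z1 = np.arctanh(r1) if abs(r1) < 1 else np.nan
                z2 = np.arctanh(r2) if abs(r2) < 1 else np.nan
            rows.append((vec.feature_id, r1, n1, r2, n2, z1, z2, t_obs, p))

    df = pd.DataFrame(
        rows,
        columns=["other_feature", "r1", "n1", "r2", "n2", "z1", "z2", "Z", "p_raw"],
    )
    df.insert(0, "target_feature", target_feature)
    df["p_adj"] = mt_adjust(df["p_raw"].to_numpy(), adjust).p_adj
    df["mode"] = mode
    return df.sort_values("other_feature", kind="mergesort").reset_index(drop=True)
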