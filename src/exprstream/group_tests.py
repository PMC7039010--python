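"""Two-group differential expression tests and streaming DE scans.

Independent designs: Mann-Whitney U (rank-based, no distributional
assumption), Student's t (equal variances), Welch's t (unequal variances,
Welch-Satterthwaite df) and a label-permutation test. Paired designs:
paired t, Wilcoxon signed-rank (zero differences dropped), and a
sign-flip permutation test.

The DE calling rule used by :func:`de_scan` is a fold-change bound
combined with an adjusted-p bound: a feature is called when
``|logFC| >= fc_bound`` and ``p_adj < p_bound`` (defaults 1.0 and 1e-3
with BH adjustment, Mann-Whitney on log2-scale data). logFC is the
difference of group means on the log2 scale.

These are large-sample methods (intended for roughly 30+ samples per
group); a warning is emitted for smaller groups.
"""

from __future__ import annotations

import itertools
import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import StatisticError
from .multitest import adjust as mt_adjust
from .multitest import empirical_pvalue
from .project import GroupSelection, Project

EXACT_N_MAX = 12  # total sample size below which rank tests enumerate exactly

INDEPENDENT_TESTS = ("mann_whitney_u", "student_t", "welch_t", "perm_independent")
PAIRED_TESTS = ("paired_t", "wilcoxon_signed_rank", "perm_paired")


@dataclass
class TestResult:
    feature_id: str
    test: str
    statistic: float
    n_a: int
    n_b: int
    logFC: float
    p_raw: float
    p_adj: float | None = None
    called: bool = False


def _clean(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v[np.isfinite(v)]


# ----------------------------------------------------------------------
# Mann-Whitney U
# ----------------------------------------------------------------------
def mann_whitney_u(a, b, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U for group A with a two-sided p-value.

    ``mode='asymptotic'`` uses the tie-corrected normal approximation with
    continuity correction; ``mode='exact'`` enumerates all label
    arrangements (handles ties; feasible for small n); ``'auto'`` picks
    exact when ``n_a + n_b <= 12``.
    """
    a = _clean(a)
    b = _clean(b)
    if a.size < 1 or b.size < 1:
        raise StatisticError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return a.size * b.size / 2.0, 1.0
    if mode == "auto":
        mode = "exact" if a.size + b.size <= EXACT_N_MAX else "asymptotic"
    if mode == "exact":
        return _mwu_exact(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _mwu_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating all C(n, n_a) label arrangements.

    Arrangements at least as extreme are those with |U' - n_a n_b / 2|
    >= |U_obs - n_a n_b / 2| (U computed from mid-ranks, so ties are
    handled naturally).
    """
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    center = na * nb / 2.0
    dev = abs(u_obs - center)
    count = 0
    total = 0
    for combo in itertools.combinations(range(na + nb), na):
        u = ranks[list(combo)].sum() - na * (na + 1) / 2.0
        if abs(u - center) >= dev - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


# ----------------------------------------------------------------------
# t tests
# ----------------------------------------------------------------------
def _t_test(a, b, equal_var: bool) -> tuple[float, float]:
    a = _clean(a)
    b = _clean(b)
    if a.size < 2 or b.size < 2:
        raise StatisticError("t tests need >= 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means; p underflows", stacklevel=3)
        return math.copysign(math.inf, np.mean(a) - np.mean(b)), np.finfo(float).tiny
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def student_t(a, b) -> tuple[float, float]:
    """Two-sample t test pooling variances (assumes equal variances)."""
    return _t_test(a, b, equal_var=True)


def welch_t(a, b) -> tuple[float, float]:
    """Welch's t test with Welch-Satterthwaite degrees of freedom."""
    return _t_test(a, b, equal_var=False)


# ----------------------------------------------------------------------
# paired designs
# ----------------------------------------------------------------------
def _paired_diffs(a, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StatisticError("paired groups must have equal length")
    d = a - b
    return d[np.isfinite(d)]


def paired_t(a, b) -> tuple[float, float]:
    """Paired t test on within-pair differences."""
    d = _paired_diffs(a, b)
    if d.size < 2:
        raise StatisticError("paired t needs >= 2 pairs")
    if np.var(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        warnings.warn("constant non-zero differences; p underflows", stacklevel=2)
        return math.copysign(math.inf, d[0]), np.finfo(float).tiny
    res = stats.ttest_rel(np.asarray(a, dtype=float), np.asarray(b, dtype=float),
                          nan_policy="omit")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(a, b, mode: str = "auto") -> tuple[float, float]:
    """Wilcoxon signed-rank test (W+ statistic) on paired data.

    Zero differences are dropped (Wilcoxon's convention); tied absolute
    differences get mean ranks. Exact mode enumerates all 2^m sign
    assignments (auto for <= 12 non-zero differences); otherwise the
    tie-corrected normal approximation is used.
    """
    d = _paired_diffs(a, b)
    if d.size < 1:
        raise StatisticError("need >= 1 pair")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if mode == "auto":
        mode = "exact" if d.size <= EXACT_N_MAX else "asymptotic"
    if mode == "exact":
        center = d.size * (d.size + 1) / 4.0
        dev = abs(w_plus - center)
        count = 0
        for signs in itertools.product((0, 1), repeat=d.size):
            t = float(np.dot(signs, ranks))
            if abs(t - center) >= dev - 1e-12:
                count += 1
        return w_plus, count / 2 ** d.size
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return w_plus, float(res.pvalue)


# ----------------------------------------------------------------------
# permutation tests
# ----------------------------------------------------------------------
def _perm_rng(seed: int, b: int) -> np.random.Generator:
    # counter-based: permutation b's stream depends only on (seed, b), so a
    # partitioned parallel run reproduces the serial stream exactly
    return np.random.Generator(np.random.Philox(key=[seed & 0xFFFFFFFFFFFFFFFF, b]))


def permutation_test(
    a,
    b,
    design: str = "independent",
    statistic=None,
    B: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test with the +1/(B+1) empirical p-value convention.

    Independent design permutes group labels of the pooled values; paired
    design flips the signs of within-pair differences. The default
    statistic is the difference of group means (independent) or the mean
    difference (paired); pass a callable ``statistic(a, b)`` to override.
    """
    if B < 1:
        raise StatisticError("B must be >= 1")
    if design == "independent":
        a = _clean(a)
        b = _clean(b)
        stat = statistic or (lambda x, y: float(np.mean(x) - np.mean(y)))
        t_obs = stat(a, b)
        pooled = np.concatenate([a, b])
        na = a.size
        null = np.empty(B)
        for i in range(B):
            perm = _perm_rng(seed, i).permutation(pooled)
            null[i] = stat(perm[:na], perm[na:])
    elif design == "paired":
        d = _paired_diffs(a, b)
        stat = statistic or (lambda diffs: float(np.mean(diffs)))
        t_obs = stat(d)
        null = np.empty(B)
        for i in range(B):
            signs = _perm_rng(seed, i).choice([-1.0, 1.0], size=d.size)
            null[i] = stat(d * signs)
    else:
        raise ValueError(f"unknown design {design!r}")
    return t_obs, empirical_pvalue(t_obs, null)


# ----------------------------------------------------------------------
# logFC and scans
# ----------------------------------------------------------------------
def log_fold_change(a, b, data_is_log2: bool = True, pseudocount: float = 0.0) -> float:
    """log2 fold change of group A over group B.

    On log2-scale data this is ``mean(a) - mean(b)``; on raw-scale data it
    is ``log2((mean(a) + c) / (mean(b) + c))`` with pseudocount ``c``.
    """
    a = _clean(a)
    b = _clean(b)
    if a.size == 0 or b.size == 0:
        raise StatisticError("logFC needs non-empty groups")
    if data_is_log2:
        return float(np.mean(a) - np.mean(b))
    return float(np.log2((np.mean(a) + pseudocount) / (np.mean(b) + pseudocount)))


def _dispatch_independent(test, a, b, B, seed):
    if test == "mann_whitney_u":
        return mann_whitney_u(a, b)
    if test == "student_t":
        return student_t(a, b)
    if test == "welch_t":
        return welch_t(a, b)
    if test == "perm_independent":
        return permutation_test(a, b, design="independent", B=B, seed=seed)
    raise ValueError(f"unknown independent test {test!r}")


def de_scan(
    project: Project,
    group_a: GroupSelection,
    group_b: GroupSelection,
    test: str = "mann_whitney_u",
    fc_bound: float = 1.0,
    p_bound: float = 1e-3,
    adjust: str = "bh",
    data_is_log2: bool | None = None,
    B: int = 999,
    seed: int = 0,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Differential-expression scan of every feature between two groups.

    Streams all features, computes the chosen test plus logFC, adjusts
    p-values across all tested features, and sets ``called`` under the
    rule ``|logFC| >= fc_bound and p_adj < p_bound``. The output is
    sorted by feature ID, so it is bit-identical for any on-disk feature
    order or worker count.
    """
    ids_a, ids_b = group_a.sample_ids, group_b.sample_ids
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise StatisticError(f"groups overlap on {len(overlap)} sample(s)")
    if min(len(ids_a), len(ids_b)) < 30:
        warnings.warn(
            "groups have fewer than 30 samples; these tests are designed for "
            "large sample sizes",
            stacklevel=2,
        )
    if data_is_log2 is None:
        data_is_log2 = project.transform.kind == "log2"
    pseudo = project.transform.pseudocount if project.transform.kind == "log2" else 0.0

    feature_order = sorted(project.feature_ids)

    def run_chunk(chunk):
        rows = []
        for vec in project.iter_features(chunk):
            va = _clean(vec.subset(ids_a))
            vb = _clean(vec.subset(ids_b))
            fid = vec.feature_id
            fseed = (seed ^ zlib.crc32(fid.encode())) & 0x7FFFFFFF
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    stat, p = _dispatch_independent(test, va, vb, B, fseed)
                    lfc = log_fold_change(va, vb, data_is_log2, pseudo)
            except StatisticError:
                stat, p, lfc = np.nan, np.nan, np.nan
            rows.append((fid, test, stat, va.size, vb.size, lfc, p))
        return rows

    from .association import _run_partitioned

    rows = _run_partitioned(feature_order, run_chunk, n_workers)
    df = pd.DataFrame(
        rows, columns=["feature_id", "test", "statistic", "n_a", "n_b", "logFC", "p_raw"]
    )
    df["p_adj"] = mt_adjust(df["p_raw"].to_numpy(), adjust).p_adj
    with np.errstate(invalid="ignore"):
        df["called"] = (
            np.isfinite(df["logFC"])
            & np.isfinite(df["p_adj"])
            & (np.abs(df["logFC"]) >= fc_bound)
            & (df["p_adj"] < p_bound)
        )
    return df.sort_values("feature_id", kind="mergesort").reset_index(drop=True)


def paired_de_scan(
    project: Project,
    pairs: list[tuple[str, str]],
    test: str = "paired_t",
    fc_bound: float = 1.0,
    p_bound: float = 1e-3,
    adjust: str = "bh",
    data_is_log2: bool | None = None,
    B: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired-design DE scan over explicit (sample_in_A, sample_in_B) pairs."""
    flat = [s for p in pairs for s in p]
    if len(set(flat)) != len(flat):
        raise StatisticError("a sample appears in more than one pair")
    ids_a = [p[0] for p in pairs]
    ids_b = [p[1] for p in pairs]
    if data_is_log2 is None:
        data_is_log2 = project.transform.kind == "log2"
    pseudo = project.transform.pseudocount if project.transform.kind == "log2" else 0.0
    rows = []
    for vec in project.iter_features(sorted(project.feature_ids)):
        va = vec.subset(ids_a)
        vb = vec.subset(ids_b)
        fid = vec.feature_id
        fseed = (seed ^ zlib.crc32(fid.encode())) & 0x7FFFFFFF
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if test == "paired_t":
                    stat, p = paired_t(va, vb)
                elif test == "wilcoxon_signed_rank":
                    stat, p = wilcoxon_signed_rank(va, vb)
                elif test == "perm_paired":
                    stat, p = permutation_test(va, vb, design="paired", B=B, seed=fseed)
                else:
                    raise ValueError(f"unknown paired test {test!r}")
                lfc = log_fold_change(_clean(va), _clean(vb), data_is_log2, pseudo)
        except StatisticError:
            stat, p, lfc = np.nan, np.nan, np.nan
        rows.append((fid, test, stat, len(ids_a), len(ids_b), lfc, p))
    df = pd.DataFrame(
        rows, columns=["feature_id", "test", "statistic", "n_a", "n_b", "logFC", "p_raw"]
    )
    df["p_adj"] = mt_adjust(df["p_raw"].to_numpy(), adjust).p_adj
    df["called"] = (
        np.isfinite(df["logFC"])
        & np.isfinite(df["p_adj"])
        & (np.abs(df["logFC"]) >= fc_bound)
        & (df["p_adj"] < p_bound)
    )
    return df.reset_index(drop=True)


def stage_scan(
    project: Project,
    organ_field: str,
    stage_field: str,
    early_stages: list[str],
    late_stages: list[str],
    base_results: list[str],
    fc_bound: float = 1.0,
    p_bound: float = 0.05,
    adjust: str = "bh",
    data_is_log2: bool | None = None,
    extra_predicate: str | None = None,
) -> pd.DataFrame:
    """Stage-wise expression scan of candidate features, per organ.

    Samples are split by ``organ_field`` and then into early and late
    stage groups from the given stage labels. For each candidate feature
    (typically the tumor-upregulated set), a Mann-Whitney test compares
    late vs early; features with a 2-fold-or-more change (``|logFC| >=
    fc_bound``) and BH-adjusted p below ``p_bound`` are labeled
    ``increasing`` or ``decreasing`` by the sign of logFC, otherwise
    ``flat``. Organs where either stage group has fewer than 2 samples are
    skipped with a warning.
    """
    candidates = sorted(base_results)
    if not candidates:
        return pd.DataFrame(
            columns=["organ", "feature_id", "n_early", "n_late", "statistic",
                     "logFC", "p_raw", "p_adj", "label"]
        )
    meta = project.sample_meta
    for fld in (organ_field, stage_field):
        if fld not in meta.columns:
            raise StatisticError(f"unknown sample-metadata field {fld!r}")
    if data_is_log2 is None:
        data_is_log2 = project.transform.kind == "log2"
    out = []
    for organ in meta[organ_field].dropna().drop_duplicates():
        base = meta[meta[organ_field] == organ]
        if extra_predicate:
            base = _stage_query(base, extra_predicate)
        early_ids = [s for s in project.sample_ids
                     if s in base.index and base.loc[s, stage_field] in early_stages]
        late_ids = [s for s in project.sample_ids
                    if s in base.index and base.loc[s, stage_field] in late_stages]
        if len(early_ids) < 2 or len(late_ids) < 2:
            warnings.warn(
                f"organ {organ!r}: a stage group has < 2 samples; skipped", stacklevel=2
            )
            continue
        rows = []
        for vec in project.iter_features(candidates):
            late = _clean(vec.subset(late_ids))
            early = _clean(vec.subset(early_ids))
            if late.size < 2 or early.size < 2:
                warnings.warn(
                    f"feature {vec.feature_id!r} in organ {organ!r}: "
                    "a stage group has < 2 observed values; skipped",
                    stacklevel=2,
                )
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = mann_whitney_u(late, early)
            lfc = log_fold_change(late, early, data_is_log2, 0.0)
            rows.append((str(organ), vec.feature_id, early.size, late.size, stat, lfc, p))
        if not rows:
            continue
        odf = pd.DataFrame(
            rows, columns=["organ", "feature_id", "n_early", "n_late", "statistic",
                           "logFC", "p_raw"]
        )
        odf["p_adj"] = mt_adjust(odf["p_raw"].to_numpy(), adjust).p_adj
        sig = (np.abs(odf["logFC"]) >= fc_bound) & (odf["p_adj"] < p_bound)
        odf["label"] = np.where(
            sig & (odf["logFC"] > 0), "increasing",
            np.where(sig & (odf["logFC"] < 0), "decreasing", "flat"),
        )
        out.append(odf)
    if not out:
        return pd.DataFrame(
            columns=["organ", "feature_id", "n_early", "n_late", "statistic",
                     "logFC", "p_raw", "p_adj", "label"]
        )
    return pd.concat(out, ignore_index=True)


def _stage_query(df: pd.DataFrame, predicate: str) -> pd.DataFrame:
    from .project import _query

    return _query(df, predicate)


def volcano_table(de_table: pd.DataFrame) -> pd.DataFrame:
    """(feature_id, logFC, -log10 p_adj) table for external volcano plotting."""
    with np.errstate(divide="ignore"):
        neg = -np.log10(de_table["p_adj"].to_numpy(dtype=float))
    return pd.DataFrame(
        {"feature_id": de_table["feature_id"], "logFC": de_table["logFC"],
         "neg_log10_p_adj": neg}
    )
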