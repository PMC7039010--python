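"""Meta-analysis of Pearson correlation coefficients across studies.

Per-study correlations r_i (sample size n_i) are pooled as a weighted
average on the Fisher-z scale (Hedges-Olkin): z_i = atanh(r_i) with
variance v_i = 1/(n_i - 3). The fixed-effects model (FEM) assumes all
studies estimate one common correlation and weighs by w_i = 1/v_i, i.e.
proportionally to sample size up to the small-sample correction. The
random-effects model (REM) allows between-study heterogeneity tau^2,
estimated by DerSimonian-Laird from Cochran's Q, and weighs by
w*_i = 1/(v_i + tau^2). The pooled z is back-transformed with tanh, which
keeps the pooled correlation inside (-1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import StatisticError


@dataclass
class StudyRecord:
    study: str
    r: float
    n: int
    weight: float


@dataclass
class MetaCorrelationResult:
    studies: list[StudyRecord]
    model: str  # fem | rem
    pooled_z: float
    pooled_r: float
    se: float
    ci95: tuple[float, float]
    Q: float
    tau2: float
    p: float


def meta_correlation(per_study, model: str = "fem") -> MetaCorrelationResult:
    """Pool per-study Pearson correlations under a fixed or random effects model.

    Parameters
    ----------
    per_study
        Iterable of ``(r_i, n_i)`` or ``(study_id, r_i, n_i)`` records;
        at least 2 studies, each with n_i >= 4 and \\|r_i\\| < 1.
    model
        ``"fem"`` or ``"rem"`` (DerSimonian-Laird tau^2).
    """
    model = model.lower()
    if model not in ("fem", "rem"):
        raise ValueError(f"model must be 'fem' or 'rem', got {model!r}")
    recs = []
    for i, rec in enumerate(per_study):
        if len(rec) == 2:
            sid, (r, n) = f"study{i + 1}", rec
        else:
            sid, r, n = rec
        r = float(r)
        n = int(n)
        if n <= 3:
            raise StatisticError(f"study {sid!r}: n={n} <= 3, Fisher-z variance undefined")
        if abs(r) >= 1:
            raise StatisticError(f"study {sid!r}: |r|={abs(r)} >= 1, Fisher z infinite")
        recs.append((sid, r, n))
    k = len(recs)
    if k < 2:
        raise StatisticError("meta-analysis needs >= 2 studies")

    z = np.array([np.arctanh(r) for _, r, _ in recs])
    v = np.array([1.0 / (n - 3) for _, _, n in recs])
    w = 1.0 / v

    zbar_fe = float(np.sum(w * z) / np.sum(w))
    Q = float(np.sum(w * (z - zbar_fe) ** 2))
    if model == "rem":
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / c)
        w_star = 1.0 / (v + tau2)
    else:
        tau2 = 0.0
        w_star = w

    pooled_z = float(np.sum(w_star * z) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    pooled_r = float(np.tanh(pooled_z))
    ci = (float(np.tanh(pooled_z - 1.959963984540054 * se)),
          float(np.tanh(pooled_z + 1.959963984540054 * se)))
    p = float(2 * stats.norm.sf(abs(pooled_z) / se))
    studies = [
        StudyRecord(sid, r, n, float(wi)) for (sid, r, n), wi in zip(recs, w_star)
    ]
    return MetaCorrelationResult(studies, model, pooled_z, pooled_r, se, ci, Q, tau2, p)


def per_study_correlation(project, feature_a: str, feature_b: str, study_field: str):
    """Per-study Pearson (r_i, n_i) records for a feature pair.

    Studies are the distinct values of ``study_field`` in the sample
    metadata, in order of first appearance. Studies where the correlation
    is undefined (too few complete pairs, constant vectors) are skipped.
    """
    from .association import pearson

    va = project.get_feature(feature_a)
    vb = project.get_feature(feature_b)
    if study_field not in project.sample_meta.columns:
        raise StatisticError(f"unknown sample-metadata field {study_field!r}")
    out = []
    studies = project.sample_meta[study_field]
    for study in studies.drop_duplicates():
        ids = [
            s for s in project.sample_ids
            if s in studies.index and studies.loc[s] == study
        ]
        try:
            res = pearson(va.subset(ids), vb.subset(ids))
        except StatisticError:
            continue
        out.append((str(study), res.r, res.n))
    return out
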