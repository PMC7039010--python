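"""Multiple-comparison adjustment and empirical (permutation) p-values.

Bonferroni and Holm control the family-wise error rate; Benjamini-Hochberg
controls the false discovery rate. Adjusted p-values are reported as such
(no reject flags); thresholds are applied downstream by the scans. Missing
entries (NaN) are excluded from the number of tests ``m`` and returned
missing. Ties in the sorted p-values are broken by original index so the
output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

METHODS = ("bonferroni", "holm", "bh")


@dataclass
class AdjustedPvalues:
    p_raw: np.ndarray
    method: str
    p_adj: np.ndarray
    m: int


def adjust(p_raw, method: str = "bh") -> AdjustedPvalues:
    """Adjust p-values by Bonferroni, Holm (step-down) or BH (step-up).

    Raises ``ValueError`` (with the offending index) for p outside [0, 1].
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    p = np.asarray(p_raw, dtype=float)
    flat = p.ravel()
    finite = np.isfinite(flat)
    bad = np.where(finite & ((flat < 0) | (flat > 1)))[0]
    if bad.size:
        raise ValueError(f"p-value out of [0, 1] at index {int(bad[0])}: {flat[bad[0]]}")

    obs = np.where(finite)[0]
    m = obs.size
    out = np.full(flat.shape, np.nan)
    if m:
        ps = flat[obs]
        # stable sort: ties broken by original index
        order = np.lexsort((obs, ps))
        sorted_p = ps[order]
        if method == "bonferroni":
            adj_sorted = np.minimum(1.0, m * sorted_p)
        elif method == "holm":
            mult = m - np.arange(m)
            adj_sorted = np.minimum(1.0, np.maximum.accumulate(mult * sorted_p))
        else:  # bh
            mult = m / (np.arange(m) + 1.0)
            adj_sorted = np.minimum(1.0, np.minimum.accumulate((mult * sorted_p)[::-1])[::-1])
        out[obs[order]] = adj_sorted
    return AdjustedPvalues(p_raw=p, method=method, p_adj=out.reshape(p.shape), m=m)


def empirical_pvalue(t_obs: float, permuted) -> float:
    """Two-sided empirical p-value with the +1/(B+1) convention.

    ``p = (1 + #{|T_b| >= |T_obs|}) / (B + 1)``; ties count as exceeding, and
    p is never 0.
    """
    perm = np.asarray(permuted, dtype=float)
    if perm.size == 0:
        raise ValueError("permuted statistics must be non-empty")
    count = int(np.sum(np.abs(perm) >= abs(t_obs)))
    return (1.0 + count) / (perm.size + 1.0)
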