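"""Synthetic expression datasets with known ground truth.

The generator emulates the structure of large multi-study expression
compilations: a feature-by-sample matrix on a log2-normal scale (values
are already log2-like, baseline mean ~8, sd ~2 across features), sample
metadata with study, organ, tumor/non-tumor status and tumor stage, and
planted effects with machine-readable truth tables:

* co-expression modules: members share a latent factor with loading
  sqrt(rho), so every within-module pair has correlation exactly rho in
  the model;
* differentially expressed features: a fixed logFC added to tumor
  samples, with a per-feature noise sd;
* differential-correlation pairs: a target/partner pair constructed with
  correlation rho1 among non-tumor samples and rho2 among tumor samples;
* stage-trend features: a monotone mean shift per tumor stage;
* optionally a promiscuous hub feature correlated with every other
  feature (for CLR benchmarking), realized by giving all features a
  loading on one global factor that the hub *is*.

Per-feature random streams are counter-based (Philox keyed by
(seed, feature index)), so generation is deterministic and the same seed
always yields byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("I", "II", "III", "IV")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset. Defaults give a multi-study,
    two-organ tumor/non-tumor compilation with one planted co-expression
    module, a block of DE features and one differential-correlation pair."""

    n_features: int = 500
    n_samples: int = 200
    n_studies: int = 3
    organs: tuple[str, ...] = ("liver", "kidney")
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 1.0
    modules: tuple[tuple[int, float], ...] = ((5, 0.9),)  # (size, rho)
    n_de: int = 20
    de_logfc: float = 2.0
    de_noise_sd: float = 0.5
    diffcorr_pairs: tuple[tuple[float, float], ...] = ((0.7, 0.0),)  # (rho group1, rho group2)
    n_stage: int = 0
    stage_delta: float = 1.0  # mean shift per stage step, tumor samples
    hub_rho: float | None = None
    n_unknown: int = 0  # null features annotated as 'unknown function'
    missing_fraction: float = 0.0
    seed: int = 0


@dataclass
class FixtureResult:
    data_path: str
    sample_meta_path: str
    truth: dict = field(default_factory=dict)
    truth_paths: dict = field(default_factory=dict)


def _feature_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[seed, i]))


def _shared_rng(seed: int, j: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[seed, (1 << 32) + j]))


def _sample_metadata(spec: FixtureSpec) -> pd.DataFrame:
    n = spec.n_samples
    ids = [f"S{i + 1:05d}" for i in range(n)]
    study = [f"study{1 + (i % spec.n_studies):02d}" for i in range(n)]
    n_org = len(spec.organs)
    organ = [spec.organs[min(i * n_org // n, n_org - 1)] for i in range(n)]
    status = []
    stage = []
    for org in spec.organs:
        members = [i for i in range(n) if organ[i] == org]
        half = len(members) // 2
        for j, i in enumerate(members):
            if j < half:
                status.append((i, "non-tumor"))
                stage.append((i, ""))
            else:
                status.append((i, "tumor"))
                stage.append((i, STAGES[(j - half) % len(STAGES)]))
    status_map = dict(status)
    stage_map = dict(stage)
    return pd.DataFrame(
        {
            "sample_id": ids,
            "study": study,
            "organ": organ,
            "status": [status_map[i] for i in range(n)],
            "stage": [stage_map[i] for i in range(n)],
        }
    )


def generate(spec: FixtureSpec, out_dir: str | os.PathLike) -> FixtureResult:
    """Write the data file, sample-metadata file and truth tables.

    Raises ``ValueError`` for infeasible specs (more planted features than
    ``n_features``).
    """
    planted = (
        sum(size for size, _ in spec.modules)
        + spec.n_de
        + 2 * len(spec.diffcorr_pairs)
        + spec.n_stage
        + (1 if spec.hub_rho is not None else 0)
    )
    if planted > spec.n_features:
        raise ValueError(
            f"spec plants {planted} features but n_features={spec.n_features}"
        )
    os.makedirs(out_dir, exist_ok=True)
    meta = _sample_metadata(spec)
    n, p = spec.n_samples, spec.n_features
    tumor = (meta["status"] == "tumor").to_numpy()
    stage_idx = np.array(
        [STAGES.index(s) if s in STAGES else -1 for s in meta["stage"]], dtype=float
    )

    # shared latent factors: 0 = global (hub), 1.. = modules
    global_factor = _shared_rng(spec.seed, 0).standard_normal(n)
    module_factors = [
        _shared_rng(spec.seed, 1 + m).standard_normal(n) for m in range(len(spec.modules))
    ]

    # feature role assignment, in id order: modules, DE, diffcorr, stage, hub, null
    roles: list[tuple] = []
    for m, (size, rho) in enumerate(spec.modules):
        roles.extend(("module", m, rho) for _ in range(size))
    roles.extend(("de",) for _ in range(spec.n_de))
    for q, (r1, r2) in enumerate(spec.diffcorr_pairs):
        roles.append(("dc_target", q))
        roles.append(("dc_partner", q, r1, r2))
    roles.extend(("stage",) for _ in range(spec.n_stage))
    if spec.hub_rho is not None:
        roles.append(("hub",))
    roles.extend(("null",) for _ in range(p - len(roles)))

    ids = [f"G{i + 1:06d}" for i in range(p)]
    a_global = np.sqrt(spec.hub_rho) if spec.hub_rho is not None else 0.0

    matrix = np.empty((p, n))
    truth_modules, truth_de, truth_dc, truth_stage = [], [], [], []
    dc_target_signal: dict[int, np.ndarray] = {}
    for i, role in enumerate(roles):
        rng = _feature_rng(spec.seed, i)
        mu = spec.baseline_mean + spec.baseline_sd * rng.standard_normal()
        kind = role[0]
        sd = spec.noise_sd
        if kind == "module":
            _, m, rho = role
            b2 = rho - a_global**2
            if b2 < 0:
                raise ValueError("hub_rho exceeds module rho; infeasible loading")
            c2 = max(0.0, 1.0 - rho)
            signal = (
                a_global * global_factor
                + np.sqrt(b2) * module_factors[m]
                + np.sqrt(c2) * rng.standard_normal(n)
            )
            truth_modules.append((ids[i], m, rho))
        elif kind == "de":
            sd = spec.de_noise_sd
            signal = rng.standard_normal(n)
            truth_de.append((ids[i], spec.de_logfc))
        elif kind == "dc_target":
            signal = rng.standard_normal(n)
            dc_target_signal[role[1]] = signal
        elif kind == "dc_partner":
            _, q, r1, r2 = role
            t = dc_target_signal[q]
            eps = rng.standard_normal(n)
            # partner = rho*t + sqrt(1-rho^2)*e gives corr(target, partner) = rho
            rho_per = np.where(tumor, r2, r1)
            signal = rho_per * t + np.sqrt(1 - rho_per**2) * eps
            truth_dc.append((ids[i - 1], ids[i], r1, r2))
        elif kind == "stage":
            signal = rng.standard_normal(n)
            truth_stage.append((ids[i], spec.stage_delta))
        elif kind == "hub":
            signal = global_factor + 1e-6 * rng.standard_normal(n)
            truth_modules.append((ids[i], -1, spec.hub_rho))
        else:
            signal = (
                a_global * global_factor
                + np.sqrt(max(0.0, 1.0 - a_global**2)) * rng.standard_normal(n)
            )
        values = mu + sd * signal
        if kind == "de":
            values = values + np.where(tumor, spec.de_logfc, 0.0)
        if kind == "stage":
            values = values + np.where(stage_idx >= 0, spec.stage_delta * stage_idx, 0.0)
        if spec.missing_fraction > 0:
            miss = rng.random(n) < spec.missing_fraction
            values = np.where(miss, np.nan, values)
        matrix[i] = values

    descriptions = []
    n_unknown_left = spec.n_unknown
    unknown_ids = []
    for i, role in enumerate(roles):
        if role[0] == "null" and n_unknown_left > 0:
            descriptions.append("unknown function")
            unknown_ids.append(ids[i])
            n_unknown_left -= 1
        else:
            descriptions.append(f"synthetic {role[0]} feature")

    data = pd.DataFrame(matrix, columns=meta["sample_id"].tolist())
    data.insert(0, "description", descriptions)
    data.insert(0, "symbol", [f"SYM{i + 1}" for i in range(p)])
    data.insert(0, "gene_id", ids)

    data_path = os.path.join(out_dir, "data.tsv")
    meta_path = os.path.join(out_dir, "samples.tsv")
    data.to_csv(data_path, sep="\t", index=False, float_format="%.6f", na_rep="NA")
    meta.to_csv(meta_path, sep="\t", index=False)

    truth = {
        "modules": pd.DataFrame(truth_modules, columns=["feature_id", "module", "rho"]),
        "de": pd.DataFrame(truth_de, columns=["feature_id", "logfc"]),
        "diffcorr": pd.DataFrame(truth_dc, columns=["target", "partner", "rho1", "rho2"]),
        "stage": pd.DataFrame(truth_stage, columns=["feature_id", "delta"]),
        "unknown": pd.DataFrame({"feature_id": unknown_ids}),
    }
    paths = {}
    for name, df in truth.items():
        tp = os.path.join(out_dir, f"truth_{name}.tsv")
        df.to_csv(tp, sep="\t", index=False)
        paths[name] = tp
    return FixtureResult(data_path, meta_path, truth, paths)
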