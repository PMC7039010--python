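"""Two-group tests, logFC, DE scan and stage-wise scan."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

import exprstream as xs
from exprstream.exceptions import StatisticError


# ----------------------------------------------------------------------
# enumeration oracles, written independently of the implementation
# ----------------------------------------------------------------------
def oracle_mwu(a, b):
    pooled = np.concatenate([a, b])
    na = len(a)
    # mid-ranks by explicit tie-group averaging
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    center = na * len(b) / 2
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        u = ranks[list(combo)].sum() - na * (na + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return u_obs, hits / total


def oracle_wilcoxon(d):
    d = np.asarray(d, float)
    d = d[d != 0]
    absd = np.abs(d)
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(d.size)
    i = 0
    while i < d.size:
        j = i
        while j + 1 < d.size and absd[order[j + 1]] == absd[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    center = d.size * (d.size + 1) / 4
    hits = 0
    for signs in itertools.product([0, 1], repeat=d.size):
        w = float(np.dot(signs, ranks))
        if abs(w - center) >= abs(w_obs - center) - 1e-12:
            hits += 1
    return w_obs, hits / 2**d.size


# ----------------------------------------------------------------------
def test_mwu_separated_groups_exact():
    u, p = xs.mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0
    assert p == pytest.approx(0.1)  # 2 of the C(6,3)=20 arrangements as extreme


def test_mwu_identical_groups():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u, p = xs.mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
    assert u == 8.0  # n^2 / 2
    assert p > 0.9


def test_mwu_all_tied_warns_p_one():
    with pytest.warns(UserWarning, match="tied"):
        u, p = xs.mann_whitney_u([5, 5, 5], [5, 5])
    assert p == 1.0


def test_mwu_exact_matches_enumeration_oracle():
    rng = np.random.default_rng(4)
    for na in range(1, 6):
        for nb in range(1, 6):
            if na + nb > 10:
                continue
            a = rng.integers(0, 6, size=na).astype(float)  # ties likely
            b = rng.integers(0, 6, size=nb).astype(float)
            if np.all(np.concatenate([a, b]) == a[0] if na else False):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u, p = xs.mann_whitney_u(a, b, mode="exact")
            uo, po = oracle_mwu(a, b)
            assert u == pytest.approx(uo, abs=1e-12)
            assert p == pytest.approx(po, abs=1e-12)


def test_t_tests_known_behaviour():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = xs.student_t([1, 2, 3], [1, 2, 3])
    assert t == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)
    # equal group variances: Student and Welch statistics coincide
    a, b = [1.0, 2, 3, 4], [3.0, 4, 5, 6]
    ts, ps = xs.student_t(a, b)
    tw, pw = xs.welch_t(a, b)
    assert ts == pytest.approx(tw, abs=1e-12)
    # hand computation: sp2 = 5/3, t = -2 / sqrt(sp2 * 0.5)
    sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
    t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
    assert ts == pytest.approx(t_hand, abs=1e-12)
    from scipy import stats

    assert ps == pytest.approx(2 * stats.t.sf(abs(t_hand), 6), abs=1e-12)


def test_t_zero_variance_edges():
    t, p = xs.student_t([2, 2, 2], [2, 2, 2])
    assert (t, p) == (0.0, 1.0)
    with pytest.warns(UserWarning, match="zero variance"):
        t, p = xs.welch_t([1, 1, 1], [2, 2, 2])
    assert p == np.finfo(float).tiny and np.isinf(t)


def test_paired_t_identical_pairs():
    t, p = xs.paired_t([1, 2, 3], [1, 2, 3])
    assert (t, p) == (0.0, 1.0)


def test_wilcoxon_all_positive_exact():
    w, p = xs.wilcoxon_signed_rank([2, 4, 6, 8, 10], [1, 2, 3, 4, 5])
    assert w == 15.0
    assert p == pytest.approx(0.0625)  # 2/32 sign assignments as extreme


def test_wilcoxon_matches_enumeration_oracle():
    rng = np.random.default_rng(8)
    for m in range(2, 11):
        d = rng.integers(-4, 5, size=m).astype(float)
        if np.all(d == 0):
            continue
        a = d
        b = np.zeros_like(d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = xs.wilcoxon_signed_rank(a, b, mode="exact")
        wo, po = oracle_wilcoxon(d)
        assert w == pytest.approx(wo, abs=1e-12)
        assert p == pytest.approx(po, abs=1e-12)


def test_wilcoxon_shift_invariance():
    a = np.array([1.0, 3, 5, 7, 11])
    b = np.array([2.0, 2, 6, 4, 9])
    w1, p1 = xs.wilcoxon_signed_rank(a, b)
    w2, p2 = xs.wilcoxon_signed_rank(a + 100, b + 100)
    assert (w1, p1) == (w2, p2)


def test_wilcoxon_all_zero_differences():
    with pytest.warns(UserWarning, match="zero"):
        w, p = xs.wilcoxon_signed_rank([1, 2], [1, 2])
    assert p == 1.0


# ----------------------------------------------------------------------
def test_permutation_extreme_observation():
    # groups large enough that no permutation reproduces the observed split
    a = list(100.0 + np.arange(10))
    b = list(np.arange(10.0))
    t, p = xs.permutation_test(a, b, B=99, seed=1)
    assert t == pytest.approx(100.0)
    assert p == pytest.approx(0.01)  # (1 + 0) / 100


def test_permutation_identical_groups():
    a = [1.0, 2, 3, 4, 5]
    t, p = xs.permutation_test(a, a, B=199, seed=0)
    assert t == 0.0
    assert p > 0.9


def test_permutation_deterministic_given_seed():
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=15), rng.normal(size=15)
    r1 = xs.permutation_test(a, b, B=99, seed=42)
    r2 = xs.permutation_test(a, b, B=99, seed=42)
    assert r1 == r2
    assert r1 != xs.permutation_test(a, b, B=99, seed=43)


def test_permutation_paired_design():
    a = [5.0, 6, 7, 8, 9, 10]
    b = [1.0, 2, 3, 4, 5, 6]
    t, p = xs.permutation_test(a, b, design="paired", B=99, seed=0)
    assert t == pytest.approx(4.0)
    assert p <= 0.05


# ----------------------------------------------------------------------
def test_log_fold_change():
    assert xs.log_fold_change([4, 4], [2, 2], data_is_log2=True) == 2.0
    assert xs.log_fold_change([3, 3], [3, 3], data_is_log2=True) == 0.0
    assert xs.log_fold_change([8, 8], [2, 2], data_is_log2=False) == 2.0
    with pytest.raises(StatisticError):
        xs.log_fold_change([], [1], data_is_log2=True)


# ----------------------------------------------------------------------
def _groups(project):
    return (
        project.select_samples("status == 'tumor'"),
        project.select_samples("status == 'non-tumor'"),
    )


def test_de_scan_recovers_planted_features(gen_project, gen_fixture):
    res, _ = gen_fixture
    ga, gb = _groups(gen_project)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = xs.de_scan(gen_project, ga, gb, data_is_log2=True)
    called = set(table[table["called"]]["feature_id"])
    truth = set(res.truth["de"]["feature_id"])
    assert called == truth  # full recall, zero false calls


def test_de_scan_null_split_calls_nothing(tmp_path):
    spec = xs.FixtureSpec(n_features=100, n_samples=80, modules=(), n_de=0,
                          diffcorr_pairs=(), seed=5)
    res = xs.generate(spec, str(tmp_path))
    proj = xs.create_project(res.data_path, res.sample_meta_path)
    # arbitrary split of homogeneous data
    ids = proj.sample_ids
    ga = xs.GroupSelection("a", ids[::2])
    gb = xs.GroupSelection("b", ids[1::2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = xs.de_scan(proj, ga, gb, data_is_log2=True)
    assert table["called"].sum() <= 1


def test_de_scan_infinite_fc_bound(gen_project):
    ga, gb = _groups(gen_project)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = xs.de_scan(gen_project, ga, gb, fc_bound=np.inf, data_is_log2=True)
    assert table["called"].sum() == 0


def test_de_scan_overlapping_groups_error(gen_project):
    ga, _ = _groups(gen_project)
    with pytest.raises(StatisticError, match="overlap"):
        xs.de_scan(gen_project, ga, ga)


def test_de_scan_warns_below_30_per_group(toy_project):
    ga = xs.GroupSelection("a", ["S1", "S2"])
    gb = xs.GroupSelection("b", ["S3", "S4"])
    with pytest.warns(UserWarning, match="30"):
        xs.de_scan(toy_project, ga, gb, data_is_log2=True)


def test_de_scan_deterministic_across_workers_and_disk_order(tmp_path, gen_fixture):
    res, _ = gen_fixture
    df = pd.read_csv(res.data_path, sep="\t")
    sh_path = tmp_path / "shuffled.tsv"
    df.sample(frac=1.0, random_state=3).to_csv(sh_path, sep="\t", index=False)
    p1 = xs.create_project(res.data_path, res.sample_meta_path)
    p2 = xs.create_project(str(sh_path), res.sample_meta_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tables = [
            xs.de_scan(p, ga_gb[0], ga_gb[1], test="perm_independent", B=49,
                       seed=7, n_workers=w, data_is_log2=True)
            for p, w in [(p1, 1), (p1, 3), (p2, 1)]
            for ga_gb in [_groups(p)]
        ]
    assert tables[0].to_csv() == tables[1].to_csv() == tables[2].to_csv()


# ----------------------------------------------------------------------
def test_stage_scan_monotone_features_labeled_increasing(tmp_path):
    spec = xs.FixtureSpec(n_features=60, n_samples=240, organs=("kidney",),
                          modules=(), n_de=0, diffcorr_pairs=(), n_stage=5,
                          stage_delta=1.2, noise_sd=0.4, seed=9)
    res = xs.generate(spec, str(tmp_path))
    proj = xs.create_project(res.data_path, res.sample_meta_path)
    cands = res.truth["stage"]["feature_id"].tolist()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = xs.stage_scan(proj, "organ", "stage", ["I", "II"], ["III", "IV"],
                              cands, fc_bound=1.0, p_bound=0.05, data_is_log2=True)
    assert (table["label"] == "increasing").all()
    assert len(table) == 5


def test_stage_scan_shuffled_stages_mostly_flat(tmp_path):
    spec = xs.FixtureSpec(n_features=60, n_samples=240, organs=("kidney",),
                          modules=(), n_de=0, diffcorr_pairs=(), n_stage=0, seed=10)
    res = xs.generate(spec, str(tmp_path))
    proj = xs.create_project(res.data_path, res.sample_meta_path)
    cands = proj.feature_ids[:20]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = xs.stage_scan(proj, "organ", "stage", ["I", "II"], ["III", "IV"],
                              cands)
    assert (table["label"] != "flat").sum() <= 1


def test_stage_scan_empty_candidates(gen_project):
    table = xs.stage_scan(gen_project, "organ", "stage", ["I"], ["III"], [])
    assert table.empty


def test_volcano_table(gen_project):
    ga, gb = _groups(gen_project)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        de = xs.de_scan(gen_project, ga, gb, data_is_log2=True)
    v = xs.volcano_table(de)
    assert list(v.columns) == ["feature_id", "logFC", "neg_log10_p_adj"]
    assert len(v) == len(de)
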