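"""Correlation statistics, streaming scans, QC screen and edge export."""

import itertools

import numpy as np
import pandas as pd
import pytest

import exprstream as xs
from exprstream.exceptions import StatisticError


def brute_pearson(x, y):
    """Textbook covariance/variance formula, independent of scipy."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def brute_rank(v):
    """Mean ranks computed by explicit tie-group averaging."""
    v = np.asarray(v, float)
    out = np.empty(v.size)
    order = np.argsort(v, kind="mergesort")
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        out[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return out


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [6, 4, 2], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ],
)
def test_pearson_known_values(x, y, expected):
    res = xs.pearson(x, y)
    assert res.r == pytest.approx(expected, abs=1e-12)
    assert res.n == len(x)


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [1, 10, 100], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
    ],
)
def test_spearman_monotone(x, y, expected):
    assert xs.spearman(x, y).r == pytest.approx(expected, abs=1e-12)


def test_spearman_ties_equal_pearson_of_mean_ranks():
    x = [1, 1, 2, 3]
    y = [1, 2, 3, 4]
    expected = brute_pearson(brute_rank(x), brute_rank(y))
    assert xs.spearman(x, y).r == pytest.approx(expected, abs=1e-12)


def test_correlations_match_brute_force_on_random_vectors():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = rng.integers(4, 51)
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        assert xs.pearson(x, y).r == pytest.approx(brute_pearson(x, y), abs=1e-12)
        assert xs.spearman(x, y).r == pytest.approx(
            brute_pearson(brute_rank(x), brute_rank(y)), abs=1e-12
        )


def test_constant_vector_is_undefined_not_zero():
    with pytest.raises(StatisticError):
        xs.pearson([1, 1, 1], [1, 2, 3])
    with pytest.raises(StatisticError):
        xs.spearman([2, 2, 2, 2], [1, 2, 3, 4])


def test_pairwise_complete_observations():
    x = [1, 2, np.nan, 4, 5]
    y = [2, np.nan, 3, 8, 10]
    res = xs.pearson(x, y)
    assert res.n == 3
    assert res.r == pytest.approx(brute_pearson([1, 4, 5], [2, 8, 10]), abs=1e-12)


def test_symmetry_in_arguments():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=20), rng.normal(size=20)
    assert xs.pearson(x, y).r == pytest.approx(xs.pearson(y, x).r, abs=1e-15)


# ----------------------------------------------------------------------
def test_feature_vs_all_ranks_module_partners_top(gen_project, gen_fixture):
    res, _ = gen_fixture
    members = res.truth["modules"]["feature_id"].tolist()
    table = xs.feature_vs_all(gen_project, members[0], method="pearson")
    assert table["feature_b"].tolist()[:4] == sorted(members[1:]) or set(
        table["feature_b"][:4]
    ) == set(members[1:])
    assert members[0] not in table["feature_b"].values  # self excluded
    assert len(table) == gen_project.n_features - 1


def test_feature_vs_all_invariant_to_disk_order(tmp_path, gen_fixture):
    res, _ = gen_fixture
    df = pd.read_csv(res.data_path, sep="\t")
    shuffled = df.sample(frac=1.0, random_state=5)
    sh_path = tmp_path / "shuffled.tsv"
    shuffled.to_csv(sh_path, sep="\t", index=False)
    p1 = xs.create_project(res.data_path, res.sample_meta_path)
    p2 = xs.create_project(str(sh_path), res.sample_meta_path)
    t1 = xs.feature_vs_all(p1, "G000001")
    t2 = xs.feature_vs_all(p2, "G000001")
    assert t1.to_csv() == t2.to_csv()


def test_feature_vs_all_worker_counts_agree(gen_project):
    t1 = xs.feature_vs_all(gen_project, "G000002", n_workers=1)
    t3 = xs.feature_vs_all(gen_project, "G000002", n_workers=3)
    assert t1.to_csv() == t3.to_csv()


def test_feature_vs_all_short_vectors_reported_missing(tmp_path):
    from conftest import write

    data = write(
        tmp_path / "d.tsv",
        "gene_id\tS1\tS2\tS3\tS4\n"
        "G1\t1\t2\t3\t4\n"
        "G2\t2\t4\t6\t8\n"
        "G3\tNA\tNA\t1\t2\n",
    )
    samples = write(
        tmp_path / "s.tsv", "sample_id\to\nS1\tx\nS2\tx\nS3\tx\nS4\tx\n"
    )
    proj = xs.create_project(data, samples)
    table = xs.feature_vs_all(proj, "G1")
    row = table[table["feature_b"] == "G3"].iloc[0]
    assert np.isnan(row["statistic"]) and row["n"] == 2


# ----------------------------------------------------------------------
def test_qc_screen_flags_shuffled_sample(tmp_path):
    rng = np.random.default_rng(3)
    n_feat = 2000
    base = rng.normal(8, 2, size=n_feat)
    mat = np.column_stack([base + rng.normal(0, 0.3, n_feat) for _ in range(4)])
    mat[:, 3] = rng.permutation(mat[:, 3])  # destroy sample 4's concordance
    df = pd.DataFrame(mat, columns=["S1", "S2", "S3", "S4"])
    df.insert(0, "gene_id", [f"G{i}" for i in range(n_feat)])
    df.to_csv(tmp_path / "d.tsv", sep="\t", index=False)
    (tmp_path / "s.tsv").write_text(
        "sample_id\torgan\nS1\tliver\nS2\tliver\nS3\tliver\nS4\tliver\n"
    )
    proj = xs.create_project(str(tmp_path / "d.tsv"), str(tmp_path / "s.tsv"))
    group = proj.select_samples("organ == 'liver'")
    screen = xs.sample_correlation_screen(proj, group, threshold=0.70)
    assert screen[screen["flag"]]["sample"].tolist() == ["S4"]
    # boundary: threshold 1.0 flags everything on noisy data
    all_flagged = xs.sample_correlation_screen(proj, group, threshold=1.0)
    assert all_flagged["flag"].all()


def test_qc_screen_group_too_small(toy_project):
    g = xs.GroupSelection("one", ["S1"])
    with pytest.raises(StatisticError):
        xs.sample_correlation_screen(toy_project, g)


def test_qc_screen_matches_direct_pairwise_pearson(gen_project):
    group = gen_project.select_samples("organ == 'liver'")
    ids = group.sample_ids[:5]
    screen = xs.sample_correlation_screen(
        gen_project, xs.GroupSelection("sub", ids), threshold=0.7
    )
    cols = {s: [] for s in ids}
    for vec in gen_project.iter_features():
        v = vec.subset(ids)
        for s, val in zip(ids, v):
            cols[s].append(val)
    direct = np.array(
        [
            [
                brute_pearson(cols[a], cols[b]) if a != b else np.nan
                for b in ids
            ]
            for a in ids
        ]
    )
    np.testing.assert_allclose(
        screen["max_r"].to_numpy(), np.nanmax(direct, axis=1), atol=1e-10
    )


# ----------------------------------------------------------------------
def test_export_edges(tmp_path, gen_project, gen_fixture):
    res, _ = gen_fixture
    members = sorted(res.truth["modules"]["feature_id"])
    table = xs.all_pairs(gen_project, gen_project.feature_ids[:40] + members)
    out = tmp_path / "edges.tsv"
    n = xs.export_edges(table, 0.6, str(out))
    edges = pd.read_csv(out, sep="\t")
    within = set(itertools.combinations(members, 2))
    got = set(zip(edges["feature_a"], edges["feature_b"]))
    assert within <= got  # all 10 within-module edges present
    # no duplicated undirected pair
    assert len(got) == len(edges) == n
    assert not any((b, a) in got for a, b in got if a != b)
    # threshold above the max statistic: nothing survives
    assert xs.export_edges(table, 2.0, str(tmp_path / "none.tsv")) == 0
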