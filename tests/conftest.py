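import textwrap

import pytest

import exprstream as xs


def write(path, text):
    path.write_text(textwrap.dedent(text).lstrip())
    return str(path)


@pytest.fixture
def toy_files(tmp_path):
    """3 features x 4 samples with one metadata column and one missing value."""
    data = write(
        tmp_path / "data.tsv",
        """
        gene_id\tdescription\tS1\tS2\tS3\tS4
        G1\talpha unknown\t1\t2\t3\t4
        G2\tbeta\t5\tNA\t7\t8
        G3\tgamma\t0\t0.5\t1\t1.5
        """,
    )
    samples = write(
        tmp_path / "samples.tsv",
        """
        sample_id\torgan\tstage\tstudy
        S1\tliver\tI\tA
        S2\tliver\tII\tA
        S3\tkidney\tI\tB
        S4\tkidney\tIII\tB
        """,
    )
    return data, samples


@pytest.fixture
def toy_project(toy_files):
    data, samples = toy_files
    return xs.create_project(data, samples)


@pytest.fixture(scope="session")
def gen_fixture(tmp_path_factory):
    """A generated multi-study dataset with planted module, DE and diffcorr pair."""
    out = tmp_path_factory.mktemp("genfix")
    spec = xs.FixtureSpec(
        n_features=120,
        n_samples=200,
        n_studies=3,
        modules=((5, 0.95),),
        n_de=10,
        de_logfc=2.0,
        de_noise_sd=0.5,
        diffcorr_pairs=((0.7, 0.0),),
        n_unknown=6,
        seed=11,
    )
    return xs.generate(spec, str(out)), spec


@pytest.fixture(scope="session")
def gen_project(gen_fixture):
    res, _ = gen_fixture
    return xs.create_project(res.data_path, res.sample_meta_path)
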