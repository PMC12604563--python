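import numpy as np
import pandas as pd
import pytest

from magtx.simulate import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """2 MAGs x 80 genes, 12 samples, moderate depth; shared by tests
    that only need a structurally valid dataset."""
    params = SimParams(
        n_mags=2, genes_per_mag=80, depth_per_sample=2e5, dispersion=0.1, seed=11
    )
    return simulate_dataset(params)


@pytest.fixture()
def tiny_files(tmp_path):
    """Hand-written 3-gene, 2-sample dataset files."""
    (tmp_path / "counts.tsv").write_text(
        "# featureCounts-style fixture\n"
        "Geneid\tMAG\tLength\ts1\ts2\n"
        "gA\tM1\t1000\t30\t10\n"
        "gB\tM1\t500\t0\t4\n"
        "gC\tM2\t2000\t8\t16\n"
    )
    (tmp_path / "annotations.tsv").write_text(
        "gene_id\tmag_id\tlength_bp\tko\tproduct\n"
        "gA\tM1\t1000\tK00001\tthing A\n"
        "gB\tM1\t500\t\t\n"
        "gC\tM2\t2000\tK00002\tthing C\n"
    )
    (tmp_path / "markers.tsv").write_text(
        "gene_id\tmag_id\tcog_id\ngA\tM1\tCOG0012\ngC\tM2\tCOG0012\n"
    )
    (tmp_path / "samples.tsv").write_text(
        "sample_id\tcondition\tphase\tcycle\tday\n"
        "s1\thigh_p\tfeeding\t1\t10\n"
        "s2\tlow_p\tfeeding\t1\t20\n"
    )
    return tmp_path


def nb_counts(rng, mean, phi, size):
    """Independent NB draws with variance = mean + phi*mean^2."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if phi == 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, phi * mean)
    return rng.poisson(lam)


@pytest.fixture(scope="session")
def nb_sampler():
    return nb_counts


def two_group_frame(rng, n_genes, n_per_group, mean, phi, de_frac=0.0, log2fc=0.0):
    """Gene x sample DataFrame of NB counts with optional true DE in
    the first de_frac genes (group A shifted by 2**log2fc)."""
    n_de = int(round(de_frac * n_genes))
    mean_a = np.full(n_genes, float(mean))
    mean_a[:n_de] *= 2.0 ** log2fc
    a = nb_counts(rng, mean_a[:, None], phi, (n_genes, n_per_group))
    b = nb_counts(rng, np.full((n_genes, 1), float(mean)), phi, (n_genes, n_per_group))
    cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    df = pd.DataFrame(np.hstack([a, b]), columns=cols)
    df.index = [f"g{i:05d}" for i in range(n_genes)]
    return df, n_de


@pytest.fixture(scope="session")
def make_two_group():
    return two_group_frame
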