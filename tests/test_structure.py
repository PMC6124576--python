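import numpy as np
import pandas as pd
import pytest

from epiconserve.errors import ValidationError
from epiconserve.expression import ExpressionMatrix, normalize
from epiconserve.structure import (correlation_cluster, flag_outliers,
                                   linkage_to_newick, pca)
from .conftest import make_matrix


def random_matrix(n_genes=40, n_samples=6, seed=0, groups=None):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.lognormal(2, 1, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)])
    samples = pd.DataFrame({
        "species": "mouse",
        "stage_or_condition": groups or ["ICM"] * n_samples,
        "replicate": range(1, n_samples + 1)}, index=data.columns)
    return ExpressionMatrix(data, samples, "cpm")


def test_duplicated_sample_correlates_perfectly_and_merges_first():
    m = random_matrix(n_samples=4, seed=1)
    m.data["s1"] = m.data["s0"]  # duplicate
    res = correlation_cluster(m)
    assert res.correlation.loc["s0", "s1"] == pytest.approx(1.0)
    first_merge = res.linkage[0]
    assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
    assert first_merge[2] == pytest.approx(0.0, abs=1e-12)


def test_negated_sample_correlates_minus_one():
    base = np.arange(10, dtype=float)
    data = pd.DataFrame({"s0": base, "s1": base.max() - base})
    samples = pd.DataFrame({"species": "mouse",
                            "stage_or_condition": ["ICM", "ICM"],
                            "replicate": [1, 2]}, index=data.columns)
    m = ExpressionMatrix(data, samples, "cpm")
    res = correlation_cluster(m)
    assert res.correlation.loc["s0", "s1"] == pytest.approx(-1.0)


def test_near_duplicates_pair_before_independent_sample():
    rng = np.random.default_rng(7)
    a = rng.lognormal(2, 1, 60)
    data = pd.DataFrame({"s0": a, "s1": a + rng.normal(0, 0.01, 60),
                         "s2": rng.lognormal(2, 1, 60)})
    samples = pd.DataFrame({"species": "mouse",
                            "stage_or_condition": ["ICM"] * 3,
                            "replicate": [1, 2, 3]}, index=data.columns)
    res = correlation_cluster(ExpressionMatrix(data, samples, "cpm"))
    assert {int(res.linkage[0][0]), int(res.linkage[0][1])} == {0, 1}


def test_zero_variance_sample_errors():
    m = random_matrix(seed=2)
    m.data["s3"] = 5.0
    with pytest.raises(ValidationError, match="s3"):
        correlation_cluster(m)


def test_collinear_samples_put_all_variance_on_pc1():
    base = np.linspace(1, 4, 30)
    data = pd.DataFrame({f"s{j}": j * base for j in range(1, 5)})
    samples = pd.DataFrame({"species": "mouse",
                            "stage_or_condition": ["ICM"] * 4,
                            "replicate": range(1, 5)}, index=data.columns)
    res = pca(ExpressionMatrix(data, samples, "cpm"))
    assert res.variance_fractions[0] == pytest.approx(1.0)


def test_rank_two_data_has_two_nonzero_components():
    rng = np.random.default_rng(11)
    u = rng.normal(size=(30, 2))
    v = rng.normal(size=(2, 4))
    low_rank = u @ v
    # shift to nonnegative; a constant offset is removed by centering
    data = pd.DataFrame(low_rank - low_rank.min() + 1.0,
                        columns=[f"s{j}" for j in range(4)])
    samples = pd.DataFrame({"species": "mouse",
                            "stage_or_condition": ["ICM"] * 4,
                            "replicate": range(1, 5)}, index=data.columns)
    res = pca(ExpressionMatrix(data, samples, "cpm"))
    assert res.variance_fractions[2] == pytest.approx(0.0, abs=1e-10)
    assert res.variance_fractions[3] == pytest.approx(0.0, abs=1e-10)


def test_variance_fractions_sorted_and_sum_to_one():
    res = pca(random_matrix(seed=3))
    f = res.variance_fractions
    assert np.all(np.diff(f) <= 1e-12)
    assert np.sum(f) == pytest.approx(1.0)


def test_scores_reproduce_spectrum():
    m = random_matrix(seed=4)
    res = pca(m)
    cov = res.scores.to_numpy().T @ res.scores.to_numpy()
    off = cov - np.diag(np.diag(cov))
    assert np.allclose(off, 0, atol=1e-8)  # orthogonal score columns


def test_pca_and_correlation_invariant_to_gene_order():
    m = random_matrix(seed=5)
    shuffled = ExpressionMatrix(
        m.data.sample(frac=1, random_state=0), m.samples, m.unit)
    assert np.allclose(pca(m).variance_fractions,
                       pca(shuffled).variance_fractions)
    assert np.allclose(correlation_cluster(m).correlation,
                       correlation_cluster(shuffled).correlation)


def test_good_replicates_not_excluded(study):
    mat = study.species_matrices["mouse"]
    logm = normalize(mat, "cpm", log2_offset=1.0)
    res = flag_outliers(logm, min_median_r=0.7)
    assert res.excluded == []


def test_poor_sample_excluded():
    m = random_matrix(n_genes=200, n_samples=4, seed=6,
                      groups=["ICM"] * 4)
    rng = np.random.default_rng(8)
    m.data["s3"] = rng.lognormal(2, 1, 200)  # unrelated to its peers
    # make the first three mutually consistent
    for s in ("s1", "s2"):
        m.data[s] = m.data["s0"] * rng.lognormal(0, 0.02, 200)
    res = flag_outliers(m, min_median_r=0.7)
    assert [s for s, _ in res.excluded] == ["s3"]
    assert "median within-group r" in res.excluded[0][1]


def test_newick_export_preserves_tree_heights():
    dendropy = pytest.importorskip("dendropy")
    m = random_matrix(n_samples=5, seed=12)
    res = correlation_cluster(m)
    nwk = linkage_to_newick(res.linkage, list(m.sample_ids))
    assert nwk.endswith(";") and nwk.count("(") == len(m.sample_ids) - 1
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    # average-linkage trees are ultrametric: every root-to-leaf depth
    # equals the final merge height
    root_h = float(res.linkage[-1][2])
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    assert np.allclose(depths, root_h, atol=1e-6)
    assert {t.taxon.label for t in tree.leaf_node_iter()} == \
        set(m.sample_ids)


def test_singleton_group_never_excluded():
    m = random_matrix(n_samples=3, seed=9, groups=["ICM", "ICM", "ERSE"])
    res = flag_outliers(m, min_median_r=0.99)
    assert all(s != "s2" for s, _ in res.excluded)
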