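import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import epiconserve as ec
from epiconserve.diffexpr import (DECallConfig, bh_adjust, call_de, de_sets,
                                  de_test, common_dispersion_cml)
from epiconserve.errors import ConfigurationError, ValidationError
from .conftest import make_matrix


def two_group_matrix(vals_a, vals_b, extra_total=1e6):
    """Matrix where sample totals are padded to 1e6 so CPM == counts."""
    genes = {}
    for i, (a, b) in enumerate(zip(vals_a, vals_b)):
        genes[f"g{i}"] = dict(
            {f"a{j}": v for j, v in enumerate(a)},
            **{f"b{j}": v for j, v in enumerate(b)})
    used_a = np.sum(vals_a, axis=0)
    used_b = np.sum(vals_b, axis=0)
    genes["pad"] = dict(
        {f"a{j}": extra_total - t for j, t in enumerate(used_a)},
        **{f"b{j}": extra_total - t for j, t in enumerate(used_b)})
    return make_matrix(genes)


def test_identical_groups_fold_change_zero():
    m = two_group_matrix([[10, 10], [30, 30]], [[10, 10], [30, 30]])
    res = de_test(m, ["a0", "a1"], ["b0", "b1"])
    assert np.allclose(res["log2fc"], 0.0)


def test_mean_based_fold_change_arithmetic():
    # gene means 10 vs 20 with pseudo-mean 0 -> log2FC = 1
    m = two_group_matrix([[10, 10]], [[20, 20]])
    res = de_test(m, ["a0", "a1"], ["b0", "b1"], pseudo_mean=0.0)
    assert res.loc["g0", "log2fc"] == pytest.approx(1.0)


def test_both_groups_all_zero_gene():
    m = two_group_matrix([[0, 0], [50, 50]], [[0, 0], [50, 50]])
    res = de_test(m, ["a0", "a1"], ["b0", "b1"])
    assert res.loc["g0", "p"] == 1.0
    assert res.loc["g0", "log2fc"] == 0.0


def test_single_sample_group_rejected():
    m = two_group_matrix([[10, 10]], [[20, 20]])
    with pytest.raises(ValidationError):
        de_test(m, ["a0"], ["b0", "b1"])


def test_reversing_transition_negates_log2fc(study):
    m = study.species_matrices["mouse"]
    icm = m.group_samples(stage_or_condition="ICM")
    erse = m.group_samples(stage_or_condition="ERSE")
    fwd = de_test(m, icm, erse)
    rev = de_test(m, erse, icm)
    assert np.allclose(fwd["log2fc"], -rev["log2fc"])
    assert np.allclose(fwd["p"], rev["p"])


def test_swapping_groups_swaps_up_and_down(study):
    m = study.species_matrices["mouse"]
    icm = m.group_samples(stage_or_condition="ICM")
    erse = m.group_samples(stage_or_condition="ERSE")
    fwd = call_de(de_test(m, icm, erse))
    rev = call_de(de_test(m, erse, icm))
    fu, fd = de_sets(fwd)
    ru, rd = de_sets(rev)
    assert fu == rd and fd == ru


def test_bh_hand_computed_example():
    q = bh_adjust([0.002, 0.01, 0.03, 0.04])
    assert np.allclose(q, [0.008, 0.02, 0.04, 0.04])


def test_bh_degenerate_inputs():
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    assert bh_adjust([0.37]) == pytest.approx([0.37])
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.2])


def brute_force_bh(p):
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
def test_bh_matches_step_up_definition(p):
    assert np.allclose(bh_adjust(p), brute_force_bh(p))


@pytest.mark.parametrize("q,fc,expected", [
    (0.30, 3.0, "ns"),    # fails the q threshold alone
    (0.01, 1.4, "ns"),    # fails the minimum fold change alone
    (0.10, 2.0, "up"),    # passes both
])
def test_directional_call_thresholds(q, fc, expected):
    res = pd.DataFrame({"log2fc": [np.log2(fc)], "p": [q]},
                       index=["g"])
    # single p-value: q == p, so thresholds act directly
    called = call_de(res)
    assert called.loc["g", "direction"] == expected


def test_up_down_sets_disjoint(study):
    m = study.species_matrices["pig"]
    icm = m.group_samples(stage_or_condition="ICM")
    erse = m.group_samples(stage_or_condition="ERSE")
    up, down = de_sets(call_de(de_test(m, icm, erse)))
    assert not (up & down)


def test_common_dispersion_recovers_generator_phi(study):
    m = study.species_matrices["mouse"]
    groups = []
    for stage in ("ICM", "ERSE"):
        ids = m.group_samples(stage_or_condition=stage)
        groups.append(m.data[ids].to_numpy(np.int64))
    phi = common_dispersion_cml(groups)
    assert 0.07 < phi < 0.14  # true value 0.1


@pytest.mark.parametrize("test", ["nb_exact", "welch_log"])
def test_type_one_error_calibrated_on_nb_null(test):
    """Empirical type-I error at p < 0.05 lies in [0.03, 0.07] on
    negative-binomial null data (fold 1, phi 0.1, 3 vs 3), 2000 genes x
    200 replicate experiments."""
    rng = np.random.default_rng(2024)
    genes, reps, phi = 2000, 200, 0.1
    hits = total = 0
    for block in range(reps):
        mu = rng.lognormal(3.5, 1.0, size=(genes, 1))
        lam = rng.gamma(1 / phi, phi * np.broadcast_to(mu, (genes, 6)))
        counts = rng.poisson(lam)
        data = pd.DataFrame(
            counts, index=[f"g{i}" for i in range(genes)],
            columns=[f"s{j}" for j in range(6)])
        samples = pd.DataFrame({
            "species": "mouse",
            "stage_or_condition": ["ICM"] * 3 + ["ERSE"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }, index=data.columns)
        m = ec.ExpressionMatrix(data.astype(float), samples, "raw")
        res = de_test(m, list(data.columns[:3]), list(data.columns[3:]),
                      test=test)
        hits += int((res["p"] < 0.05).sum())
        total += len(res)
    alpha = hits / total
    assert 0.03 <= alpha <= 0.07, f"empirical alpha {alpha:.4f}"


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        DECallConfig(q_max=0.0).validate()
    with pytest.raises(ConfigurationError):
        DECallConfig(fc_min=0.9).validate()
    with pytest.raises(ConfigurationError):
        DECallConfig(test="deseq").validate()
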