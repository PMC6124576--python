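import numpy as np
import pandas as pd
import pytest

from epiconserve.errors import ValidationError
from epiconserve.expression import ExpressionMatrix
from epiconserve.predictor import (derive_panel, score_samples,
                                   transitional_fraction)

SP = ("mouse", "pig", "bovine")


def build_invivo(down=(), up=(), species=SP):
    return {sp: {"ICM->ERSE": {"up": set(up), "down": set(down)},
                 "ICM->APE": {"up": set(up), "down": set(down)}}
            for sp in species}


def build_invitro(up_full=(), down_full=(), up_early=(), down_early=()):
    return {"2i->serum": {"up": set(up_early), "down": set(down_early)},
            "serum->EpiSC": {"up": set(), "down": set()},
            "2i->EpiSC": {"up": set(up_full), "down": set(down_full)}}


EXPR = {"2i": {"Klf4", "Spic", "Gjb5"}, "serum": {"Klf4", "Gjb5", "Dusp6"},
        "EpiSC": {"Dusp6", "Sema6a"}}


def test_naive_pattern_classified():
    # conserved down ICM->late in all species, down 2i->EpiSC, expressed in
    # serum -> plain naive
    panel = derive_panel(build_invivo(down={"Klf4"}),
                         build_invitro(down_full={"Klf4"}), EXPR)
    assert [(g.group_id, g.klass) for g in panel] == [("Klf4", "naive")]


def test_ground_state_restricted_classified():
    # naive pattern but expressed only in 2i among the culture conditions
    panel = derive_panel(build_invivo(down={"Spic"}),
                         build_invitro(down_full={"Spic"}), EXPR)
    assert [(g.group_id, g.klass) for g in panel] == \
        [("Spic", "ground_state_restricted")]


def test_transition_gene_classified():
    # primed pattern with upregulation already at 2i->serum
    panel = derive_panel(build_invivo(up={"Dusp6"}),
                         build_invitro(up_full={"Dusp6"},
                                       up_early={"Dusp6"}), EXPR)
    assert [(g.group_id, g.klass) for g in panel] == [("Dusp6", "transition")]


def test_plain_primed_classified():
    panel = derive_panel(build_invivo(up={"Sema6a"}),
                         build_invitro(up_full={"Sema6a"}), EXPR)
    assert [(g.group_id, g.klass) for g in panel] == [("Sema6a", "primed")]


def test_two_of_three_species_admitted_only_with_min_species_two():
    invivo = build_invivo()
    for sp in ("pig", "bovine"):  # conserved in the two ungulates only
        invivo[sp]["ICM->ERSE"]["up"].add("Sema6a")
    vitro = build_invitro(up_full={"Sema6a"})
    assert derive_panel(invivo, vitro, EXPR, min_species=3) == []
    panel = derive_panel(invivo, vitro, EXPR, min_species=2)
    assert [(g.group_id, g.klass) for g in panel] == [("Sema6a", "primed")]


def test_classes_mutually_exclusive(invivo_de, invitro_de, mapped, study):
    from epiconserve.expression import call_expressed, normalize
    _, vitro, _ = mapped
    norm = normalize(vitro, "cpm")
    expressed = {c: call_expressed(norm, "mouse", c)
                 for c in ("2i", "serum", "EpiSC")}
    panel = derive_panel(invivo_de, invitro_de, expressed)
    ids = [g.group_id for g in panel]
    assert len(ids) == len(set(ids))


def test_transitional_fraction_counting():
    k, n = transitional_fraction({"a", "b", "c", "d"}, {"a", "b", "e"})
    assert (k, n) == (2, 4)
    assert transitional_fraction({"a"}, {"a"}) == (1, 1)
    assert transitional_fraction({"a", "b"}, {"c"}) == (0, 2)
    # restricting to a conserved pool
    k, n = transitional_fraction({"a", "b", "c"}, {"a", "c"}, {"a", "b"})
    assert (k, n) == (1, 2)


def score_fixture(n_naive=4, n_primed=4, n_null=5, seed=0):
    """Cohort with clearly naive-like and primed-like samples."""
    rng = np.random.default_rng(seed)
    from epiconserve.predictor import PredictorGene
    genes, panel = {}, []
    cols = [f"naive_{i}" for i in range(3)] + [f"primed_{i}" for i in range(3)]
    for g in range(n_naive):
        genes[f"nv{g}"] = dict(zip(cols, [100, 110, 90, 2, 1, 3]))
        panel.append(PredictorGene(f"nv{g}", "naive"))
    for g in range(n_primed):
        genes[f"pr{g}"] = dict(zip(cols, [1, 3, 2, 95, 105, 100]))
        panel.append(PredictorGene(f"pr{g}", "primed"))
    for g in range(n_null):
        v = rng.lognormal(3, 0.1, 6)
        genes[f"bg{g}"] = dict(zip(cols, v))
    data = pd.DataFrame(genes).T
    samples = pd.DataFrame({
        "species": "mouse",
        "stage_or_condition": ["2i"] * 3 + ["EpiSC"] * 3,
        "replicate": [1, 2, 3, 1, 2, 3]}, index=pd.Index(cols, name="sample_id"))
    return ExpressionMatrix(data.astype(float), samples, "cpm"), panel


def test_score_forced_signs():
    mat, panel = score_fixture()
    scores = {s.sample_id: s for s in score_samples(mat, panel)}
    for sid, s in scores.items():
        if sid.startswith("naive"):
            assert s.delta > 0 and s.call == "naive-like"
        else:
            assert s.delta < 0 and s.call == "primed-like"


def test_identical_samples_identical_scores():
    mat, panel = score_fixture()
    mat.data["primed_2"] = mat.data["primed_1"]
    scores = {s.sample_id: s for s in score_samples(mat, panel)}
    assert scores["primed_1"].delta == pytest.approx(scores["primed_2"].delta)


def test_score_invariant_to_gene_order_and_extra_genes():
    mat, panel = score_fixture()
    base = {s.sample_id: s.delta for s in score_samples(mat, panel)}
    shuffled = ExpressionMatrix(mat.data.sample(frac=1, random_state=1),
                                mat.samples, mat.unit)
    extra = shuffled.data.copy()
    extra.loc["unrelated"] = 42.0
    bigger = ExpressionMatrix(extra, mat.samples, mat.unit)
    for variant in (shuffled, bigger):
        got = {s.sample_id: s.delta for s in score_samples(variant, panel)}
        assert all(got[k] == pytest.approx(v) for k, v in base.items())


def test_insufficient_panel_coverage_errors():
    mat, panel = score_fixture(n_naive=2)
    panel = [g for g in panel if not (g.klass == "naive"
                                      and g.group_id in ("nv2", "nv3"))]
    with pytest.raises(ValidationError, match="panel coverage"):
        score_samples(mat, panel)
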