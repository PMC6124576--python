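import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import epiconserve as ec
from epiconserve.expression import ExpressionMatrix

settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("suite")


def make_matrix(values: dict, species: str = "mouse",
                stages: dict | None = None, unit: str = "raw"):
    """Tiny ExpressionMatrix from {gene: {sample: value}} plus stage map."""
    data = pd.DataFrame(values).T
    samples = pd.DataFrame({
        "species": species,
        "stage_or_condition": [
            (stages or {}).get(s, "ICM") for s in data.columns],
        "replicate": range(1, len(data.columns) + 1),
    }, index=pd.Index(data.columns, name="sample_id"))
    return ExpressionMatrix(data.astype(float), samples, unit)


@pytest.fixture(scope="session")
def study():
    """One default-condition synthetic study, shared across tests."""
    return ec.simulate(ec.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def mapped(study):
    """Species matrices re-keyed onto 1:1:1 orthologue groups."""
    one = ec.filter_one_to_one(study.ortholog_table)
    mats = {sp: ec.map_to_groups(m, one, sp)
            for sp, m in study.species_matrices.items()}
    vitro = ec.map_to_groups(study.invitro, one, "mouse")
    return mats, vitro, set(ec.shared_universe(mats))


@pytest.fixture(scope="session")
def invivo_de(mapped):
    mats, _, _ = mapped
    trans = [("ICM", "ERSE"), ("ERSE", "APE"), ("ICM", "APE")]
    return {sp: {t: dict(zip(("up", "down"), ec.de_sets(c)))
                 for t, c in ec.transition_tests(m, sp, trans).items()}
            for sp, m in mats.items()}


@pytest.fixture(scope="session")
def invitro_de(mapped):
    _, vitro, _ = mapped
    vtrans = [("2i", "serum"), ("serum", "EpiSC"), ("2i", "EpiSC")]
    return {t: dict(zip(("up", "down"), ec.de_sets(c)))
            for t, c in ec.transition_tests(vitro, "mouse", vtrans).items()}
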