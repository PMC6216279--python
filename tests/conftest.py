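import pytest
from hypothesis import HealthCheck, settings

import mitofidelity as mf

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code1() -> mf.GeneticCode:
    return mf.load_genetic_code(1)


@pytest.fixture(scope="session")
def code2() -> mf.GeneticCode:
    return mf.load_genetic_code(2)


@pytest.fixture(scope="session")
def code11() -> mf.GeneticCode:
    return mf.load_genetic_code(11)


@pytest.fixture(scope="session")
def human_mtdna() -> mf.Genome:
    return mf.load_human_mtdna()


@pytest.fixture(scope="session")
def mtdna_features(human_mtdna):
    return {f.gene_id: f for f in human_mtdna.features}


@pytest.fixture(scope="session")
def co1(human_mtdna, mtdna_features, code2) -> mf.CodingSequence:
    return mf.extract_cds(human_mtdna, mtdna_features["MT-CO1"], code2, utr3_len=69)


@pytest.fixture(scope="session")
def co2(human_mtdna, mtdna_features, code2) -> mf.CodingSequence:
    return mf.extract_cds(human_mtdna, mtdna_features["MT-CO2"], code2, utr3_len=69)


@pytest.fixture(scope="session")
def cys_hood(code2) -> mf.CodonNeighborhood:
    return mf.near_cognate_set("C", code2)


@pytest.fixture(scope="session")
def met_hood(code2) -> mf.CodonNeighborhood:
    return mf.near_cognate_set("M", code2)
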