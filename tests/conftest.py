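import io

import pytest
from hypothesis import HealthCheck, settings

from filterlab import corpus, ovidql, synthcorpus

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


MEDLINE_SAMPLE = """\
PMID- 1001
TI  - Prognostic significance of tumour markers
AB  - A cohort of patients was followed to assess survival.
MH  - Risk Factors/*epidemiology
MH  - Prognosis
DP  - 2019 Mar

PMID- 1002
TI  - Dietary habits in a rural population
AB  - A causal factor in dietary change was examined.
MH  - Diet
DP  - 2020

PMID- 1003
TI  - Incidence of adverse events
MH  - Incidence
DP  - 2018
"""


@pytest.fixture
def medline_records():
    return corpus.read_records(io.StringIO(MEDLINE_SAMPLE))


@pytest.fixture(scope="session")
def toy_tree():
    return synthcorpus.toy_mesh_tree()


@pytest.fixture(scope="session")
def pf_filter():
    return ovidql.builtin_strategies()["pf_filter"]


@pytest.fixture(scope="session")
def haynes_broad():
    return ovidql.builtin_strategies()["haynes_broad"]


def make_record(rid, title="Untitled study", abstract="", mesh=(), year=None):
    return corpus.Record(
        id=str(rid),
        title=title,
        abstract=abstract,
        mesh_headings=frozenset(mesh),
        year=year,
    )
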