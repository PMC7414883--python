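import pytest

from snpmeta import GeneticModel, builtin_fixture
from snpmeta.meta import effects_from_tables
from snpmeta.models import build_table
from snpmeta.stratify import analyze_all


@pytest.fixture(scope="session")
def fixture_studies():
    """The bundled 15-study rs1805087 prostate-cancer dataset."""
    return builtin_fixture()


@pytest.fixture(scope="session")
def stratified(fixture_studies):
    """Full stratified analysis of the bundled dataset, by stratum level."""
    report = analyze_all(fixture_studies)
    return {level: stratum for (_, level), stratum in report.rows.items()}


@pytest.fixture(scope="session")
def model_effects(fixture_studies):
    """Per-model Woolf effects for all 15 studies."""
    return {
        m: effects_from_tables(
            [build_table(s.cases, s.controls, m) for s in fixture_studies]
        )
        for m in GeneticModel
    }
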