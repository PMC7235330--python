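import pytest

from gsoverlap import AliasTable, GeneSet


@pytest.fixture
def toy_alias_table() -> AliasTable:
    return AliasTable({"SEPT4-ALIAS": "SEPTIN4", "MEF2C": "MEF2C", "A1-OLD": "A1"})


@pytest.fixture
def toy_query() -> GeneSet:
    return GeneSet("QUERY", frozenset({"A", "B", "C", "D"}))


@pytest.fixture
def toy_reference() -> GeneSet:
    return GeneSet("REF", frozenset({"B", "C", "E", "F"}))
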