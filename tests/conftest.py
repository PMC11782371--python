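import pytest

import glycopath as gp


@pytest.fixture(scope="session")
def toy_pathway():
    return gp.load_fixture("n_glycan_toy")


@pytest.fixture(scope="session")
def hmo_pathway():
    return gp.load_fixture("hmo")


@pytest.fixture(scope="session")
def queuosine_pathway():
    return gp.load_fixture("queuosine_trna")


@pytest.fixture()
def all_active_profile(toy_pathway):
    """Every toy-fixture gene robustly expressed at 10 TPM."""
    return gp.ExpressionProfile("allon", {g: 10.0 for g in toy_pathway.genes})


@pytest.fixture()
def mgat3_limited_profile(toy_pathway):
    """All genes at 10 TPM except MGAT3 at 0.4 (below the TPM=1 threshold)."""
    tpm = {g: 10.0 for g in toy_pathway.genes}
    tpm["MGAT3"] = 0.4
    return gp.ExpressionProfile("hek_like", tpm)


MINIMAL_PATHWAY = """
{
 "name": "minimal",
 "structures": [
  {"id": "A", "name": "start", "composition": {"Man": 1}, "is_root": true},
  {"id": "B", "name": "end", "composition": {"Man": 1, "GlcNAc": 1},
   "is_terminal": true}
 ],
 "reactions": [
  {"id": "r1", "substrate": "A", "product": "B", "requirement": "MGAT1"}
 ]
}
"""


@pytest.fixture()
def minimal_pathway():
    return gp.parse_pathway(MINIMAL_PATHWAY)
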