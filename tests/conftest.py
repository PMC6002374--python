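import pytest

from bpfrag import (
    builtin_table,
    candidate_bonds,
    make_precursor,
    parse_structure,
    resonance_forms,
)

GLYCYLLEUCINE_SMILES = "NCC(=O)NC(CC(C)C)C(O)=O"
ETHYL_ARGININATE_SMILES = "CCOC(=O)C(N)CCCNC(=N)N"


@pytest.fixture(scope="session")
def table():
    return builtin_table()


@pytest.fixture()
def glycylleucine():
    return parse_structure(GLYCYLLEUCINE_SMILES, "glycylleucine")


@pytest.fixture()
def ethyl_argininate():
    return parse_structure(ETHYL_ARGININATE_SMILES, "ethyl-argininate")


def find_channel(ion, table, bp_id):
    """(resonance form, bond) whose pattern matches a catalog entry."""
    for form in resonance_forms(ion):
        for bond, bp in candidate_bonds(form):
            rec = table.record_for(bp)
            if rec is not None and rec.bp_id == bp_id:
                return form, bond
    raise LookupError(f"no candidate bond with pattern {bp_id}")


@pytest.fixture()
def gly_precursor(glycylleucine):
    return make_precursor(glycylleucine)


@pytest.fixture()
def arg_precursor(ethyl_argininate):
    return make_precursor(ethyl_argininate)
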