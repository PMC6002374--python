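"""Bonding-pattern extraction, the energy catalog, and pattern-space counts."""

from itertools import combinations_with_replacement

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpfrag import (
    BondingPattern,
    EnergyRecord,
    EnergyTable,
    UNCATALOGUED,
    builtin_table,
    canonical_key,
    enumerate_bp_space,
    extract_bp,
    load_energy_table,
    lookup_energy,
    make_precursor,
    repeated_combination,
    save_energy_table,
)
from bpfrag.catalog import DIRECT, REARRANGED, PatternExtractionError
from bpfrag.errors import TableFormatError
from conftest import find_channel


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def test_carboxyl_bond_pattern(glycylleucine, table):
    ion = make_precursor(glycylleucine)
    _, bond = find_channel(ion, table, 6)
    bp = extract_bp(glycylleucine, bond)
    assert bp.atoms == ("C", "O")
    assert bp.carbon_groups == ("-CH3", "=O")
    assert bp.hetero_groups == ()


def test_amide_bond_truncates_leucyl_to_methyl(glycylleucine, table):
    # the isobutyl-bearing leucyl side collapses to a methyl: saturated
    # carbons adjacent to the bond are always simplified
    ion = make_precursor(glycylleucine)
    _, bond = find_channel(ion, table, 2)
    bp = extract_bp(glycylleucine, bond)
    assert bp.carbon_groups == ("-CH3", "=O")
    assert bp.hetero_groups == ("-CH3",)


def test_ester_alkyl_bond_keeps_acyl_group(ethyl_argininate, table):
    ion = make_precursor(ethyl_argininate)
    _, bond = find_channel(ion, table, 15)
    bp = extract_bp(ethyl_argininate, bond)
    assert bp.atoms == ("C", "O")
    assert bp.carbon_groups == ("-CH3",)
    assert bp.hetero_groups == ("-C(-CH3)(=O)",)


def test_guanidine_patterns(ethyl_argininate, table):
    ion = make_precursor(ethyl_argininate)
    _, bond13 = find_channel(ion, table, 13)
    bp13 = extract_bp(ethyl_argininate, bond13)
    assert bp13.carbon_groups == ("-NH2", "=NH")
    _, bond14 = find_channel(ion, table, 14)
    bp14 = extract_bp(ethyl_argininate, bond14)
    assert bp14.carbon_groups == ("-NH(-CH3)", "=NH")
    assert bp14.hetero_groups == ()


def test_extract_rejects_multiple_bond(glycylleucine):
    double = next(b for b in glycylleucine.bonds if b.order == 2)
    with pytest.raises(PatternExtractionError):
        extract_bp(glycylleucine, double)


def test_extract_rejects_cc_without_acylium_context(glycylleucine):
    cc = next(
        b
        for b in glycylleucine.bonds
        if b.order == 1
        and {glycylleucine.atom(b.i).element, glycylleucine.atom(b.j).element}
        == {"C"}
    )
    with pytest.raises(PatternExtractionError):
        extract_bp(glycylleucine, cc)


# ---------------------------------------------------------------------------
# canonical keys
# ---------------------------------------------------------------------------

_DESCRIPTOR_POOL = [
    "-CH3", "-NH2", "-OH", "=O", "=NH", "=CH2",
    "-C(-OH)(=O)", "-C(-NH2)(=O)", "-NH(-CH3)", "=C(=NH)",
]


@settings(max_examples=50, deadline=None)
@given(
    cg=st.lists(st.sampled_from(_DESCRIPTOR_POOL), max_size=3),
    hg=st.lists(st.sampled_from(_DESCRIPTOR_POOL), max_size=2),
    data=st.data(),
)
def test_canonical_key_order_invariant(cg, hg, data):
    """Keys depend only on the group multisets, never their listing order."""
    cg_perm = data.draw(st.permutations(cg))
    hg_perm = data.draw(st.permutations(hg))
    a = BondingPattern(("C", "N"), tuple(cg), tuple(hg))
    b = BondingPattern(("C", "N"), tuple(cg_perm), tuple(hg_perm))
    assert canonical_key(a) == canonical_key(b)
    assert a == b


def test_distinct_patterns_have_distinct_keys(table):
    keys = {canonical_key(rec.pattern) for rec in table.records}
    assert len(keys) == len(table.records)


def test_extracted_pattern_matches_stored_record(glycylleucine, table):
    ion = make_precursor(glycylleucine)
    _, bond = find_channel(ion, table, 2)
    bp = extract_bp(glycylleucine, bond)
    assert canonical_key(bp) == canonical_key(table.record_by_id(2).pattern)


# ---------------------------------------------------------------------------
# energy table
# ---------------------------------------------------------------------------


def test_packaged_table_has_seventeen_records(table):
    assert len(table) == 17
    assert sorted(rec.bp_id for rec in table.records) == list(range(1, 18))


@pytest.mark.parametrize(
    "bp_id, direct, rearranged",
    [
        (6, 25, None),
        (8, -153, None),
        (12, 403, None),
        (2, 124, 95),
        (15, None, 105),
        (16, 28, 91),
    ],
)
def test_packaged_energies(table, bp_id, direct, rearranged):
    rec = table.record_by_id(bp_id)
    assert rec.e_direct == direct
    assert rec.e_rearranged == rearranged


def test_lookup_distinguishes_absent_from_uncatalogued(table):
    row6 = table.record_by_id(6).pattern
    assert lookup_energy(table, row6, DIRECT) == 25
    assert lookup_energy(table, row6, REARRANGED) is None
    unknown = BondingPattern(("C", "N"), ("-OH",), ("-OH",))
    assert lookup_energy(table, unknown, DIRECT) is UNCATALOGUED


def test_table_round_trip(table, tmp_path):
    path = tmp_path / "table.tsv"
    save_energy_table(table, path)
    again = load_energy_table(path)
    assert again.records == table.records


def test_single_record_round_trip(tmp_path):
    rec = EnergyRecord(
        bp_id=99,
        pattern=BondingPattern(("C", "O"), ("-CH3",), ()),
        e_direct=12.5,
        e_rearranged=None,
    )
    path = tmp_path / "one.tsv"
    save_energy_table(EnergyTable([rec]), path)
    assert load_energy_table(path).records == [rec]


def test_duplicate_key_load_fails(tmp_path):
    text = (
        "bp_id\tatoms\tcarbon_groups\thetero_groups\te_direct\te_rearranged\n"
        "1\tC-O\t-CH3\tnone\t10\tNA\n"
        "2\tC-O\t-CH3\tnone\t20\tNA\n"
    )
    path = tmp_path / "dup.tsv"
    path.write_text(text)
    with pytest.raises(TableFormatError, match="line 3.*line 2"):
        load_energy_table(path)


def test_malformed_energy_reports_line(tmp_path):
    text = (
        "bp_id\tatoms\tcarbon_groups\thetero_groups\te_direct\te_rearranged\n"
        "1\tC-O\t-CH3\tnone\ttwelve\tNA\n"
    )
    path = tmp_path / "bad.tsv"
    path.write_text(text)
    with pytest.raises(TableFormatError, match="line 2"):
        load_energy_table(path)


def test_merge_collision_is_error(table, tmp_path):
    extra = EnergyTable(
        [
            EnergyRecord(
                bp_id=6,
                pattern=table.record_by_id(6).pattern,
                e_direct=1.0,
                e_rearranged=None,
            )
        ]
    )
    with pytest.raises(TableFormatError):
        table.merged(extra)


# ---------------------------------------------------------------------------
# combinatorics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n, r, expected", [(4, 3, 20), (4, 2, 10), (7, 0, 1)])
def test_repeated_combination_values(n, r, expected):
    assert repeated_combination(n, r) == expected


@settings(max_examples=40, deadline=None)
@given(n=st.integers(1, 8), r=st.integers(0, 6))
def test_repeated_combination_matches_enumeration(n, r):
    brute = len(list(combinations_with_replacement(range(n), r)))
    assert repeated_combination(n, r) == brute


def test_repeated_combination_rejects_bad_input():
    with pytest.raises(ValueError):
        repeated_combination(0, 2)
    with pytest.raises(ValueError):
        repeated_combination(3, -1)


def _brute_force_side(free_valence, max_order):
    """Independent oracle: all multisets of (order, element) bonds a bond
    atom can make with its remaining valence, the rest filled by H."""
    tokens = {
        (1, "C"): "-CH3", (1, "N"): "-NH2", (1, "O"): "-OH",
        (2, "C"): "=CH2", (2, "N"): "=NH", (2, "O"): "=O",
        (3, "C"): "#CH", (3, "N"): "#N",
    }
    choices = [
        (o, el)
        for el in "CNO"
        for o in range(1, max_order + 1)
        if (o, el) in tokens
    ]
    seen = set()
    for size in range(free_valence + 1):
        for combo in combinations_with_replacement(choices, size):
            if sum(o for o, _ in combo) <= free_valence:
                seen.add(tuple(sorted(tokens[c] for c in combo)))
    return seen


def test_side_counts_match_brute_force():
    assert len(_brute_force_side(3, 3)) == 34  # carbon side
    assert len(_brute_force_side(2, 2)) == 13  # nitrogen side
    assert len(_brute_force_side(1, 1)) == 4  # oxygen side


def test_enumerate_bp_space_against_brute_force():
    count, patterns = enumerate_bp_space(radius=1)
    carbon = _brute_force_side(3, 3)
    brute = {
        ("C", "N", cg, hg) for cg in carbon for hg in _brute_force_side(2, 2)
    } | {("C", "O", cg, hg) for cg in carbon for hg in _brute_force_side(1, 1)}
    ours = {
        (p.atoms[0], p.atoms[1], p.carbon_groups, p.hetero_groups)
        for p in patterns
    }
    assert len(ours) == len(patterns), "enumerated list contains duplicates"
    assert ours == brute
    assert count == len(patterns) == 34 * 17 == 578


def test_enumerate_count_closed_form():
    count, _ = enumerate_bp_space(radius=1)
    carbon = repeated_combination(4, 3) + 3 * 4 + 2
    hetero = repeated_combination(4, 2) + 3 + 4
    assert count == carbon * hetero


def test_enumerate_radius_two_not_implemented():
    with pytest.raises(NotImplementedError):
        enumerate_bp_space(radius=2)


def test_plausibility_filter_drops_heteroatom_chains():
    count, patterns = enumerate_bp_space(radius=1, plausibility_filter=True)
    assert count == len(patterns) < 578
    for p in patterns:
        assert not any(g[1] in "NO" for g in p.hetero_groups)


def test_all_seventeen_patterns_extractable_from_fixture_chemistry(
    glycylleucine, ethyl_argininate, table
):
    """Catalog/extractor consistency: each packaged pattern is recovered by
    fresh extraction from the two example molecules or their fragments."""
    from bpfrag import (
        acylium_co_loss,
        candidate_bonds,
        direct_cleave,
        rearranged_cleave,
        resonance_forms,
    )

    found = set()

    def scan(ion, depth=0):
        for form in resonance_forms(ion):
            for bond, bp in candidate_bonds(form):
                rec = table.record_for(bp)
                if rec is not None:
                    found.add(rec.bp_id)
        if depth >= 3:
            return
        from bpfrag.errors import BpfragError

        for form in resonance_forms(ion):
            for bond, bp in candidate_bonds(form):
                for op in (direct_cleave, rearranged_cleave):
                    if bp.atoms == ("C", "C"):
                        continue
                    try:
                        scan(op(form, bond, table), depth + 1)
                    except BpfragError:
                        pass
            try:
                scan(acylium_co_loss(form, table), depth + 1)
            except BpfragError:
                pass

    scan(make_precursor(glycylleucine))
    scan(make_precursor(ethyl_argininate))
    assert found == set(range(1, 18))
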