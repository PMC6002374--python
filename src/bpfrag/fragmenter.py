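"""Single-step cleavage of protonated ions.

Semantics (positive-ion mode, singly charged, even-electron only):

* **direct** cleavage breaks the C-X bond heterolytically with no hydrogen
  movement; the heteroatom side leaves together with the mobile proton as
  the neutral, the carbon side keeps the charge (a carbocation, possibly
  an acylium when it bears a carbonyl oxygen).
* **rearranged** cleavage transfers one hydrogen from the carbon side to
  the heteroatom side, which retains the charge (protonated amine /
  alcohol products); the carbon side minus that hydrogen is the neutral.
* **CO loss** is the immediate follow-up available to acylium ions: the
  charged carbonyl leaves as carbon monoxide and the charge moves to the
  adjacent alkyl carbon. Its energy comes from the direct column of the
  C-C patterns.

Every operation conserves composition exactly (parent = fragment +
neutral) and rejects any channel whose neutral would be a radical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from .catalog import (
    DIRECT,
    REARRANGED,
    UNCATALOGUED,
    BondingPattern,
    EnergyTable,
    extract_bp,
    lookup_energy,
)
from .errors import ChannelAbsentError, NoAcyliumError, RingBondError
from .molgraph import (
    ELECTRON_MASS,
    H1,
    BondEdge,
    ElementalFormula,
    MolecularGraph,
    monoisotopic_mass,
    nominal_mass,
    split_on_bond,
)

CO_LOSS = "co_loss"

#: small molecules recognized as named neutral losses
KNOWN_NEUTRALS = {
    ElementalFormula(h=2, o=1): "H2O",
    ElementalFormula(h=3, n=1): "NH3",
    ElementalFormula(c=1, o=1): "CO",
    ElementalFormula(c=2, h=4): "C2H4",
    ElementalFormula(c=1, h=2, n=2): "HN=C=NH",
    ElementalFormula(c=2, h=6, o=1): "C2H5OH",
}


def _is_even_electron_neutral(f: ElementalFormula) -> bool:
    # closed-shell CHNO neutrals have even H+N; odd parity means a radical
    return (f.h + f.n) % 2 == 0


@dataclass(frozen=True)
class NeutralLoss:
    formula: ElementalFormula
    label: str = ""

    @property
    def nominal_mass(self) -> int:
        return nominal_mass(self.formula)

    @staticmethod
    def from_formula(f: ElementalFormula) -> "NeutralLoss":
        return NeutralLoss(formula=f, label=KNOWN_NEUTRALS.get(f, ""))


@dataclass(frozen=True)
class CleavageEvent:
    bond: BondEdge
    mode: str  # direct | rearranged | co_loss
    bp: BondingPattern
    bp_id: Optional[int]
    energy: float
    neutral: NeutralLoss


@dataclass(frozen=True)
class ProtonatedIon:
    """A singly charged even-electron cation at the formula+graph level.

    ``formula`` is the full charged composition (mobile protons included);
    ``graph`` holds the heavy-atom skeleton with the hydrogens that are
    actually placed. ``mobile_protons`` counts charge protons not located
    on any atom (1 for an intact [M+H]+ precursor). ``charged_atom`` is
    None for the precursor, whose proton is mobile over all heteroatoms,
    and a concrete atom index on every fragment ion.
    """

    graph: MolecularGraph
    formula: ElementalFormula
    mobile_protons: int = 0
    charged_atom: Optional[int] = None
    provenance: tuple[CleavageEvent, ...] = ()

    @property
    def nominal_mz(self) -> int:
        return nominal_mass(self.formula)

    @property
    def monoisotopic_mz(self) -> float:
        return monoisotopic_mass(self.formula) - ELECTRON_MASS

    @property
    def depth(self) -> int:
        return len(self.provenance)

    def _is_carbocation(self) -> bool:
        if self.charged_atom is None:
            return False
        a = self.graph.atom(self.charged_atom)
        if a.element != "C":
            return False
        return self.graph.degree_order_sum(a.index) + a.hydrogens == 3

    @property
    def acylium_carbon(self) -> Optional[int]:
        """Index of the charged carbonyl carbon, or None."""
        if not self._is_carbocation():
            return None
        for nbr, order in self.graph.neighbors(self.charged_atom):
            if nbr.element == "O" and order == 2:
                return self.charged_atom
        return None


class FragmentIon(ProtonatedIon):
    """A ProtonatedIon produced by a cleavage; ``event`` is the last step."""

    @property
    def event(self) -> CleavageEvent:
        return self.provenance[-1]


def make_precursor(graph: MolecularGraph) -> ProtonatedIon:
    """Protonate a neutral molecule: [M+H]+ with a mobile proton."""
    return ProtonatedIon(
        graph=graph,
        formula=graph.formula() + H1,
        mobile_protons=1,
        charged_atom=None,
    )


# ---------------------------------------------------------------------------
# resonance normalization
# ---------------------------------------------------------------------------


def resonance_forms(ion: ProtonatedIon) -> list[ProtonatedIon]:
    """The ion itself plus charge-shifted forms of a carbocation.

    A carbocation adjacent to a lone-pair heteroatom is stabilized by
    forming the double bond and moving the charge onto the heteroatom
    (acylium, iminium, oxocarbenium). Pattern assignment sees each form,
    so e.g. an iminium nitrogen presents its partner as ``=CH2``.
    """
    forms = [ion]
    if not ion._is_carbocation():
        return forms
    q = ion.charged_atom
    for nbr, order in ion.graph.neighbors(q):
        if order == 1 and nbr.element in ("N", "O"):
            shifted = ion.graph.with_bond_order(q, nbr.index, 2)
            forms.append(
                ProtonatedIon(
                    graph=shifted,
                    formula=ion.formula,
                    mobile_protons=ion.mobile_protons,
                    charged_atom=nbr.index,
                    provenance=ion.provenance,
                )
            )
    return forms


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------


def candidate_bonds(ion: ProtonatedIon) -> list[tuple[BondEdge, BondingPattern]]:
    """Cleavage-candidate bonds of one ion (one resonance form).

    For a precursor (mobile proton) every single C-N / C-O bridge bond is
    a candidate; for a fragment ion only bonds incident to the charge
    site are, since the charge is no longer mobile. The acylium C-C bond
    is included when present. Ring bonds are skipped with a warning.
    """
    out: list[tuple[BondEdge, BondingPattern]] = []
    for bond in sorted(ion.graph.bonds, key=lambda b: b.key):
        if bond.order != 1:
            continue
        elements = {ion.graph.atom(bond.i).element, ion.graph.atom(bond.j).element}
        if elements not in ({"C", "N"}, {"C", "O"}):
            continue
        if ion.charged_atom is not None and ion.charged_atom not in bond.endpoints:
            continue
        try:
            split_on_bond(ion.graph, bond)
        except RingBondError:
            warnings.warn(
                f"skipping ring bond {bond.i}-{bond.j} of {ion.graph.name!r}: "
                "ring cleavage is not modeled",
                stacklevel=2,
            )
            continue
        out.append((bond, extract_bp(ion.graph, bond)))
    q = ion.acylium_carbon
    if q is not None:
        for nbr, order in ion.graph.neighbors(q):
            if nbr.element == "C" and order == 1:
                bond = ion.graph.bond_between(q, nbr.index)
                out.append((bond, extract_bp(ion.graph, bond, charged_atom=q)))
    return out


# ---------------------------------------------------------------------------
# cleavage operations
# ---------------------------------------------------------------------------


def _orient(ion: ProtonatedIon, bond: BondEdge) -> tuple[int, int]:
    """(carbon index, heteroatom index) of a C-N / C-O bond."""
    a, b = ion.graph.atom(bond.i), ion.graph.atom(bond.j)
    if a.element == "C" and b.element in ("N", "O"):
        return a.index, b.index
    if b.element == "C" and a.element in ("N", "O"):
        return b.index, a.index
    raise ChannelAbsentError(
        f"bond {bond.i}-{bond.j} ({a.element}-{b.element}) is not a "
        "carbon-heteroatom bond"
    )


def _energy_for(
    table: EnergyTable, bp: BondingPattern, mode: str
) -> float:
    e = lookup_energy(table, bp, mode)
    if e is UNCATALOGUED:
        err = ChannelAbsentError(f"pattern not in table: {bp}")
        err.uncatalogued = True
        raise err
    if e is None:
        err = ChannelAbsentError(f"no {mode} energy for {bp}")
        err.uncatalogued = False
        raise err
    return e


def _make_event(
    table: EnergyTable,
    bond: BondEdge,
    mode: str,
    bp: BondingPattern,
    energy: float,
    neutral: ElementalFormula,
) -> CleavageEvent:
    rec = table.record_for(bp)
    return CleavageEvent(
        bond=bond,
        mode=mode,
        bp=bp,
        bp_id=rec.bp_id if rec is not None else None,
        energy=energy,
        neutral=NeutralLoss.from_formula(neutral),
    )


def direct_cleave(
    ion: ProtonatedIon, bond: BondEdge, table: EnergyTable
) -> FragmentIon:
    """Break a C-X bond without hydrogen movement; carbon keeps the charge."""
    c_idx, x_idx = _orient(ion, bond)
    bp = extract_bp(ion.graph, bond)
    energy = _energy_for(table, bp, DIRECT)
    sides = dict(zip(bond.endpoints, split_on_bond(ion.graph, bond)))
    side_c, side_x = sides[c_idx], sides[x_idx]
    neutral = ion.graph.subgraph(side_x).formula() + ElementalFormula(
        h=ion.mobile_protons
    )
    if not _is_even_electron_neutral(neutral):
        raise ChannelAbsentError(
            f"direct cleavage of {bp} would emit a radical neutral ({neutral})"
        )
    event = _make_event(table, bond, DIRECT, bp, energy, neutral)
    return FragmentIon(
        graph=ion.graph.subgraph(side_c),
        formula=ion.formula - neutral,
        mobile_protons=0,
        charged_atom=c_idx,
        provenance=ion.provenance + (event,),
    )


def rearranged_cleave(
    ion: ProtonatedIon, bond: BondEdge, table: EnergyTable
) -> FragmentIon:
    """Break a C-X bond with one H moving from the carbon side to the
    heteroatom side, which retains the charge."""
    c_idx, x_idx = _orient(ion, bond)
    bp = extract_bp(ion.graph, bond)
    energy = _energy_for(table, bp, REARRANGED)
    sides = dict(zip(bond.endpoints, split_on_bond(ion.graph, bond)))
    side_c, side_x = sides[c_idx], sides[x_idx]
    carbon_part = ion.graph.subgraph(side_c).formula()
    if carbon_part.h < 1:
        raise ChannelAbsentError(
            f"rearranged cleavage of {bp}: no transferable hydrogen on the "
            "carbon side"
        )
    neutral = carbon_part - H1
    if not _is_even_electron_neutral(neutral):
        raise ChannelAbsentError(
            f"rearranged cleavage of {bp} would emit a radical neutral ({neutral})"
        )
    event = _make_event(table, bond, REARRANGED, bp, energy, neutral)
    return FragmentIon(
        graph=ion.graph.subgraph(side_x).with_hydrogen_delta(x_idx, +1),
        formula=ion.formula - neutral,
        mobile_protons=ion.mobile_protons,
        charged_atom=x_idx,
        provenance=ion.provenance + (event,),
    )


def acylium_co_loss(ion: ProtonatedIon, table: EnergyTable) -> FragmentIon:
    """Eject CO from an acylium ion; the charge moves to the alkyl carbon."""
    q = ion.acylium_carbon
    if q is None:
        raise NoAcyliumError("ion has no charged carbonyl carbon")
    o_idx = next(
        nbr.index
        for nbr, order in ion.graph.neighbors(q)
        if nbr.element == "O" and order == 2
    )
    alkyl = [
        nbr.index
        for nbr, order in ion.graph.neighbors(q)
        if nbr.element == "C" and order == 1
    ]
    if not alkyl:
        raise NoAcyliumError("acylium carbon has no alkyl neighbor to keep the charge")
    c_idx = alkyl[0]
    bond = ion.graph.bond_between(q, c_idx)
    bp = extract_bp(ion.graph, bond, charged_atom=q)
    energy = _energy_for(table, bp, DIRECT)
    sides = dict(zip(bond.endpoints, split_on_bond(ion.graph, bond)))
    if sides[q] != {q, o_idx}:
        raise NoAcyliumError("carbonyl side carries more than CO")
    neutral = ion.graph.subgraph(sides[q]).formula()
    event = _make_event(table, bond, CO_LOSS, bp, energy, neutral)
    return FragmentIon(
        graph=ion.graph.subgraph(sides[c_idx]),
        formula=ion.formula - neutral,
        mobile_protons=ion.mobile_protons,
        charged_atom=c_idx,
        provenance=ion.provenance + (event,),
    )


# ---------------------------------------------------------------------------
# channel listing (reporting; no competition, no threshold)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Channel:
    bond: BondEdge
    bp: BondingPattern
    bp_id: Optional[int]
    mode: str
    energy: float


def assign_channels(ion: ProtonatedIon, table: EnergyTable) -> list[Channel]:
    """Every catalogued cleavage channel of an ion, over all resonance
    forms, with its activation energy. Pure assignment: nothing is pruned."""
    seen: dict[tuple[tuple[int, int], str], Channel] = {}
    for form in resonance_forms(ion):
        for bond, bp in candidate_bonds(form):
            rec = table.record_for(bp)
            if rec is None:
                continue
            if bp.atoms == ("C", "C"):
                modes = [(CO_LOSS, rec.e_direct)]
            else:
                modes = [(DIRECT, rec.e_direct), (REARRANGED, rec.e_rearranged)]
            for mode, energy in modes:
                if energy is None:
                    continue
                key = (bond.key, mode)
                ch = Channel(bond=bond, bp=bp, bp_id=rec.bp_id, mode=mode, energy=energy)
                if key not in seen or energy < seen[key].energy:
                    seen[key] = ch
    return sorted(seen.values(), key=lambda c: (c.energy, c.bond.key, c.mode))
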