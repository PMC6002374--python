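"""Molecular graphs, elemental formulas and mass arithmetic.

Molecules are represented as heavy-atom graphs over {C, N, O} with implicit
hydrogen counts on each atom, the substrate for bonding-pattern assignment.
Hydrogen counts on fragment ions are inherited from the parent ion rather
than recomputed from valence, so carbocations keep their true composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
from rdkit import Chem, RDLogger

from .errors import RingBondError, StructureParseError, UnsupportedElementError

RDLogger.DisableLog("rdApp.*")

SUPPORTED_ELEMENTS = ("C", "N", "O")

#: standard neutral valences of the supported heavy atoms
VALENCE = {"C": 4, "N": 3, "O": 2}

#: nominal (integer) masses, Da
NOMINAL_MASS = {"H": 1, "C": 12, "N": 14, "O": 16}

#: monoisotopic masses, Da
MONOISOTOPIC_MASS = {"H": 1.0078250, "C": 12.0, "N": 14.0030740, "O": 15.9949146}

#: mass of the proton, Da (used for m/z of protonated species)
PROTON_MASS = 1.0072765

#: electron mass implied by the constants above (H minus proton)
ELECTRON_MASS = MONOISOTOPIC_MASS["H"] - PROTON_MASS


@dataclass(frozen=True, order=True)
class ElementalFormula:
    """Element counts over C, H, N, O. Supports +/- with non-negativity."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name.upper()} count in formula")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            self.c + other.c, self.h + other.h, self.n + other.n, self.o + other.o
        )

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            self.c - other.c, self.h - other.h, self.n - other.n, self.o - other.o
        )

    def __str__(self) -> str:
        parts = []
        for sym, cnt in (("C", self.c), ("H", self.h), ("N", self.n), ("O", self.o)):
            if cnt == 1:
                parts.append(sym)
            elif cnt > 1:
                parts.append(f"{sym}{cnt}")
        return "".join(parts) or "(empty)"


#: one hydrogen, the mobile proton's contribution to a charged composition
H1 = ElementalFormula(h=1)


def nominal_mass(f: ElementalFormula) -> int:
    """Integer mass with H=1, C=12, N=14, O=16 (the scale of printed m/z)."""
    return 12 * f.c + f.h + 14 * f.n + 16 * f.o


def monoisotopic_mass(f: ElementalFormula) -> float:
    m = MONOISOTOPIC_MASS
    return m["C"] * f.c + m["H"] * f.h + m["N"] * f.n + m["O"] * f.o


def protonated_mz(f: ElementalFormula, scale: str = "nominal") -> float:
    """m/z of the singly protonated, singly charged species [M+H]+.

    ``f`` is the neutral composition. Nominal scale adds 1; monoisotopic
    scale adds the proton mass.
    """
    if scale == "nominal":
        return nominal_mass(f) + 1
    if scale == "monoisotopic":
        return monoisotopic_mass(f) + PROTON_MASS
    raise ValueError(f"unknown scale {scale!r}")


@dataclass(frozen=True)
class AtomNode:
    element: str
    hydrogens: int
    index: int


@dataclass(frozen=True)
class BondEdge:
    """Unordered pair of atom indices plus an integer bond order."""

    i: int
    j: int
    order: int = 1

    @property
    def endpoints(self) -> tuple[int, int]:
        return (self.i, self.j)

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)

    def other(self, index: int) -> int:
        if index == self.i:
            return self.j
        if index == self.j:
            return self.i
        raise ValueError(f"atom {index} is not an endpoint of {self}")


@dataclass
class MolecularGraph:
    """Heavy-atom graph with implicit hydrogens.

    Atom indices are stable identifiers: subgraphs of an ion keep the
    indices of the parent, so provenance of every atom can be traced
    through a fragmentation cascade.
    """

    atoms: list[AtomNode] = field(default_factory=list)
    bonds: list[BondEdge] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self._by_index = {a.index: a for a in self.atoms}
        if len(self._by_index) != len(self.atoms):
            raise ValueError("duplicate atom indices")
        seen = set()
        for b in self.bonds:
            if b.i == b.j:
                raise ValueError("self-bond")
            if b.i not in self._by_index or b.j not in self._by_index:
                raise ValueError(f"bond {b} references a missing atom")
            if b.key in seen:
                raise ValueError(f"duplicate bond between atoms {b.key}")
            seen.add(b.key)

    # -- access -----------------------------------------------------------
    def atom(self, index: int) -> AtomNode:
        return self._by_index[index]

    def bonds_at(self, index: int) -> list[BondEdge]:
        return [b for b in self.bonds if index in b.endpoints]

    def neighbors(self, index: int) -> list[tuple[AtomNode, int]]:
        """(neighbor atom, bond order) pairs, in stable index order."""
        out = [(self.atom(b.other(index)), b.order) for b in self.bonds_at(index)]
        return sorted(out, key=lambda t: t[0].index)

    def bond_between(self, i: int, j: int) -> BondEdge:
        for b in self.bonds:
            if b.key == ((i, j) if i < j else (j, i)):
                return b
        raise KeyError(f"no bond between atoms {i} and {j}")

    def degree_order_sum(self, index: int) -> int:
        return sum(b.order for b in self.bonds_at(index))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(a.index for a in self.atoms)
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def is_connected(self) -> bool:
        if not self.atoms:
            return True
        return nx.is_connected(self.to_networkx())

    # -- derived ----------------------------------------------------------
    def formula(self) -> ElementalFormula:
        counts = {"C": 0, "H": 0, "N": 0, "O": 0}
        for a in self.atoms:
            counts[a.element] += 1
            counts["H"] += a.hydrogens
        return ElementalFormula(counts["C"], counts["H"], counts["N"], counts["O"])

    def subgraph(self, indices: set[int], name: str = "") -> "MolecularGraph":
        atoms = [a for a in self.atoms if a.index in indices]
        bonds = [b for b in self.bonds if b.i in indices and b.j in indices]
        return MolecularGraph(atoms=atoms, bonds=bonds, name=name or self.name)

    def with_hydrogen_delta(self, index: int, delta: int) -> "MolecularGraph":
        """Copy with the hydrogen count of one atom changed by ``delta``."""
        atoms = [
            replace(a, hydrogens=a.hydrogens + delta) if a.index == index else a
            for a in self.atoms
        ]
        return MolecularGraph(atoms=atoms, bonds=list(self.bonds), name=self.name)

    def with_bond_order(self, i: int, j: int, order: int) -> "MolecularGraph":
        key = (i, j) if i < j else (j, i)
        bonds = [
            replace(b, order=order) if b.key == key else b for b in self.bonds
        ]
        return MolecularGraph(atoms=list(self.atoms), bonds=bonds, name=self.name)


def elemental_formula(graph: MolecularGraph) -> ElementalFormula:
    """Element counts of the graph, implicit hydrogens included."""
    return graph.formula()


# ---------------------------------------------------------------------------
# structure input
# ---------------------------------------------------------------------------


def _from_rdkit(mol: "Chem.Mol", name: str) -> MolecularGraph:
    if mol is None:
        raise StructureParseError("structure could not be parsed")
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Exception as exc:  # pragma: no cover - exotic aromatic systems
        raise StructureParseError(f"kekulization failed: {exc}") from exc
    atoms: list[AtomNode] = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "H":
            continue
        if sym not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(sym)
        if atom.GetFormalCharge() != 0:
            raise StructureParseError(
                f"atom {atom.GetIdx()} carries a formal charge; inputs must be neutral"
            )
        if atom.GetNumRadicalElectrons() != 0:
            raise StructureParseError(
                f"atom {atom.GetIdx()} is a radical; only closed-shell inputs are handled"
            )
        atoms.append(
            AtomNode(element=sym, hydrogens=atom.GetTotalNumHs(), index=atom.GetIdx())
        )
    bonds = []
    for bond in mol.GetBonds():
        order = int(bond.GetBondTypeAsDouble())
        if order not in (1, 2, 3):
            raise StructureParseError(
                f"unsupported bond order {bond.GetBondTypeAsDouble()}"
            )
        bonds.append(BondEdge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
    graph = MolecularGraph(atoms=atoms, bonds=bonds, name=name)
    if not graph.is_connected():
        raise StructureParseError("input encodes more than one connected molecule")
    for a in graph.atoms:
        valence = graph.degree_order_sum(a.index) + a.hydrogens
        if valence != VALENCE[a.element]:
            raise StructureParseError(
                f"atom {a.index} ({a.element}) has valence {valence}, "
                f"expected {VALENCE[a.element]}"
            )
    return graph


def parse_structure(text: str, name: str = "") -> MolecularGraph:
    """Parse a SMILES string or an MDL MOL (V2000) block.

    The molecule must be a single neutral connected structure over C, H,
    N and O. Atom order of the input is preserved, so output is
    deterministic for a given input string.
    """
    text = text.rstrip()
    if "V2000" in text or text.count("\n") >= 3:
        mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
        if mol is None:
            raise StructureParseError("MOL block could not be parsed")
    else:
        mol = Chem.MolFromSmiles(text.strip(), sanitize=True)
        if mol is None:
            raise StructureParseError(f"SMILES could not be parsed: {text.strip()!r}")
    return _from_rdkit(mol, name)


def load_structures(path: str) -> list[MolecularGraph]:
    """Read one or more structures from a .mol or (multi-record) .sdf file."""
    graphs = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise StructureParseError(f"record {i} of {path} could not be parsed")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record-{i}"
        graphs.append(_from_rdkit(mol, name))
    return graphs


# ---------------------------------------------------------------------------
# bond splitting
# ---------------------------------------------------------------------------


def split_on_bond(
    graph: MolecularGraph, bond: BondEdge
) -> tuple[set[int], set[int]]:
    """Atom-index sets of the two components after removing a bridge bond.

    Returns ``(side_i, side_j)`` where ``side_i`` contains ``bond.i``.
    Raises :class:`RingBondError` if the bond lies in a ring (removal
    leaves the graph connected).
    """
    g = graph.to_networkx()
    if not g.has_edge(bond.i, bond.j):
        raise KeyError(f"bond {bond} is not in the graph")
    g.remove_edge(bond.i, bond.j)
    side_i = nx.node_connected_component(g, bond.i)
    if bond.j in side_i:
        raise RingBondError(
            f"bond {bond.i}-{bond.j} is a ring bond and cannot partition the graph"
        )
    side_j = nx.node_connected_component(g, bond.j)
    return set(side_i), set(side_j)
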