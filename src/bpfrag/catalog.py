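"""Bonding patterns and their activation-energy catalog.

A bonding pattern (BP) is the local signature of a cleavable bond: the two
bound atoms plus their adjacent chemical groups, with substructures distant
from the bond simplified away. Activation energies for direct and
rearranged cleavage of each catalogued pattern come from quantum-chemistry
calculations and are consumed here purely as data (a packaged TSV,
user-extensible).

Group descriptors use a small canonical grammar::

    group := ('-' | '=' | '#') atom
    atom  := element ['H' [digit]] ['(' group ')']*

with children sorted lexicographically, e.g. ``-CH3``, ``=O``,
``-C(-OH)(=O)`` (a carboxyl), ``-NH(-CH3)`` (an N-methylamino). Hydrogen
counts are always valence fill: atoms replaced during simplification
appear as hydrogens.

Simplification of a neighbor subtree follows the conventions of the
packaged catalog:

* a saturated carbon neighbor truncates to ``-CH3`` (even if it bears
  single-bonded heteroatoms one bond further out);
* an unsaturated carbon bonded singly to the bond atom keeps all of its
  depth-2 children, each saturated with H (``-C(-OH)(=O)``);
* a doubly bonded carbon keeps only heteroatom or multiply bonded
  children (``=CH2``, ``=C(=NH)``);
* a heteroatom neighbor keeps all depth-2 children (``-NH(-CH3)``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement, product
from pathlib import Path
from typing import Iterable, Optional

from .errors import BpfragError, TableFormatError
from .molgraph import VALENCE, BondEdge, MolecularGraph

BOND_CHAR = {1: "-", 2: "=", 3: "#"}

_GROUP_RE = re.compile(
    r"^[-=#][CNO](H\d?)?(\([-=#][CNO](H\d?)?\))*$"
)


class PatternExtractionError(BpfragError):
    """The bond cannot carry a bonding pattern (multiple bond, bad atoms)."""


@dataclass(frozen=True, order=True)
class NeighborGroup:
    """A simplified substituent adjacent to one of the two bond atoms."""

    descriptor: str

    @property
    def bond_order_to_root(self) -> int:
        return {"-": 1, "=": 2, "#": 3}[self.descriptor[0]]

    def __str__(self) -> str:
        return self.descriptor


def _h_suffix(n: int) -> str:
    if n <= 0:
        return ""
    return "H" if n == 1 else f"H{n}"


def _child_token(order: int, element: str) -> str:
    """Depth-2 atom saturated with hydrogen, e.g. ``-CH3`` or ``=O``."""
    fill = max(VALENCE[element] - order, 0)
    return f"{BOND_CHAR[order]}{element}{_h_suffix(fill)}"


def _render_group(order: int, element: str, children: list[tuple[int, str]]) -> str:
    kept = sorted(_child_token(o, el) for o, el in children)
    fill = max(VALENCE[element] - order - sum(o for o, _ in children), 0)
    body = f"{element}{_h_suffix(fill)}" + "".join(f"({c})" for c in kept)
    return f"{BOND_CHAR[order]}{body}"


@dataclass(frozen=True)
class BondingPattern:
    """Canonical signature of a cleavable bond.

    ``atoms`` is ordered: carbon first for C-N / C-O bonds; for C-C bonds
    (acylium context) the charged carbonyl side is second. Group tuples
    are stored sorted, so equal patterns compare equal.
    """

    atoms: tuple[str, str]
    carbon_groups: tuple[str, ...]
    hetero_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "carbon_groups", tuple(sorted(self.carbon_groups)))
        object.__setattr__(self, "hetero_groups", tuple(sorted(self.hetero_groups)))

    def __str__(self) -> str:
        def side(el: str, groups: tuple[str, ...]) -> str:
            return f"{el}({', '.join(groups) if groups else 'none'})"

        return (
            f"{self.atoms[0]}-{self.atoms[1]} "
            f"{side(self.atoms[0], self.carbon_groups)} "
            f"{side(self.atoms[1], self.hetero_groups)}"
        )


def canonical_key(bp: BondingPattern) -> str:
    """Deterministic string key, invariant to group listing order."""
    cg = ",".join(sorted(bp.carbon_groups)) or "none"
    hg = ",".join(sorted(bp.hetero_groups)) or "none"
    return f"{bp.atoms[0]}-{bp.atoms[1]}|{cg}|{hg}"


# ---------------------------------------------------------------------------
# extraction from a molecular graph
# ---------------------------------------------------------------------------


def _groups_of(graph: MolecularGraph, root: int, exclude: int) -> tuple[str, ...]:
    """Simplified neighbor groups of ``root``, skipping the bond partner."""
    out = []
    for nbr, order in graph.neighbors(root):
        if nbr.index == exclude:
            continue
        grandchildren = [
            (o2, g.element)
            for g, o2 in graph.neighbors(nbr.index)
            if g.index != root
        ]
        if order > 1:
            # doubly bonded carbon keeps only heteroatom / unsaturated children
            kept = [
                (o2, el)
                for o2, el in grandchildren
                if el in ("N", "O") or o2 > 1
            ]
        elif nbr.element in ("N", "O"):
            kept = grandchildren
        elif any(o2 > 1 for o2, _ in grandchildren):
            # unsaturated carbon: retain the functional group to depth 2
            kept = grandchildren
        else:
            # saturated carbon truncates to a methyl
            kept = []
        out.append(_render_group(order, nbr.element, kept))
    return tuple(sorted(out))


def extract_bp(
    graph: MolecularGraph,
    bond: BondEdge,
    charged_atom: Optional[int] = None,
) -> BondingPattern:
    """Assign the bonding pattern of a single bond.

    For C-C bonds ``charged_atom`` must mark the acylium carbon (the
    carbonyl-bearing endpoint, listed second in the pattern); C-C bonds
    without that context are rejected, as are multiple bonds.
    """
    if bond.order != 1:
        raise PatternExtractionError("bonding patterns cover single bonds only")
    a, b = graph.atom(bond.i), graph.atom(bond.j)
    elements = (a.element, b.element)
    if elements in (("C", "N"), ("C", "O")):
        carbon, hetero = a, b
    elif elements in (("N", "C"), ("O", "C")):
        carbon, hetero = b, a
    elif elements == ("C", "C"):
        if charged_atom not in bond.endpoints:
            raise PatternExtractionError(
                "C-C bonds carry a pattern only in an acylium context "
                "(charged_atom must be one endpoint)"
            )
        hetero = graph.atom(charged_atom)  # acylium side, listed second
        carbon = graph.atom(bond.other(charged_atom))
    else:
        raise PatternExtractionError(
            f"unsupported bond atoms {elements[0]}-{elements[1]}"
        )
    return BondingPattern(
        atoms=(carbon.element, hetero.element),
        carbon_groups=_groups_of(graph, carbon.index, hetero.index),
        hetero_groups=_groups_of(graph, hetero.index, carbon.index),
    )


# ---------------------------------------------------------------------------
# energy table
# ---------------------------------------------------------------------------

DIRECT = "direct"
REARRANGED = "rearranged"

#: sentinel distinguishing "pattern not in the table" from "channel absent"
UNCATALOGUED = object()


@dataclass(frozen=True)
class EnergyRecord:
    bp_id: Optional[int]
    pattern: BondingPattern
    e_direct: Optional[float]
    e_rearranged: Optional[float]

    def __post_init__(self) -> None:
        if self.e_direct is None and self.e_rearranged is None:
            raise ValueError("record needs at least one of e_direct/e_rearranged")

    def energy(self, mode: str) -> Optional[float]:
        if mode == DIRECT:
            return self.e_direct
        if mode == REARRANGED:
            return self.e_rearranged
        raise ValueError(f"unknown cleavage mode {mode!r}")


@dataclass
class EnergyTable:
    """Activation energies keyed by canonical bonding-pattern key."""

    records: list[EnergyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, EnergyRecord] = {}
        for rec in self.records:
            key = canonical_key(rec.pattern)
            if key in self._index:
                raise TableFormatError(f"duplicate pattern in table: {key}")
            self._index[key] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, bp: BondingPattern) -> bool:
        return canonical_key(bp) in self._index

    def record_for(self, bp: BondingPattern) -> Optional[EnergyRecord]:
        return self._index.get(canonical_key(bp))

    def record_by_id(self, bp_id: int) -> EnergyRecord:
        for rec in self.records:
            if rec.bp_id == bp_id:
                return rec
        raise KeyError(f"no record with bp_id {bp_id}")

    def merged(self, other: "EnergyTable") -> "EnergyTable":
        """New table with ``other``'s rows appended; key collision is an error."""
        return EnergyTable(records=self.records + other.records)


def lookup_energy(table: EnergyTable, bp: BondingPattern, mode: str):
    """Activation energy in kJ/mol, ``None`` if the channel is absent, or
    the :data:`UNCATALOGUED` sentinel if the pattern is not in the table."""
    rec = table.record_for(bp)
    if rec is None:
        return UNCATALOGUED
    return rec.energy(mode)


_HEADER = ["bp_id", "atoms", "carbon_groups", "hetero_groups", "e_direct", "e_rearranged"]


def _parse_groups(cell: str, line_no: int) -> tuple[str, ...]:
    cell = cell.strip()
    if cell in ("", "none"):
        return ()
    groups = tuple(g.strip() for g in cell.split(","))
    for g in groups:
        if not _GROUP_RE.match(g):
            raise TableFormatError(
                f"line {line_no}: malformed group descriptor {g!r}"
            )
    return groups


def _parse_energy(cell: str, line_no: int) -> Optional[float]:
    cell = cell.strip()
    if cell in ("NA", "", "-", "—"):
        return None
    try:
        return float(cell)
    except ValueError:
        raise TableFormatError(f"line {line_no}: malformed energy {cell!r}") from None


def load_energy_table(path) -> EnergyTable:
    """Read a tab-separated activation-energy table.

    Columns: bp_id, atoms (e.g. ``C-N``), carbon_groups, hetero_groups
    (comma-joined descriptors or ``none``), e_direct, e_rearranged
    (kJ/mol, ``NA`` for an absent channel).
    """
    text = Path(path).read_text()
    return _load_table_text(text, origin=str(path))


def _load_table_text(text: str, origin: str = "<string>") -> EnergyTable:
    lines = [ln for ln in text.splitlines()]
    if not lines:
        raise TableFormatError(f"{origin}: empty table")
    header = [c.strip() for c in lines[0].split("\t")]
    if header != _HEADER:
        raise TableFormatError(
            f"{origin}: bad header {header!r}, expected {_HEADER!r}"
        )
    records = []
    seen_keys: dict[str, int] = {}
    for line_no, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if len(cells) != len(_HEADER):
            raise TableFormatError(
                f"{origin} line {line_no}: expected {len(_HEADER)} columns, "
                f"got {len(cells)}"
            )
        bp_id = int(cells[0]) if cells[0].strip() else None
        atoms = tuple(cells[1].strip().split("-"))
        if len(atoms) != 2 or any(a not in ("C", "N", "O") for a in atoms):
            raise TableFormatError(f"{origin} line {line_no}: bad atoms {cells[1]!r}")
        pattern = BondingPattern(
            atoms=atoms,  # type: ignore[arg-type]
            carbon_groups=_parse_groups(cells[2], line_no),
            hetero_groups=_parse_groups(cells[3], line_no),
        )
        key = canonical_key(pattern)
        if key in seen_keys:
            raise TableFormatError(
                f"{origin} line {line_no}: pattern collides with line "
                f"{seen_keys[key]} ({key})"
            )
        seen_keys[key] = line_no
        records.append(
            EnergyRecord(
                bp_id=bp_id,
                pattern=pattern,
                e_direct=_parse_energy(cells[4], line_no),
                e_rearranged=_parse_energy(cells[5], line_no),
            )
        )
    return EnergyTable(records=records)


def _fmt_energy(e: Optional[float]) -> str:
    if e is None:
        return "NA"
    return str(int(e)) if float(e).is_integer() else repr(e)


def save_energy_table(table: EnergyTable, path) -> None:
    lines = ["\t".join(_HEADER)]
    for rec in table.records:
        lines.append(
            "\t".join(
                [
                    "" if rec.bp_id is None else str(rec.bp_id),
                    "-".join(rec.pattern.atoms),
                    ",".join(rec.pattern.carbon_groups) or "none",
                    ",".join(rec.pattern.hetero_groups) or "none",
                    _fmt_energy(rec.e_direct),
                    _fmt_energy(rec.e_rearranged),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def builtin_table() -> EnergyTable:
    """The packaged activation-energy catalog (17 patterns)."""
    text = resources.files("bpfrag").joinpath("data/activation_energies.tsv").read_text()
    return _load_table_text(text, origin="packaged activation_energies.tsv")


# ---------------------------------------------------------------------------
# combinatorics of the pattern space
# ---------------------------------------------------------------------------


def repeated_combination(n: int, r: int) -> int:
    """Number of multisets of size r from n kinds: C(n+r-1, r)."""
    if n < 1 or r < 0:
        raise ValueError("repeated_combination requires n >= 1 and r >= 0")
    return math.comb(n + r - 1, r)


_SINGLE = {"C": "-CH3", "N": "-NH2", "O": "-OH"}
_DOUBLE = {"C": "=CH2", "N": "=NH", "O": "=O"}
_TRIPLE = {"C": "#CH", "N": "#N"}


def _carbon_side_options() -> list[tuple[str, ...]]:
    """All radius-1 substitution states of the bond carbon (34 of them):
    three single bonds, one double + one single, or one triple."""
    opts: list[tuple[str, ...]] = []
    for combo in combinations_with_replacement("HCNO", 3):
        opts.append(tuple(sorted(_SINGLE[e] for e in combo if e != "H")))
    for d, s in product("CNO", "HCNO"):
        groups = [_DOUBLE[d]] + ([_SINGLE[s]] if s != "H" else [])
        opts.append(tuple(sorted(groups)))
    for t in "CN":
        opts.append((_TRIPLE[t],))
    return opts


def _hetero_side_options(element: str) -> list[tuple[str, ...]]:
    """Radius-1 states of the heteroatom: N makes two single bonds or one
    double (13 states); O makes one single bond (4 states)."""
    opts: list[tuple[str, ...]] = []
    if element == "N":
        for combo in combinations_with_replacement("HCNO", 2):
            opts.append(tuple(sorted(_SINGLE[e] for e in combo if e != "H")))
        for d in "CNO":
            opts.append((_DOUBLE[d],))
    elif element == "O":
        for s in "HCNO":
            opts.append(tuple([_SINGLE[s]] if s != "H" else []))
    else:
        raise ValueError(f"heteroatom must be N or O, not {element!r}")
    return opts


def _plausible(bp: BondingPattern) -> bool:
    """Heuristic filter dropping heteroatom-heteroatom adjacency on the
    heteroatom side (e.g. an N bonded to two further N). Off by default:
    the closed-form count deliberately includes such patterns."""
    return not any(g[1] in ("N", "O") for g in bp.hetero_groups)


def enumerate_bp_space(
    radius: int = 1,
    plausibility_filter: bool = False,
) -> tuple[int, list[BondingPattern]]:
    """Enumerate every nearest-neighbor bonding pattern over {H, C, N, O}.

    Returns the closed-form count (a product of repeated-combination
    terms) together with the explicit, duplicate-free pattern list; the
    two agree by construction and are cross-checked in the test suite.
    Radius 2 is not implemented: no enumeration scheme is defined for it.
    """
    if radius != 1:
        raise NotImplementedError(
            "only nearest-neighbor (radius 1) enumeration is defined"
        )
    carbon = repeated_combination(4, 3) + 3 * 4 + 2
    hetero = (repeated_combination(4, 2) + 3) + 4
    count = carbon * hetero

    patterns = []
    for het in ("N", "O"):
        for cg in _carbon_side_options():
            for hg in _hetero_side_options(het):
                patterns.append(
                    BondingPattern(atoms=("C", het), carbon_groups=cg, hetero_groups=hg)
                )
    if plausibility_filter:
        patterns = [p for p in patterns if _plausible(p)]
        count = len(patterns)
    return count, patterns
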