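"""Multi-step fragmentation search and theoretical peak lists.

The search expands the protonated precursor exhaustively to ``max_depth``
cleavage steps, scoring each pathway by its *bottleneck* (maximum step)
activation energy. A fragment is *predicted* when some pathway reaches it
with every step at or below ``step_threshold`` (default 100 kJ/mol);
fragments reachable only over higher barriers are reported separately.

Two pruning rules shape the tree beyond raw channel enumeration:

* competition: when one bond offers both direct and rearranged cleavage,
  only the lower-energy mode propagates (the faster channel suppresses
  its competitor);
* charge direction: on fragment ions the charge is localized, so only
  bonds at the charge site (over its resonance forms) are expanded; the
  mobile-proton assumption applies to the intact precursor only.

Single-step operations in :mod:`bpfrag.fragmenter` are not affected by
either rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .catalog import DIRECT, REARRANGED, EnergyTable, canonical_key
from .errors import BpfragError, ChannelAbsentError, NoAcyliumError
from .fragmenter import (
    CO_LOSS,
    CleavageEvent,
    FragmentIon,
    ProtonatedIon,
    acylium_co_loss,
    candidate_bonds,
    direct_cleave,
    make_precursor,
    rearranged_cleave,
    resonance_forms,
)
from .molgraph import MolecularGraph

DEFAULT_MAX_DEPTH = 3
DEFAULT_STEP_THRESHOLD = 100.0


def expand(
    ion: ProtonatedIon,
    table: EnergyTable,
    compete: bool = True,
    gaps: Optional[set] = None,
) -> list[FragmentIon]:
    """All single-step products of an ion over its resonance forms.

    Channels with absent energies are skipped; uncatalogued patterns are
    recorded in ``gaps`` when a set is supplied. With ``compete`` (the
    default) the higher-energy of a bond's direct/rearranged pair is
    dropped.
    """
    best: dict[tuple, FragmentIon] = {}

    def consider(key: tuple, child: FragmentIon) -> None:
        if key not in best or child.event.energy < best[key].event.energy:
            best[key] = child

    for form in resonance_forms(ion):
        for bond, bp in candidate_bonds(form):
            if bp.atoms == ("C", "C"):
                try:
                    consider((bond.key, CO_LOSS), acylium_co_loss(form, table))
                except (ChannelAbsentError, NoAcyliumError) as err:
                    if gaps is not None and getattr(err, "uncatalogued", False):
                        gaps.add(_gap_note(form, bond, bp))
                continue
            for mode, op in ((DIRECT, direct_cleave), (REARRANGED, rearranged_cleave)):
                try:
                    consider((bond.key, mode), op(form, bond, table))
                except ChannelAbsentError as err:
                    if gaps is not None and getattr(err, "uncatalogued", False):
                        gaps.add(_gap_note(form, bond, bp))

    if compete:
        for bond_key in {k[0] for k in best}:
            d, r = best.get((bond_key, DIRECT)), best.get((bond_key, REARRANGED))
            if d is not None and r is not None:
                # tie goes to direct (no hydrogen movement required)
                loser = (bond_key, REARRANGED) if d.event.energy <= r.event.energy \
                    else (bond_key, DIRECT)
                del best[loser]
    return sorted(
        best.values(), key=lambda c: (-c.nominal_mz, c.event.energy, c.event.mode)
    )


def _gap_note(ion: ProtonatedIon, bond, bp) -> str:
    return (
        f"m/z {ion.nominal_mz} bond {bond.key[0]}-{bond.key[1]}: "
        f"{canonical_key(bp)}"
    )


# ---------------------------------------------------------------------------
# pathways and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentationPathway:
    """An ordered cleavage cascade ending at ``terminal``."""

    terminal: FragmentIon

    @property
    def steps(self) -> tuple[CleavageEvent, ...]:
        return self.terminal.provenance

    @property
    def energy_sequence(self) -> tuple[float, ...]:
        return tuple(e.energy for e in self.steps)

    @property
    def bottleneck(self) -> float:
        return max(self.energy_sequence)

    @property
    def terminal_mz(self) -> int:
        return self.terminal.nominal_mz

    def sort_key(self):
        return (
            self.bottleneck,
            sum(self.energy_sequence),
            len(self.steps),
            self.terminal_mz,
            tuple((e.bp_id or 0, e.mode, e.energy) for e in self.steps),
        )

    def describe(self) -> str:
        steps = " -> ".join(
            f"BP{e.bp_id}({'co-loss' if e.mode == CO_LOSS else e.mode}, "
            f"{e.energy:g})"
            for e in self.steps
        )
        return f"{steps} => m/z {self.terminal_mz}"


@dataclass(frozen=True)
class PredictedFragment:
    mz_nominal: int
    mz_mono: float
    formula: str
    pathway: FragmentationPathway

    @property
    def bottleneck(self) -> float:
        return self.pathway.bottleneck

    @property
    def first_step_energy(self) -> float:
        return self.pathway.energy_sequence[0]


@dataclass
class PredictionResult:
    precursor: ProtonatedIon
    fragments: list[PredictedFragment]
    above_threshold: list[PredictedFragment]
    coverage_gaps: list[str]
    max_depth: int
    step_threshold: float
    nodes_expanded: int
    maximal_pathways: list[FragmentationPathway] = field(default_factory=list)

    def fragment(self, mz: int) -> PredictedFragment:
        for f in self.fragments:
            if f.mz_nominal == mz:
                return f
        raise KeyError(f"m/z {mz} is not a predicted fragment")

    def to_dict(self) -> dict:
        def frag_dict(f: PredictedFragment) -> dict:
            mz = self.precursor.nominal_mz
            steps = []
            for e in f.pathway.steps:
                mz -= e.neutral.nominal_mass
                steps.append(
                    {
                        "bp_id": e.bp_id,
                        "mode": e.mode,
                        "energy_kj_mol": e.energy,
                        "neutral": e.neutral.label or str(e.neutral.formula),
                        "neutral_formula": str(e.neutral.formula),
                        "mz_nominal": mz,
                    }
                )
            return {
                "mz_nominal": f.mz_nominal,
                "mz_mono": round(f.mz_mono, 6),
                "formula": f.formula,
                "bottleneck_kj_mol": f.pathway.bottleneck,
                "pathway": steps,
            }

        return {
            "precursor": {
                "name": self.precursor.graph.name,
                "formula": str(self.precursor.graph.formula()),
                "mz_nominal": self.precursor.nominal_mz,
                "mz_mono": round(self.precursor.monoisotopic_mz, 6),
            },
            "parameters": {
                "max_depth": self.max_depth,
                "step_threshold_kj_mol": self.step_threshold,
            },
            "fragments": [frag_dict(f) for f in self.fragments],
            "above_threshold": [frag_dict(f) for f in self.above_threshold],
            "coverage_gaps": list(self.coverage_gaps),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def search(
    precursor: MolecularGraph | ProtonatedIon,
    table: EnergyTable,
    max_depth: int = DEFAULT_MAX_DEPTH,
    step_threshold: float = DEFAULT_STEP_THRESHOLD,
    compete: bool = True,
) -> PredictionResult:
    """Exhaustive fragmentation-tree search from a protonated precursor.

    Every reachable ion within ``max_depth`` steps is recorded; per
    nominal m/z the minimum-bottleneck pathway is kept. Output order is
    deterministic (m/z descending).
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    ion = precursor if isinstance(precursor, ProtonatedIon) else make_precursor(precursor)
    gaps: set[str] = set()
    by_mz: dict[int, list[FragmentationPathway]] = {}
    maximal: list[FragmentationPathway] = []
    nodes = 0

    def visit(node: ProtonatedIon) -> None:
        nonlocal nodes
        nodes += 1
        children = (
            expand(node, table, compete=compete, gaps=gaps)
            if node.depth < max_depth
            else []
        )
        if node.depth >= 1:
            pw = FragmentationPathway(terminal=node)  # type: ignore[arg-type]
            by_mz.setdefault(node.nominal_mz, []).append(pw)
            if not any(c.event.energy <= step_threshold for c in children):
                maximal.append(pw)
        for child in children:
            visit(child)

    visit(ion)

    fragments: list[PredictedFragment] = []
    above: list[PredictedFragment] = []
    for mz in sorted(by_mz, reverse=True):
        pathways = sorted(by_mz[mz], key=FragmentationPathway.sort_key)
        best = pathways[0]
        entry = PredictedFragment(
            mz_nominal=mz,
            mz_mono=best.terminal.monoisotopic_mz,
            formula=str(best.terminal.formula),
            pathway=best,
        )
        if best.bottleneck <= step_threshold:
            fragments.append(entry)
        else:
            above.append(entry)

    return PredictionResult(
        precursor=ion,
        fragments=fragments,
        above_threshold=above,
        coverage_gaps=sorted(gaps),
        max_depth=max_depth,
        step_threshold=step_threshold,
        nodes_expanded=nodes,
        maximal_pathways=sorted(maximal, key=FragmentationPathway.sort_key),
    )


def min_energy_pathway(result: PredictionResult) -> FragmentationPathway:
    """The most favorable complete cascade: among pathways that cannot be
    extended by a sub-threshold step (within the depth budget), the one
    with minimal bottleneck energy; ties break on smaller energy sum,
    fewer steps, then lower terminal m/z."""
    if not result.maximal_pathways:
        raise BpfragError("empty prediction: no pathways were found")
    return result.maximal_pathways[0]


def peak_list(
    result: PredictionResult,
    scale: str = "nominal",
    include_precursor: bool = False,
) -> list:
    """Sorted unique m/z of the predicted fragments."""
    if scale == "nominal":
        mzs = [f.mz_nominal for f in result.fragments]
        if include_precursor:
            mzs.append(result.precursor.nominal_mz)
    elif scale == "monoisotopic":
        mzs = [f.mz_mono for f in result.fragments]
        if include_precursor:
            mzs.append(result.precursor.monoisotopic_mz)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return sorted(set(mzs))
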