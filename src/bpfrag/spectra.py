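"""MSP spectrum I/O, predicted-vs-observed comparison, example fixtures.

The MSP dialect handled is the plain NIST-style text format: ``Name:``,
optional metadata lines, ``Num Peaks: N`` followed by N ``m/z intensity``
lines, records separated by blank lines.

The two built-in example molecules (a dipeptide and an amino-acid ester
with a heteroatom-rich guanidine/ester chemistry) come with toy spectra
whose m/z values are taken from published peak annotations of standard
product-ion spectra; their intensities are synthetic placeholders, so
comparisons should assert peak presence, never intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import SpectrumFormatError, UnknownFixtureError
from .molgraph import MolecularGraph, parse_structure


@dataclass
class SpectrumRecord:
    name: str
    precursor_mz: Optional[float] = None
    collision_energy: str = ""
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")

    def normalized(self) -> "SpectrumRecord":
        """Copy with intensities scaled so the base peak is 1."""
        top = max((i for _, i in self.peaks), default=0.0)
        if top <= 0:
            return self
        return SpectrumRecord(
            name=self.name,
            precursor_mz=self.precursor_mz,
            collision_energy=self.collision_energy,
            peaks=[(mz, i / top) for mz, i in self.peaks],
        )


# ---------------------------------------------------------------------------
# MSP text format
# ---------------------------------------------------------------------------


def read_msp(path, normalize: bool = False) -> list[SpectrumRecord]:
    """Parse a NIST-style MSP file into spectrum records."""
    records: list[SpectrumRecord] = []
    name = None
    precursor = None
    ce = ""
    peaks: list[tuple[float, float]] = []
    expected: Optional[int] = None

    def flush(line_no: int) -> None:
        nonlocal name, precursor, ce, peaks, expected
        if name is None and not peaks:
            return
        if expected is not None and len(peaks) != expected:
            raise SpectrumFormatError(
                f"record {name!r}: Num Peaks says {expected} but "
                f"{len(peaks)} peak lines were read"
            )
        rec = SpectrumRecord(
            name=name or "", precursor_mz=precursor, collision_energy=ce, peaks=peaks
        )
        records.append(rec.normalized() if normalize else rec)
        name, precursor, ce, peaks, expected = None, None, "", [], None

    lines = Path(path).read_text().splitlines()
    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            flush(line_no)
            continue
        low = line.lower()
        if low.startswith("name:"):
            name = line.split(":", 1)[1].strip()
        elif low.startswith("precursormz:") or low.startswith("precursor_mz:"):
            precursor = float(line.split(":", 1)[1])
        elif low.startswith("collisionenergy:") or low.startswith("collision_energy:"):
            ce = line.split(":", 1)[1].strip()
        elif low.startswith("num peaks:"):
            expected = int(line.split(":", 1)[1])
        elif ":" in line and not line[0].isdigit():
            continue  # unknown metadata line, tolerated
        else:
            parts = line.replace(";", " ").split()
            if len(parts) < 2:
                raise SpectrumFormatError(f"line {line_no}: malformed peak line {raw!r}")
            try:
                peaks.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise SpectrumFormatError(
                    f"line {line_no}: non-numeric peak line {raw!r}"
                ) from None
    flush(len(lines) + 1)
    return records


def write_msp(records: list[SpectrumRecord], path) -> None:
    chunks = []
    for rec in records:
        lines = [f"Name: {rec.name}"]
        if rec.precursor_mz is not None:
            lines.append(f"PrecursorMZ: {rec.precursor_mz:g}")
        if rec.collision_energy:
            lines.append(f"CollisionEnergy: {rec.collision_energy}")
        lines.append(f"Num Peaks: {len(rec.peaks)}")
        lines += [f"{mz:g} {i:g}" for mz, i in rec.peaks]
        chunks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(chunks) + "\n")


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    matched: list[tuple[float, float, float]]  # (predicted, observed, delta)
    predicted_unobserved: list[float]
    observed_unexplained: list[float]
    explained_fraction: float

    def to_dict(self) -> dict:
        return {
            "matched": [
                {"predicted_mz": p, "observed_mz": o, "delta_mz": round(d, 6)}
                for p, o, d in self.matched
            ],
            "predicted_unobserved": self.predicted_unobserved,
            "observed_unexplained": self.observed_unexplained,
            "explained_fraction": round(self.explained_fraction, 6),
        }


def match_peaks(
    predicted: list[float],
    observed: SpectrumRecord,
    tolerance: float = 0.5,
    min_rel_intensity: float = 0.05,
) -> ComparisonReport:
    """Greedy nearest-neighbor matching of predicted m/z against observed
    peaks at or above ``min_rel_intensity`` of the base peak.

    Each observed peak is assigned to at most one predicted value;
    ``explained_fraction`` is matched observed peaks over all observed
    peaks above the cutoff (0 when there are none).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    obs = [mz for mz, i in observed.normalized().peaks if i >= min_rel_intensity]
    candidates = sorted(
        (abs(p - o), p, o) for p in set(predicted) for o in obs if abs(p - o) <= tolerance
    )
    matched: list[tuple[float, float, float]] = []
    used_p: set[float] = set()
    used_o: set[float] = set()
    for delta, p, o in candidates:
        if p in used_p or o in used_o:
            continue
        matched.append((p, o, p - o))
        used_p.add(p)
        used_o.add(o)
    return ComparisonReport(
        matched=matched,
        predicted_unobserved=sorted(set(predicted) - used_p),
        observed_unexplained=sorted(set(obs) - used_o),
        explained_fraction=(len(matched) / len(obs)) if obs else 0.0,
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: every fixture m/z value with the published observation it reproduces;
#: intensities are synthetic placeholders (never transcribed from figures)
FIXTURE_PROVENANCE = {
    "glycylleucine": {
        "smiles": "NCC(=O)NC(CC(C)C)C(O)=O",
        "precursor_mz": 189,
        "peaks": {
            86: "major product ion of the standard spectrum (CE 20 eV)",
            132: "major product ion of the standard spectrum (CE 20 eV)",
            143: "major product ion of the standard spectrum (CE 20 eV)",
            171: "slight peak, 0.6% of the base peak at m/z 86",
        },
    },
    "ethyl-argininate": {
        "smiles": "CCOC(=O)C(N)CCCNC(=N)N",
        "precursor_mz": 203,
        "peaks": {
            60: "major peak of the standard spectrum (CE 20 eV)",
            70: "major peak of the standard spectrum (CE 20 eV)",
            144: "major peak of the standard spectrum (CE 20 eV)",
            186: "major peak of the standard spectrum (CE 20 eV)",
        },
    },
}

#: synthetic relative intensities for the fixture spectra (placeholders,
#: chosen only so that the "slight" 171 peak falls below a 5% cutoff)
_SYNTHETIC_INTENSITY = {
    "glycylleucine": {86: 1.0, 132: 0.65, 143: 0.45, 171: 0.006},
    "ethyl-argininate": {60: 1.0, 70: 0.8, 144: 0.6, 186: 0.4},
}


def make_fixture(name: str) -> tuple[MolecularGraph, SpectrumRecord]:
    """Build a named example molecule and its toy product-ion spectrum."""
    if name not in FIXTURE_PROVENANCE:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: "
            + ", ".join(sorted(FIXTURE_PROVENANCE))
        )
    info = FIXTURE_PROVENANCE[name]
    graph = parse_structure(info["smiles"], name=name)
    spectrum = SpectrumRecord(
        name=f"{name} (synthetic intensities)",
        precursor_mz=float(info["precursor_mz"]),
        collision_energy="20 eV",
        peaks=[
            (float(mz), _SYNTHETIC_INTENSITY[name][mz]) for mz in info["peaks"]
        ],
    )
    return graph, spectrum
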