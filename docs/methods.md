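# Methods

## Model

A metabolite is represented as a heavy-atom graph over {C, N, O} with
implicit hydrogen counts; inputs must be neutral, connected and
closed-shell (valence 4/3/2 for C/N/O). Fragment ions inherit their
hydrogen counts from the parent rather than recomputing them from
valence, so carbocations keep their true composition through a cascade.

Cleavage candidates are single bonds between a carbon and a heteroatom
(N or O). Each candidate is summarized as a **bonding pattern**: the two
bound atoms plus their adjacent groups after simplification. The
activation energy of cleaving each catalogued pattern — computed once,
elsewhere, with quantum chemistry — is looked up in a table and assigned
to the bond. The heteroatom of the bond under consideration is assumed
to carry the proton; no global protonation-site enumeration is performed
and no energy penalty is charged for proton relocation, because the
pattern energies already price the protonated configuration.

Two cleavage modes exist (positive mode, singly charged, even-electron
ions only). *Direct*: no hydrogen moves; the heteroatom side departs
with the mobile proton as a closed-shell neutral and the carbon side
keeps the charge. *Rearranged*: one hydrogen migrates from the carbon
side to the heteroatom side, which retains the charge (placed on the
heteroatom; the donor atom is not resolved — products are computed at
the formula level, where the donor is immaterial). A charged carbonyl
carbon (acylium) formed by direct cleavage can additionally eject CO;
this uses the direct-column energy of the corresponding C–C pattern and
is typically strongly negative ("immediate"), but is still counted as a
pathway step. Any channel whose neutral would be a radical (odd H+N
parity in a CHNO composition) is rejected outright.

### Pattern simplification

Groups are written in a small canonical grammar (`-CH3`, `=O`,
`-C(-OH)(=O)`, `-NH(-CH3)`, `=C(=NH)`, ...) with children sorted, and
hydrogen counts always valence-filled, so removed atoms reappear as H.
The truncation convention, chosen to be reproducible from the packaged
catalog itself:

* a saturated carbon neighbor truncates to `-CH3`, even when it carries
  single-bonded heteroatoms one bond further out;
* a singly bonded unsaturated carbon neighbor keeps all of its depth-2
  children, saturated with H (`-C(-CH3)(=O)` for an acetyl);
* a doubly bonded carbon neighbor keeps only children that are
  heteroatoms or multiply bonded (`=CH2`, `=C(=NH)`);
* heteroatom neighbors keep all depth-2 children (`-NH(-CH3)`).

Matching against the table is by canonical string key, never by row id,
so user-supplied tables cannot silently shadow packaged rows (merging a
colliding key is an error). An uncatalogued pattern is not an error:
the search records it as a coverage gap and continues, because the
catalog is meant to grow incrementally.

### Resonance forms

A carbocation adjacent to a lone-pair heteroatom is stabilized by
shifting the charge onto the heteroatom and forming the double bond
(acylium, iminium, oxocarbenium). Pattern assignment on fragment ions
therefore runs over the base structure plus all one-shift resonance
forms; e.g. after CO loss from a peptide acylium, the amide nitrogen
presents its partner as `=CH2` and the corresponding iminium pattern
becomes assignable.

## Pathway search

The precursor tree is expanded exhaustively to `max_depth` steps
(default 3, the deepest cascade the packaged chemistry supports; CO-loss
steps count toward depth). Two rules shape expansion beyond raw channel
enumeration:

* **Charge direction.** The mobile-proton assumption applies to the
  intact precursor only: all candidate bonds compete. On fragment ions
  the charge is localized, so only bonds incident to the charge site
  (over its resonance forms) are expanded. This is what excludes, e.g.,
  charge-remote water loss from a protonated amino acid fragment.
* **Competition.** When one bond offers both direct and rearranged
  channels, only the lower-energy mode propagates (the faster channel
  starves its competitor; ties go to direct, which moves no hydrogen).
  Single-step operations and the channel-listing API are unaffected.

A fragment is *predicted* when some pathway reaches it with every step
at or below `step_threshold` (default 100 kJ mol⁻¹, the conventional
low/high split; the proper threshold is an open scientific question, so
it is a parameter). Per nominal m/z the minimum-bottleneck pathway is
kept; fragments reachable only over higher barriers are reported
separately rather than dropped, with their best pathway. Duplicate
structures at one m/z merge in the peak list; the pathway detail keeps
the winning route.

`min_energy_pathway` returns the most favorable *complete* cascade: the
candidate set is pathways that cannot be extended by any sub-threshold
step within the depth budget, ranked by (bottleneck, energy sum, step
count, terminal m/z). Restricting to maximal pathways matters — every
prefix of a cascade has a bottleneck no larger than the cascade itself,
so ranking all pathways would always return a one-step prefix.

Determinism: expansion, deduplication and every tie-break are fully
ordered, so two runs on the same input produce byte-identical JSON.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_depth` | 3 | maximum cleavage steps per cascade |
| `step_threshold` | 100 kJ mol⁻¹ | per-step ceiling for a "predicted" fragment |
| `tolerance` | 0.5 Da | peak-matching window (nominal predictions) |
| `min_rel_intensity` | 0.05 | observed-peak cutoff relative to the base peak |

Masses: nominal H=1/C=12/N=14/O=16 (the scale of published peak
annotations, and the default for reported peaks); monoisotopic
H 1.0078250, C 12 exactly, N 14.0030740, O 15.9949146, proton 1.0072765,
carried to ≥6 decimals. m/z of a cation is its composition's
monoisotopic mass minus the electron mass implied by these constants.

## Packaged energy table

`src/bpfrag/data/activation_energies.tsv` holds the 17 calculated
patterns spanning the chemistry of the two example molecules (amide,
amine, carboxyl, ester, guanidine; plus the three C–C acylium rows for
CO loss). Energies range from −153 to 403 kJ mol⁻¹; "NA" marks a mode
with no computed channel. The TSV round-trips exactly through
`load_energy_table`/`save_energy_table`, and user tables merge with the
packaged one (`--table`), with key collisions rejected.

## Pattern-space enumeration

At radius 1 (nearest neighbors only, elements {H, C, N, O}) the bond
carbon has 34 substitution states (20 with three single bonds, 12 with a
double plus a single, 2 with a triple), the nitrogen side 13, the oxygen
side 4 — 578 patterns total, as both a closed-form repeated-combination
count and an explicit duplicate-free list (cross-checked against an
independent brute-force multiset generator in the tests). Chemically
implausible patterns (e.g. N–N–N chains) are deliberately *not* removed
by default because the closed form counts them; an optional filter flag
exists. Radius-2 enumeration is not implemented: no well-defined
enumeration scheme exists for it, and a count would be a guess.

## Synthetic fixtures

The two built-in molecules are constructed from SMILES; their toy MSP
spectra contain only m/z values traceable to published peak annotations
of measured standard spectra (a provenance note accompanies each peak),
with *synthetic placeholder intensities* — chosen only so the known
"slight" dipeptide peak at m/z 171 falls below the default 5% intensity
cutoff. The fixtures therefore exercise peak presence/absence logic
faithfully but say nothing about intensity behavior, collision-energy
dependence, noise, isotope clusters or mass error of real spectra;
passing comparison tests demonstrates the cleavage model, not detector
realism.

## Known limitations

* Only C/H/N/O; other elements are rejected loudly.
* Ring bonds are never cleaved (skipped with a warning): ring-opening
  products are not defined in this model.
* The catalog covers 17 patterns; molecules with other chemistry will
  report coverage gaps and predict only partially.
* No kinetics: competition is resolved by activation energy alone, so
  collision-energy dependence and intensities are out of reach.
* Charge-remote fragmentation, cyclization/recombination (e.g. b-ion
  stabilization, SN2 guanidine loss) are not modeled — exactly the
  routes behind the unexplained major peaks of the ester example.
* Rearranged-cleavage product *structures* place the transferred H on
  the charged heteroatom; the true donor position is unresolved
  (formula-level m/z is unaffected).
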