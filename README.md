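# bpfrag

Mechanistic prediction of collision-induced dissociation (CID) fragment
ions for protonated small metabolites, from structure alone.

Spectral libraries of measured MS/MS product-ion spectra will never cover
the metabolite space, so *in silico* fragmentation matters for non-target
metabolite identification. `bpfrag` implements a physicochemical route to
it: every single bond between a carbon and a heteroatom (N, O) in a
molecule is assigned a **bonding pattern (BP)** — the two bound atoms
plus their adjacent chemical groups, with distant substructures
simplified to hydrogens or a methyl. Each catalogued pattern carries
quantum-chemistry-derived activation energies (kJ mol⁻¹) for the two
cleavage modes of a protonated, even-electron ion:

* **direct** — heterolytic cleavage with no hydrogen movement; the
  charge moves to the carbon side (possibly forming an acylium, which
  then ejects CO spontaneously: these C–C steps have negative activation
  energies);
* **rearranged** — one hydrogen moves from the carbon side to the
  heteroatom side, which keeps the charge (e.g. y-type peptide ions).

Tracing cleavage cascades whose every step stays at or below a threshold
(default 100 kJ mol⁻¹) and ranking pathways by their **bottleneck**
(maximum-step) energy yields a theoretical peak list comparable to
standard product-ion spectra. The energies are consumed as data (a
packaged, user-extensible TSV of 17 patterns); no quantum chemistry is
computed here.

Intended users: mass-spectrometry and metabolomics researchers exploring
mechanistic spectrum prediction, and developers of theoretical spectral
libraries.

## Worked example

```python
from bpfrag import (builtin_table, min_energy_pathway, parse_structure,
                    peak_list, search)

glycylleucine = parse_structure("NCC(=O)NC(CC(C)C)C(O)=O", "glycylleucine")
result = search(glycylleucine, builtin_table(), max_depth=3, step_threshold=100)
print(peak_list(result))
print(min_energy_pathway(result).describe())
```

prints

```
[86, 132, 143, 171]
BP6(direct, 25) -> BP8(co-loss, -153) -> BP3(rearranged, 68) => m/z 86
```

Reading: protonated glycylleucine (m/z 189) loses water from its
carboxyl group for only 25 kJ mol⁻¹ (m/z 171), the resulting acylium
sheds CO downhill (−153 kJ mol⁻¹, m/z 143), and a rearranged amide
cleavage at 68 kJ mol⁻¹ leaves the iminium at m/z 86 — the complete
cascade with the cheapest worst step. The rearranged amide cleavage of
the precursor itself (95 kJ mol⁻¹) yields protonated leucine at m/z 132.
All four peaks are the major product ions of the measured standard
spectrum. See `examples/` for runnable narrative scripts (prediction,
spectrum comparison, pattern-space counting).

The same is available from the shell:

```sh
bpfrag predict --input "NCC(=O)NC(CC(C)C)C(O)=O" --out result.json
bpfrag fixtures --name glycylleucine --out-dir fx/
bpfrag compare --prediction result.json --spectrum fx/glycylleucine.msp
bpfrag count-space --radius 1
```

## Scope and limits

Only C/H/N/O chemistry, positive-ion mode, singly charged even-electron
ions. Ring-bond cleavage, charge-remote fragmentation, cyclization/
recombination, kinetics and intensity prediction are out of scope; see
`docs/methods.md` for the model, its conventions and known limitations.
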