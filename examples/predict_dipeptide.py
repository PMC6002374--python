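"""Predict the product-ion peak list of a protonated dipeptide.

Builds glycylleucine from SMILES, runs the depth-3 pathway search with the
packaged activation-energy catalog, and prints the predicted peaks with
the most favorable cleavage cascade.
"""

from bpfrag import (
    builtin_table,
    min_energy_pathway,
    parse_structure,
    peak_list,
    protonated_mz,
    search,
)

glycylleucine = parse_structure("NCC(=O)NC(CC(C)C)C(O)=O", "glycylleucine")
table = builtin_table()

print(f"precursor [M+H]+ m/z {protonated_mz(glycylleucine.formula()):.0f} "
      f"({glycylleucine.formula()})")

result = search(glycylleucine, table, max_depth=3, step_threshold=100)
print("predicted peaks (nominal m/z):", peak_list(result))

best = min_energy_pathway(result)
print("most favorable cascade:", best.describe())
print("step energies (kJ/mol):", list(best.energy_sequence),
      "| bottleneck:", best.bottleneck)

# Each predicted peak is a fragment reachable with every cleavage step at
# or below 100 kJ/mol; the cascade above is the complete pathway whose
# worst step is cheapest, i.e. the one most likely seen in a spectrum.
for frag in result.fragments:
    print(f"  m/z {frag.mz_nominal:>3}  bottleneck {frag.bottleneck:>4g} kJ/mol  "
          f"via {frag.pathway.describe()}")
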