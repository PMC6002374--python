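"""Count the space of nearest-neighbor bonding patterns.

Shows the closed-form repeated-combination count next to the explicit
enumeration, and the effect of the optional plausibility filter.
"""

from bpfrag import enumerate_bp_space, repeated_combination

carbon = repeated_combination(4, 3) + 3 * 4 + 2
nitrogen = repeated_combination(4, 2) + 3
oxygen = 4
print(f"carbon-side states: {carbon}  (20 all-single + 12 double+single + 2 triple)")
print(f"heteroatom-side states: {nitrogen} for N + {oxygen} for O")

count, patterns = enumerate_bp_space(radius=1)
print(f"total radius-1 bonding patterns: {count} "
      f"(explicit list: {len(patterns)}, duplicates: {len(patterns) - len(set(patterns))})")

filtered_count, _ = enumerate_bp_space(radius=1, plausibility_filter=True)
print(f"after dropping heteroatom-heteroatom adjacency: {filtered_count}")

# A catalog would need an activation energy for each pattern (x2 cleavage
# modes); the count shows why simplification strategies matter before
# extending the neighborhood radius.
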