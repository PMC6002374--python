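"""Compare a prediction with an observed product-ion spectrum.

Uses the built-in ethyl argininate fixture: the guanidine/ester chemistry
is only partly covered by simple bond cleavage, so most major observed
peaks stay unexplained - a worked example of reading the comparison
report.
"""

from bpfrag import builtin_table, make_fixture, match_peaks, peak_list, search

graph, spectrum = make_fixture("ethyl-argininate")
result = search(graph, builtin_table())
predicted = peak_list(result)

print("predicted:", predicted)
print("observed major peaks:", [int(mz) for mz, _ in spectrum.peaks])

report = match_peaks(predicted, spectrum, tolerance=0.5, min_rel_intensity=0.05)
print("matched:", [(p, o) for p, o, _ in report.matched])
print("predicted but not observed:", report.predicted_unobserved)
print("observed but unexplained:", report.observed_unexplained)
print(f"explained fraction: {report.explained_fraction:.2f}")

# Only m/z 186 (ammonia loss) is both predicted and observed. The peaks
# at 60/70/144 need high-energy or charge-remote routes outside the
# low-energy cleavage model, which the above-threshold report makes
# explicit:
for frag in result.above_threshold:
    print(f"  above threshold: m/z {frag.mz_nominal} "
          f"(bottleneck {frag.bottleneck:g} kJ/mol)")
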