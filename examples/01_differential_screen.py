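"""Screen simulated three-stage miRNA count libraries for differential
expression with the exact count-ratio test.

Generates 200 miRNAs sequenced to a depth of 10^6 clean reads per stage, 20
of them up-regulated 8-fold at peak lactation, then applies the published
screening rules: expression above 50 reads per million in at least one
stage, |log2 fold change| > 1, and exact-test p < 0.01.
"""

from lactmir import screen_mirnas, simulate_count_libraries

counts, truth = simulate_count_libraries(n_mirnas=200, n_de=20, seed=42)
kept = screen_mirnas(counts)  # compares peak vs early lactation by default

print(f"{len(kept)} of {len(counts.mirnas)} miRNAs pass the screen "
      f"({len(truth.de_mirnas)} were planted)\n")
print(f"{'miRNA':10s} {'peak rpm':>10s} {'early rpm':>10s} {'log2 FC':>8s} {'p':>10s}")
for mirna, res in kept[:8]:
    print(f"{mirna:10s} {res.h_expr:10.1f} {res.s_expr:10.1f} "
          f"{res.log2_fc:8.2f} {res.p_value:10.2e}")
print("...")
missed = set(truth.de_mirnas) - {m for m, _ in kept}
false = {m for m, _ in kept} - set(truth.de_mirnas)
print(f"\nmissed planted miRNAs: {sorted(missed) or 'none'}; "
      f"false positives: {sorted(false) or 'none'}")
# Each kept miRNA roughly shows the planted 8-fold change (log2 FC near 3);
# the tiny p-values reflect counts in the hundreds to tens of thousands.
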