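"""Analytic panel-sizing: how many diagnostic loci are enough?

For a panel of L independent diagnostic loci the probability that a
hybrid presents a pure-species multilocus genotype is (1/2)^L for a
backcross and 2*(1/4)^L for an F2; F1 hybrids are always detected.
"""

import diagpanel as dp

C = dp.HybridClass

print("L\tBC miss\tF2 miss\tworst power")
for L in range(1, 11):
    bc = dp.pure_appearance_prob(C.BC_A, L)
    f2 = dp.pure_appearance_prob(C.F2, L)
    worst = min(dp.detection_power(c, L) for c in (C.BC_A, C.BC_B, C.F2))
    print(f"{L}\t{bc:.5f}\t{f2:.5f}\t{worst:.5f}")

for cls in (C.BC_A, C.F2):
    L = dp.min_loci_for_confidence(cls, 0.95)
    print(f"\nsmallest panel with >=95% power against {cls.value}: {L} loci")

# At L = 7 the worst-case miss probability is 0.5^7 = 0.0078 (< 0.05), so
# the worst-case detection power is 0.9922 (> 0.95): seven diagnostic loci
# already identify backcross and F2 hybrids with high confidence.
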