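"""Estimate F_IS and test the heterozygote deficit by permutation.

Marine bivalve populations commonly show fewer heterozygotes than
Hardy-Weinberg predicts (F_IS > 0). The permutation test shuffles alleles
among individuals within each locus, destroying the within-individual
correlation while keeping allele frequencies fixed.
"""

import diagpanel as dp

gm, _, _ = dp.simulate_two_species(
    dp.SimulationConfig(n_ind_A=120, n_ind_B=30, n_tags=300, seed=3)
)

for pop in (dp.Population.SPECIES_A, dp.Population.SPECIES_B):
    rep = dp.fis_report(gm, pop, n_perm=999, seed=3)
    print(f"{pop.value}: global F_IS = {rep.fis_global:.3f} "
          f"over {rep.n_loci_used} polymorphic loci "
          f"({rep.n_loci_excluded} monomorphic excluded), "
          f"one-sided P {rep.p_value_text}")

# The generator injects F = 0.129 (species A) and F = 0.252 (species B),
# so both estimates should be clearly positive and the permutation
# p-values at or near the 1/(n_perm+1) floor: a significant heterozygote
# deficit in both species, stronger in species B.
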