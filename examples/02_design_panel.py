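"""Run the diagnostic-SNP filter cascade on synthetic data.

Reproduces the marker-selection logic of a two-species screen: keep SNPs
observed fixed for alternative alleles, drop tags carrying any other
polymorphism, enforce per-species call-count minima, drop multi-mapping
tags, and finally draw a random subset sized for one multiplex assay.
"""

import diagpanel as dp

gm, catalog, truth = dp.simulate_two_species(
    dp.SimulationConfig(n_ind_A=120, n_ind_B=30, n_tags=400, seed=7)
)

cfg = dp.PanelFilterConfig(min_called_A=30, min_called_B=15,
                           n_final_random=9, seed=7)
panel = dp.run_cascade(gm, catalog, cfg)

print(panel.provenance_table().to_string(index=False))
print(f"\nfinal panel ({len(panel)} markers):")
for m in panel:
    place = f"{m.placement[0]}:{m.placement[1]}" if m.placement else "unplaced"
    print(f"  {m.marker_id:<14} {m.allele_A}/{m.allele_B}  {place}")

# Each provenance row shows how many candidate SNPs entered and survived a
# stage; the final random subset mirrors picking a handful of markers for
# a single-tube genotyping assay. allele_A/allele_B are the alleles fixed
# in species A and species B respectively.
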