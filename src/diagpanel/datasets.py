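"""Bundled reference data: the nine-marker cockle SNaPshot assay.

The panel distinguishes the edible cockle *Cerastoderma edule* from the
lagoon cockle *C. glaucum*; each marker is a SNP fixed for alternative
alleles in the two species (allele_A = *C. edule*, allele_B =
*C. glaucum*), placed on its GenBank marker sequence (MN178488-MN178496).
The matching internal SNaPshot primers carry lowercase 5' "gact"-repeat
tails that stagger product lengths for single-multiplex electrophoresis.
"""

from __future__ import annotations

import csv
from importlib import resources

from .assay_multiplex import TailedPrimer, TailedPrimerSet
from .genotype_io import DiagnosticPanel, read_panel_json

__all__ = ["load_cockle_panel", "load_cockle_primers"]


def _data_path(name: str):
    return resources.files("diagpanel.data") / name


def load_cockle_panel() -> DiagnosticPanel:
    """The nine diagnostic *Cerastoderma* SNP markers as a panel."""
    with resources.as_file(_data_path("cockle_snapshot_panel.json")) as p:
        return read_panel_json(p)


def load_cockle_primers() -> TailedPrimerSet:
    """The nine tailed internal SNaPshot primers of the cockle assay.

    Tails are recovered from the lowercase prefix of each printed primer
    sequence; the published scheme uses the 4-nt unit "gact" and total
    lengths pairwise at least 4 nt apart.
    """
    entries = []
    with resources.as_file(_data_path("cockle_snapshot_primers.csv")) as p:
        with open(p, newline="") as fh:
            for row in csv.DictReader(fh):
                seq = row["tailed_sequence"]
                i = 0
                while i < len(seq) and seq[i].islower():
                    i += 1
                entries.append(
                    TailedPrimer(
                        marker_id=row["marker_id"],
                        core=seq[i:],
                        sense=row["sense"],
                        tail=seq[:i],
                    )
                )
    return TailedPrimerSet(entries=entries, tail_unit="gact", min_spacing=4)
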