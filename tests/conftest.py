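import numpy as np
import pytest

from diagpanel import (
    GenotypeMatrix,
    Individual,
    Locus,
    Population,
    RadTag,
    RadTagCatalog,
)

NUC = "ACGT"


def build_matrix(calls_a, calls_b, tag_of=None, alleles=None):
    """Build a small GenotypeMatrix from per-population call-code grids.

    ``calls_a``/``calls_b`` are (n_ind, n_loci) nested lists using the codes
    0/1/2/-1. Loci are named L0.. and live each on its own tag unless
    ``tag_of`` maps column index -> tag_id.
    """
    calls_a = np.asarray(calls_a, dtype=np.int8).reshape(len(calls_a), -1)
    calls_b = np.asarray(calls_b, dtype=np.int8).reshape(len(calls_b), -1)
    n_loci = calls_a.shape[1]
    loci = []
    for j in range(n_loci):
        tag = tag_of[j] if tag_of else f"t{j}"
        ref, alt = alleles[j] if alleles else ("A", "G")
        loci.append(Locus(f"L{j}", tag, 0 if not tag_of else j, ref, alt))
    individuals = [
        Individual(f"a{i}", Population.SPECIES_A) for i in range(calls_a.shape[0])
    ] + [Individual(f"b{i}", Population.SPECIES_B) for i in range(calls_b.shape[0])]
    return GenotypeMatrix(individuals, loci, np.vstack([calls_a, calls_b]))


def catalog_for(gm, n_hits=None, placements=None):
    """One tag per distinct tag_id in gm; n_hits/placements overridable."""
    n_hits = n_hits or {}
    placements = placements or {}
    tags = {}
    for locus in gm.loci:
        tags.setdefault(locus.tag_id, []).append(locus.locus_id)
    out = RadTagCatalog()
    for tid, lids in tags.items():
        hits = n_hits.get(tid, 1)
        aln = placements.get(tid)
        if aln is None:
            aln = [(f"chr{k}", 1000 * k, 1000 * k + 36) for k in range(hits)]
        out.add(RadTag(tag_id=tid, locus_ids=lids, alignments=aln, n_hits=hits))
    return out


@pytest.fixture(scope="session")
def random_matrix():
    """A 12-individual x 30-locus matrix with all call codes present."""
    rng = np.random.default_rng(42)
    calls = rng.choice([0, 1, 2, -1], size=(12, 30), p=[0.4, 0.3, 0.2, 0.1])
    return build_matrix(calls[:8], calls[8:], tag_of={j: f"t{j // 2}" for j in range(30)})
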