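"""Diagnostic-SNP classification and the panel filter cascade.

Given genotypes of two putative species, each SNP is placed in one of the
categories below; diagnostic SNPs (fixed for alternative alleles in the two
species) are then pushed through an ordered filter cascade that mirrors how
assayable markers are selected from RAD-tag data:

1. keep SNPs observed fixed for alternative alleles in the two species;
2. keep tags whose diagnostic SNP is the tag's only SNP, with no other
   polymorphism on the tag;
3. keep loci called in enough specimens of each species;
4. keep tags aligning to a single genome site;
5. optionally draw a final random subset for assay design.

Every stage records (n_in, n_out) so the provenance of the final panel is
auditable. Fixation is defined on observed calls (sample-fixed), not on a
frequency threshold; the per-species minimum call counts carry the
sampling-depth burden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    DiagnosticMarker,
    DiagnosticPanel,
    GenotypeMatrix,
    Population,
    RadTagCatalog,
)

__all__ = [
    "SnpCategory",
    "PopLocusStats",
    "LocusFreqSummary",
    "PanelFilterConfig",
    "summarize_locus",
    "summarize_all",
    "classify_snp",
    "maf_spectrum",
    "MafSpectrum",
    "run_cascade",
    "random_subset",
]


class SnpCategory(str, Enum):
    DIAGNOSTIC = "DIAGNOSTIC"  # fixed for alternative alleles in the two species
    PRIVATE_A = "PRIVATE_A"  # polymorphic only in species A
    PRIVATE_B = "PRIVATE_B"  # polymorphic only in species B
    SHARED_POLY = "SHARED_POLY"  # polymorphic in both
    MONOMORPHIC = "MONOMORPHIC"  # same allele fixed in both
    UNCLASSIFIED_LOW_CALLS = "UNCLASSIFIED_LOW_CALLS"


@dataclass(frozen=True)
class PopLocusStats:
    """Per-population per-locus allele/genotype statistics.

    All frequencies are computed from non-missing calls only and are NaN
    when the population has zero called individuals.
    """

    n_called: int
    p_ref: float
    obs_het: float
    exp_het: float

    @property
    def maf(self) -> float:
        if math.isnan(self.p_ref):
            return float("nan")
        return min(self.p_ref, 1.0 - self.p_ref)

    @property
    def is_polymorphic(self) -> bool:
        return self.n_called > 0 and 0.0 < self.p_ref < 1.0


@dataclass
class LocusFreqSummary:
    locus_id: str
    stats: dict[Population, PopLocusStats]
    category: SnpCategory = SnpCategory.UNCLASSIFIED_LOW_CALLS

    def pop(self, population: Population) -> PopLocusStats:
        return self.stats[population]

    @property
    def maf_polymorphic(self) -> float:
        """MAF in the polymorphic population (meaningful for private SNPs;
        the other species' MAF is identically 0)."""
        for st in self.stats.values():
            if st.is_polymorphic:
                return st.maf
        return float("nan")


@dataclass
class PanelFilterConfig:
    """Thresholds of the panel filter cascade.

    ``min_called_A``/``min_called_B`` are the per-species minimum numbers of
    genotyped specimens a locus must reach (defaults 30 and 15, matching a
    design with ~120 species-A and ~30 species-B specimens).
    """

    min_called_A: int = 30
    min_called_B: int = 15
    require_single_snp_tag: bool = True
    require_no_other_polymorphism: bool = True
    require_unique_alignment: bool = True
    n_final_random: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_called_A < 1 or self.min_called_B < 1:
            raise ValueError("minimum call counts must be >= 1")
        if self.n_final_random is not None and self.n_final_random < 1:
            raise ValueError("n_final_random must be >= 1 when set")


def _pop_stats(col: np.ndarray) -> PopLocusStats:
    called = col[col != MISSING]
    n = int(called.size)
    if n == 0:
        nan = float("nan")
        return PopLocusStats(0, nan, nan, nan)
    n_het = int(np.count_nonzero(called == HET))
    n_alt = int(np.count_nonzero(called == HOM_ALT))
    p_ref = 1.0 - (2 * n_alt + n_het) / (2 * n)
    ho = n_het / n
    he = 2.0 * p_ref * (1.0 - p_ref)
    return PopLocusStats(n, p_ref, ho, he)


def summarize_locus(gm: GenotypeMatrix, locus_id: str) -> LocusFreqSummary:
    """Per-population call counts, allele frequencies and heterozygosities
    for one locus. The category stays UNCLASSIFIED_LOW_CALLS until
    :func:`classify_snp` runs."""
    j = gm.locus_index(locus_id)
    stats = {}
    for pop in (Population.SPECIES_A, Population.SPECIES_B):
        stats[pop] = _pop_stats(gm.calls[gm.population_mask(pop), j])
    return LocusFreqSummary(locus_id, stats)


def summarize_all(gm: GenotypeMatrix) -> list[LocusFreqSummary]:
    """Vectorised :func:`summarize_locus` over every locus in the matrix."""
    out = []
    masks = {
        pop: gm.population_mask(pop)
        for pop in (Population.SPECIES_A, Population.SPECIES_B)
    }
    per_pop: dict[Population, tuple[np.ndarray, ...]] = {}
    for pop, mask in masks.items():
        sub = gm.calls[mask]
        n_called = np.count_nonzero(sub != MISSING, axis=0)
        n_het = np.count_nonzero(sub == HET, axis=0)
        n_alt = np.count_nonzero(sub == HOM_ALT, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_ref = 1.0 - (2 * n_alt + n_het) / (2 * n_called)
            ho = n_het / n_called
        he = 2.0 * p_ref * (1.0 - p_ref)
        per_pop[pop] = (n_called, p_ref, ho, he)
    for j, locus in enumerate(gm.loci):
        stats = {
            pop: PopLocusStats(
                int(vals[0][j]), float(vals[1][j]), float(vals[2][j]), float(vals[3][j])
            )
            for pop, vals in per_pop.items()
        }
        out.append(LocusFreqSummary(locus.locus_id, stats))
    return out


def classify_snp(
    summary: LocusFreqSummary, cfg: PanelFilterConfig
) -> SnpCategory:
    """Assign the SNP category; also stored on the summary.

    DIAGNOSTIC requires strict fixation of alternative alleles on the
    observed calls of both species *and* both per-species minimum call
    counts; any locus below its call-count threshold is
    UNCLASSIFIED_LOW_CALLS regardless of its frequencies.
    """
    a = summary.pop(Population.SPECIES_A)
    b = summary.pop(Population.SPECIES_B)
    if a.n_called < cfg.min_called_A or b.n_called < cfg.min_called_B:
        cat = SnpCategory.UNCLASSIFIED_LOW_CALLS
    elif (a.p_ref == 1.0 and b.p_ref == 0.0) or (a.p_ref == 0.0 and b.p_ref == 1.0):
        cat = SnpCategory.DIAGNOSTIC
    elif a.is_polymorphic and b.is_polymorphic:
        cat = SnpCategory.SHARED_POLY
    elif a.is_polymorphic:
        cat = SnpCategory.PRIVATE_A
    elif b.is_polymorphic:
        cat = SnpCategory.PRIVATE_B
    else:
        cat = SnpCategory.MONOMORPHIC
    summary.category = cat
    return cat


@dataclass(frozen=True)
class MafSpectrum:
    n_total: int
    n_at_or_above: int

    @property
    def proportion_at_or_above(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return self.n_at_or_above / self.n_total

    @property
    def percent_at_or_above(self) -> float:
        """Display-rounded percentage (1 decimal place)."""
        return round(100.0 * self.proportion_at_or_above, 1)

    @property
    def percent_below(self) -> float:
        return round(100.0 * (1.0 - self.proportion_at_or_above), 1)


def maf_spectrum(
    summaries: Iterable[LocusFreqSummary],
    category: SnpCategory,
    threshold: float = 0.05,
) -> MafSpectrum:
    """Count private SNPs of one species with MAF at or above ``threshold``.

    MAF is taken in the polymorphic population (in the other species a
    private SNP is monomorphic, so its MAF there is identically zero).
    Proportions are kept at full precision; percentages are rounded only
    at display time.
    """
    if category not in (SnpCategory.PRIVATE_A, SnpCategory.PRIVATE_B):
        raise ValueError(f"maf_spectrum is defined for private SNPs, got {category}")
    n_total = 0
    n_above = 0
    for s in summaries:
        if s.category is not category:
            continue
        n_total += 1
        if s.maf_polymorphic >= threshold:
            n_above += 1
    return MafSpectrum(n_total, n_above)


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

_RELAXED = PanelFilterConfig(min_called_A=1, min_called_B=1)


def _fixed_alleles(summary: LocusFreqSummary, locus) -> tuple[str, str]:
    """(allele fixed in species A, allele fixed in species B)."""
    a = summary.pop(Population.SPECIES_A)
    if a.p_ref == 1.0:
        return locus.ref_allele, locus.alt_allele
    return locus.alt_allele, locus.ref_allele


def run_cascade(
    gm: GenotypeMatrix, cat: RadTagCatalog, cfg: PanelFilterConfig
) -> DiagnosticPanel:
    """Run the full filter cascade and return a provenance-tracked panel.

    Stage 1 tests fixation on observed calls only (any locus with at least
    one call per species can qualify); the per-species call-count
    thresholds are applied at their own later stage, so each (n_in, n_out)
    pair isolates one filter.
    """
    summaries = {s.locus_id: s for s in summarize_all(gm)}
    for s in summaries.values():
        classify_snp(s, _RELAXED)

    provenance: list[tuple[str, int, int]] = []
    current = [l for l in gm.loci]

    # 1. diagnostic: observed fixation for alternative alleles
    n_in = len(current)
    current = [
        l for l in current if summaries[l.locus_id].category is SnpCategory.DIAGNOSTIC
    ]
    provenance.append(("diagnostic", n_in, len(current)))

    # 2. single-SNP tags with no other polymorphism
    if cfg.require_single_snp_tag or cfg.require_no_other_polymorphism:
        n_in = len(current)
        diag_per_tag: dict[str, int] = {}
        poly_per_tag: dict[str, int] = {}
        for l in gm.loci:
            c = summaries[l.locus_id].category
            if c is SnpCategory.DIAGNOSTIC:
                diag_per_tag[l.tag_id] = diag_per_tag.get(l.tag_id, 0) + 1
            elif c is not SnpCategory.MONOMORPHIC:
                # private/shared polymorphism (or unclassifiable) on the tag
                poly_per_tag[l.tag_id] = poly_per_tag.get(l.tag_id, 0) + 1
        kept = []
        for l in current:
            if cfg.require_single_snp_tag and diag_per_tag.get(l.tag_id, 0) != 1:
                continue
            if cfg.require_no_other_polymorphism and poly_per_tag.get(l.tag_id, 0):
                continue
            kept.append(l)
        current = kept
        provenance.append(("single_snp_tag", n_in, len(current)))

    # 3. per-species minimum call counts
    n_in = len(current)
    current = [
        l
        for l in current
        if summaries[l.locus_id].pop(Population.SPECIES_A).n_called >= cfg.min_called_A
        and summaries[l.locus_id].pop(Population.SPECIES_B).n_called >= cfg.min_called_B
    ]
    provenance.append(("call_count", n_in, len(current)))

    # 4. unique genome alignment
    if cfg.require_unique_alignment:
        n_in = len(current)
        current = [l for l in current if cat[l.tag_id].n_hits == 1]
        provenance.append(("unique_alignment", n_in, len(current)))

    markers = []
    for l in current:
        allele_a, allele_b = _fixed_alleles(summaries[l.locus_id], l)
        tag = cat[l.tag_id]
        unique = tag.unique_placement
        markers.append(
            DiagnosticMarker(
                marker_id=l.locus_id,
                locus_id=l.locus_id,
                tag_id=l.tag_id,
                allele_A=allele_a,
                allele_B=allele_b,
                placement=(unique[0], unique[1] + l.offset) if unique else None,
            )
        )
    panel = DiagnosticPanel(markers=markers, provenance=provenance)

    # 5. final random subset for assay design
    if cfg.n_final_random is not None:
        panel = random_subset(panel, cfg.n_final_random, cfg.seed)
    return panel


def random_subset(panel: DiagnosticPanel, n: int, seed: int) -> DiagnosticPanel:
    """Draw ``n`` markers uniformly without replacement (panel order kept),
    reproducibly under ``seed``; provenance gets a 'random_subset' stage."""
    if n > len(panel):
        raise ValueError(
            f"cannot draw {n} markers from a panel of {len(panel)}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(panel), size=n, replace=False))
    markers = [panel.markers[i] for i in idx]
    return DiagnosticPanel(
        markers=markers,
        provenance=panel.provenance + [("random_subset", len(panel), n)],
    )
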