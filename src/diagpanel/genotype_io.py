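"""Readers, writers and in-memory containers for two-species RAD-tag genotype data.

The central object is :class:`GenotypeMatrix`: individuals x biallelic loci
with population labels and first-class missing calls. Loci are grouped into
RAD-tags (short restriction-site-anchored fragments, 36 bp for AlfI 2b-RAD)
described by a :class:`RadTagCatalog` that also carries genome-alignment
information used by the panel-design filters.

Conventions
-----------
* internal call codes: 0 = HOM_REF, 1 = HET, 2 = HOM_ALT, -1 = MISSING
* internal tag offsets are 0-based; VCF POS is 1-based; BED is half-open 0-based
* population labels live in a two-column sidecar sample map (``sample\tpop``),
  never inside the VCF, because VCF has no standard population field
* tags without a unique genome placement are written with the synthetic
  contig name ``tag:<tag_id>`` so that multi-mapping/unplaced tags remain
  representable end to end
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

__all__ = [
    "Population",
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "Individual",
    "Locus",
    "GenotypeMatrix",
    "RadTag",
    "RadTagCatalog",
    "DiagnosticMarker",
    "DiagnosticPanel",
    "SpecimenPanelGenotype",
    "read_sample_map",
    "write_sample_map",
    "read_vcf",
    "write_vcf",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_bed",
    "read_panel_json",
    "write_panel_json",
    "read_specimens_csv",
    "write_specimens_csv",
]

# genotype call codes (int8 in the calls matrix)
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

_VALID_CALLS = frozenset({HOM_REF, HET, HOM_ALT, MISSING})
_NUCLEOTIDES = frozenset("ACGT")

#: specimen-level genotype codes on a diagnostic panel, where A is the
#: species-A diagnostic allele and B the species-B one
PANEL_CODES = ("AA", "AB", "BB", "NA")


class Population(str, Enum):
    """Population label of an individual in the two-species design."""

    SPECIES_A = "SPECIES_A"
    SPECIES_B = "SPECIES_B"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, text: str) -> "Population":
        t = text.strip().upper()
        aliases = {
            "A": cls.SPECIES_A,
            "SPECIES_A": cls.SPECIES_A,
            "B": cls.SPECIES_B,
            "SPECIES_B": cls.SPECIES_B,
            "UNKNOWN": cls.UNKNOWN,
            "?": cls.UNKNOWN,
        }
        if t not in aliases:
            raise ValueError(f"unknown population label {text!r}")
        return aliases[t]


@dataclass(frozen=True)
class Individual:
    individual_id: str
    population: Population = Population.UNKNOWN


@dataclass(frozen=True)
class Locus:
    """One biallelic SNP inside a RAD-tag."""

    locus_id: str
    tag_id: str
    offset: int  # 0-based position within the tag consensus
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError(f"locus {self.locus_id}: negative offset")
        for a in (self.ref_allele, self.alt_allele):
            if a not in _NUCLEOTIDES:
                raise ValueError(f"locus {self.locus_id}: invalid allele {a!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"locus {self.locus_id}: ref and alt alleles are both {self.ref_allele!r}"
            )


class GenotypeMatrix:
    """Individuals x loci genotype calls with population labels.

    Parameters
    ----------
    individuals
        Ordered individuals (rows).
    loci
        Ordered loci (columns); each belongs to exactly one tag.
    calls
        ``(n_individuals, n_loci)`` int8 array of call codes. The table is
        complete: every pair has exactly one code (possibly MISSING).
    """

    def __init__(
        self,
        individuals: Sequence[Individual],
        loci: Sequence[Locus],
        calls: np.ndarray,
    ) -> None:
        self.individuals = list(individuals)
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        bad = set(np.unique(calls)) - _VALID_CALLS
        if bad:
            raise ValueError(f"invalid call codes in matrix: {sorted(bad)}")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus_id in matrix")
        iids = [i.individual_id for i in self.individuals]
        if len(set(iids)) != len(iids):
            raise ValueError("duplicate individual_id in matrix")
        self.calls = calls
        self._locus_index = {lid: j for j, lid in enumerate(ids)}

    # ------------------------------------------------------------------ views
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def locus_index(self, locus_id: str) -> int:
        try:
            return self._locus_index[locus_id]
        except KeyError:
            raise KeyError(f"locus {locus_id!r} not in matrix") from None

    def population_mask(self, population: Population) -> np.ndarray:
        return np.array(
            [ind.population is population for ind in self.individuals], dtype=bool
        )

    def subset_loci(self, locus_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(lid) for lid in locus_ids]
        return GenotypeMatrix(
            self.individuals, [self.loci[j] for j in idx], self.calls[:, idx]
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypeMatrix({self.n_individuals} individuals x "
            f"{self.n_loci} loci)"
        )


@dataclass
class RadTag:
    """One RAD-tag: consensus fragment grouping one or more SNP loci.

    ``n_hits`` counts alignments of the tag consensus to the reference
    genome. When the full alignment list is known (e.g. from a BED file)
    it equals ``len(alignments)``; a VCF carries only the placement used
    for CHROM/POS plus the hit count, so ``alignments`` may then hold just
    the primary placement.
    """

    tag_id: str
    consensus_length: int = 36
    locus_ids: list[str] = field(default_factory=list)
    alignments: list[tuple[str, int, int]] = field(default_factory=list)
    n_hits: int | None = None

    def __post_init__(self) -> None:
        if self.consensus_length <= 0:
            raise ValueError(f"tag {self.tag_id}: consensus_length must be > 0")
        if self.n_hits is None:
            self.n_hits = len(self.alignments) if self.alignments else 1
        if self.n_hits < 0:
            raise ValueError(f"tag {self.tag_id}: negative n_hits")
        if self.alignments and self.n_hits < len(self.alignments):
            raise ValueError(
                f"tag {self.tag_id}: n_hits={self.n_hits} < "
                f"{len(self.alignments)} recorded alignments"
            )

    @property
    def unique_placement(self) -> tuple[str, int, int] | None:
        """The single genome placement, or None if unplaced/multi-mapping."""
        if self.n_hits == 1 and self.alignments:
            return self.alignments[0]
        return None


class RadTagCatalog:
    """Mapping of tag_id -> :class:`RadTag`, ordered by insertion."""

    def __init__(self, tags: Iterable[RadTag] = ()) -> None:
        self._tags: dict[str, RadTag] = {}
        for t in tags:
            self.add(t)

    def add(self, tag: RadTag) -> None:
        if tag.tag_id in self._tags:
            raise ValueError(f"duplicate tag_id {tag.tag_id!r}")
        self._tags[tag.tag_id] = tag

    def __getitem__(self, tag_id: str) -> RadTag:
        return self._tags[tag_id]

    def __contains__(self, tag_id: str) -> bool:
        return tag_id in self._tags

    def __iter__(self):
        return iter(self._tags.values())

    def __len__(self) -> int:
        return len(self._tags)

    @property
    def tag_ids(self) -> list[str]:
        return list(self._tags)

    def with_alignments(
        self, alignments: Mapping[str, Sequence[tuple[str, int, int]]]
    ) -> "RadTagCatalog":
        """Return a copy whose alignment lists are replaced from a BED read."""
        out = RadTagCatalog()
        for t in self:
            hits = [tuple(a) for a in alignments.get(t.tag_id, [])]
            out.add(
                RadTag(
                    tag_id=t.tag_id,
                    consensus_length=t.consensus_length,
                    locus_ids=list(t.locus_ids),
                    alignments=hits,
                    n_hits=len(hits) if hits else t.n_hits,
                )
            )
        return out


# ---------------------------------------------------------------------------
# diagnostic panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticMarker:
    """One assayable diagnostic SNP: fixed for alternative alleles in the
    two species, so any heterozygote implies mixed ancestry."""

    marker_id: str
    locus_id: str
    tag_id: str
    allele_A: str
    allele_B: str
    placement: tuple[str, int] | None = None  # (chrom, 0-based start) if unique

    def __post_init__(self) -> None:
        if self.allele_A == self.allele_B:
            raise ValueError(
                f"marker {self.marker_id}: diagnostic alleles are identical "
                f"({self.allele_A!r})"
            )


@dataclass
class DiagnosticPanel:
    """Ordered diagnostic markers plus the per-stage filter provenance."""

    markers: list[DiagnosticMarker] = field(default_factory=list)
    provenance: list[tuple[str, int, int]] = field(default_factory=list)  # (stage, n_in, n_out)

    def __post_init__(self) -> None:
        names = [m.marker_id for m in self.markers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate marker ids in panel: {dupes}")
        prev = None
        for stage, n_in, n_out in self.provenance:
            if n_out > n_in:
                raise ValueError(f"stage {stage!r}: n_out {n_out} > n_in {n_in}")
            if prev is not None and n_in > prev:
                raise ValueError(
                    f"stage {stage!r}: n_in {n_in} exceeds previous n_out {prev}"
                )
            prev = n_out

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def provenance_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.provenance, columns=["stage", "n_in", "n_out"])


@dataclass
class SpecimenPanelGenotype:
    """Genotypes of one specimen over a diagnostic panel.

    Codes are AA / AB / BB / NA with A the species-A diagnostic allele and
    B the species-B one; the marker -> code mapping contains each panel
    locus exactly once (enforced by the dict).
    """

    specimen_id: str
    genotypes: dict[str, str]

    def __post_init__(self) -> None:
        for marker, code in self.genotypes.items():
            if code not in PANEL_CODES:
                raise ValueError(
                    f"specimen {self.specimen_id}, marker {marker}: "
                    f"invalid panel genotype {code!r}"
                )

    @property
    def n_typed(self) -> int:
        return sum(1 for c in self.genotypes.values() if c != "NA")


# ---------------------------------------------------------------------------
# sample maps
# ---------------------------------------------------------------------------


def read_sample_map(path: str | Path) -> dict[str, Population]:
    """Read a two-column (sample_id, population) whitespace/TSV file."""
    out: dict[str, Population] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
        sid, pop = parts
        if sid in out:
            raise ValueError(f"{path}:{lineno}: duplicate sample {sid!r}")
        out[sid] = Population.parse(pop)
    return out


def write_sample_map(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind in gm.individuals:
            fh.write(f"{ind.individual_id}\t{ind.population.value}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_TAG_CONTIG_PREFIX = "tag:"


def _parse_locus_identity(variant) -> tuple[str, int]:
    """Extract (tag_id, offset) from INFO TAG/OFF or from an ID like tag7_12."""
    tag = variant.INFO.get("TAG")
    off = variant.INFO.get("OFF")
    if tag is not None and off is not None:
        return str(tag), int(off)
    vid = variant.ID
    if vid is None:
        raise ValueError(
            f"record {variant.CHROM}:{variant.POS} has no ID and no TAG/OFF INFO"
        )
    tag_part, _, off_part = vid.rpartition("_")
    if not tag_part or not off_part.isdigit():
        raise ValueError(
            f"record {variant.CHROM}:{variant.POS}: malformed ID {vid!r} "
            "(expected '<tag>_<offset>')"
        )
    return tag_part, int(off_part)


def read_vcf(
    path: str | Path, sample_map: str | Path | Mapping[str, Population] | None = None
) -> tuple[GenotypeMatrix, RadTagCatalog]:
    """Read a biallelic-SNP VCF into a genotype matrix and tag catalog.

    Population labels come from ``sample_map`` (path to a two-column file or
    a ready mapping); every VCF sample must appear in it. Tag identity is
    taken from INFO keys TAG/OFF when present, otherwise from an ID column
    of the form ``<tag_id>_<offset>``. INFO key NH gives the genome-hit
    count of the tag (absent -> 1).
    """
    if sample_map is None:
        popmap: Mapping[str, Population] = {}
    elif isinstance(sample_map, (str, Path)):
        popmap = read_sample_map(sample_map)
    else:
        popmap = sample_map

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    individuals = []
    for s in samples:
        if popmap:
            if s not in popmap:
                raise ValueError(f"sample {s!r} in VCF is absent from the sample map")
            individuals.append(Individual(s, popmap[s]))
        else:
            individuals.append(Individual(s, Population.UNKNOWN))

    loci: list[Locus] = []
    columns: list[np.ndarray] = []
    tags: dict[str, RadTag] = {}
    # cyvcf2 gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
    code_map = np.array([HOM_REF, HET, HOM_ALT, MISSING], dtype=np.int8)
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {variant.CHROM}:{variant.POS} "
                f"(ALT={','.join(variant.ALT) or '.'}) is not supported"
            )
        tag_id, offset = _parse_locus_identity(variant)
        lid = variant.ID or f"{tag_id}_{offset}"
        loci.append(Locus(lid, tag_id, offset, variant.REF, variant.ALT[0]))
        columns.append(code_map[variant.gt_types])
        n_hits = variant.INFO.get("NH")
        placed = not variant.CHROM.startswith(_TAG_CONTIG_PREFIX)
        if tag_id not in tags:
            aln: list[tuple[str, int, int]] = []
            if placed:
                start = variant.POS - 1 - offset  # tag consensus start, 0-based
                aln = [(variant.CHROM, start, start + 36)]
            tags[tag_id] = RadTag(
                tag_id=tag_id,
                locus_ids=[lid],
                alignments=aln,
                n_hits=int(n_hits) if n_hits is not None else (1 if placed else 1),
            )
        else:
            tags[tag_id].locus_ids.append(lid)
    vcf.close()

    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, loci, calls), RadTagCatalog(tags.values())


def write_vcf(gm: GenotypeMatrix, cat: RadTagCatalog, path: str | Path) -> None:
    """Write a VCF v4.2. Uniquely placed tags get genomic CHROM/POS; all
    other tags use the synthetic contig ``tag:<tag_id>`` with POS = offset+1."""
    header = pysam.VariantHeader()
    header.info.add("TAG", 1, "String", "RAD tag id")
    header.info.add("OFF", 1, "Integer", "0-based offset of the SNP in the tag")
    header.info.add("NH", 1, "Integer", "number of genome alignment hits of the tag")
    header.formats.add("GT", 1, "String", "Genotype")

    contigs: dict[str, int | None] = {}
    placements: dict[str, tuple[str, int] | None] = {}
    for locus in gm.loci:
        tag = cat[locus.tag_id]
        unique = tag.unique_placement
        if unique is not None:
            chrom, start, _end = unique
            placements[locus.tag_id] = (chrom, start)
            contigs.setdefault(chrom, None)
        else:
            placements[locus.tag_id] = None
            contigs.setdefault(
                f"{_TAG_CONTIG_PREFIX}{locus.tag_id}", tag.consensus_length
            )
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for ind in gm.individuals:
        header.add_sample(ind.individual_id)

    gt_of = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, locus in enumerate(gm.loci):
            placed = placements[locus.tag_id]
            if placed is not None:
                chrom, tag_start = placed
                pos0 = tag_start + locus.offset
            else:
                chrom = f"{_TAG_CONTIG_PREFIX}{locus.tag_id}"
                pos0 = locus.offset
            rec = out.new_record(
                contig=chrom,
                start=pos0,
                alleles=(locus.ref_allele, locus.alt_allele),
            )
            rec.id = locus.locus_id
            rec.info["TAG"] = locus.tag_id
            rec.info["OFF"] = locus.offset
            rec.info["NH"] = cat[locus.tag_id].n_hits
            for i, ind in enumerate(gm.individuals):
                rec.samples[ind.individual_id]["GT"] = gt_of[int(gm.calls[i, j])]
            out.write(rec)


# ---------------------------------------------------------------------------
# genotype-matrix CSV (rows = individuals, columns = loci)
# ---------------------------------------------------------------------------

_CSV_HEADER_ROWS = ("locus_id", "tag_id", "offset")
_CSV_CELLS = {"0": HOM_REF, "1": HET, "2": HOM_ALT, "NA": MISSING}
_CSV_CELLS_INV = {v: k for k, v in _CSV_CELLS.items()}

# The CSV dialect carries no allele columns; loci read from CSV get these
# placeholder alleles (the matrix semantics downstream use only call codes).
_CSV_DEFAULT_ALLELES = ("A", "C")


def write_genotype_csv(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["locus_id"] + [l.locus_id for l in gm.loci])
        w.writerow(["tag_id"] + [l.tag_id for l in gm.loci])
        w.writerow(["offset"] + [str(l.offset) for l in gm.loci])
        for i, ind in enumerate(gm.individuals):
            w.writerow(
                [ind.individual_id]
                + [_CSV_CELLS_INV[int(c)] for c in gm.calls[i]]
            )


def read_genotype_csv(
    path: str | Path, sample_map: str | Path | Mapping[str, Population] | None = None
) -> tuple[GenotypeMatrix, RadTagCatalog]:
    """Read the rectangular CSV dialect: three header rows (locus_id, tag_id,
    offset), then one row per individual with cells in {0,1,2,NA}."""
    if isinstance(sample_map, (str, Path)):
        popmap: Mapping[str, Population] = read_sample_map(sample_map)
    else:
        popmap = sample_map or {}
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3 or tuple(r[0] for r in rows[:3]) != _CSV_HEADER_ROWS:
        raise ValueError(
            f"{path}: expected three header rows {_CSV_HEADER_ROWS}, "
            f"got {[r[0] for r in rows[:3]]!r}"
        )
    locus_ids, tag_ids, offsets = (r[1:] for r in rows[:3])
    ref, alt = _CSV_DEFAULT_ALLELES
    loci = [
        Locus(lid, tid, int(off), ref, alt)
        for lid, tid, off in zip(locus_ids, tag_ids, offsets, strict=True)
    ]
    individuals: list[Individual] = []
    calls = np.full((len(rows) - 3, len(loci)), MISSING, dtype=np.int8)
    for i, row in enumerate(rows[3:]):
        sid, cells = row[0], row[1:]
        if len(cells) != len(loci):
            raise ValueError(f"{path}: row {sid!r} has {len(cells)} cells, expected {len(loci)}")
        if popmap and sid not in popmap:
            raise ValueError(f"sample {sid!r} in CSV is absent from the sample map")
        individuals.append(Individual(sid, popmap.get(sid, Population.UNKNOWN)))
        for j, cell in enumerate(cells):
            try:
                calls[i, j] = _CSV_CELLS[cell.strip()]
            except KeyError:
                raise ValueError(
                    f"{path}: invalid genotype cell {cell!r} at ({sid}, {loci[j].locus_id})"
                ) from None
    tags: dict[str, RadTag] = {}
    for locus in loci:
        tags.setdefault(
            locus.tag_id, RadTag(tag_id=locus.tag_id, n_hits=1)
        ).locus_ids.append(locus.locus_id)
    return GenotypeMatrix(individuals, loci, calls), RadTagCatalog(tags.values())


# ---------------------------------------------------------------------------
# BED alignments (chrom, start, end, tag_id; half-open 0-based)
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read tag alignments from a 4-column BED; multi-mapping tags occupy
    several lines and all of them are kept."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "tag_id"],
        dtype={"chrom": str, "start": int, "end": int, "tag_id": str},
        comment="#",
    )
    out: dict[str, list[tuple[str, int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.tag_id, []).append((row.chrom, row.start, row.end))
    return out


# ---------------------------------------------------------------------------
# panel JSON
# ---------------------------------------------------------------------------


def write_panel_json(panel: DiagnosticPanel, path: str | Path) -> None:
    doc = {
        "markers": [
            {
                "marker_id": m.marker_id,
                "locus_id": m.locus_id,
                "tag_id": m.tag_id,
                "allele_A": m.allele_A,
                "allele_B": m.allele_B,
                "placement": (
                    {"chrom": m.placement[0], "start": m.placement[1]}
                    if m.placement
                    else None
                ),
            }
            for m in panel.markers
        ],
        "provenance": [
            {"stage": s, "n_in": n_in, "n_out": n_out}
            for s, n_in, n_out in panel.provenance
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_panel_json(path: str | Path) -> DiagnosticPanel:
    doc = json.loads(Path(path).read_text())
    markers = [
        DiagnosticMarker(
            marker_id=m["marker_id"],
            locus_id=m["locus_id"],
            tag_id=m["tag_id"],
            allele_A=m["allele_A"],
            allele_B=m["allele_B"],
            placement=(
                (m["placement"]["chrom"], int(m["placement"]["start"]))
                if m.get("placement")
                else None
            ),
        )
        for m in doc.get("markers", [])
    ]
    provenance = [
        (p["stage"], int(p["n_in"]), int(p["n_out"]))
        for p in doc.get("provenance", [])
    ]
    return DiagnosticPanel(markers=markers, provenance=provenance)


# ---------------------------------------------------------------------------
# specimen panel genotypes (rows = specimens, columns = markers)
# ---------------------------------------------------------------------------


def write_specimens_csv(
    specimens: Sequence[SpecimenPanelGenotype], path: str | Path
) -> None:
    if not specimens:
        raise ValueError("no specimens to write")
    markers = list(specimens[0].genotypes)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["specimen_id"] + markers)
        for sp in specimens:
            if list(sp.genotypes) != markers:
                raise ValueError(
                    f"specimen {sp.specimen_id} marker set differs from header"
                )
            w.writerow([sp.specimen_id] + [sp.genotypes[m] for m in markers])


def read_specimens_csv(path: str | Path) -> list[SpecimenPanelGenotype]:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][:1] != ["specimen_id"]:
        raise ValueError(f"{path}: expected header starting with 'specimen_id'")
    markers = rows[0][1:]
    if len(set(markers)) != len(markers):
        raise ValueError(f"{path}: duplicate marker columns")
    out = []
    for row in rows[1:]:
        sid, cells = row[0], row[1:]
        out.append(
            SpecimenPanelGenotype(sid, dict(zip(markers, cells, strict=True)))
        )
    return out
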