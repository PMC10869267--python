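"""Parental-allele classification of alignments on a diploid hybrid genome.

Reads competitively mapped to a diploid genome land on one haplotype
contig (``<chrom>_<strain>``); reads that map equally well to both
haplotypes receive a low aligner MAPQ and are filtered out, which is the
mechanism by which variant-free reads become unassigned.  The mapped
haplotype plus the cross orientation (which strain was the mother)
determines the parental origin.  Variant-strain coordinates are then
projected back onto the reference through the strain LiftMap so that all
downstream tracks share one coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

from .genome import split_diploid_contig_name
from .liftover import LiftMap
from .variants import VariantKind, VariantSet

__all__ = [
    "CrossOrientation",
    "FilterConfig",
    "AllelicAlignment",
    "Rejected",
    "classify_alignment",
    "project_to_reference",
    "classify_and_project",
    "pileup_allelic_counts",
]

MATERNAL = "maternal"
PATERNAL = "paternal"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CrossOrientation:
    """Which inbred strain is the mother in this F1 cross.

    A B6 mother x JF1 father cross (the "BJ" orientation) is
    ``CrossOrientation("B6", "JF1")``; the reciprocal "JB" cross swaps
    the fields.
    """

    maternal_strain: str
    paternal_strain: str

    def __post_init__(self) -> None:
        if self.maternal_strain == self.paternal_strain:
            raise ValueError("maternal and paternal strains must differ")

    def parent_of(self, strain: str) -> str:
        if strain == self.maternal_strain:
            return MATERNAL
        if strain == self.paternal_strain:
            return PATERNAL
        raise ValueError(
            f"strain {strain!r} is neither {self.maternal_strain!r} nor "
            f"{self.paternal_strain!r}"
        )

    def strain_of(self, parent: str) -> str:
        if parent == MATERNAL:
            return self.maternal_strain
        if parent == PATERNAL:
            return self.paternal_strain
        raise ValueError(f"unknown parent {parent!r}")

    def swapped(self) -> "CrossOrientation":
        return CrossOrientation(self.paternal_strain, self.maternal_strain)


@dataclass(frozen=True)
class FilterConfig:
    """Alignment filters applied before allelic assignment.

    Defaults follow standard hybrid RNA/ChIP filtering (proper pairs at
    MAPQ >= 20); 4C-seq uses ``mapq_min=10`` without the pair filter.
    """

    mapq_min: int = 20
    require_proper_pair: bool = True
    drop_duplicates: bool = False

    def __post_init__(self) -> None:
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")


@dataclass(frozen=True)
class Rejected:
    """A record that failed alignment filters, with the reason."""

    read_id: str
    reason: str


@dataclass
class AllelicAlignment:
    """An alignment with haplotype and parental-origin annotation.

    ``chrom`` is the reference chromosome name (haplotype suffix
    stripped); ``start``/``end`` are haplotype-local until
    :func:`project_to_reference` replaces them with the reference
    projection (``projected`` flips to True).
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    haplotype: str
    parent: str
    flags: set[str] = field(default_factory=set)
    projected: bool = False
    source: pysam.AlignedSegment | None = None


def classify_alignment(
    record: pysam.AlignedSegment,
    cross: CrossOrientation,
    cfg: FilterConfig = FilterConfig(),
) -> AllelicAlignment | Rejected:
    """Assign a diploid-genome alignment to a parental allele.

    The haplotype is read from the mapped contig name suffix; an
    unrecognised suffix is a hard error (genome/alignment mismatch).
    Records failing the MAPQ, proper-pair or duplicate filters come back
    as :class:`Rejected` with a reason.  Aligner-reported MAPQ is
    trusted, not recomputed.
    """
    if record.is_unmapped:
        return Rejected(record.query_name, "unmapped")
    chrom, strain = split_diploid_contig_name(record.reference_name)
    if strain not in (cross.maternal_strain, cross.paternal_strain):
        raise ValueError(
            f"contig {record.reference_name!r}: haplotype suffix {strain!r} "
            f"matches neither strain of the cross"
        )
    if cfg.require_proper_pair and not record.is_proper_pair:
        return Rejected(record.query_name, "not_proper_pair")
    if cfg.drop_duplicates and record.is_duplicate:
        return Rejected(record.query_name, "duplicate")
    if record.mapping_quality < cfg.mapq_min:
        return Rejected(record.query_name, "low_mapq")
    return AllelicAlignment(
        read_id=record.query_name,
        chrom=chrom,
        start=record.reference_start,
        end=record.reference_end,
        strand="-" if record.is_reverse else "+",
        mapq=record.mapping_quality,
        haplotype=strain,
        parent=cross.parent_of(strain),
        source=record,
    )


def project_to_reference(
    aln: AllelicAlignment, liftmaps: Mapping[str, LiftMap]
) -> AllelicAlignment:
    """Replace haplotype-local coordinates by their reference projection.

    ``liftmaps`` maps strain name -> LiftMap; the reference strain's map
    is the identity, so its alignments pass through unchanged apart from
    the ``projected`` flag.
    """
    lm = liftmaps[aln.haplotype]
    start, end, flags = lm.lift_interval(aln.chrom, aln.start, aln.end)
    return replace(
        aln, start=start, end=end, flags=aln.flags | flags, projected=True
    )


def classify_and_project(
    records: Iterable[pysam.AlignedSegment],
    cross: CrossOrientation,
    liftmaps: Mapping[str, LiftMap],
    cfg: FilterConfig = FilterConfig(),
) -> Iterator[AllelicAlignment | Rejected]:
    """Stream classification + reference projection over a SAM/BAM."""
    for rec in records:
        res = classify_alignment(rec, cross, cfg)
        if isinstance(res, AllelicAlignment):
            res = project_to_reference(res, liftmaps)
        yield res


def _base_at(record: pysam.AlignedSegment, contig_pos: int,
             min_base_quality: int) -> str | None:
    """Read base (and quality gate) at a contig position, or None."""
    seq = record.query_sequence
    if seq is None:
        return None
    quals = record.query_qualities
    for qpos, rpos in record.get_aligned_pairs(matches_only=True):
        if rpos == contig_pos:
            if quals is not None and quals[qpos] < min_base_quality:
                return None
            return seq[qpos].upper()
    return None


def pileup_allelic_counts(
    alignments: Iterable[AllelicAlignment],
    snps: VariantSet,
    cross: CrossOrientation,
    variant_strain: str,
    liftmaps: Mapping[str, LiftMap],
    min_base_quality: int = 13,
) -> pd.DataFrame:
    """Per-SNP allelic read counts and maternal fraction.

    For every strain SNP, counts reads whose base at the SNP matches the
    maternal-strain or paternal-strain allele (``other_count`` collects
    mismatches to both).  The maternal fraction is m/(m+p), reported as
    NaN when no allelic read covers the SNP.  Alignments must carry their
    source records and be reference-projected.
    """
    snp_records = [v for v in snps if v.kind is VariantKind.SNP]
    by_chrom: dict[str, tuple[np.ndarray, list[int]]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for i, v in enumerate(snp_records):
        tmp.setdefault(v.chrom, []).append((v.ref_start0, i))
    for chrom, pairs in tmp.items():
        pairs.sort()
        by_chrom[chrom] = (
            np.array([p for p, _ in pairs], dtype=np.int64),
            [i for _, i in pairs],
        )
    m_cnt = np.zeros(len(snp_records), dtype=np.int64)
    p_cnt = np.zeros(len(snp_records), dtype=np.int64)
    o_cnt = np.zeros(len(snp_records), dtype=np.int64)
    # The variant strain carries the ALT allele; the other strain the REF.
    alt_parent = cross.parent_of(variant_strain)
    for aln in alignments:
        if aln.source is None:
            raise ValueError("pileup requires AllelicAlignment.source records")
        if not aln.projected:
            raise ValueError("pileup requires reference-projected alignments")
        if aln.chrom not in by_chrom:
            continue
        lm = liftmaps[aln.haplotype]
        positions, indices = by_chrom[aln.chrom]
        lo = int(np.searchsorted(positions, aln.start, side="left"))
        hi = int(np.searchsorted(positions, aln.end, side="left"))
        for j in range(lo, hi):
            i = indices[j]
            v = snp_records[i]
            contig_pos = lm.ref_to_pseudo(aln.chrom, int(positions[j]))
            if contig_pos is None:
                continue
            base = _base_at(aln.source, contig_pos, min_base_quality)
            if base is None:
                continue
            if base == (v.alt_allele if alt_parent == MATERNAL else v.ref_allele):
                m_cnt[i] += 1
            elif base == (v.alt_allele if alt_parent == PATERNAL else v.ref_allele):
                p_cnt[i] += 1
            else:
                o_cnt[i] += 1
    counts = pd.DataFrame(
        {
            "chrom": [v.chrom for v in snp_records],
            "pos": [v.ref_start0 for v in snp_records],
            "ref_allele": [v.ref_allele for v in snp_records],
            "alt_allele": [v.alt_allele for v in snp_records],
            "maternal_count": m_cnt,
            "paternal_count": p_cnt,
            "other_count": o_cnt,
        }
    )
    total = counts["maternal_count"] + counts["paternal_count"]
    counts["maternal_fraction"] = counts["maternal_count"] / total.where(total > 0)
    return counts
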