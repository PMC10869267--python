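"""Strain-variant handling: primitive SNP/insertion/deletion records.

Variants describe how one inbred strain (e.g. JF1) differs from the
reference strain (e.g. C57BL/6) and are consumed from a VCF that has been
normalised and decomposed into allelic primitives upstream.  All records
are treated as fixed homozygous strain differences (F1 inbred-cross
assumption); genotype fields are ignored.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam

__all__ = [
    "VariantKind",
    "Variant",
    "VariantSet",
    "LoadReport",
    "VcfFormatError",
    "load_variants",
]


class VcfFormatError(ValueError):
    """Raised for a VCF data line that cannot be interpreted."""


class VariantKind(str, enum.Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True)
class Variant:
    """One primitive strain difference anchored on the reference.

    ``pos`` follows the VCF convention (1-based position of the first
    ``ref_allele`` base).  Insertions and deletions are left-anchored:
    ``ref_allele`` and ``alt_allele`` share their first base.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    kind: VariantKind

    @property
    def ref_start0(self) -> int:
        """0-based start of the reference footprint."""
        return self.pos - 1

    @property
    def ref_end0(self) -> int:
        """0-based half-open end of the reference footprint."""
        return self.pos - 1 + len(self.ref_allele)

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    def sort_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def classify_alleles(ref: str, alt: str) -> VariantKind | None:
    """Classify a (ref, alt) pair as a primitive variant, or None.

    Primitives are: single-base substitutions; left-anchored insertions
    (ref is one base and a prefix of alt); left-anchored deletions (alt is
    one base and a prefix of ref).  MNPs and complex records are not
    primitive.
    """
    if not ref or not alt or ref == alt:
        return None
    if len(ref) == 1 and len(alt) == 1:
        return VariantKind.SNP
    if len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
        return VariantKind.INS
    if len(alt) == 1 and len(ref) > 1 and ref[0] == alt:
        return VariantKind.DEL
    return None


@dataclass
class LoadReport:
    """Bookkeeping for a :func:`load_variants` call."""

    n_input_records: int = 0
    n_loaded: int = 0
    n_split_multiallelic: int = 0
    n_dropped_nonprimitive: int = 0
    n_dropped_overlap: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_nonprimitive + self.n_dropped_overlap

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k in (
                "n_input_records",
                "n_loaded",
                "n_split_multiallelic",
                "n_dropped_nonprimitive",
                "n_dropped_overlap",
            ):
                fh.write(f"{k}\t{getattr(self, k)}\n")


@dataclass
class VariantSet:
    """Sorted, primitive, non-overlapping strain variants.

    Invariants (enforced by :meth:`from_records`): records sorted by
    (chrom, pos); reference footprints never overlap; every record is a
    primitive SNP/INS/DEL.
    """

    records: list[Variant] = field(default_factory=list)

    @classmethod
    def from_records(
        cls,
        records: Iterable[Variant],
        report: LoadReport | None = None,
    ) -> "VariantSet":
        """Sort and de-overlap records (first-wins), validating primitivity."""
        out: list[Variant] = []
        last_end: dict[str, int] = {}
        for v in sorted(records, key=Variant.sort_key):
            if classify_alleles(v.ref_allele, v.alt_allele) != v.kind:
                if report is not None:
                    report.n_dropped_nonprimitive += 1
                continue
            if v.ref_start0 < last_end.get(v.chrom, 0):
                if report is not None:
                    report.n_dropped_overlap += 1
                continue
            last_end[v.chrom] = v.ref_end0
            out.append(v)
        if report is not None:
            report.n_loaded = len(out)
        return cls(out)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.records)

    def by_chrom(self, chrom: str) -> list[Variant]:
        return [v for v in self.records if v.chrom == chrom]

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.records:
            seen.setdefault(v.chrom, None)
        return list(seen)

    def snps(self) -> "VariantSet":
        return VariantSet([v for v in self.records if v.kind is VariantKind.SNP])

    def indels(self) -> "VariantSet":
        return VariantSet([v for v in self.records if v.kind is not VariantKind.SNP])

    def total_inserted(self) -> int:
        return sum(v.length_change for v in self.records if v.kind is VariantKind.INS)

    def total_deleted(self) -> int:
        return sum(-v.length_change for v in self.records if v.kind is VariantKind.DEL)


def _prescan_vcf(path: Path) -> None:
    """Cheap structural validation so parse failures carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VcfFormatError(
                    f"{path}:{lineno}: VCF data line has {len(fields)} fields, expected >= 8"
                )
            try:
                int(fields[1])
            except ValueError:
                raise VcfFormatError(
                    f"{path}:{lineno}: POS field {fields[1]!r} is not an integer"
                ) from None


def load_variants(
    vcf_path: str | Path,
    reference: Mapping[str, str] | None = None,
) -> tuple[VariantSet, LoadReport]:
    """Load strain variants from a VCF into a validated :class:`VariantSet`.

    Multi-allelic records are split into one candidate per ALT allele.
    Non-primitive candidates (MNPs, complex substitutions) and candidates
    whose reference footprint overlaps an earlier record are dropped and
    counted in the returned :class:`LoadReport` (first record wins).

    Parameters
    ----------
    vcf_path:
        Plain-text or bgzipped VCF 4.x; records may be unsorted.
    reference:
        Optional chrom -> sequence mapping; when given, a record on a
        chromosome absent from the reference is a hard error.
    """
    vcf_path = Path(vcf_path)
    _prescan_vcf(vcf_path)
    report = LoadReport()
    candidates: list[Variant] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            report.n_input_records += 1
            if reference is not None and rec.chrom not in reference:
                raise ValueError(
                    f"VCF record {rec.chrom}:{rec.pos} on a chromosome absent "
                    f"from the reference"
                )
            alts = rec.alts or ()
            if len(alts) > 1:
                report.n_split_multiallelic += 1
            for alt in alts:
                if alt is None or alt.startswith("<"):
                    report.n_dropped_nonprimitive += 1
                    continue
                ref_allele = rec.ref.upper()
                alt_allele = alt.upper()
                kind = classify_alleles(ref_allele, alt_allele)
                if kind is None:
                    report.n_dropped_nonprimitive += 1
                    continue
                candidates.append(
                    Variant(rec.chrom, rec.pos, ref_allele, alt_allele, kind)
                )
    vs = VariantSet.from_records(candidates, report)
    return vs, report
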