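"""Alignment-target genome construction for F1 hybrid sequencing.

From a reference genome and a set of strain variants this module builds
the three alignment targets used for hybrid samples:

* an N-masked reference (SNP positions replaced by ``N``, indels left
  untouched) for allele-blind mapping without strain bias;
* a strain pseudogenome (SNPs and indels applied) together with the
  :class:`~hybridome.liftover.LiftMap` that projects pseudogenome
  coordinates back onto the reference;
* a diploid hybrid genome holding both haplotypes of every chromosome as
  separate contigs (``<chrom>_<strainA>`` / ``<chrom>_<strainB>``) for
  competitive allele-specific mapping.

Sequences are plain Python strings in chrom -> sequence mappings; FASTA
I/O lives in :mod:`hybridome.io`.
"""

from __future__ import annotations

from typing import Mapping

from .liftover import INSERTED, MATCH, Block, LiftMap
from .variants import VariantKind, VariantSet

__all__ = [
    "ReferenceMismatchError",
    "mask_reference",
    "build_pseudogenome",
    "build_diploid_genome",
    "diploid_contig_name",
    "split_diploid_contig_name",
]

_UNAMBIGUOUS = set("ACGT")


class ReferenceMismatchError(ValueError):
    """A variant's ref allele does not match the reference sequence."""


def _check_ref_allele(ref: Mapping[str, str], v) -> None:
    seq = ref[v.chrom]
    observed = seq[v.ref_start0 : v.ref_end0].upper()
    if observed != v.ref_allele:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos}: variant ref allele {v.ref_allele!r} does not "
            f"match reference {observed!r}"
        )
    if v.kind is VariantKind.SNP and observed not in _UNAMBIGUOUS:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos}: SNP placed on ambiguity code {observed!r}"
        )


def mask_reference(ref: Mapping[str, str], variants: VariantSet) -> dict[str, str]:
    """Mask strain SNP positions with ``N``; indels are left untouched.

    Output sequences have exactly the input lengths; a ref-allele
    mismatch at any SNP is a hard error naming chrom:pos.
    """
    out = {c: list(s) for c, s in ref.items()}
    for v in variants:
        if v.kind is not VariantKind.SNP:
            continue
        if v.chrom not in out:
            raise KeyError(f"variant chromosome {v.chrom!r} absent from reference")
        _check_ref_allele(ref, v)
        out[v.chrom][v.ref_start0] = "N"
    return {c: "".join(s) for c, s in out.items()}


def build_pseudogenome(
    ref: Mapping[str, str], variants: VariantSet
) -> tuple[dict[str, str], LiftMap]:
    """Apply SNPs and indels to the reference, producing the strain
    pseudogenome and its lift map back to reference coordinates.

    With an empty variant set this returns the reference verbatim with an
    identity LiftMap.
    """
    pseudo: dict[str, str] = {}
    blocks: dict[str, list[Block]] = {}
    for chrom, refseq in ref.items():
        chrom_vars = variants.by_chrom(chrom)
        for v in chrom_vars:
            if v.ref_end0 > len(refseq):
                raise ReferenceMismatchError(
                    f"{chrom}:{v.pos}: variant footprint exceeds chromosome length"
                )
            _check_ref_allele(ref, v)
        # SNP substitutions do not move coordinates; apply them first.
        seq = list(refseq)
        for v in chrom_vars:
            if v.kind is VariantKind.SNP:
                seq[v.ref_start0] = v.alt_allele
        parts: list[str] = []
        blist: list[Block] = []
        r = 0  # reference cursor
        p = 0  # pseudogenome cursor

        def emit_match(ref_end: int) -> None:
            nonlocal r, p
            if ref_end > r:
                n = ref_end - r
                blist.append(Block(p, p + n, r, ref_end, MATCH))
                parts.append("".join(seq[r:ref_end]))
                r = ref_end
                p += n

        for v in chrom_vars:
            if v.kind is VariantKind.INS:
                emit_match(v.ref_start0 + 1)  # include the anchor base
                ins = v.alt_allele[1:]
                blist.append(Block(p, p + len(ins), r - 1, r - 1, INSERTED))
                parts.append(ins)
                p += len(ins)
            elif v.kind is VariantKind.DEL:
                emit_match(v.ref_start0 + 1)
                r += len(v.ref_allele) - 1  # skip deleted reference bases
        emit_match(len(refseq))
        if not blist and refseq:
            blist.append(Block(0, len(refseq), 0, len(refseq), MATCH))
            parts.append("".join(seq))
        pseudo[chrom] = "".join(parts)
        blocks[chrom] = _merge_match_blocks(blist)
    return pseudo, LiftMap(blocks)


def _merge_match_blocks(blist: list[Block]) -> list[Block]:
    """Fuse MATCH blocks that are contiguous in both coordinate systems."""
    out: list[Block] = []
    for b in blist:
        if (
            out
            and out[-1].kind == MATCH
            and b.kind == MATCH
            and out[-1].pseudo_end == b.pseudo_start
            and out[-1].ref_end == b.ref_start
        ):
            prev = out.pop()
            b = Block(prev.pseudo_start, b.pseudo_end, prev.ref_start, b.ref_end, MATCH)
        out.append(b)
    return out


def diploid_contig_name(chrom: str, strain: str) -> str:
    return f"{chrom}_{strain}"


def split_diploid_contig_name(contig: str) -> tuple[str, str]:
    """Split ``<chrom>_<strain>`` into (chrom, strain suffix)."""
    chrom, _, strain = contig.rpartition("_")
    if not chrom:
        raise ValueError(f"contig {contig!r} carries no haplotype suffix")
    return chrom, strain


def build_diploid_genome(
    ref: Mapping[str, str],
    pseudo: Mapping[str, str],
    strain_a: str,
    strain_b: str,
) -> dict[str, str]:
    """Interleave reference and pseudogenome haplotypes into one genome.

    For each chromosome the output holds ``<chrom>_<strainA>`` (the
    reference haplotype) followed by ``<chrom>_<strainB>`` (the strain
    haplotype), in reference chromosome order.
    """
    if strain_a == strain_b:
        raise ValueError("the two strain names must differ")
    if set(ref) != set(pseudo):
        raise ValueError(
            f"chromosome sets differ: reference {sorted(ref)} vs "
            f"pseudogenome {sorted(pseudo)}"
        )
    if not ref:
        raise ValueError("empty chromosome set")
    out: dict[str, str] = {}
    for chrom in ref:
        out[diploid_contig_name(chrom, strain_a)] = ref[chrom]
        out[diploid_contig_name(chrom, strain_b)] = pseudo[chrom]
    return out
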