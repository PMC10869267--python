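"""Synthetic data with known ground truth for every pipeline stage.

Emulates the inputs of an F1 reciprocal-cross imprinting experiment: a
random reference genome, strain SNP/indel divergence at mouse-like
density (one SNP per 150 bp, one short indel per 1,500 bp, the
approximate JF1-vs-B6 divergence), allelic paired-end sequencing reads
with per-gene parental expression fractions, and 4C-seq read pairs drawn
from a distance-decay contact model with injectable allele-specific
loops (biallelic contacts by default, parentally biased at loop
anchors).

Reads are emitted as already-aligned SAM so the test suite never needs
an external aligner: a read from a variant-free region would map equally
well to both haplotypes of the diploid genome, which the generator
encodes as MAPQ 0 (the ambiguous-mapping surrogate); variant-overlapping
reads get MAPQ 42.  FASTQ emission is provided for users who want to run
a real aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .allelic import CrossOrientation
from .fourc import (
    MATERNAL,
    PATERNAL,
    FragendTable,
    FragmentMap,
    MateAlignment,
    ViewpointSpec,
    digest_genome,
    revcomp,
)
from .genome import build_pseudogenome, diploid_contig_name
from .io import write_simple_vcf
from .liftover import LiftMap
from .variants import Variant, VariantKind, VariantSet

__all__ = [
    "SimulationConfig",
    "GeneModel",
    "LoopSpec",
    "FourCModel",
    "simulate_reference",
    "simulate_strain_variants",
    "simulate_allelic_reads",
    "AllelicReadSim",
    "simulate_4c_counts",
    "simulate_4c_experiment",
    "FourCSim",
    "table_from_counts",
    "snap_to_fragend",
    "make_viewpoint",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Global simulation parameters.

    Rates are per base: ``snp_rate`` 1/150 and ``indel_rate`` 1/1500
    with indels up to 6 bp mimic the SNP/indel density of a JF1 x B6
    comparison.  The same seed always reproduces byte-identical outputs.
    """

    seed: int = 0
    contigs: Mapping[str, int] = field(default_factory=lambda: {"chrS": 100_000})
    snp_rate: float = 1 / 150
    indel_rate: float = 1 / 1500
    max_indel: int = 6
    read_length: int = 100
    fragment_size: int = 250
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.snp_rate, self.indel_rate, self.error_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class GeneModel:
    """A transcribed interval with a programmed parental expression bias."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    maternal_fraction: float = 0.5
    n_fragments: int = 500


@dataclass(frozen=True)
class LoopSpec:
    """An allele-specific contact enrichment spanning consecutive fragends.

    ``anchor`` must sit exactly on a fragend (use :func:`snap_to_fragend`
    first); the multiplier applies to ``n_fragends`` fragends starting at
    the anchor.
    """

    anchor: int
    n_fragends: int = 8
    maternal_mult: float = 1.0
    paternal_mult: float = 1.0

    def mult(self, allele: str) -> float:
        return self.maternal_mult if allele == MATERNAL else self.paternal_mult


@dataclass(frozen=True)
class FourCModel:
    """Distance-decay contact model for one 4C viewpoint.

    Contact probability for a fragend at distance d from the bait is
    proportional to ``max(d, min_dist) ** -alpha`` times any loop
    multiplier for the allele; ``alpha = 1`` is a realistic near-bait
    decay exponent.
    """

    chrom: str
    bait_pos: int
    alpha: float = 1.0
    loops: tuple[LoopSpec, ...] = ()
    reads_per_allele: int = 5000
    n_replicates: int = 2
    min_dist: int = 1000


# ---------------------------------------------------------------------------
# Reference and variants
# ---------------------------------------------------------------------------


def simulate_reference(cfg: SimulationConfig) -> dict[str, str]:
    """Uniform-random ACGT contigs, deterministic under the seed."""
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, str] = {}
    for chrom, length in cfg.contigs.items():
        if length < 1000:
            raise ValueError(f"contig {chrom!r}: length must be >= 1 kb")
        out[chrom] = "".join(_BASES[rng.integers(0, 4, size=length)])
    return out


def simulate_strain_variants(
    ref: Mapping[str, str],
    cfg: SimulationConfig,
    vcf_path: str | Path | None = None,
) -> VariantSet:
    """Draw SNPs and short indels at the configured per-base rates.

    Variants are non-overlapping by construction (events whose footprint
    would collide with the previous one are skipped).  When ``vcf_path``
    is given the set is also written as a site-only VCF that round-trips
    losslessly through :func:`hybridome.variants.load_variants`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    total_rate = cfg.snp_rate + cfg.indel_rate
    records: list[Variant] = []
    for chrom, seq in ref.items():
        length = len(seq)
        if total_rate <= 0:
            continue
        hits = np.nonzero(rng.random(length) < total_rate)[0]
        last_end = 0  # 0-based exclusive end of the previous footprint
        for i in hits.tolist():
            # leave room for an indel anchor and stay clear of the ends
            if i < 1 or i >= length - cfg.max_indel - 1 or i < last_end:
                continue
            pos = i + 1  # VCF 1-based
            ref_base = seq[i]
            if rng.random() < cfg.snp_rate / total_rate:
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                records.append(Variant(chrom, pos, ref_base, alt, VariantKind.SNP))
                last_end = i + 1
            else:
                size = int(rng.integers(1, cfg.max_indel + 1))
                if rng.random() < 0.5:
                    ins = "".join(_BASES[rng.integers(0, 4, size=size)])
                    records.append(
                        Variant(chrom, pos, ref_base, ref_base + ins, VariantKind.INS)
                    )
                    last_end = i + 1
                else:
                    ref_allele = seq[i : i + size + 1]
                    records.append(
                        Variant(chrom, pos, ref_allele, ref_base, VariantKind.DEL)
                    )
                    last_end = i + size + 1
    vs = VariantSet.from_records(records)
    if vcf_path is not None:
        write_simple_vcf(vs, {c: len(s) for c, s in ref.items()}, vcf_path)
    return vs


# ---------------------------------------------------------------------------
# Allelic paired-end reads
# ---------------------------------------------------------------------------


@dataclass
class AllelicReadSim:
    """Simulated allelic reads plus their ground truth."""

    sam_path: Path
    truth: pd.DataFrame  # one row per read (two per fragment)


def _variant_footprints(variants: VariantSet, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    vs = variants.by_chrom(chrom)
    starts = np.array([v.ref_start0 for v in vs], dtype=np.int64)
    ends = np.array([v.ref_end0 for v in vs], dtype=np.int64)
    return starts, ends


def _overlaps_variant(starts: np.ndarray, ends: np.ndarray, lo: int, hi: int) -> bool:
    if len(starts) == 0:
        return False
    i = int(np.searchsorted(ends, lo, side="right"))
    return i < len(starts) and starts[i] < hi


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    for i in np.nonzero(rng.random(len(arr)) < error_rate)[0]:
        arr[i] = str(rng.choice([b for b in "ACGT" if b != arr[i]]))
    return "".join(arr)


def simulate_allelic_reads(
    ref: Mapping[str, str],
    variants: VariantSet,
    genes: Sequence[GeneModel],
    cross: CrossOrientation,
    variant_strain: str,
    cfg: SimulationConfig,
    sam_path: str | Path,
) -> AllelicReadSim:
    """Simulate paired RNA-seq-style fragments with programmed allelic bias.

    Fragments are drawn uniformly inside each gene; the parental allele
    is Bernoulli(maternal_fraction).  Reads are written as proper-pair
    alignments on the diploid genome under the fr-firststrand
    convention; the truth table records every read's haplotype, parent,
    gene and reference position.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    pseudo, liftmap = build_pseudogenome(ref, variants)
    ref_strain = (
        cross.maternal_strain
        if cross.paternal_strain == variant_strain
        else cross.paternal_strain
    )
    if variant_strain not in (cross.maternal_strain, cross.paternal_strain):
        raise ValueError("variant_strain must be one strain of the cross")
    haplo = {ref_strain: ref, variant_strain: pseudo}
    identity = LiftMap.identity({c: len(s) for c, s in ref.items()})
    lifts = {ref_strain: identity, variant_strain: liftmap}
    L = cfg.read_length
    fsize = max(cfg.fragment_size, L)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": diploid_contig_name(c, strain), "LN": len(haplo[strain][c])}
            for c in ref
            for strain in (ref_strain, variant_strain)
        ],
    }
    foot = {c: _variant_footprints(variants, c) for c in ref}
    rows = []
    sam_path = Path(sam_path)
    with pysam.AlignmentFile(str(sam_path), "wh", header=dict(header)) as out:
        tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for gene in genes:
            if gene.chrom not in ref or gene.end > len(ref[gene.chrom]):
                raise ValueError(f"gene {gene.name!r} outside contig bounds")
            if gene.end - gene.start <= fsize:
                raise ValueError(f"gene {gene.name!r} shorter than the fragment size")
            starts_fp, ends_fp = foot[gene.chrom]
            for i in range(gene.n_fragments):
                parent = (
                    MATERNAL
                    if rng.random() < gene.maternal_fraction
                    else PATERNAL
                )
                strain = cross.strain_of(parent)
                rstart = int(rng.integers(gene.start, gene.end - fsize))
                hstart = lifts[strain].ref_to_pseudo(gene.chrom, rstart)
                while hstart is None:  # fragment starts in strain-deleted sequence
                    rstart += 1
                    hstart = lifts[strain].ref_to_pseudo(gene.chrom, rstart)
                hseq = haplo[strain][gene.chrom]
                hend = min(hstart + fsize, len(hseq))
                mapq = (
                    42
                    if _overlaps_variant(starts_fp, ends_fp, rstart, rstart + fsize)
                    else 0
                )
                contig = diploid_contig_name(gene.chrom, strain)
                rid = f"{gene.name}_f{i:06d}"
                # fr-firststrand: on a + gene, read1 is the reverse mate.
                plus_gene = gene.strand == "+"
                r1_start, r1_rev = (hend - L, True) if plus_gene else (hstart, False)
                r2_start, r2_rev = (hstart, False) if plus_gene else (hend - L, True)
                for mate, (mstart, mrev) in (
                    (1, (r1_start, r1_rev)),
                    (2, (r2_start, r2_rev)),
                ):
                    a = pysam.AlignedSegment()
                    a.query_name = rid
                    a.query_sequence = _mutate(
                        hseq[mstart : mstart + L], rng, cfg.error_rate
                    )
                    a.query_qualities = pysam.qualitystring_to_array("I" * L)
                    a.reference_id = tid[contig]
                    a.reference_start = mstart
                    a.mapping_quality = mapq
                    a.cigarstring = f"{L}M"
                    a.flag = (
                        0x1  # paired
                        | 0x2  # proper pair
                        | (0x10 if mrev else 0)
                        | (0x20 if not mrev else 0)
                        | (0x40 if mate == 1 else 0x80)
                    )
                    a.next_reference_id = tid[contig]
                    a.next_reference_start = r2_start if mate == 1 else r1_start
                    out.write(a)
                    rows.append(
                        (rid, mate, gene.name, strain, parent, gene.chrom, rstart, mstart)
                    )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "mate",
            "gene",
            "strain",
            "parent",
            "chrom",
            "ref_start",
            "hap_start",
        ],
    )
    return AllelicReadSim(sam_path, truth)


# ---------------------------------------------------------------------------
# 4C-seq
# ---------------------------------------------------------------------------


def snap_to_fragend(fragmap: FragmentMap, chrom: str, pos: int) -> int:
    """Nearest fragend position to ``pos``."""
    fe = fragmap.fragends[chrom]
    i = int(np.argmin(np.abs(fe - pos)))
    return int(fe[i])


def make_viewpoint(
    ref: Mapping[str, str],
    variants: VariantSet,
    chrom: str,
    bait_pos: int,
    cross: CrossOrientation,
    variant_strain: str,
    read_length: int = 100,
    trim5: int = 10,
    trim3: int = 0,
) -> ViewpointSpec:
    """Build a viewpoint spec around the strain SNP nearest the bait.

    The variant strain carries the ALT base at the SNP; the cross
    orientation turns ref/alt into maternal/paternal bases.
    """
    snps = [v for v in variants.by_chrom(chrom) if v.kind is VariantKind.SNP]
    if not snps:
        raise ValueError(f"no SNP on {chrom!r} to type the viewpoint allele")
    snp = min(snps, key=lambda v: abs(v.ref_start0 - bait_pos))
    snp_pos = snp.ref_start0
    usable = read_length - trim5
    start = max(0, snp_pos - usable // 3)
    end = min(len(ref[chrom]), start + usable)
    alt_parent = cross.parent_of(variant_strain)
    mat_base = snp.alt_allele if alt_parent == MATERNAL else snp.ref_allele
    pat_base = snp.alt_allele if alt_parent == PATERNAL else snp.ref_allele
    return ViewpointSpec(
        chrom=chrom,
        start=start,
        end=end,
        snp_pos=snp_pos,
        snp_maternal=mat_base,
        snp_paternal=pat_base,
        trim5=trim5,
        trim3=trim3,
    )


def _eligible_fragends(
    fragmap: FragmentMap, model: FourCModel, margin: int
) -> np.ndarray:
    fe = fragmap.fragends[model.chrom]
    clen = fragmap.chrom_length(model.chrom)
    ok = (fe >= margin) & (fe <= clen - margin)
    li, ri = fragmap.containing_fragment(model.chrom, model.bait_pos)
    ok[[li, ri]] = False  # self-ligation / undigested products
    return np.nonzero(ok)[0]


def _contact_weights(
    fragmap: FragmentMap, model: FourCModel, allele: str, eligible: np.ndarray
) -> np.ndarray:
    fe = fragmap.fragends[model.chrom]
    dist = np.maximum(np.abs(fe[eligible] - model.bait_pos), model.min_dist)
    w = dist.astype(float) ** -model.alpha
    fe_index = fragmap.fragend_index(model.chrom)
    for loop in model.loops:
        if loop.anchor not in fe_index:
            raise ValueError(
                f"loop anchor {loop.anchor} is not on a fragend of {model.chrom!r}"
            )
        i0 = fe_index[loop.anchor]
        in_loop = (eligible >= i0) & (eligible < i0 + loop.n_fragends)
        w[in_loop] *= loop.mult(allele)
    return w / w.sum()


def simulate_4c_counts(
    fragmap: FragmentMap,
    model: FourCModel,
    seed: int,
    margin: int = 200,
) -> dict[tuple[str, str], np.ndarray]:
    """Draw per-fragend contact counts only (no read synthesis).

    Returns ``(allele, replicate) -> counts`` arrays parallel to the
    chromosome's fragend array.  Fast path for statistical calibration.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    fe = fragmap.fragends[model.chrom]
    eligible = _eligible_fragends(fragmap, model, margin)
    out: dict[tuple[str, str], np.ndarray] = {}
    for allele in (MATERNAL, PATERNAL):
        probs = _contact_weights(fragmap, model, allele, eligible)
        for r in range(model.n_replicates):
            counts = np.zeros(len(fe), dtype=np.int64)
            counts[eligible] = rng.multinomial(model.reads_per_allele, probs)
            out[(allele, f"rep{r + 1}")] = counts
    return out


def table_from_counts(
    fragmap: FragmentMap,
    chrom: str,
    counts: Mapping[tuple[str, str], np.ndarray],
) -> FragendTable:
    """Wrap simulated per-fragend count arrays into a FragendTable."""
    table = FragendTable(fragmap)
    for key, arr in counts.items():
        table.get(*key)[chrom][:] = arr
    return table


@dataclass
class FourCSim:
    """Simulated 4C library: read pairs, truth and pre-aligned mates."""

    pairs: dict[str, list[tuple[str, str, str]]]  # replicate -> (id, R1, R2)
    mate_alignments: list[MateAlignment]
    truth: pd.DataFrame
    counts: dict[tuple[str, str], np.ndarray]
    viewpoint: ViewpointSpec

    def write_fastq(self, out_dir: str | Path, prefix: str = "fourc") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rep, pairs in self.pairs.items():
            for mate in (1, 2):
                path = out_dir / f"{prefix}_{rep}_R{mate}.fastq"
                with open(path, "w") as fh:
                    for rid, r1, r2 in pairs:
                        seq = r1 if mate == 1 else r2
                        fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_4c_experiment(
    ref: Mapping[str, str],
    variants: VariantSet,
    model: FourCModel,
    cross: CrossOrientation,
    variant_strain: str,
    cfg: SimulationConfig,
    viewpoint: ViewpointSpec | None = None,
) -> FourCSim:
    """Synthesize a full allelic 4C library from the contact model.

    R1 is the viewpoint mate (``trim5`` primer bases, then viewpoint
    sequence carrying the allele's base at the viewpoint SNP); R2 is the
    interacting mate (``trim5`` primer bases, the contacted fragend
    sequence read off the + or − strand, then ``trim3`` trailing bases).
    After trimming, the interacting sequence starts exactly at the drawn
    fragend.  Truth records one row per pair: allele, replicate, fragend
    and strand.
    """
    fragmap = digest_genome(ref)
    chrom = model.chrom
    seq = ref[chrom].upper()
    if viewpoint is None:
        viewpoint = make_viewpoint(
            ref, variants, chrom, model.bait_pos, cross, variant_strain,
            read_length=cfg.read_length,
        )
    vp = viewpoint
    L = cfg.read_length
    key_len = L - vp.trim5 - vp.trim3
    if key_len < 20:
        raise ValueError("read length minus trims leaves < 20 usable bases")
    counts = simulate_4c_counts(fragmap, model, cfg.seed, margin=key_len + 1)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    fe = fragmap.fragends[chrom]
    snp_off = vp.snp_pos - vp.start
    vp_template = list(seq[vp.start : vp.start + (L - vp.trim5)])
    base_of = {MATERNAL: vp.snp_maternal.upper(), PATERNAL: vp.snp_paternal.upper()}
    pairs: dict[str, list[tuple[str, str, str]]] = {}
    alns: list[MateAlignment] = []
    rows = []
    for (allele, rep), arr in sorted(counts.items()):
        plist = pairs.setdefault(rep, [])
        vp_read_body = vp_template.copy()
        vp_read_body[snp_off] = base_of[allele]
        vp_body = "".join(vp_read_body)
        for i in np.nonzero(arr)[0].tolist():
            pos = int(fe[i])
            for _ in range(int(arr[i])):
                junk5 = "".join(_BASES[rng.integers(0, 4, size=vp.trim5)])
                r1 = _mutate(junk5 + vp_body, rng, cfg.error_rate)
                can_plus = i < len(fe) - 1 and pos + key_len <= len(seq)
                can_minus = i > 0 and pos - key_len >= 0
                plus = can_plus and (not can_minus or rng.random() < 0.5)
                if plus:
                    segment = seq[pos : pos + key_len]
                    start, end, strand = pos, pos + key_len, "+"
                else:
                    segment = revcomp(seq[pos - key_len : pos])
                    start, end, strand = pos - key_len, pos, "-"
                junk5b = "".join(_BASES[rng.integers(0, 4, size=vp.trim5)])
                junk3 = "".join(_BASES[rng.integers(0, 4, size=vp.trim3)])
                r2 = _mutate(junk5b + segment + junk3, rng, cfg.error_rate)
                rid = f"4c_{allele[0]}_{rep}_{len(plist):07d}"
                plist.append((rid, r1, r2))
                alns.append(
                    MateAlignment(rid, chrom, start, end, strand, allele, rep, 42)
                )
                rows.append((rid, allele, rep, pos, strand))
    truth = pd.DataFrame(
        rows, columns=["read_id", "allele", "replicate", "fragend", "strand"]
    )
    return FourCSim(pairs, alns, truth, counts, vp)
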