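"""FASTA / bedGraph / VCF serialization helpers."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bedgraph",
    "write_simple_vcf",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) multi-record FASTA into an ordered chrom -> sequence dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bedgraph(
    values: Mapping[str, np.ndarray],
    bin_size: int,
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
    precision: int = 5,
) -> None:
    """Write per-bin values as 4-column bedGraph (0-based half-open).

    Runs of adjacent equal-value bins are merged into one line; the last
    bin of a chromosome is truncated to the chromosome end when
    ``chrom_lengths`` is given.
    """
    with open(path, "w") as fh:
        for chrom, arr in values.items():
            arr = np.asarray(arr, dtype=float)
            n = len(arr)
            clen = chrom_lengths.get(chrom) if chrom_lengths else None
            i = 0
            while i < n:
                j = i + 1
                while j < n and arr[j] == arr[i]:
                    j += 1
                start = i * bin_size
                end = j * bin_size
                if clen is not None:
                    end = min(end, clen)
                fh.write(f"{chrom}\t{start}\t{end}\t{round(float(arr[i]), precision)}\n")
                i = j


def write_simple_vcf(
    variants: Iterable,
    contig_lengths: Mapping[str, int],
    path: str | Path,
    source: str = "hybridome-simulate",
) -> None:
    """Emit primitive strain variants as a minimal site-only VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\n"
            )
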