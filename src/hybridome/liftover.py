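"""Block-wise, indel-aware coordinate lifting between a strain
pseudogenome and the reference.

A :class:`LiftMap` is an ordered list of blocks per chromosome that tile
the pseudogenome with no gaps or overlaps.  MATCH blocks map a
pseudogenome interval onto an equal-length reference interval (SNPs do
not break blocks); INSERTED blocks cover strain-specific inserted
sequence and carry a single reference anchor — the last reference base at
or left of the insertion (-1 at a contig start).  Deleted reference
sequence appears as a gap between the reference images of consecutive
MATCH blocks.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = ["Block", "LiftMap", "LiftError"]

MATCH = "MATCH"
INSERTED = "INSERTED"

#: Flags attached to lifted intervals.
FLAG_TOUCHES_INSERTION = "touches_insertion"
FLAG_SPANS_DELETION = "spans_deletion"
FLAG_INSERTION_ONLY = "insertion_only"


class LiftError(ValueError):
    """Raised for out-of-bounds queries or malformed block lists."""


@dataclass(frozen=True)
class Block:
    """One lift block.  For INSERTED blocks ``ref_start == ref_end`` holds
    the anchor position (see module docstring)."""

    pseudo_start: int
    pseudo_end: int
    ref_start: int
    ref_end: int
    kind: str

    @property
    def anchor(self) -> int:
        if self.kind != INSERTED:
            raise ValueError("anchor is defined for INSERTED blocks only")
        return self.ref_start


def _validate_blocks(chrom: str, blocks: list[Block]) -> None:
    prev_pseudo_end = 0
    prev_ref_end: int | None = None
    for b in blocks:
        if b.pseudo_start != prev_pseudo_end:
            raise LiftError(
                f"{chrom}: blocks do not tile the pseudogenome at {b.pseudo_start}"
            )
        if b.pseudo_end <= b.pseudo_start:
            raise LiftError(f"{chrom}: empty or inverted block at {b.pseudo_start}")
        if b.kind == MATCH:
            if (b.ref_end - b.ref_start) != (b.pseudo_end - b.pseudo_start):
                raise LiftError(f"{chrom}: MATCH block length mismatch at {b.pseudo_start}")
            if prev_ref_end is not None and b.ref_start < prev_ref_end:
                raise LiftError(f"{chrom}: reference mapping not increasing at {b.pseudo_start}")
            prev_ref_end = b.ref_end
        elif b.kind == INSERTED:
            if b.ref_start != b.ref_end:
                raise LiftError(f"{chrom}: INSERTED block must carry a point anchor")
        else:
            raise LiftError(f"{chrom}: unknown block kind {b.kind!r}")
        prev_pseudo_end = b.pseudo_end


@dataclass
class LiftMap:
    """Per-chromosome block lists mapping pseudogenome -> reference."""

    blocks: dict[str, list[Block]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, blist in self.blocks.items():
            _validate_blocks(chrom, blist)

    # -- constructors -------------------------------------------------

    @classmethod
    def identity(cls, lengths: Mapping[str, int]) -> "LiftMap":
        """Identity map (reference strain): one MATCH block per chromosome."""
        return cls(
            {c: [Block(0, n, 0, n, MATCH)] for c, n in lengths.items() if n > 0}
        )

    # -- basic queries ------------------------------------------------

    def chroms(self) -> list[str]:
        return list(self.blocks)

    def pseudo_length(self, chrom: str) -> int:
        return self.blocks[chrom][-1].pseudo_end

    def _blocks_overlapping(self, chrom: str, start: int, end: int) -> list[Block]:
        blist = self.blocks[chrom]
        starts = [b.pseudo_start for b in blist]
        i = bisect.bisect_right(starts, start) - 1
        out = []
        while i < len(blist) and blist[i].pseudo_start < end:
            if blist[i].pseudo_end > start:
                out.append(blist[i])
            i += 1
        return out

    # -- lifting ------------------------------------------------------

    def lift_interval(
        self, chrom: str, start: int, end: int
    ) -> tuple[int, int, set[str]]:
        """Project a pseudogenome interval onto the reference.

        Returns the smallest reference half-open interval covering the
        images of all MATCH bases in the query, plus a flag set.  A query
        wholly inside inserted sequence returns the zero-length interval
        at the insertion anchor, flagged ``insertion_only``.
        """
        if chrom not in self.blocks:
            raise LiftError(f"unknown chromosome {chrom!r}")
        n = self.pseudo_length(chrom)
        if not (0 <= start < end <= n):
            raise LiftError(f"{chrom}:[{start},{end}) outside pseudogenome [0,{n})")
        flags: set[str] = set()
        images: list[tuple[int, int]] = []
        for b in self._blocks_overlapping(chrom, start, end):
            if b.kind == INSERTED:
                flags.add(FLAG_TOUCHES_INSERTION)
                continue
            lo = max(start, b.pseudo_start)
            hi = min(end, b.pseudo_end)
            images.append((b.ref_start + (lo - b.pseudo_start),
                           b.ref_start + (hi - b.pseudo_start)))
        if not images:
            flags.discard(FLAG_TOUCHES_INSERTION)
            flags.add(FLAG_INSERTION_ONLY)
            anchor = self._blocks_overlapping(chrom, start, end)[0].anchor
            return anchor, anchor, flags
        for (_, e1), (s2, _) in zip(images, images[1:]):
            if s2 > e1:
                flags.add(FLAG_SPANS_DELETION)
        return images[0][0], images[-1][1], flags

    def ref_to_pseudo(self, chrom: str, ref_pos: int) -> int | None:
        """Image of a reference position on the pseudogenome.

        Returns None when the position falls in strain-deleted sequence.
        """
        if chrom not in self.blocks:
            raise LiftError(f"unknown chromosome {chrom!r}")
        for b in self.blocks[chrom]:
            if b.kind == MATCH and b.ref_start <= ref_pos < b.ref_end:
                return b.pseudo_start + (ref_pos - b.ref_start)
        return None

    # -- serialization ------------------------------------------------

    HEADER = "chrom\tpseudo_start\tpseudo_end\tref_start\tref_end\tkind"

    def write(self, path: str | Path) -> None:
        """Write a chain-like tab-separated block file."""
        with open(path, "w") as fh:
            fh.write(self.HEADER + "\n")
            for chrom, blist in self.blocks.items():
                for b in blist:
                    fh.write(
                        f"{chrom}\t{b.pseudo_start}\t{b.pseudo_end}\t"
                        f"{b.ref_start}\t{b.ref_end}\t{b.kind}\n"
                    )

    @classmethod
    def read(cls, path: str | Path) -> "LiftMap":
        blocks: dict[str, list[Block]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if header != cls.HEADER:
                raise LiftError(f"{path}: unexpected liftmap header {header!r}")
            for line in fh:
                chrom, ps, pe, rs, re_, kind = line.rstrip("\n").split("\t")
                blocks.setdefault(chrom, []).append(
                    Block(int(ps), int(pe), int(rs), int(re_), kind)
                )
        return cls(blocks)
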