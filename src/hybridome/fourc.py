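"""Allelic 4C-seq interactome analysis.

Circular chromosome conformation capture (4C) measures every genomic
contact of one chosen "viewpoint" (bait) restriction fragment.  In an F1
hybrid, a SNP inside the viewpoint tells which parental allele each
ligation product came from, so the two parental interactomes can be read
out separately from one library.

The pipeline implemented here:

1. in-silico digestion of the genome at the enzyme site (DpnII, GATC),
   giving the fragment grid and its fragment ends ("fragends");
2. demultiplexing of read pairs by the viewpoint-SNP base into maternal
   and paternal pools;
3. exact fragend counting — a valid 4C product maps with its 5' end
   precisely at a fragment boundary, everything else is discarded;
4. rpm normalization (reads per million informative reads per allele)
   with centered running-mean smoothing over k fragends, plus
   maternal/paternal log2 ratio tracks;
5. near-bait interaction-domain calling against a fitted distance-decay
   background (one-sided Poisson, BH-corrected);
6. paired maternal-vs-paternal differential testing per window of k
   consecutive fragends with a method-of-moments beta-binomial model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FragmentMap",
    "ViewpointSpec",
    "TaggedMate",
    "DemuxReport",
    "MateAlignment",
    "FragendTable",
    "RpmTracks",
    "Window",
    "DomainCalls",
    "InteractionCallSet",
    "digest_genome",
    "demultiplex_viewpoint_pairs",
    "align_mates_to_fragends",
    "count_fragends",
    "fragend_rpm_smooth",
    "interaction_ratio_track",
    "nearbait_windows",
    "call_interaction_domains",
    "differential_allelic_interactions",
    "analyze_nearbait",
    "benjamini_hochberg",
]

MATERNAL = "maternal"
PATERNAL = "paternal"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# In-silico digestion
# ---------------------------------------------------------------------------


@dataclass
class FragmentMap:
    """Restriction-fragment grid: per-chromosome fragments and fragends.

    Fragments are 0-based half-open and tile each chromosome; every
    internal boundary is the start of an enzyme-site occurrence.  The
    fragend array holds the sorted unique boundary positions
    (``fragments + 1`` entries per chromosome); an internal fragend is
    simultaneously the right end of one fragment and the left end of the
    next.
    """

    site: str
    fragends: dict[str, np.ndarray] = field(default_factory=dict)

    def fragments(self, chrom: str) -> list[tuple[int, int]]:
        fe = self.fragends[chrom]
        return list(zip(fe[:-1].tolist(), fe[1:].tolist()))

    def n_fragments(self, chrom: str) -> int:
        return len(self.fragends[chrom]) - 1

    def chrom_length(self, chrom: str) -> int:
        return int(self.fragends[chrom][-1])

    def fragend_index(self, chrom: str) -> dict[int, int]:
        return {int(p): i for i, p in enumerate(self.fragends[chrom])}

    def containing_fragment(self, chrom: str, pos: int) -> tuple[int, int]:
        """Indices (into the fragend array) of the fragment containing pos."""
        fe = self.fragends[chrom]
        i = int(np.searchsorted(fe, pos, side="right")) - 1
        i = min(max(i, 0), len(fe) - 2)
        return i, i + 1


def digest_genome(genome: Mapping[str, str], site: str = "GATC") -> FragmentMap:
    """Cut every chromosome immediately before each enzyme-site occurrence.

    A chromosome without the site yields a single fragment spanning it.
    """
    if not site or set(site.upper()) - set("ACGT"):
        raise ValueError(f"enzyme site {site!r} must be non-empty uppercase ACGT")
    site = site.upper()
    fragends: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        s = seq.upper()
        cuts = [0]
        i = s.find(site)
        while i != -1:
            if i > 0:
                cuts.append(i)
            i = s.find(site, i + 1)
        cuts.append(len(s))
        fragends[chrom] = np.unique(np.asarray(cuts, dtype=np.int64))
    return FragmentMap(site=site, fragends=fragends)


# ---------------------------------------------------------------------------
# Viewpoint demultiplexing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViewpointSpec:
    """The bait: its reference interval, allele-diagnostic SNP and trims.

    ``snp_maternal`` / ``snp_paternal`` are the bases carried by the
    maternal and paternal strains at ``snp_pos`` (0-based, inside the
    viewpoint interval).  ``trim5`` (default 10) strips primer bases from
    the 5' end of both mates; ``trim3`` (viewpoint-specific) strips the
    3' end of the interacting mate.  ``mapq_min`` (default 10) is the
    alignment-quality floor for the interacting mates.
    """

    chrom: str
    start: int
    end: int
    snp_pos: int
    snp_maternal: str
    snp_paternal: str
    trim5: int = 10
    trim3: int = 0
    mapq_min: int = 10
    min_identity: float = 0.9

    def __post_init__(self) -> None:
        if not (self.start <= self.snp_pos < self.end):
            raise ValueError("viewpoint SNP must lie inside the viewpoint interval")
        if self.snp_maternal.upper() == self.snp_paternal.upper():
            raise ValueError(
                "viewpoint SNP bases are identical for the two strains "
                "(uninformative viewpoint)"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "ViewpointSpec":
        """Parse a small ``key=value`` viewpoint config file."""
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                kv[key.strip()] = val.strip().strip('"')
        ints = {"start", "end", "snp_pos", "trim5", "trim3", "mapq_min"}
        kwargs = {
            k: (int(v) if k in ints else v)
            for k, v in kv.items()
            if k in cls.__dataclass_fields__
        }
        return cls(**kwargs)


@dataclass
class TaggedMate:
    """An interacting-mate sequence tagged with its viewpoint allele."""

    read_id: str
    allele: str
    sequence: str
    replicate: str = "rep1"


@dataclass
class DemuxReport:
    n_pairs: int = 0
    n_maternal: int = 0
    n_paternal: int = 0
    n_viewpoint_unmapped: int = 0
    n_uninformative_base: int = 0

    @property
    def n_informative(self) -> int:
        return self.n_maternal + self.n_paternal


def demultiplex_viewpoint_pairs(
    pairs: Iterable[tuple[str, str, str]],
    vp: ViewpointSpec,
    reference: Mapping[str, str],
    replicate: str = "rep1",
) -> tuple[list[TaggedMate], DemuxReport]:
    """Split read pairs into maternal/paternal pools via the viewpoint SNP.

    ``pairs`` yields ``(read_id, viewpoint_mate_seq, interacting_mate_seq)``.
    The viewpoint mate's mapping position is fixed by the bait primer, so
    after removing ``trim5`` primer bases it is compared ungapped against
    the reference at the viewpoint; pairs below ``min_identity`` (the
    stand-in for an alignment missing the viewpoint coordinates or a low
    MAPQ) are discarded.  The base at the viewpoint SNP assigns the
    allele; an N or third allele discards the pair.  Interacting mates
    are emitted trimmed (``trim5`` off the 5' end, ``trim3`` off the 3').
    """
    ref_seq = reference[vp.chrom]
    snp_off = vp.snp_pos - vp.start
    mat = vp.snp_maternal.upper()
    pat = vp.snp_paternal.upper()
    out: list[TaggedMate] = []
    report = DemuxReport()
    for read_id, vp_seq, mate_seq in pairs:
        report.n_pairs += 1
        probe = vp_seq[vp.trim5 :].upper()
        if snp_off >= len(probe):
            report.n_viewpoint_unmapped += 1
            continue
        target = ref_seq[vp.start : vp.start + len(probe)].upper()
        mism = sum(
            1
            for i, (a, b) in enumerate(zip(probe, target))
            if i != snp_off and a != b
        )
        if len(target) == 0 or 1 - mism / len(target) < vp.min_identity:
            report.n_viewpoint_unmapped += 1
            continue
        base = probe[snp_off]
        if base == mat:
            report.n_maternal += 1
            allele = MATERNAL
        elif base == pat:
            report.n_paternal += 1
            allele = PATERNAL
        else:
            report.n_uninformative_base += 1
            continue
        trimmed = (
            mate_seq[vp.trim5 : len(mate_seq) - vp.trim3]
            if vp.trim3 > 0
            else mate_seq[vp.trim5 :]
        )
        out.append(TaggedMate(read_id, allele, trimmed, replicate))
    return out, report


# ---------------------------------------------------------------------------
# Fragend counting
# ---------------------------------------------------------------------------


@dataclass
class MateAlignment:
    """A mapped interacting mate in reference coordinates."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    allele: str
    replicate: str = "rep1"
    mapq: int = 60


def align_mates_to_fragends(
    mates: Iterable[TaggedMate],
    fragmap: FragmentMap,
    genome: Mapping[str, str],
) -> tuple[list[MateAlignment], int]:
    """Place trimmed interacting mates by exact match at fragment ends.

    Valid 4C ligation products begin at a restriction cut site, so each
    mate either matches the forward sequence starting at a left fragend
    or the reverse complement ending at a right fragend.  Sequences
    matching no fragend (or more than one, which would earn MAPQ 0 from
    an aligner) are dropped; the second return value counts the drops.
    """
    mates = list(mates)
    if not mates:
        return [], 0
    key_len = min(len(m.sequence) for m in mates)
    lookup: dict[str, tuple[str, int, str] | None] = {}
    for chrom, fe in fragmap.fragends.items():
        seq = genome[chrom].upper()
        for pos in fe[:-1].tolist():  # left fragends, + orientation
            if pos + key_len <= len(seq):
                k = seq[pos : pos + key_len]
                lookup[k] = None if k in lookup else (chrom, pos, "+")
        for pos in fe[1:].tolist():  # right fragends, - orientation
            if pos - key_len >= 0:
                k = revcomp(seq[pos - key_len : pos])
                lookup[k] = None if k in lookup else (chrom, pos, "-")
    out: list[MateAlignment] = []
    dropped = 0
    for m in mates:
        hit = lookup.get(m.sequence[:key_len].upper())
        if hit is None:
            dropped += 1
            continue
        chrom, pos, strand = hit
        if strand == "+":
            start, end = pos, pos + key_len
        else:
            start, end = pos - key_len, pos
        out.append(
            MateAlignment(m.read_id, chrom, start, end, strand, m.allele, m.replicate)
        )
    return out, dropped


@dataclass
class FragendTable:
    """Per-(fragend, allele, replicate) read counts on the fragend grid.

    ``counts[(allele, replicate)][chrom]`` is an integer array parallel
    to ``fragmap.fragends[chrom]``.  Totals are sums of counts per
    allele per replicate (the rpm denominators).
    """

    fragmap: FragmentMap
    counts: dict[tuple[str, str], dict[str, np.ndarray]] = field(default_factory=dict)
    n_dropped: int = 0

    def alleles(self) -> list[str]:
        return sorted({a for a, _ in self.counts})

    def replicates(self) -> list[str]:
        return sorted({r for _, r in self.counts})

    def _zeros(self) -> dict[str, np.ndarray]:
        return {
            c: np.zeros(len(fe), dtype=np.int64)
            for c, fe in self.fragmap.fragends.items()
        }

    def get(self, allele: str, replicate: str) -> dict[str, np.ndarray]:
        key = (allele, replicate)
        if key not in self.counts:
            self.counts[key] = self._zeros()
        return self.counts[key]

    def total(self, allele: str, replicate: str) -> int:
        return int(sum(int(a.sum()) for a in self.get(allele, replicate).values()))

    def summed(self, allele: str, chrom: str) -> np.ndarray:
        """Counts summed over replicates for one allele on one chromosome."""
        arrs = [
            arrs[chrom]
            for (a, _), arrs in self.counts.items()
            if a == allele and chrom in arrs
        ]
        if not arrs:
            return np.zeros(len(self.fragmap.fragends[chrom]), dtype=np.int64)
        return np.sum(arrs, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (allele, rep), per_chrom in sorted(self.counts.items()):
            for chrom, arr in per_chrom.items():
                fe = self.fragmap.fragends[chrom]
                nz = np.nonzero(arr)[0]
                for i in nz:
                    rows.append((chrom, int(fe[i]), allele, rep, int(arr[i])))
        return pd.DataFrame(
            rows, columns=["chrom", "fragend", "allele", "replicate", "count"]
        )


def count_fragends(
    alignments: Iterable[MateAlignment],
    fragmap: FragmentMap,
    mapq_min: int = 0,
) -> FragendTable:
    """Count alignments mapped exactly to a fragment end.

    A + strand alignment is counted at fragend f iff its start equals a
    fragment's left boundary; a − strand alignment iff its end equals a
    fragment's right boundary.  Everything else is dropped and tallied in
    ``n_dropped``.
    """
    table = FragendTable(fragmap)
    left_idx: dict[str, dict[int, int]] = {}
    right_idx: dict[str, dict[int, int]] = {}
    for chrom, fe in fragmap.fragends.items():
        idx = {int(p): i for i, p in enumerate(fe)}
        left_idx[chrom] = {p: i for p, i in idx.items() if i < len(fe) - 1}
        right_idx[chrom] = {p: i for p, i in idx.items() if i > 0}
    for aln in alignments:
        if aln.mapq < mapq_min or aln.chrom not in fragmap.fragends:
            table.n_dropped += 1
            continue
        if aln.strand == "+":
            i = left_idx[aln.chrom].get(aln.start)
        else:
            i = right_idx[aln.chrom].get(aln.end)
        if i is None:
            table.n_dropped += 1
            continue
        table.get(aln.allele, aln.replicate)[aln.chrom][i] += 1
    return table


# ---------------------------------------------------------------------------
# rpm tracks
# ---------------------------------------------------------------------------


def running_mean(values: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean over k points with shrunken edge windows."""
    if k <= 1:
        return values.astype(float)
    n = len(values)
    out = np.empty(n, dtype=float)
    lo_off = (k - 1) // 2
    hi_off = k // 2 + 1
    csum = np.concatenate([[0.0], np.cumsum(values, dtype=float)])
    for i in range(n):
        lo = max(0, i - lo_off)
        hi = min(n, i + hi_off)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


@dataclass
class RpmTracks:
    """Per-allele rpm tracks on the fragend grid of one chromosome."""

    chrom: str
    positions: np.ndarray
    rpm: dict[tuple[str, str], np.ndarray]
    smoothed: dict[tuple[str, str], np.ndarray]
    mean_smoothed: dict[str, np.ndarray]


def fragend_rpm_smooth(
    table: FragendTable, chrom: str, k: int = 8, combined_denominator: bool = False
) -> RpmTracks:
    """rpm-normalize fragend counts and smooth over k fragends.

    rpm(fragend, allele, replicate) = count * 1e6 / total where the
    total is that allele+replicate's informative (on-grid) reads, so the
    maternal and paternal tracks compare interaction shapes rather than
    library depth.  ``combined_denominator=True`` instead divides both
    alleles of a replicate by their combined total.  An allele with zero
    total yields a NaN track with a warning.
    """
    positions = table.fragmap.fragends[chrom]
    rpm: dict[tuple[str, str], np.ndarray] = {}
    smoothed: dict[tuple[str, str], np.ndarray] = {}
    for (allele, rep), per_chrom in sorted(table.counts.items()):
        counts = per_chrom[chrom].astype(float)
        if combined_denominator:
            total = sum(table.total(a, rep) for a in table.alleles())
        else:
            total = table.total(allele, rep)
        if total == 0:
            warnings.warn(
                f"allele {allele!r} replicate {rep!r} has no informative reads",
                stacklevel=2,
            )
            track = np.full(len(counts), np.nan)
            rpm[(allele, rep)] = track
            smoothed[(allele, rep)] = track
            continue
        track = counts * 1e6 / total
        rpm[(allele, rep)] = track
        smoothed[(allele, rep)] = running_mean(track, k)
    with warnings.catch_warnings():
        # an absent allele yields an all-NaN column mean, already warned above
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_smoothed = {
            allele: np.nanmean(
                [s for (a, _), s in smoothed.items() if a == allele], axis=0
            )
            for allele in {a for a, _ in smoothed}
        }
    return RpmTracks(chrom, positions, rpm, smoothed, mean_smoothed)


def interaction_ratio_track(
    maternal: np.ndarray, paternal: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """log2((maternal + c) / (paternal + c)) on a shared fragend grid.

    The pseudocount (default 1 rpm-equivalent) makes the ratio 0 where
    both tracks are empty and bounds it where one allele is absent.
    Swapping the tracks negates the output exactly.
    """
    maternal = np.asarray(maternal, dtype=float)
    paternal = np.asarray(paternal, dtype=float)
    if maternal.shape != paternal.shape:
        raise ValueError("maternal and paternal tracks are not on the same grid")
    return np.log2((maternal + pseudocount) / (paternal + pseudocount))


# ---------------------------------------------------------------------------
# Near-bait windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """k consecutive fragends (indices into the chrom fragend array)."""

    start_idx: int
    end_idx: int  # exclusive
    start_pos: int
    end_pos: int
    distance: float  # |window midpoint - bait|, floored at 1 bp

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start_idx, self.end_idx)


def nearbait_windows(
    fragmap: FragmentMap,
    chrom: str,
    bait_pos: int,
    k: int = 8,
    region: int = 1_000_000,
    exclude_bait_fragends: bool = True,
    bait_exclusion: int = 5000,
) -> list[Window]:
    """Tile the near-bait fragends into non-overlapping windows of k.

    Fragends within ``bait_exclusion`` bp of the bait are masked: that
    zone is dominated by self-ligation, re-ligation and incomplete
    digestion products, and the contact decay there is too steep for a
    window-level background fit to represent.  The two fragends flanking
    the bait fragment are excluded regardless.  A trailing remainder of
    fewer than k fragends is dropped.
    """
    fe = fragmap.fragends[chrom]
    mask = (fe >= bait_pos - region) & (fe <= bait_pos + region)
    if bait_exclusion > 0:
        mask &= np.abs(fe - bait_pos) > bait_exclusion
    if exclude_bait_fragends:
        li, ri = fragmap.containing_fragment(chrom, bait_pos)
        mask[[li, ri]] = False
    idx = np.nonzero(mask)[0]
    windows: list[Window] = []
    for w0 in range(0, len(idx) - k + 1, k):
        block = idx[w0 : w0 + k]
        if block[-1] - block[0] != k - 1:
            # the excluded bait fragends split the tiling; realign here
            continue
        start_pos, end_pos = int(fe[block[0]]), int(fe[block[-1]])
        mid = (start_pos + end_pos) / 2
        windows.append(
            Window(
                int(block[0]),
                int(block[-1]) + 1,
                start_pos,
                end_pos,
                max(abs(mid - bait_pos), 1.0),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# Domain calling
# ---------------------------------------------------------------------------


@dataclass
class DomainCalls:
    """Per-window statistics and merged significant domains for one allele."""

    windows: pd.DataFrame
    domains: list[tuple[int, int]]


def call_interaction_domains(
    counts: np.ndarray,
    fragmap: FragmentMap,
    chrom: str,
    bait_pos: int,
    total: int | None = None,
    k: int = 8,
    region: int = 1_000_000,
    alpha: float = 0.05,
    windows: Sequence[Window] | None = None,
) -> DomainCalls:
    """Call near-bait interaction domains against a distance-decay fit.

    Windows of k fragends are scored against a least-squares fit of
    log(window rpm + 1) on log(distance to bait); windows whose observed
    count exceeds the fitted expectation under a one-sided Poisson test
    at BH-adjusted p < ``alpha`` are flagged, and adjacent flagged
    windows merge into domains (reported as (start, end) reference
    intervals).
    """
    if windows is None:
        windows = nearbait_windows(fragmap, chrom, bait_pos, k=k, region=region)
    if len(windows) * k < 3 * k:
        raise ValueError(
            f"only {len(windows)} windows of {k} fragends near the bait; "
            f">= 3 required"
        )
    counts = np.asarray(counts, dtype=float)
    if total is None:
        total = int(counts.sum())
    wcounts = np.array([counts[w.indices].sum() for w in windows])
    dist = np.array([w.distance for w in windows])
    if total <= 0:
        obs_rpm = np.zeros(len(windows))
    else:
        obs_rpm = wcounts * 1e6 / total
    y = np.log(obs_rpm + 1.0)
    x = np.log(dist)
    slope, intercept = np.polyfit(x, y, 1)
    exp_rpm = np.maximum(np.exp(intercept + slope * x) - 1.0, 0.0)
    mu = np.maximum(exp_rpm * total / 1e6, 1e-9)
    pvals = stats.poisson.sf(wcounts - 1, mu)
    padj = benjamini_hochberg(pvals)
    flagged = padj < alpha
    df = pd.DataFrame(
        {
            "start": [w.start_pos for w in windows],
            "end": [w.end_pos for w in windows],
            "count": wcounts.astype(int),
            "rpm": obs_rpm,
            "expected_rpm": exp_rpm,
            "pvalue": pvals,
            "padj": padj,
            "domain": flagged,
        }
    )
    domains: list[tuple[int, int]] = []
    for i, w in enumerate(windows):
        if not flagged[i]:
            continue
        if domains and windows[i - 1].end_idx == w.start_idx and flagged[i - 1]:
            domains[-1] = (domains[-1][0], w.end_pos)
        else:
            domains.append((w.start_pos, w.end_pos))
    return DomainCalls(df, domains)


# ---------------------------------------------------------------------------
# Differential maternal vs paternal testing
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p values; NaNs are passed through untested."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return out
    order = np.argsort(p[ok], kind="stable")
    ranked = p[ok][order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def _estimate_overdispersion(
    m: np.ndarray, n: np.ndarray
) -> float:
    """Pooled chi-square moment estimator of beta-binomial overdispersion.

    ``m``/``n`` are (windows x replicates) maternal counts and totals.
    Under binomial sampling the per-window chi-square statistic has k-1
    degrees of freedom; excess scatter across replicates is attributed to
    a common intra-class correlation rho, floored at 0.
    """
    s_tot = 0.0
    df_tot = 0.0
    scale_tot = 0.0
    for mi, ni in zip(m, n):
        use = ni > 0
        k = int(use.sum())
        if k < 2:
            continue
        mi, ni = mi[use], ni[use]
        pi = mi.sum() / ni.sum()
        if pi <= 0.0 or pi >= 1.0:
            continue
        s_tot += float(np.sum((mi - ni * pi) ** 2 / (ni * pi * (1 - pi))))
        df_tot += k - 1
        scale_tot += (k - 1) * (float(ni.mean()) - 1.0)
    if scale_tot <= 0:
        return 0.0
    return float(min(max((s_tot - df_tot) / scale_tot, 0.0), 0.99))


def _two_sided_p(x: int, n: int, pi0: float, rho: float) -> float:
    """Two-sided p by doubling the smaller exact tail (point included)."""
    if n == 0:
        return np.nan
    if rho < 1e-9:
        lo = stats.binom.cdf(x, n, pi0)
        hi = stats.binom.sf(x - 1, n, pi0)
    else:
        a = pi0 * (1 - rho) / rho
        b = (1 - pi0) * (1 - rho) / rho
        lo = stats.betabinom.cdf(x, n, a, b)
        hi = stats.betabinom.sf(x - 1, n, a, b)
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass
class InteractionCallSet:
    """Windowed near-bait statistics: counts, rpm, ratio, differential test.

    ``table`` columns: window coordinates, per-replicate maternal and
    paternal counts, smoothed rpm per allele, log2 maternal/paternal
    ratio, two-sided p, BH-adjusted p and the significance flag at
    ``alpha``; plus per-allele domain flags when domain calling ran.
    """

    table: pd.DataFrame
    pi0: float
    rho: float
    alpha: float = 0.05
    domains: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]


def differential_allelic_interactions(
    table: FragendTable,
    chrom: str,
    bait_pos: int,
    k: int = 8,
    region: int = 1_000_000,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    windows: Sequence[Window] | None = None,
) -> InteractionCallSet:
    """Paired maternal-vs-paternal test per window of k fragends.

    Per window the replicate count pairs (m_i, p_i) are tested against
    the library allele balance pi0 = sum(m)/sum(m+p) (over all windows)
    with a beta-binomial model whose overdispersion is estimated across
    replicates by the method of moments and floored at 0, where the test
    reduces to an exact binomial.  P values are two-sided and
    BH-corrected across windows; significance means adjusted p < alpha.
    Windows with zero total in all replicates get a missing p.
    """
    if windows is None:
        windows = nearbait_windows(table.fragmap, chrom, bait_pos, k=k, region=region)
    if not windows:
        raise ValueError("no near-bait windows")
    reps = table.replicates()
    if not reps:
        raise ValueError("fragend table holds no counts")
    W = len(windows)
    m = np.zeros((W, len(reps)), dtype=np.int64)
    p = np.zeros((W, len(reps)), dtype=np.int64)
    for j, rep in enumerate(reps):
        mat = table.get(MATERNAL, rep)[chrom]
        pat = table.get(PATERNAL, rep)[chrom]
        for i, w in enumerate(windows):
            m[i, j] = mat[w.indices].sum()
            p[i, j] = pat[w.indices].sum()
    n = m + p
    grand = n.sum()
    if grand == 0:
        raise ValueError("no maternal or paternal counts in the near-bait region")
    pi0 = float(m.sum() / grand)
    rho = _estimate_overdispersion(m, n)
    pvals = np.array(
        [
            _two_sided_p(int(m[i].sum()), int(n[i].sum()), pi0, rho)
            if n[i].sum() > 0
            else np.nan
            for i in range(W)
        ]
    )
    padj = benjamini_hochberg(pvals)
    tracks = fragend_rpm_smooth(table, chrom, k=k)
    mat_rpm = tracks.mean_smoothed.get(MATERNAL, np.zeros(len(tracks.positions)))
    pat_rpm = tracks.mean_smoothed.get(PATERNAL, np.zeros(len(tracks.positions)))
    w_mat = np.array([float(np.mean(mat_rpm[w.indices])) for w in windows])
    w_pat = np.array([float(np.mean(pat_rpm[w.indices])) for w in windows])
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": [w.start_pos for w in windows],
            "end": [w.end_pos for w in windows],
            "maternal_rpm": w_mat,
            "paternal_rpm": w_pat,
            "log2_ratio": interaction_ratio_track(w_mat, w_pat, pseudocount),
            "pvalue": pvals,
            "padj": padj,
        }
    )
    for j, rep in enumerate(reps):
        df[f"maternal_{rep}"] = m[:, j]
        df[f"paternal_{rep}"] = p[:, j]
    sig = pd.array(padj < alpha, dtype="boolean")
    sig[np.isnan(padj)] = pd.NA
    df["significant"] = sig
    return InteractionCallSet(df, pi0=pi0, rho=rho, alpha=alpha)


def analyze_nearbait(
    table: FragendTable,
    chrom: str,
    bait_pos: int,
    k: int = 8,
    region: int = 1_000_000,
    alpha: float = 0.05,
) -> InteractionCallSet:
    """Full near-bait analysis: differential test plus per-allele domains."""
    windows = nearbait_windows(table.fragmap, chrom, bait_pos, k=k, region=region)
    calls = differential_allelic_interactions(
        table, chrom, bait_pos, k=k, region=region, alpha=alpha, windows=windows
    )
    for allele in (MATERNAL, PATERNAL):
        counts = table.summed(allele, chrom)
        total = int(counts.sum())
        dc = call_interaction_domains(
            counts,
            table.fragmap,
            chrom,
            bait_pos,
            total=total,
            k=k,
            region=region,
            alpha=alpha,
            windows=windows,
        )
        calls.table[f"{allele}_domain"] = dc.windows["domain"].to_numpy()
        calls.domains[allele] = dc.domains
    return calls
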