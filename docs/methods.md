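# Methods

This note documents the models and procedures implemented in
`hybridome`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Genome construction and coordinate lifting

All internal coordinates are 0-based half-open; VCF positions are
converted on load and bedGraph/BED output stays 0-based. One convention,
stated once.

**Variant model.** Strain differences are consumed as primitive records:
single-base substitutions, left-anchored insertions (ref `A` → alt
`ATT`) and left-anchored deletions (ref `ACG` → alt `A`). MNPs and
complex records — which upstream normalization plus allelic-primitive
decomposition should already have removed — are dropped and counted in
the load report, as are records whose reference footprint overlaps an
earlier record (first record wins; deterministic and auditable beats
silent merging). All records are treated as fixed homozygous strain
differences: in an F1 inbred cross there are no heterozygous strain
variants, so genotype fields are ignored. A SNP placed on an IUPAC
ambiguity code is an error; ambiguity codes elsewhere pass through.

**Lift map.** The pseudogenome is described by blocks that tile it
exactly: MATCH blocks map equal-length intervals (SNPs do not break
blocks), INSERTED blocks cover strain-specific sequence and carry a
single anchor — the last reference base at or left of the insertion.
Deletions appear as gaps between the reference images of consecutive
MATCH blocks. Interval lifting returns the smallest reference interval
covering the images of all matched bases, with flags: `touches_insertion`,
`spans_deletion`, and `insertion_only` (the query lies wholly in inserted
sequence; the result is the zero-length interval at the anchor). This
covering-interval-plus-flags contract is a deliberate choice for reads
spanning indel edges: it never invents reference bases and downstream
consumers can filter on the flags.

Correctness is established two ways in the tests: an independent
per-base oracle that splices variants right-to-left and tracks every
base's origin, and the optimality check that the edit distance between
reference and pseudogenome (edlib) equals #SNPs + total indel bases.

## Allelic classification

Haplotype is taken from the mapped contig name (`<chrom>_<strain>`), the
diploid-genome route; no per-read SNP voting is implemented. MAPQ is
aligner-reported and trusted — on a diploid target, ambiguous (variant
free) reads receive MAPQ ≈ 0 from any modern aligner, which is the
mechanism that sends them to the unassigned pool. Default filters are
proper pairs at MAPQ ≥ 20 (RNA/ChIP-style); 4C uses MAPQ ≥ 10 without
the pair filter. Duplicate handling honors the SAM flag only.

The per-SNP pileup counts read bases matching the maternal- or
paternal-strain allele (the variant strain carries ALT); the maternal
fraction m/(m+p) is reported as missing where no allelic read covers
the SNP.

## Coverage tracks

`bamCoverage`-style semantics, stated explicitly because they are a
dialect: a read overlapping k bins counts once in each (not
fractionally); RPKM = count × 10⁹ / (bin_size × total_mapped) with the
nominal bin size used for the truncated final bin; optional extension
stretches reads to a fixed fragment length from their 5′ end. Strand
splitting follows fr-firststrand: the forward track holds fragments
transcribed from the + strand (read2 on +, read1 on −), each fragment
counted once via read1. Cut&Run spike-in scaling multiplies bins by
(reference constant / spike-in read count); the constant is a free
parameter with default 10⁴ — only ratios between samples matter.
Defaults: 20-bp bins (ChIP), 25-bp (Cut&Run), 200-bp extension for
single-end ChIP. bedGraph output run-length merges equal adjacent bins.

## Allelic 4C-seq

**Digestion.** The genome is cut immediately before every occurrence of
the enzyme site (DpnII, `GATC`); fragends are the fragment boundaries.

**Demultiplexing.** 4C viewpoint mates all start at the bait primer, so
their mapping position is fixed by the library design; the viewpoint
mate is compared ungapped against the reference at the viewpoint after
removing `trim5` primer bases (default 10), and pairs under 90%
identity are discarded as unmapped. The base at the viewpoint SNP
assigns the allele; `N` or a third allele discards the pair. Trim
semantics (the one genuinely open interface choice): `trim5` strips the
5′ end of both mates, `trim3` the 3′ end of the interacting mate; after
trimming, a valid interacting sequence begins exactly at a restriction
cut site. The FASTQ route therefore places interacting mates by exact
match against per-fragend sequences (forward at left fragends, reverse
complement at right fragends); aligned SAM input is accepted
equivalently.

**Counting and normalization.** A + alignment is counted iff its start
is a fragment's left boundary, a − alignment iff its end is a right
boundary; everything else is dropped and reported. rpm uses the
per-allele per-replicate informative total as denominator so maternal
and paternal tracks compare interaction *shapes*, not library depth (a
combined-denominator flag exists). Smoothing is a centered running mean
over k fragends with shrunken edge windows; k is shared with the window
size of the callers (k = 8) to keep one fewer free parameter. Ratio
tracks are log2((mat + c)/(pat + c)) with c = 1 rpm-equivalent, making
the ratio 0 where both tracks are empty and antisymmetric under label
swap.

**Near-bait windows.** Fragends within ±1 Mb of the bait are tiled into
non-overlapping windows of k = 8, excluding the two fragends flanking
the bait fragment and everything within 5 kb of the bait. The 5-kb
exclusion is the package's own calibration choice: that zone is
dominated by self-ligation, re-ligation and incomplete-digestion
products, and — more technically — per-fragend contact decay is so
convex there that a window-level power-law background systematically
under-predicts the nearest window (the window mean of 1/d exceeds 1/d
at the window midpoint), which otherwise produces recurrent false
domain calls immediately beside the bait.

**Domain calling.** Background = least-squares fit of log(window rpm+1)
on log(distance to bait); windows whose observed count exceeds the
fitted expectation under a one-sided Poisson test at BH-adjusted
p < 0.05 are flagged; adjacent flagged windows merge. This is a
deliberately simple, fully specified caller — not a reproduction of
adaptive-window methods like 4C-ker — chosen so that every number it
produces is auditable.

**Differential testing.** Per window, replicate pairs (mᵢ, pᵢ) are
tested against the library allele balance π₀ = Σm/Σ(m+p) (over all
windows) with a beta-binomial whose intra-class correlation ρ is
estimated by a pooled chi-square method of moments across replicates:
Σ_w Σ_i (mᵢ − nᵢπ̂_w)²/(nᵢπ̂_w(1−π̂_w)) has expectation Σ_w (k_w − 1)
under binomial sampling, and the excess is attributed to ρ via
(S − df)/Σ_w (k_w − 1)(n̄_w − 1), floored at 0 (where the test reduces
to an exact binomial) and capped at 0.99. With only two replicates —
the realistic design — a full hierarchical fit is unjustifiable; the
moment estimator borrows strength across windows instead. P values are
two-sided by doubling the smaller exact tail (point included), BH
corrected across windows; windows with zero total get a missing p and
do not consume multiple-testing budget.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of an F1 reciprocal-cross
experiment with exact ground truth: uniform-random contigs; SNPs at
1/150 bp and ≤6-bp indels at 1/1500 bp (mouse-strain-like divergence),
non-overlapping by construction; paired allelic reads with per-gene
maternal fractions, emitted as already-aligned proper pairs on the
diploid genome so no external aligner is needed — a read from a
variant-free region gets MAPQ 0 (the ambiguous-mapping surrogate),
variant-overlapping reads MAPQ 42; and 4C read pairs drawn per allele
with probability ∝ max(d, 1 kb)^(−α) (α = 1) times per-allele loop
multipliers over 8-fragend anchors, with the correct strain base at the
viewpoint SNP and interacting mates starting exactly at the drawn
fragend. Identical seeds give byte-identical outputs; sequencing errors
default to 0 for oracle tests.

Not emulated: realistic base-quality models, mapping errors other than
the MAPQ-0 surrogate, PCR duplicates and amplification jackpots in 4C
libraries, undigested/partially digested chromatin, structural variants,
and cross-contamination. Passing tests therefore demonstrate that the
*computational* machinery is exact and calibrated under its stated
model; they do not certify aligner behaviour or wet-lab artifact
handling on real libraries.

## Problem sizes and numerical choices

The validation experiments run at desk scale, chosen so the binomial /
Poisson concentration bounds in the assertions are meaningful while the
whole suite stays in seconds on one CPU: 25 seeded 10-kb genomes with
~1,000 probed positions each for liftover; 1,000–2,000 fragment
libraries for classification and ratio recovery (ratio recovery is
asserted within 3 binomial SE with the fragment as the binomial unit);
1,000-read instances for the fragend-counting oracle; a ~440-kb fragend
grid giving 200 windows × 2 replicates × 25 seeds for null FDR; a
200-kb grid with a 5× maternal-only loop 30 kb from the bait, at 5,000
informative reads per allele, for detection power (25 runs) and a
loop-free control (20 runs).

Degenerate inputs are handled explicitly: an allele with zero
informative reads yields a NaN rpm track with a warning; zero-count
windows get missing p values; a site-free chromosome digests to a
single fragment; an empty variant set produces an identity lift map.
Ties in BH are handled by the standard step-up minimum-accumulation;
Poisson means are floored at 10⁻⁹ to keep the one-sided test defined
for empty windows.

## Known limitations

* The domain caller's power-law background is a global two-parameter
  fit; strong genuine loops inflate it slightly and very non-uniform
  fragend density can bias it locally.
* The moment estimator of ρ is noisy with two replicates and floors at
  0 roughly half the time under the null, making the differential test
  mildly conservative (observed null significant fractions ≪ 0.05).
* Reads spanning indel edges are projected to the covering reference
  interval with flags; other conventions (clipping to matched bases)
  would shift coverage by a few bases at indel boundaries.
* The FASTQ-route mate placement requires exact sequence match at a
  fragend and is intended for noiseless or low-error data; with real
  error rates, use an external aligner and feed SAM.
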