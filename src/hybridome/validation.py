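"""Desk-scale validation experiments over the synthetic-data generator.

Each function runs one pipeline stage end-to-end on simulated inputs
with known ground truth and returns the measured quantities.  The test
suite asserts the expected behaviour on these measurements and the
reproduction script reports them; both call the same code so the
numbers always come from a fresh computation.

Problem sizes are desk-scale on purpose: 10-kb genomes for liftover
calibration, 2,000-fragment libraries for allelic-ratio recovery,
5,000 informative reads per allele for the 4C power and false-discovery
runs — large enough for the binomial/Poisson concentration bounds used
in the assertions, small enough to run in seconds on one CPU.
"""

from __future__ import annotations

import numpy as np
import pysam

from .allelic import (
    AllelicAlignment,
    CrossOrientation,
    FilterConfig,
    classify_and_project,
    pileup_allelic_counts,
)
from .coverage import CoverageConfig, binned_coverage, spike_in_factor
from .fourc import (
    MATERNAL,
    PATERNAL,
    MateAlignment,
    analyze_nearbait,
    call_interaction_domains,
    count_fragends,
    differential_allelic_interactions,
    digest_genome,
    fragend_rpm_smooth,
    nearbait_windows,
)
from .genome import build_pseudogenome
from .liftover import LiftMap
from .simulate import (
    FourCModel,
    GeneModel,
    LoopSpec,
    SimulationConfig,
    simulate_4c_counts,
    simulate_allelic_reads,
    simulate_reference,
    simulate_strain_variants,
    snap_to_fragend,
    table_from_counts,
)
from .variants import VariantKind

__all__ = [
    "liftover_roundtrip_experiment",
    "classification_experiment",
    "fragend_experiment",
    "ratio_recovery_experiment",
    "null_fdr_experiment",
    "loop_detection_experiment",
    "decay_control_experiment",
    "coverage_contract_experiment",
]

CROSS = CrossOrientation("B6", "JF1")
VARIANT_STRAIN = "JF1"


def _sub_seed(seed: int, stream: int, run: int = 0) -> int:
    return (seed * 10_000 + stream * 100 + run) % (2**31 - 1)


# ---------------------------------------------------------------------------


def liftover_roundtrip_experiment(
    seed: int, n_genomes: int = 25, length: int = 10_000, n_positions: int = 1000
) -> dict:
    """Ref -> pseudo -> ref round trip on seeded random genomes.

    Variants are drawn at one SNP per 150 bp and one indel per 1,500 bp.
    Every non-deleted reference position must map to the pseudogenome
    and lift back to itself exactly.
    """
    n_checked = n_exact = 0
    for g in range(n_genomes):
        cfg = SimulationConfig(seed=_sub_seed(seed, 1, g), contigs={"chrS": length})
        ref = simulate_reference(cfg)
        variants = simulate_strain_variants(ref, cfg)
        _, lm = build_pseudogenome(ref, variants)
        deleted = set()
        for v in variants:
            if v.kind is VariantKind.DEL:
                deleted.update(range(v.ref_start0 + 1, v.ref_end0))
        rng = np.random.default_rng(_sub_seed(seed, 2, g))
        for r in rng.integers(0, length, size=n_positions).tolist():
            if r in deleted:
                continue
            n_checked += 1
            p = lm.ref_to_pseudo("chrS", r)
            if p is None:
                continue
            start, end, _ = lm.lift_interval("chrS", p, p + 1)
            n_exact += (start, end) == (r, r + 1)
    return {
        "accuracy_pct": 100.0 * n_exact / n_checked,
        "n": n_checked,
    }


def _classify_sam(sam_path, cross, lifts, mapq_min=20):
    kept, rejected = [], []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for res in classify_and_project(
            fh, cross, lifts, FilterConfig(mapq_min=mapq_min)
        ):
            (kept if isinstance(res, AllelicAlignment) else rejected).append(res)
    return kept, rejected


def _allelic_sim(seed: int, maternal_fraction: float, n_fragments: int, tmp_dir):
    cfg = SimulationConfig(seed=seed, contigs={"chrS": 20_000})
    ref = simulate_reference(cfg)
    variants = simulate_strain_variants(ref, cfg)
    genes = [
        GeneModel(
            "g1", "chrS", 1_000, 19_000,
            maternal_fraction=maternal_fraction, n_fragments=n_fragments,
        )
    ]
    sam = tmp_dir / f"reads_{seed}_{maternal_fraction}.sam"
    sim = simulate_allelic_reads(
        ref, variants, genes, CROSS, VARIANT_STRAIN, cfg, sam
    )
    _, lm = build_pseudogenome(ref, variants)
    lifts = {
        VARIANT_STRAIN: lm,
        "B6": LiftMap.identity({"chrS": len(ref["chrS"])}),
    }
    return cfg, ref, variants, sim, sam, lifts


def classification_experiment(seed: int, tmp_dir, n_fragments: int = 1000) -> dict:
    """Noiseless allelic reads: haplotype recovery and label equivariance.

    Counts mis-assignments among variant-overlapping (MAPQ-passing)
    reads against the simulation truth, and verifies that swapping the
    cross orientation swaps every parental label.
    """
    _, _, _, sim, sam, lifts = _allelic_sim(
        _sub_seed(seed, 3), 0.5, n_fragments, tmp_dir
    )
    kept, rejected = _classify_sam(sam, CROSS, lifts)
    truth = sim.truth.drop_duplicates("read_id").set_index("read_id")
    mis = sum(
        aln.parent != truth.loc[aln.read_id, "parent"] for aln in kept
    )
    kept_sw, _ = _classify_sam(sam, CROSS.swapped(), lifts)
    swap = {"maternal": "paternal", "paternal": "maternal"}
    equivariant = len(kept) == len(kept_sw) and all(
        b.parent == swap[a.parent] for a, b in zip(kept, kept_sw)
    )
    low_mapq_only = all(r.reason == "low_mapq" for r in rejected)
    return {
        "n_assigned": len(kept),
        "misassigned": int(mis),
        "accuracy_pct": 100.0 * (len(kept) - mis) / len(kept),
        "equivariant": bool(equivariant and low_mapq_only),
    }


def fragend_experiment(seed: int, n_reads: int = 1000) -> dict:
    """Exact fragend counting vs a brute-force boundary scan.

    Half the reads start exactly on a fragment boundary, half are offset;
    the pipeline count table must agree entry-by-entry with an
    independent per-read scan, and per-allele rpm must sum to 1e6.
    """
    cfg = SimulationConfig(seed=_sub_seed(seed, 4), contigs={"chrS": 50_000})
    ref = simulate_reference(cfg)
    fm = digest_genome(ref)
    fe = fm.fragends["chrS"]
    rng = np.random.default_rng(_sub_seed(seed, 5))
    reads = []
    for i in range(n_reads):
        if rng.random() < 0.5:
            j = int(rng.integers(1, len(fe) - 1))
            pos = int(fe[j])
            if rng.random() < 0.5:
                reads.append(
                    MateAlignment(f"r{i}", "chrS", pos, pos + 40, "+", MATERNAL)
                )
            else:
                reads.append(
                    MateAlignment(f"r{i}", "chrS", pos - 40, pos, "-", MATERNAL)
                )
        else:
            pos = int(rng.integers(50, len(ref["chrS"]) - 50))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(
                MateAlignment(f"r{i}", "chrS", pos, pos + 40, strand, MATERNAL)
            )
    table = count_fragends(reads, fm)
    starts = set(fe[:-1].tolist())
    ends = set(fe[1:].tolist())
    expected = np.zeros(len(fe), dtype=int)
    for r in reads:
        if r.strand == "+" and r.start in starts:
            expected[int(np.searchsorted(fe, r.start))] += 1
        elif r.strand == "-" and r.end in ends:
            expected[int(np.searchsorted(fe, r.end))] += 1
    observed = table.get(MATERNAL, "rep1")["chrS"]
    mismatches = int(np.sum(observed != expected))
    tracks = fragend_rpm_smooth(table, "chrS", k=8)
    rpm_sum = float(tracks.rpm[(MATERNAL, "rep1")].sum())
    return {
        "n": n_reads,
        "mismatched_fragends": mismatches,
        "oracle_agreement_pct": 100.0 * (mismatches == 0),
        "rpm_sum": rpm_sum,
    }


def ratio_recovery_experiment(
    seed: int,
    tmp_dir,
    fractions: tuple[float, ...] = (0.5, 0.6, 0.8, 0.9, 1.0),
    n_fragments: int = 2000,
) -> dict:
    """Programmed maternal fractions recovered by the SNP pileup.

    For each programmed fraction, the per-SNP pileup estimate (pooled
    over SNPs) must fall within 3 binomial standard errors, where the
    binomial unit is the sequenced fragment.
    """
    results = []
    for fi, f in enumerate(fractions):
        _, _, variants, sim, sam, lifts = _allelic_sim(
            _sub_seed(seed, 6, fi), f, n_fragments, tmp_dir
        )
        kept, _ = _classify_sam(sam, CROSS, lifts)
        counts = pileup_allelic_counts(
            kept, variants.snps(), CROSS, VARIANT_STRAIN, lifts
        )
        m = int(counts["maternal_count"].sum())
        p = int(counts["paternal_count"].sum())
        n_frag = len({aln.read_id for aln in kept})
        est = m / (m + p)
        se = float(np.sqrt(f * (1 - f) / n_frag))
        results.append(
            {
                "programmed": f,
                "estimated": est,
                "n_fragments": n_frag,
                "se": se,
                "within_3se": bool(abs(est - f) <= 3 * se),
            }
        )
    return {
        "per_fraction": results,
        "max_abs_error": max(abs(r["estimated"] - r["programmed"]) for r in results),
        "all_within_3se": all(r["within_3se"] for r in results),
        "n": n_fragments,
    }


# ---------------------------------------------------------------------------
# 4C statistics
# ---------------------------------------------------------------------------


def _fourc_genome(seed: int, length: int):
    cfg = SimulationConfig(seed=seed, contigs={"chrS": length})
    ref = simulate_reference(cfg)
    fm = digest_genome(ref)
    bait = snap_to_fragend(fm, "chrS", length // 2)
    return ref, fm, bait


def null_fdr_experiment(
    seed: int,
    n_seeds: int = 25,
    n_windows: int = 200,
    reads_per_allele: int = 5000,
    n_replicates: int = 2,
) -> dict:
    """False-discovery behaviour under equal allelic contact rates.

    Both alleles share the same distance-decay contact model; across
    seeds, the mean fraction of BH-significant windows at adjusted
    p < 0.05 must stay at or below 0.05.  One simulated fragend grid is
    used throughout; the seeds vary the contact sampling.
    """
    ref, fm, bait = _fourc_genome(_sub_seed(seed, 7), 440_000)
    windows = nearbait_windows(fm, "chrS", bait, k=8)
    if len(windows) < n_windows:
        raise ValueError("fragend grid too small for the requested window count")
    windows = windows[:n_windows]
    model = FourCModel(
        "chrS", bait, reads_per_allele=reads_per_allele, n_replicates=n_replicates
    )
    fracs = []
    for s in range(n_seeds):
        counts = simulate_4c_counts(fm, model, _sub_seed(seed, 8, s))
        table = table_from_counts(fm, "chrS", counts)
        calls = differential_allelic_interactions(
            table, "chrS", bait, windows=windows
        )
        sig = calls.table["significant"].fillna(False)
        fracs.append(float(sig.mean()))
    return {
        "mean_significant_fraction": float(np.mean(fracs)),
        "n": n_seeds,
        "n_windows": n_windows,
    }


def loop_detection_experiment(
    seed: int,
    n_runs: int = 25,
    reads_per_allele: int = 5000,
    maternal_mult: float = 5.0,
) -> dict:
    """Power to detect a maternal-only loop anchor.

    A 5x maternal-specific enrichment over 8 fragends ~30 kb from the
    bait must yield a significant maternally biased window (positive
    log2 ratio, adjusted p < 0.05) and a maternal-track-only domain call
    at the anchor in >= 90% of seeded runs.
    """
    ref, fm, bait = _fourc_genome(_sub_seed(seed, 9), 200_000)
    fe = fm.fragends["chrS"]
    anchor_i = int(np.searchsorted(fe, bait + 30_000))
    anchor = int(fe[anchor_i])
    loop_end = int(fe[anchor_i + 8])
    model = FourCModel(
        "chrS", bait, reads_per_allele=reads_per_allele, n_replicates=2,
        loops=(LoopSpec(anchor, maternal_mult=maternal_mult),),
    )
    n_sig = n_dom = 0
    for s in range(n_runs):
        counts = simulate_4c_counts(fm, model, _sub_seed(seed, 10, s))
        table = table_from_counts(fm, "chrS", counts)
        calls = analyze_nearbait(table, "chrS", bait)
        t = calls.table
        hit = t[(t["start"] <= loop_end) & (anchor <= t["end"])]
        sig = hit["significant"].fillna(False) & (hit["log2_ratio"] > 0)
        n_sig += bool(sig.any())
        mat_dom = any(s0 <= loop_end and anchor <= e0
                      for s0, e0 in calls.domains[MATERNAL])
        pat_dom = any(s0 <= loop_end and anchor <= e0
                      for s0, e0 in calls.domains[PATERNAL])
        n_dom += bool(mat_dom and not pat_dom)
    return {
        "significant_rate_pct": 100.0 * n_sig / n_runs,
        "maternal_domain_only_rate_pct": 100.0 * n_dom / n_runs,
        "n": n_runs,
    }


def decay_control_experiment(
    seed: int, n_runs: int = 20, reads_per_allele: int = 5000
) -> dict:
    """Pure distance-decay control: the domain caller should stay silent."""
    ref, fm, bait = _fourc_genome(_sub_seed(seed, 9), 200_000)
    model = FourCModel(
        "chrS", bait, reads_per_allele=reads_per_allele, n_replicates=1
    )
    clean = 0
    for s in range(n_runs):
        counts = simulate_4c_counts(fm, model, _sub_seed(seed, 11, s))
        calls = call_interaction_domains(
            counts[(MATERNAL, "rep1")], fm, "chrS", bait
        )
        clean += not calls.domains
    return {"zero_domain_runs": clean, "n": n_runs}


def coverage_contract_experiment(seed: int) -> dict:
    """Closed-form RPKM, allelic additivity and spike-in depth invariance."""

    def iv(chrom, start, end, name="r", strand="+"):
        return AllelicAlignment(name, chrom, start, end, strand, 42, "B6", MATERNAL)

    chroms = {"chrT": 1000}
    reads = [iv("chrT", 210, 260) for _ in range(10)]
    rpkm = binned_coverage(
        reads, chroms, CoverageConfig(bin_size=200), total_mapped=10**6
    ).values["chrT"][1]

    rng = np.random.default_rng(_sub_seed(seed, 12))
    pools = {
        p: [iv("chrT", int(s), int(s) + 30, name=f"{p}{i}")
            for i, s in enumerate(rng.integers(0, 950, size=100))]
        for p in ("maternal", "paternal", "unassigned")
    }
    cfg_raw = CoverageConfig(bin_size=50, normalization="raw")
    total = binned_coverage(
        [r for pool in pools.values() for r in pool], chroms, cfg_raw
    )
    parts = [binned_coverage(pool, chroms, cfg_raw) for pool in pools.values()]
    combined = parts[0] + parts[1] + parts[2]
    additive = bool(
        np.array_equal(total.values["chrT"], combined.values["chrT"])
    )

    starts = rng.integers(0, 950, size=200)
    base = [iv("chrT", int(s), int(s) + 30) for s in starts]
    shallow = binned_coverage(
        base, chroms,
        CoverageConfig(bin_size=50, normalization="scale_factor",
                       scale_factor=spike_in_factor(10_000, 1e4)),
    )
    deep = binned_coverage(
        base * 2, chroms,
        CoverageConfig(bin_size=50, normalization="scale_factor",
                       scale_factor=spike_in_factor(20_000, 1e4)),
    )
    spike_ok = bool(
        np.allclose(shallow.values["chrT"], deep.values["chrT"])
    )
    return {
        "rpkm_closed_form": float(rpkm),
        "allelic_additivity_exact": additive,
        "spikein_depth_invariant": spike_ok,
    }
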