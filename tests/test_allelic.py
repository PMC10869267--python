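"""Parental classification on the diploid genome: filters, projection,
label equivariance, allelic pileup recovery."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from hybridome.allelic import (
    AllelicAlignment,
    CrossOrientation,
    FilterConfig,
    Rejected,
    classify_alignment,
    classify_and_project,
    pileup_allelic_counts,
    project_to_reference,
)
from hybridome.genome import build_pseudogenome
from hybridome.liftover import FLAG_INSERTION_ONLY, LiftMap
from hybridome.simulate import (
    GeneModel,
    SimulationConfig,
    simulate_allelic_reads,
    simulate_reference,
    simulate_strain_variants,
)
from hybridome.variants import VariantSet

from conftest import make_variant_set


def make_record(contig="chrT_JF1", mapq=30, proper=True, length=6, start=0,
                reverse=False, name="r1"):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": contig, "LN": 1000}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = "A" * length
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = f"{length}M"
    a.flag = 0x1 | (0x2 if proper else 0) | (0x10 if reverse else 0)
    return a


class TestClassify:
    def test_jf1_contig_is_paternal_in_bj_cross(self, bj_cross):
        aln = classify_alignment(make_record("chrT_JF1"), bj_cross)
        assert isinstance(aln, AllelicAlignment)
        assert aln.parent == "paternal" and aln.haplotype == "JF1"
        assert aln.chrom == "chrT"

    def test_low_mapq_rejected(self, bj_cross):
        res = classify_alignment(
            make_record(mapq=5), bj_cross, FilterConfig(mapq_min=20)
        )
        assert res == Rejected("r1", "low_mapq")

    def test_orientation_swap_flips_parent(self):
        jb = CrossOrientation("JF1", "B6")
        aln = classify_alignment(make_record("chrT_B6"), jb)
        assert aln.parent == "paternal"

    def test_improper_pair_rejected(self, bj_cross):
        res = classify_alignment(make_record(proper=False), bj_cross)
        assert res == Rejected("r1", "not_proper_pair")

    def test_unknown_suffix_is_hard_error(self, bj_cross):
        with pytest.raises(ValueError, match="CAST"):
            classify_alignment(make_record("chrT_CAST"), bj_cross)


class TestProjection:
    def test_variant_strain_interval_lifted(self, toy_ref, ins_variant, bj_cross):
        _, lm = build_pseudogenome(toy_ref, make_variant_set(ins_variant))
        lifts = {"JF1": lm, "B6": LiftMap.identity({"chrT": 6})}
        aln = classify_alignment(make_record("chrT_JF1", start=4, length=4), bj_cross)
        proj = project_to_reference(aln, lifts)
        assert (proj.start, proj.end) == (2, 6) and proj.projected

    def test_reference_strain_unchanged(self, toy_ref, bj_cross):
        lifts = {"B6": LiftMap.identity({"chrT": 6})}
        aln = classify_alignment(make_record("chrT_B6", start=1, length=4), bj_cross)
        proj = project_to_reference(aln, lifts)
        assert (proj.start, proj.end) == (1, 5)

    def test_fully_inserted_read_flagged(self, toy_ref, ins_variant, bj_cross):
        _, lm = build_pseudogenome(toy_ref, make_variant_set(ins_variant))
        aln = classify_alignment(make_record("chrT_JF1", start=2, length=2), bj_cross)
        proj = project_to_reference(aln, {"JF1": lm})
        assert (proj.start, proj.end) == (1, 1)
        assert FLAG_INSERTION_ONLY in proj.flags


@pytest.fixture(scope="module")
def allelic_sim(tmp_path_factory):
    """Simulated allelic RNA reads at programmed maternal fraction 0.9."""
    cfg = SimulationConfig(seed=42, contigs={"chrS": 20_000})
    ref = simulate_reference(cfg)
    variants = simulate_strain_variants(ref, cfg)
    genes = [GeneModel("g1", "chrS", 2_000, 18_000, maternal_fraction=0.9,
                       n_fragments=500)]
    cross = CrossOrientation("B6", "JF1")
    sam = tmp_path_factory.mktemp("allelic") / "reads.sam"
    result = simulate_allelic_reads(ref, variants, genes, cross, "JF1", cfg, sam)
    pseudo, lm = build_pseudogenome(ref, variants)
    lifts = {"JF1": lm, "B6": LiftMap.identity({"chrS": len(ref["chrS"])})}
    return cfg, ref, variants, cross, sam, result, lifts


def classify_all(sam, cross, lifts, mapq_min=20):
    out, rejected = [], []
    with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
        for res in classify_and_project(
            fh, cross, lifts, FilterConfig(mapq_min=mapq_min)
        ):
            (out if isinstance(res, AllelicAlignment) else rejected).append(res)
    return out, rejected


def test_noiseless_reads_classified_without_error(allelic_sim):
    """Variant-overlapping reads recover their true haplotype exactly;
    variant-free reads carry the ambiguity surrogate MAPQ 0 and are
    rejected as low_mapq, never mis-assigned."""
    _, _, _, cross, sam, result, lifts = allelic_sim
    kept, rejected = classify_all(sam, cross, lifts)
    truth = result.truth.set_index(["read_id", "mate"])
    truth_by_read = result.truth.drop_duplicates("read_id").set_index("read_id")
    assert kept, "no reads passed filters"
    for aln in kept:
        assert aln.parent == truth_by_read.loc[aln.read_id, "parent"]
    assert all(r.reason == "low_mapq" for r in rejected)


def test_cross_swap_is_exact_label_equivariance(allelic_sim):
    _, _, _, cross, sam, _, lifts = allelic_sim
    kept_bj, _ = classify_all(sam, cross, lifts)
    kept_jb, _ = classify_all(sam, cross.swapped(), lifts)
    swap = {"maternal": "paternal", "paternal": "maternal"}
    assert len(kept_bj) == len(kept_jb)
    for a, b in zip(kept_bj, kept_jb):
        assert a.read_id == b.read_id and b.parent == swap[a.parent]


def test_pileup_recovers_programmed_fraction(allelic_sim):
    """Estimated maternal fraction within 3 binomial SE of the programmed
    0.9 at the covered SNPs."""
    _, _, variants, cross, sam, _, lifts = allelic_sim
    kept, _ = classify_all(sam, cross, lifts)
    counts = pileup_allelic_counts(kept, variants.snps(), cross, "JF1", lifts)
    m = counts["maternal_count"].sum()
    p = counts["paternal_count"].sum()
    n = m + p
    assert n > 200
    se = np.sqrt(0.9 * 0.1 / n)
    assert abs(m / n - 0.9) < 3 * se
    assert counts["other_count"].sum() == 0  # noiseless reads


def test_pileup_count_sum_invariant(allelic_sim):
    """maternal + paternal + other = filtered reads overlapping each SNP."""
    _, _, variants, cross, sam, _, lifts = allelic_sim
    kept, _ = classify_all(sam, cross, lifts)
    counts = pileup_allelic_counts(kept, variants.snps(), cross, "JF1", lifts)
    covered = counts.dropna(subset=["maternal_fraction"])
    assert len(covered) > 0
    for _, row in counts.head(50).iterrows():
        n_overlap = sum(
            1
            for aln in kept
            if aln.chrom == row["chrom"]
            and aln.start <= row["pos"] < aln.end
            and lifts[aln.haplotype].ref_to_pseudo(aln.chrom, int(row["pos"]))
            is not None
        )
        total = row["maternal_count"] + row["paternal_count"] + row["other_count"]
        assert total == n_overlap

    empty = counts[
        counts[["maternal_count", "paternal_count"]].sum(axis=1) == 0
    ]
    assert empty["maternal_fraction"].isna().all()
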