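"""4C-seq machinery: digestion, demultiplexing, exact fragend counting,
rpm tracks, domain calling and differential testing."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import pytest

from hybridome.allelic import CrossOrientation
from hybridome.fourc import (
    MATERNAL,
    PATERNAL,
    FragendTable,
    MateAlignment,
    ViewpointSpec,
    align_mates_to_fragends,
    analyze_nearbait,
    benjamini_hochberg,
    call_interaction_domains,
    count_fragends,
    demultiplex_viewpoint_pairs,
    differential_allelic_interactions,
    digest_genome,
    fragend_rpm_smooth,
    interaction_ratio_track,
    nearbait_windows,
    running_mean,
)
from hybridome.simulate import (
    FourCModel,
    LoopSpec,
    SimulationConfig,
    simulate_4c_counts,
    simulate_4c_experiment,
    simulate_reference,
    simulate_strain_variants,
    snap_to_fragend,
    table_from_counts,
)


class TestDigest:
    def test_cut_before_every_site(self):
        fm = digest_genome({"chrT": "AAGATCTTGATCCA"})
        assert fm.fragments("chrT") == [(0, 2), (2, 8), (8, 14)]

    def test_no_site_single_fragment(self):
        fm = digest_genome({"chrT": "A" * 30})
        assert fm.fragments("chrT") == [(0, 30)]

    def test_fragment_count_matches_regex_oracle(self):
        cfg = SimulationConfig(seed=13, contigs={"chrS": 10_000})
        seq = simulate_reference(cfg)["chrS"]
        fm = digest_genome({"chrS": seq})
        n_sites = len(re.findall("(?=GATC)", seq))
        assert fm.n_fragments("chrS") == n_sites + 1

    def test_bad_site_rejected(self):
        with pytest.raises(ValueError):
            digest_genome({"chrT": "ACGT"}, site="GATX")


VP_REF = {"chrV": "T" * 20 + "ACGTACGTAGGTACGTACGTACGTACGTAC" + "T" * 50}
# viewpoint interval [20, 50); SNP at position 29 (ref G, maternal G / paternal C)
VP = ViewpointSpec(
    chrom="chrV", start=20, end=50, snp_pos=29,
    snp_maternal="G", snp_paternal="C", trim5=4, trim3=0,
)


def make_pair(snp_base, rid="p1", junk="AAAA"):
    body = list(VP_REF["chrV"][20:50])
    body[9] = snp_base
    return (rid, junk + "".join(body), junk + "G" * 30)


class TestDemux:
    def test_maternal_base_tags_maternal(self):
        mates, report = demultiplex_viewpoint_pairs([make_pair("G")], VP, VP_REF)
        assert mates[0].allele == MATERNAL and report.n_maternal == 1

    def test_paternal_base_tags_paternal(self):
        mates, _ = demultiplex_viewpoint_pairs([make_pair("C")], VP, VP_REF)
        assert mates[0].allele == PATERNAL

    def test_n_or_third_allele_discarded(self):
        for base in "NT":
            mates, report = demultiplex_viewpoint_pairs(
                [make_pair(base)], VP, VP_REF
            )
            assert not mates and report.n_uninformative_base == 1

    def test_mismatching_viewpoint_discarded(self):
        pair = ("p1", "AAAA" + "T" * 30, "AAAA" + "G" * 30)
        mates, report = demultiplex_viewpoint_pairs([pair], VP, VP_REF)
        assert not mates and report.n_viewpoint_unmapped == 1

    def test_interacting_mate_trimmed(self):
        mates, _ = demultiplex_viewpoint_pairs([make_pair("G")], VP, VP_REF)
        assert mates[0].sequence == "G" * 30  # trim5=4 removed the junk

    def test_identical_snp_bases_is_hard_error(self):
        with pytest.raises(ValueError, match="uninformative"):
            ViewpointSpec("chrV", 20, 50, 29, "G", "G")

    def test_programmed_mix_recovered(self):
        """60:40 maternal:paternal mix recovered within 3 binomial SE."""
        rng = np.random.default_rng(5)
        n = 2000
        pairs = [
            make_pair("G" if rng.random() < 0.6 else "C", rid=f"p{i}")
            for i in range(n)
        ]
        true_frac = sum(1 for _, r1, _ in pairs if r1[13] == "G") / n
        mates, report = demultiplex_viewpoint_pairs(pairs, VP, VP_REF)
        frac = report.n_maternal / report.n_informative
        assert frac == pytest.approx(true_frac)
        assert abs(frac - 0.6) < 3 * np.sqrt(0.6 * 0.4 / n)


TOY_DIGEST = {"chrT": "AAGATCTTGATCCA"}  # fragends at 0, 2, 8, 14


def mate(start, end, strand, allele=MATERNAL, rep="rep1", rid="m", mapq=42):
    return MateAlignment(rid, "chrT", start, end, strand, allele, rep, mapq)


class TestCountFragends:
    def test_plus_read_at_left_boundary(self):
        fm = digest_genome(TOY_DIGEST)
        table = count_fragends([mate(2, 6, "+")], fm)
        assert table.get(MATERNAL, "rep1")["chrT"][1] == 1  # fragend at 2

    def test_offset_read_dropped(self):
        fm = digest_genome(TOY_DIGEST)
        table = count_fragends([mate(3, 7, "+")], fm)
        assert table.total(MATERNAL, "rep1") == 0 and table.n_dropped == 1

    def test_minus_read_at_right_boundary(self):
        fm = digest_genome(TOY_DIGEST)
        table = count_fragends([mate(4, 8, "-")], fm)
        assert table.get(MATERNAL, "rep1")["chrT"][2] == 1  # fragend at 8

    def test_brute_force_oracle_on_random_reads(self):
        """Exact agreement with a per-read boundary scan on a 1e3-read mix
        of valid fragend reads and offset reads."""
        cfg = SimulationConfig(seed=21, contigs={"chrS": 30_000})
        seq = simulate_reference(cfg)["chrS"]
        fm = digest_genome({"chrS": seq})
        fe = fm.fragends["chrS"]
        rng = np.random.default_rng(21)
        reads = []
        for i in range(1000):
            if rng.random() < 0.5:  # valid fragend read
                j = int(rng.integers(1, len(fe) - 1))
                pos = int(fe[j])
                if rng.random() < 0.5:
                    reads.append(MateAlignment(f"r{i}", "chrS", pos, pos + 40, "+",
                                               MATERNAL, "rep1", 42))
                else:
                    reads.append(MateAlignment(f"r{i}", "chrS", pos - 40, pos, "-",
                                               MATERNAL, "rep1", 42))
            else:  # random offset read
                pos = int(rng.integers(50, 29_900))
                strand = "+" if rng.random() < 0.5 else "-"
                reads.append(MateAlignment(f"r{i}", "chrS", pos, pos + 40, strand,
                                           MATERNAL, "rep1", 42))
        table = count_fragends(reads, fm)
        # independent brute-force scan over every (read, boundary) pair
        expected = np.zeros(len(fe), dtype=int)
        starts = set(fe[:-1].tolist())
        ends = set(fe[1:].tolist())
        n_valid = 0
        for r in reads:
            if r.strand == "+" and r.start in starts:
                expected[np.searchsorted(fe, r.start)] += 1
                n_valid += 1
            elif r.strand == "-" and r.end in ends:
                expected[np.searchsorted(fe, r.end)] += 1
                n_valid += 1
        np.testing.assert_array_equal(table.get(MATERNAL, "rep1")["chrS"], expected)
        assert table.total(MATERNAL, "rep1") == n_valid
        assert table.n_dropped == 1000 - n_valid


class TestRpmTracks:
    def test_rpm_formula(self):
        fm = digest_genome(TOY_DIGEST)
        table = FragendTable(fm)
        arr = table.get(MATERNAL, "rep1")["chrT"]
        arr[1] = 5
        arr[2] = 995
        tracks = fragend_rpm_smooth(table, "chrT", k=1)
        assert tracks.rpm[(MATERNAL, "rep1")][1] == pytest.approx(5000.0)

    def test_rpm_sums_to_one_million(self):
        cfg = SimulationConfig(seed=2, contigs={"chrS": 50_000})
        ref = simulate_reference(cfg)
        fm = digest_genome(ref)
        model = FourCModel("chrS", snap_to_fragend(fm, "chrS", 25_000),
                           reads_per_allele=2000)
        table = table_from_counts(fm, "chrS", simulate_4c_counts(fm, model, 2))
        tracks = fragend_rpm_smooth(table, "chrS", k=8)
        for key, rpm in tracks.rpm.items():
            assert rpm.sum() == pytest.approx(1e6)

    def test_running_mean_examples(self):
        np.testing.assert_allclose(
            running_mean(np.array([0.0, 3.0, 6.0]), 3), [1.5, 3.0, 4.5]
        )
        assert running_mean(np.array([0.0, 3.0, 6.0]), 3)[1] == 3.0
        const = np.full(20, 7.0)
        np.testing.assert_allclose(running_mean(const, 8), const)

    def test_zero_total_warns_with_nan_track(self):
        fm = digest_genome(TOY_DIGEST)
        table = FragendTable(fm)
        table.get(MATERNAL, "rep1")  # all-zero allele
        with pytest.warns(UserWarning, match="no informative"):
            tracks = fragend_rpm_smooth(table, "chrT")
        assert np.isnan(tracks.rpm[(MATERNAL, "rep1")]).all()


class TestRatioTrack:
    def test_zero_zero_gives_zero(self):
        assert interaction_ratio_track(np.zeros(3), np.zeros(3))[0] == 0.0

    def test_closed_form(self):
        out = interaction_ratio_track(np.array([3.0]), np.array([1.0]),
                                      pseudocount=1.0)
        assert out[0] == pytest.approx(1.0)

    def test_antisymmetry_on_random_tracks(self):
        rng = np.random.default_rng(9)
        a, b = rng.gamma(1, 100, size=50), rng.gamma(1, 100, size=50)
        np.testing.assert_allclose(
            interaction_ratio_track(a, b), -interaction_ratio_track(b, a)
        )

    def test_grid_mismatch_is_error(self):
        with pytest.raises(ValueError):
            interaction_ratio_track(np.zeros(3), np.zeros(4))


def test_benjamini_hochberg_hand_example():
    """Step-up adjustment computed by hand for four p values."""
    adj = benjamini_hochberg(np.array([0.001, 0.02, 0.03, 0.5]))
    np.testing.assert_allclose(adj, [0.004, 0.04, 0.04, 0.5])


@pytest.fixture(scope="module")
def fourc_genome():
    cfg = SimulationConfig(seed=17, contigs={"chrS": 200_000})
    ref = simulate_reference(cfg)
    fm = digest_genome(ref)
    bait = snap_to_fragend(fm, "chrS", 100_000)
    return cfg, ref, fm, bait


class TestWindows:
    def test_tiling_is_ordered_and_disjoint(self, fourc_genome):
        _, _, fm, bait = fourc_genome
        windows = nearbait_windows(fm, "chrS", bait, k=8)
        assert len(windows) >= 24
        for w in windows:
            assert w.end_idx - w.start_idx == 8
        for a, b in zip(windows, windows[1:]):
            assert a.end_idx <= b.start_idx

    def test_bait_flanking_fragends_excluded(self, fourc_genome):
        _, _, fm, bait = fourc_genome
        li, ri = fm.containing_fragment("chrS", bait)
        windows = nearbait_windows(fm, "chrS", bait, k=8)
        used = {i for w in windows for i in w.indices}
        assert li not in used and ri not in used


class TestDomainCaller:
    def test_uniform_zero_counts_no_domains(self, fourc_genome):
        _, _, fm, bait = fourc_genome
        counts = np.zeros(len(fm.fragends["chrS"]))
        calls = call_interaction_domains(counts, fm, "chrS", bait, total=0)
        assert calls.domains == []

    def test_pure_decay_rarely_calls_domains(self, fourc_genome):
        """Null distance-decay simulation: no domains in >= 4/5 runs."""
        _, _, fm, bait = fourc_genome
        model = FourCModel("chrS", bait, reads_per_allele=5000, n_replicates=1)
        clean = 0
        for seed in range(5):
            counts = simulate_4c_counts(fm, model, 1000 + seed)
            arr = counts[(MATERNAL, "rep1")]
            calls = call_interaction_domains(arr, fm, "chrS", bait)
            clean += not calls.domains
        assert clean >= 4

    def test_enriched_loop_called_on_that_allele_only(self, fourc_genome):
        _, _, fm, bait = fourc_genome
        fe = fm.fragends["chrS"]
        anchor = int(fe[np.searchsorted(fe, bait + 30_000)])
        model = FourCModel(
            "chrS", bait, reads_per_allele=5000, n_replicates=1,
            loops=(LoopSpec(anchor, maternal_mult=5.0),),
        )
        counts = simulate_4c_counts(fm, model, 77)
        mat = call_interaction_domains(counts[(MATERNAL, "rep1")], fm, "chrS", bait)
        pat = call_interaction_domains(counts[(PATERNAL, "rep1")], fm, "chrS", bait)
        assert any(s <= anchor <= e for s, e in mat.domains)
        assert not any(s <= anchor <= e for s, e in pat.domains)

    def test_too_few_fragends_is_hard_error(self):
        fm = digest_genome(TOY_DIGEST)
        with pytest.raises(ValueError):
            call_interaction_domains(np.zeros(4), fm, "chrT", 5)

    def test_loop_anchor_off_fragend_is_hard_error(self, fourc_genome):
        _, _, fm, bait = fourc_genome
        model = FourCModel("chrS", bait,
                           loops=(LoopSpec(anchor=bait + 30_001),))
        with pytest.raises(ValueError, match="not on a fragend"):
            simulate_4c_counts(fm, model, 1)


class TestDifferential:
    def test_perfectly_balanced_window_p_one(self, fourc_genome):
        _, _, fm, bait = fourc_genome
        windows = nearbait_windows(fm, "chrS", bait, k=8)
        table = FragendTable(fm)
        i = windows[0].start_idx
        table.get(MATERNAL, "rep1")["chrS"][i] = 30
        table.get(PATERNAL, "rep1")["chrS"][i] = 30
        calls = differential_allelic_interactions(table, "chrS", bait)
        row = calls.table.iloc[0]
        assert calls.pi0 == pytest.approx(0.5)
        assert row["pvalue"] == pytest.approx(1.0)
        assert calls.table["pvalue"].iloc[1:].isna().all()

    def test_adjusted_p_at_least_p(self, fourc_genome):
        _, _, fm, bait = fourc_genome
        model = FourCModel("chrS", bait, reads_per_allele=3000)
        table = table_from_counts(fm, "chrS",
                                  simulate_4c_counts(fm, model, 31))
        calls = differential_allelic_interactions(table, "chrS", bait)
        ok = calls.table.dropna(subset=["pvalue"])
        assert (ok["padj"] >= ok["pvalue"] - 1e-12).all()
        assert ((ok["padj"] < 0.05) == ok["significant"]).all()

    def test_maternal_loop_detected_with_positive_ratio(self, fourc_genome):
        _, _, fm, bait = fourc_genome
        fe = fm.fragends["chrS"]
        anchor = int(fe[np.searchsorted(fe, bait + 30_000)])
        model = FourCModel(
            "chrS", bait, reads_per_allele=5000, n_replicates=2,
            loops=(LoopSpec(anchor, maternal_mult=4.0),),
        )
        table = table_from_counts(fm, "chrS", simulate_4c_counts(fm, model, 99))
        calls = analyze_nearbait(table, "chrS", bait)
        # the loop spans 8 fragends starting at the anchor; check the
        # windows overlapping that span
        loop_end = int(fe[np.searchsorted(fe, anchor) + 8])
        hit = calls.table[
            (calls.table["start"] <= loop_end) & (anchor <= calls.table["end"])
        ]
        best = hit.loc[hit["pvalue"].idxmin()]
        assert bool(best["significant"])
        assert best["log2_ratio"] > 0
        assert bool(best["maternal_domain"])

    def test_label_swap_equivariance(self, fourc_genome):
        """Swapping the allele labels negates every ratio and swaps the
        domain calls, leaving significance untouched."""
        _, _, fm, bait = fourc_genome
        fe = fm.fragends["chrS"]
        anchor = int(fe[np.searchsorted(fe, bait - 25_000)])
        model = FourCModel(
            "chrS", bait, reads_per_allele=4000, n_replicates=2,
            loops=(LoopSpec(anchor, maternal_mult=3.0),),
        )
        counts = simulate_4c_counts(fm, model, 55)
        swapped = {
            (MATERNAL if a == PATERNAL else PATERNAL, r): arr
            for (a, r), arr in counts.items()
        }
        calls = analyze_nearbait(table_from_counts(fm, "chrS", counts),
                                 "chrS", bait)
        calls_sw = analyze_nearbait(table_from_counts(fm, "chrS", swapped),
                                    "chrS", bait)
        np.testing.assert_allclose(
            calls.table["log2_ratio"], -calls_sw.table["log2_ratio"]
        )
        np.testing.assert_allclose(
            calls.table["pvalue"].fillna(-1), calls_sw.table["pvalue"].fillna(-1)
        )
        pd.testing.assert_series_equal(
            calls.table["maternal_domain"], calls_sw.table["paternal_domain"],
            check_names=False,
        )

    def test_null_fdr_fraction_small(self, fourc_genome):
        """Equal allelic rates: mean significant fraction stays below the
        nominal 0.05 across seeds."""
        _, _, fm, bait = fourc_genome
        model = FourCModel("chrS", bait, reads_per_allele=3000, n_replicates=2)
        fracs = []
        for seed in range(5):
            table = table_from_counts(
                fm, "chrS", simulate_4c_counts(fm, model, 400 + seed)
            )
            calls = differential_allelic_interactions(table, "chrS", bait)
            sig = calls.table["significant"].fillna(False)
            fracs.append(sig.mean())
        assert np.mean(fracs) <= 0.05


class TestEndToEnd:
    def test_fastq_pipeline_closure(self, tmp_path):
        """Full route: simulate pairs -> demultiplex -> place mates ->
        count fragends -> differential; recovers the simulated counts."""
        cfg = SimulationConfig(seed=23, contigs={"chrS": 120_000})
        ref = simulate_reference(cfg)
        variants = simulate_strain_variants(ref, cfg)
        fm = digest_genome(ref)
        bait = snap_to_fragend(fm, "chrS", 60_000)
        cross = CrossOrientation("B6", "JF1")
        model = FourCModel("chrS", bait, reads_per_allele=1500, n_replicates=2)
        sim = simulate_4c_experiment(ref, variants, model, cross, "JF1", cfg)
        all_alns = []
        for rep, pairs in sim.pairs.items():
            mates, report = demultiplex_viewpoint_pairs(
                pairs, sim.viewpoint, ref, rep
            )
            assert report.n_viewpoint_unmapped == 0
            assert report.n_informative == len(pairs)
            alns, dropped = align_mates_to_fragends(mates, fm, ref)
            # noiseless mates all sit on the grid; rare dropped reads come
            # from k-mer collisions between fragend sequences
            assert dropped <= 0.01 * len(mates)
            all_alns.extend(alns)
        table = count_fragends(all_alns, fm, mapq_min=0)
        truth_total = len(sim.truth)
        counted = sum(
            table.total(a, r) for a in table.alleles() for r in table.replicates()
        )
        assert counted >= 0.99 * truth_total
        # demux tags match the simulation truth exactly
        truth = sim.truth.set_index("read_id")
        for aln in all_alns[:500]:
            assert truth.loc[aln.read_id, "allele"] == aln.allele
        calls = analyze_nearbait(table, "chrS", bait)
        assert len(calls.table) >= 24

    def test_seed_determinism(self, tmp_path):
        cfg = SimulationConfig(seed=31, contigs={"chrS": 60_000})
        ref = simulate_reference(cfg)
        variants = simulate_strain_variants(ref, cfg)
        fm = digest_genome(ref)
        model = FourCModel("chrS", snap_to_fragend(fm, "chrS", 30_000),
                           reads_per_allele=300, n_replicates=1)
        cross = CrossOrientation("B6", "JF1")
        a = simulate_4c_experiment(ref, variants, model, cross, "JF1", cfg)
        b = simulate_4c_experiment(ref, variants, model, cross, "JF1", cfg)
        a.write_fastq(tmp_path / "a")
        b.write_fastq(tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
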