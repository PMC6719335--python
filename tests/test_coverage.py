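"""Mapper semantics, MAPQ filtering, window depth oracle, copy calls."""

import numpy as np
import pytest

import sta1typer as st
from sta1typer.coverage import (AlignmentRecord, DepthSummary, _round_half_away,
                                zygosity_from_copies)
from sta1typer.dna import revcomp


def rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def oracle_placements(read, reference, max_mm):
    """Every minimal-mismatch placement by exhaustive sliding comparison."""
    hits = []
    for contig, seq in reference.items():
        for strand, query in (("+", read), ("-", revcomp(read))):
            for i in range(len(seq) - len(query) + 1):
                d = sum(a != b for a, b in zip(seq[i:i + len(query)], query))
                if d <= max_mm:
                    hits.append((d, contig, i + 1, strand))
    if not hits:
        return []
    best = min(h[0] for h in hits)
    return sorted(h for h in hits if h[0] == best)


class TestMapper:
    def test_unique_reads_get_mapq60_at_true_positions(self):
        rng = np.random.default_rng(0)
        ref = {"c": rand_dna(rng, 5000)}
        reads = [(f"r{i}", ref["c"][p:p + 100])
                 for i, p in enumerate(rng.integers(0, 4900, size=200))]
        aln = st.map_reads(reads, ref)
        assert len(aln) == 200
        assert all(a.mapq == 60 and a.mismatches == 0 for a in aln)
        by_id = {a.read_id: a for a in aln}
        for rid, seq in reads:
            assert ref["c"][by_id[rid].pos - 1:by_id[rid].pos - 1 + 100] == seq

    def test_duplicated_segment_reads_tie_at_mapq0(self):
        rng = np.random.default_rng(1)
        dup = rand_dna(rng, 400)
        ref = {"c": rand_dna(rng, 1000) + dup + rand_dna(rng, 1000) + dup
               + rand_dna(rng, 500)}
        reads = [("r0", dup[100:200]), ("r1", dup[250:350])]
        aln = st.map_reads(reads, ref)
        assert len(aln) == 4
        assert all(a.mapq == 0 for a in aln)
        for rid, seq in reads:
            got = sorted((a.mismatches, a.contig, a.pos, a.strand)
                         for a in aln if a.read_id == rid)
            assert got == oracle_placements(seq, ref, 3)

    @pytest.mark.parametrize("seed", [2, 3])
    def test_minimal_mismatch_placements_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = {"a": rand_dna(rng, 1500), "b": rand_dna(rng, 800)}
        reads = []
        for i in range(30):
            contig = "a" if rng.random() < 0.6 else "b"
            p = int(rng.integers(0, len(ref[contig]) - 60))
            seq = list(ref[contig][p:p + 60])
            for j in rng.choice(60, size=int(rng.integers(0, 4)), replace=False):
                seq[j] = "ACGT"[(("ACGT".index(seq[j])) + 1) % 4]
            seq = "".join(seq)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append((f"r{i}", seq))
        aln = st.map_reads(reads, ref, max_mismatch=3)
        for rid, seq in reads:
            got = sorted((a.mismatches, a.contig, a.pos, a.strand)
                         for a in aln if a.read_id == rid)
            assert got == oracle_placements(seq, ref, 3), rid

    def test_unmappable_read_dropped(self):
        rng = np.random.default_rng(4)
        ref = {"c": rand_dna(rng, 2000)}
        aln = st.map_reads([("junk", rand_dna(rng, 80))], ref, max_mismatch=3)
        assert aln == []

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            st.map_reads([("r", "ACGT" * 20)], {})


class TestFilterAndDepth:
    def test_filter_unique_keeps_only_high_mapq(self):
        recs = [AlignmentRecord("a", "c", 1, "+", 0, 60, 100),
                AlignmentRecord("b", "c", 5, "+", 0, 0, 100)]
        assert st.filter_unique(recs) == recs[:1]
        assert st.filter_unique(recs, mapq_min=0) == recs

    def test_window_depth_equals_bruteforce_overlap_count(self):
        rng = np.random.default_rng(5)
        ref = {"c": rand_dna(rng, 100)}
        recs = [AlignmentRecord(f"r{i}", "c", int(p) + 1, "+", 0, 60, int(l))
                for i, (p, l) in enumerate(zip(rng.integers(0, 90, 2000),
                                               rng.integers(5, 11, 2000)))]
        windows = {"w1": ("c", 10, 30), "w2": ("c", 55, 55)}
        summary = st.window_depth(recs, windows, ref)
        depth = np.zeros(100, dtype=int)
        for r in recs:
            for pos in range(r.pos, min(r.pos + r.read_len, 101)):
                depth[pos - 1] += 1
        assert summary.genome_median == np.median(depth)
        assert summary.window_medians["w1"] == np.median(depth[9:30])
        assert summary.window_medians["w2"] == depth[54]

    def test_uncovered_window_and_bad_windows(self):
        ref = {"c": "ACGT" * 50}
        recs = [AlignmentRecord("r", "c", 1, "+", 0, 60, 20)]
        summary = st.window_depth(recs, {"w": ("c", 100, 150)}, ref)
        assert summary.window_medians["w"] == 0.0
        with pytest.raises(ValueError):
            st.window_depth(recs, {"w": ("c", 30, 20)}, ref)
        with pytest.raises(ValueError):
            st.window_depth(recs, {"w": ("c", 100, 500)}, ref)

    def test_simulated_genome_median_near_target(self):
        rng = np.random.default_rng(6)
        hap = rand_dna(rng, 30_000)
        reads = st.simulate_reads([hap], st.ReadSimParams(100, 30.0, 0.0, 7))
        aln = st.map_reads(reads, {"c": hap}, max_mismatch=0)
        summary = st.window_depth(st.filter_unique(aln, 0),
                                  {"mid": ("c", 10_000, 20_000)}, {"c": hap})
        assert abs(summary.genome_median - 30.0) / 30.0 < 0.10


class TestCopyCalls:
    def test_rounding_half_away_from_zero(self):
        assert _round_half_away(1.5) == 2
        assert _round_half_away(2.49) == 2
        assert _round_half_away(0.5) == 1
        assert _round_half_away(0.49) == 0

    @pytest.mark.parametrize("orf,prom,expected", [
        (2, 2, "homozygous_intact"),
        (2, 1, "heterozygous_deletion"),
        (2, 0, "homozygous_deletion"),
        (1, 1, "hemizygous_sta1"),
        (1, 0, "hemizygous_sta1"),
        (3, 3, "multi_copy"),
        (0, 0, "absent"),
    ])
    def test_diploid_zygosity_rules(self, orf, prom, expected):
        assert zygosity_from_copies(orf, prom, ploidy=2) == expected

    def test_higher_ploidy_reports_raw_copy_vector(self):
        assert zygosity_from_copies(3, 2, ploidy=4) == "copies_3_2"

    def test_estimate_copies_ratios_and_errors(self):
        summary = DepthSummary({"orf_marker": 50.0, "promoter_marker": 24.0},
                               genome_median=50.0, n_reads=1000,
                               mapq_threshold=50)
        call = st.estimate_copies(summary, ploidy=2)
        assert call.copies == {"orf_marker": 2, "promoter_marker": 1}
        assert call.ratios["promoter_marker"] == pytest.approx(0.48)
        assert call.zygosity == "heterozygous_deletion"
        dead = DepthSummary({"orf_marker": 0.0}, 0.0, 0, 50)
        with pytest.raises(ValueError):
            st.estimate_copies(dead)


class TestSharedSequenceFilter:
    """Reads from chimera/parent-shared sequence must die at the MAPQ
    filter; reads inside a diagnostic window must survive."""

    def test_shared_reads_removed_marker_reads_kept(self, parents,
                                                    locus_intact):
        spec = st.GenotypeSpec(states=("intact", "intact"),
                               background_length=40_000, seed=8)
        g = st.build_genome(spec, locus_intact, parents)
        hap = next(iter(g.haplotypes.values()))
        cas_start = hap.find(locus_intact.orf_marker_seq) - \
            locus_intact.coord_map.slice_offsets(65, 143)[0]
        # reads wholly inside parent-shared promoter sequence (upstream of
        # the promoter marker island)
        shared = [(f"s{i}", hap[cas_start + 100 + i * 7:
                                cas_start + 200 + i * 7]) for i in range(20)]
        # reads wholly inside the ORF diagnostic window would be < 100 bp;
        # use reads centred on it instead (unique by construction)
        a, b = locus_intact.coord_map.slice_offsets(65, 143)
        marker_reads = [(f"m{i}", hap[cas_start + a - 15 + i:
                                      cas_start + a - 15 + i + 100])
                        for i in range(10)]
        aln = st.map_reads(shared + marker_reads, g.reference)
        kept = {x.read_id for x in st.filter_unique(aln)}
        assert not any(rid.startswith("s") for rid in kept)
        assert all(f"m{i}" in kept for i in range(10))


class TestSamRoundTrip:
    def test_records_survive_sam_io_and_threshold(self, tmp_path):
        ref = {"c1": "ACGT" * 300, "c2": "TTGGCCAA" * 100}
        recs = [AlignmentRecord("r1", "c1", 10, "+", 1, 60, 150),
                AlignmentRecord("r2", "c2", 33, "-", 0, 0, 150)]
        path = tmp_path / "x.sam"
        st.write_sam(path, recs, ref)
        back = st.read_sam(path)
        assert back == recs
        assert st.filter_unique(back) == recs[:1]


class TestEndToEnd:
    def test_hemizygous_genotype_recovered_from_reads(self, parents,
                                                      locus_intact):
        spec = st.GenotypeSpec(states=("intact", "absent"),
                               background_length=40_000, seed=12)
        g = st.build_genome(spec, locus_intact, parents)
        reads = st.simulate_reads(g.haplotypes,
                                  st.ReadSimParams(150, 40.0, 0.005, 12))
        call, summary = st.genotype_from_reads(reads, g.reference, g.windows)
        assert call.copies == {"orf_marker": 1, "promoter_marker": 1}
        assert call.zygosity == "hemizygous_sta1"
        assert summary.genome_median > 0

    @pytest.mark.parametrize("n_seeds", [20])
    def test_ratio_estimator_unbiased(self, parents, locus_intact, n_seeds):
        """Mean depth ratio across seeds within 5% of truth at 50x."""
        ratios = []
        for seed in range(n_seeds):
            spec = st.GenotypeSpec(states=("intact", "intact"),
                                   background_length=40_000, seed=seed)
            g = st.build_genome(spec, locus_intact, parents)
            reads = st.simulate_reads(g.haplotypes,
                                      st.ReadSimParams(150, 50.0, 0.005, seed))
            call, _ = st.genotype_from_reads(reads, g.reference, g.windows)
            ratios.append(call.ratios["orf_marker"])
        assert abs(np.mean(ratios) - 1.0) < 0.05
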