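"""Reference building, seed-and-extend mapping, SAM import, coverage."""

import numpy as np
import pytest

from aquadetect import (
    DataError,
    GenomeRecord,
    build_reference,
    compute_coverage,
    generate_genome,
    import_alignments,
    map_reads,
    plant_shared_repeat,
)
from aquadetect.mapping import AlignmentRecord
from aquadetect.synthetic import Read, ReadSet

from conftest import simulate_single


def _single_read(seq, read_id="r0"):
    return ReadSet(reads=[Read(read_id, seq)], read_length=len(seq))


def _mutate(seq, positions):
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    s = list(seq)
    for p in positions:
        s[p] = swap[s[p]]
    return "".join(s)


class TestBuildReference:
    def test_unmasked_length_with_mask(self):
        g = generate_genome(1000, 0.5, seed=1, genome_id="A")
        ref = build_reference([g], masks=[("A", 0, 100, 200)])
        assert ref.unmasked_length[0] == 900

    def test_no_masks(self):
        g = generate_genome(1000, 0.5, seed=1, genome_id="A")
        ref = build_reference([g])
        assert ref.unmasked_length[0] == g.total_length

    def test_overlapping_masks_merged(self):
        # interval-union oracle: [0,50) u [25,75) covers 75 positions
        g = generate_genome(1000, 0.5, seed=1, genome_id="A")
        ref = build_reference([g], masks=[("A", 0, 0, 50), ("A", 0, 25, 75)])
        assert ref.unmasked_length[0] == 1000 - 75

    def test_coordinate_bijection(self):
        gs = [generate_genome(2000, 0.5, n_contigs=2, seed=s, genome_id=f"g{s}") for s in (1, 2)]
        ref = build_reference(gs)
        for gpos in [0, 999, 1000, 1999, 2000, 3999]:
            gi, ci, pos = ref.locate(gpos)
            back = ref.offsets[gi] + ref.contig_offsets[gi][ci] + pos
            assert back == gpos

    def test_duplicate_ids_rejected(self):
        g = generate_genome(1000, 0.5, seed=1, genome_id="A")
        with pytest.raises(DataError):
            build_reference([g, g])


class TestMapReads:
    def test_error_free_truth_accuracy(self, genome_200k):
        # truth-label audit: >= 99% of reads placed on their genome at 100% id
        other = generate_genome(50_000, 0.42, seed=99, genome_id="other")
        reads = simulate_single(genome_200k, depth=0.5, seed=31)
        ref = build_reference([genome_200k, other])
        alignments = map_reads(reads, ref)
        by_id = {a.read_id: a for a in alignments}
        correct = sum(
            1
            for r in reads.reads
            if r.read_id in by_id
            and by_id[r.read_id].genome_id == r.truth_genome_id
            and by_id[r.read_id].identity_pct == 100.0
        )
        assert correct / len(reads.reads) >= 0.99

    @pytest.mark.parametrize("n_mm,kept", [(8, False), (7, True)])
    def test_identity_filter_boundary(self, genome_small, n_mm, kept):
        # 100*142/150 = 94.67 < 95 suppressed; 100*143/150 = 95.33 kept
        seq = genome_small.contigs[0][1000:1150]
        read = _mutate(seq, range(60, 60 + n_mm))
        ref = build_reference([genome_small])
        alignments = map_reads(_single_read(read), ref, min_identity_pct=95)
        assert bool(alignments) == kept
        if kept:
            assert alignments[0].matches == 150 - n_mm

    def test_reverse_strand_reported_forward(self, genome_small):
        from aquadetect.genomes import reverse_complement

        seq = reverse_complement(genome_small.contigs[0][2000:2150])
        ref = build_reference([genome_small])
        alignments = map_reads(_single_read(seq), ref)
        assert len(alignments) == 1
        assert alignments[0].start == 2000
        assert alignments[0].identity_pct == 100.0

    def test_repeat_cross_mapping_masked_out(self):
        # reads from A's shared repeat: placement is ambiguous across genomes,
        # but with masking the repeat contributes nothing to coverage
        gs = [generate_genome(20_000, 0.5, seed=s, genome_id=f"g{s}") for s in (1, 2)]
        ga, gb = plant_shared_repeat(gs, repeat_length=3000, copies_per_genome=1, seed=3)
        c, s, e = ga.masked_intervals[0]
        repeat_reads = ReadSet(
            reads=[
                Read(f"rep{i}", ga.contigs[c][s + i * 100: s + i * 100 + 150])
                for i in range(20)
            ],
            read_length=150,
        )
        ref = build_reference([ga, gb])
        alignments = map_reads(repeat_reads, ref)
        assert alignments  # the repeat itself maps somewhere
        profiles = compute_coverage(alignments, ref, total_reads=len(repeat_reads))
        for p in profiles:
            assert p.breadth_pct == 0.0  # masked everywhere it landed

    def test_empty_reads_rejected(self, genome_small):
        ref = build_reference([genome_small])
        with pytest.raises(Exception):
            map_reads(ReadSet(reads=[], read_length=150), ref)


SAM_TEMPLATE = """@HD\tVN:1.6
@SQ\tSN:A|0\tLN:5000
{records}"""


def _sam(records: list[str], tmp_path):
    p = tmp_path / "in.sam"
    p.write_text(SAM_TEMPLATE.format(records="\n".join(records) + "\n"))
    return str(p)


class TestImportAlignments:
    @pytest.fixture()
    def ref(self, genome_small):
        g = GenomeRecord("A", list(genome_small.contigs))
        return build_reference([g])

    def _rec(self, ref, name, flag, pos1, n_mm, tags=True):
        seq = ref.genomes[0].contigs[0][pos1 - 1: pos1 - 1 + 150]
        seq = _mutate(seq, range(n_mm))
        tag = f"\tNM:i:{n_mm}" if tags else ""
        return f"{name}\t{flag}\tA|0\t{pos1}\t255\t150M\t*\t0\t0\t{seq}\t*{tag}"

    def test_nm_zero_identity_100(self, ref, tmp_path):
        recs = import_alignments(_sam([self._rec(ref, "r1", 0, 101, 0)], tmp_path), ref)
        assert len(recs) == 1
        assert recs[0].identity_pct == 100.0
        assert recs[0].start == 100  # 1-based SAM -> 0-based internal

    def test_nm_8_suppressed(self, ref, tmp_path):
        recs = import_alignments(_sam([self._rec(ref, "r1", 0, 101, 8)], tmp_path), ref)
        assert recs == []

    def test_secondary_ignored(self, ref, tmp_path):
        recs = import_alignments(_sam([self._rec(ref, "r1", 256, 101, 0)], tmp_path), ref)
        assert recs == []

    def test_missing_tags_skipped(self, ref, tmp_path):
        recs = import_alignments(_sam([self._rec(ref, "r1", 0, 101, 0, tags=False)], tmp_path), ref)
        assert recs == []

    def test_roundtrip_with_internal_mapper(self, tmp_path, genome_small):
        from aquadetect.io import write_sam

        reads = simulate_single(genome_small, depth=1.0, seed=17)
        ref = build_reference([genome_small])
        alignments = map_reads(reads, ref)
        sam_path = tmp_path / "out.sam"
        write_sam(alignments, ref, sam_path)
        back = import_alignments(str(sam_path), ref)
        key = lambda a: (a.read_id, a.genome_id, a.contig_index, a.start, a.matches)
        assert sorted(map(key, back)) == sorted(map(key, alignments))


class TestComputeCoverage:
    def _genome(self, n=300):
        return generate_genome(max(n, 1000), 0.5, seed=4, genome_id="C")

    def test_disjoint_halves(self):
        g = GenomeRecord("C", [generate_genome(1000, 0.5, seed=4).contigs[0][:300]])
        ref = build_reference([g])
        alns = [
            AlignmentRecord("r1", "C", 0, 0, 150, 150),
            AlignmentRecord("r2", "C", 0, 150, 150, 150),
        ]
        (p,) = compute_coverage(alns, ref, total_reads=2)
        assert p.breadth_pct == 100.0
        assert p.mean_depth == 1.0

    def test_half_covered(self):
        g = GenomeRecord("C", [generate_genome(1000, 0.5, seed=4).contigs[0][:300]])
        ref = build_reference([g])
        (p,) = compute_coverage([AlignmentRecord("r1", "C", 0, 0, 150, 150)], ref, total_reads=1)
        assert p.breadth_pct == 50.0
        assert p.mean_depth == 0.5
        assert p.mapped_read_pct == 100.0

    def test_naive_counting_oracle(self):
        # exact agreement with per-position counting on a small instance
        rng = np.random.default_rng(8)
        g = generate_genome(5000, 0.5, seed=5, genome_id="C")
        g.masked_intervals[:] = [(0, 1000, 1500)]
        ref = build_reference([g])
        alns = [
            AlignmentRecord(f"r{i}", "C", 0, int(rng.integers(0, 4850)), 150, 150)
            for i in range(60)
        ]
        (p,) = compute_coverage(alns, ref, total_reads=80)
        depth = np.zeros(5000, dtype=int)
        for a in alns:
            for pos in range(a.start, a.start + 150):
                depth[pos] += 1
        unmasked = np.ones(5000, dtype=bool)
        unmasked[1000:1500] = False
        assert p.breadth_pct == 100.0 * (depth[unmasked] >= 1).sum() / unmasked.sum()
        assert p.mean_depth == depth[unmasked].sum() / unmasked.sum()
        assert p.mapped_read_pct == 100.0 * 60 / 80

    def test_fully_masked_genome_warns(self):
        g = generate_genome(1000, 0.5, seed=5, genome_id="C")
        g.masked_intervals[:] = [(0, 0, 1000)]
        ref = build_reference([g])
        with pytest.warns(UserWarning):
            (p,) = compute_coverage([], ref, total_reads=0)
        assert p.breadth_pct == 0.0

    def test_out_of_bounds_alignment(self, genome_small):
        ref = build_reference([genome_small])
        with pytest.raises(DataError):
            compute_coverage(
                [AlignmentRecord("r", "Gsmall", 0, 4950, 150, 150)], ref, total_reads=1
            )

    def test_read_conservation(self, genome_200k):
        reads = simulate_single(genome_200k, depth=0.3, seed=41)
        ref = build_reference([genome_200k])
        alignments = map_reads(reads, ref)
        profiles = compute_coverage(alignments, ref, total_reads=len(reads))
        assert sum(p.mapped_reads for p in profiles) <= len(reads)
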