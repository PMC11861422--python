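import numpy as np
import pytest

from aquadetect import (
    CommunityDesign,
    build_reference,
    generate_genome,
    simulate_metagenome,
)


@pytest.fixture(scope="session")
def genome_200k():
    return generate_genome(200_000, 0.42, seed=11, genome_id="G200")


@pytest.fixture(scope="session")
def genome_small():
    return generate_genome(5_000, 0.5, seed=13, genome_id="Gsmall")


def truth_breadth(reads, genome) -> float:
    """Oracle: coverage breadth (%) computed from the reads' truth labels.

    Counts covered positions directly from recorded (contig, start) origins,
    independent of the mapper.
    """
    covered = [np.zeros(len(c), dtype=bool) for c in genome.contigs]
    for r in reads.reads:
        if r.truth_genome_id != genome.genome_id:
            continue
        covered[r.truth_contig][r.truth_start: r.truth_start + len(r.sequence)] = True
    return 100.0 * sum(int(c.sum()) for c in covered) / genome.total_length


def simulate_single(genome, depth, read_length=150, seed=0, error_rate=0.0):
    """Reads from one genome at a target mean depth."""
    n = max(1, int(round(depth * genome.total_length / read_length)))
    design = CommunityDesign(
        members=[(genome.genome_id, 1.0)],
        n_reads=n,
        read_length=read_length,
        substitution_error_rate=error_rate,
        seed=seed,
    )
    return simulate_metagenome(design, [genome])


@pytest.fixture(scope="session")
def mapped_depth12(genome_200k):
    """Deeply covered single-genome metagenome, mapped: shared by the
    subsampling/calibration tests."""
    from aquadetect import map_reads

    reads = simulate_single(genome_200k, depth=12, seed=21)
    ref = build_reference([genome_200k])
    alignments = map_reads(reads, ref)
    return reads, ref, alignments
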