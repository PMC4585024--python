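import numpy as np
import pandas as pd
import pytest

from virasm import (
    build_ideal_assembly,
    generate_genomes,
    inherit_taxonomy,
    sample_abundances,
    simulate_paired_reads,
)
from virasm.types import Contig, ContigAssembly, Read


def make_assembly(contig_reads, unassembled=()):
    """Build a ContigAssembly from [(gi, start, end), ...] per contig."""
    contigs = []
    rid = 0
    for k, members in enumerate(contig_reads):
        reads = []
        for gi, s, e in members:
            reads.append(Read(f"r{rid:05d}", gi, s, e))
            rid += 1
        contigs.append(Contig(contig_id=f"c{k:04d}", members=reads))
    una = {}
    for gi, s, e in unassembled:
        una[f"r{rid:05d}"] = Read(f"r{rid:05d}", gi, s, e)
        rid += 1
    return ContigAssembly(contigs=contigs, unassembled=una)


@pytest.fixture(scope="session")
def small_dataset():
    """20 genomes, skewed profile, ~2000 read pairs with provenance."""
    genomes = generate_genomes(20, (2_000, 8_000), seed=11)
    profile = sample_abundances(20, "power_law", alpha=1.0, gis=[g.gi for g in genomes])
    reads, prov = simulate_paired_reads(
        genomes, profile, 2_000, read_len=300, insert=(500, 50),
        error_rate=0.0, qc_loss=0.0, seed=11,
    )
    return genomes, profile, reads, prov


@pytest.fixture(scope="session")
def small_ideal(small_dataset):
    genomes, profile, reads, prov = small_dataset
    return build_ideal_assembly(prov, genomes.lengths)


@pytest.fixture(scope="session")
def small_taxonomy(small_dataset):
    genomes = small_dataset[0]
    return inherit_taxonomy(genomes.taxonomy_table())


def brute_force_interval_union(intervals):
    """Oracle: exhaustive pairwise merging of half-open intervals.

    Any two intervals sharing at least one base merge; repeat to a
    fixpoint. Touching intervals (a.end == b.start) share no base and
    stay separate.
    """
    spans = [list(i) for i in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                a, b = spans[i], spans[j]
                if a[0] < b[1] and b[0] < a[1]:
                    spans[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    del spans[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(s) for s in spans)


def brute_force_n50(lengths):
    """Oracle: scan every candidate length for the half-total condition."""
    total = sum(lengths)
    for cand in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= cand) >= total / 2:
            return cand
    raise AssertionError("unreachable")
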