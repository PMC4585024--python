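"""Per-genome coverage, fragmentation, and penalized-coverage spectra.

The fragmentation (completeness) score of a genome with fragments of
lengths l_1..l_n on a genome of length L is

    F = (sum_i l_i / L) / n,   clamped to [0, 1],

so a single full-length fragment scores 1 and many short scattered
fragments score near 0. Coverage C of a species is the total read bases
attributable to it over its genome length, and the penalized coverage
P = C * F deflates coverage for incomplete, scattered reconstructions.

Fragments of a genome are the contigs assigned to it (by modal species
of their member reads) plus, by default, each unassembled read of the
genome as a fragment of its own length; a contigs-only policy is
available via ``unassembled_as_fragments=False``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ContigAssembly


def genome_fragmentation(fragment_lengths, genome_length: int) -> float:
    """Completeness score F = (sum l_i / L) / n in [0, 1]."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    lengths = list(fragment_lengths)
    if not lengths:
        raise ValueError("fragmentation of a genome with no fragments is undefined")
    if any(l > genome_length for l in lengths):
        raise ValueError("fragment longer than its genome")
    f = (sum(lengths) / genome_length) / len(lengths)
    return float(min(1.0, max(0.0, f)))


def _fragments_by_genome(
    assembly: ContigAssembly, unassembled_as_fragments: bool = True
) -> dict[str, list[int]]:
    frags: dict[str, list[int]] = {}
    for c in assembly.contigs:
        frags.setdefault(c.modal_gi(), []).append(c.length)
    if unassembled_as_fragments:
        for r in assembly.unassembled.values():
            frags.setdefault(r.gi, []).append(r.length)
    return frags


def _genomes_in_dataset(assembly: ContigAssembly) -> set[str]:
    """Distinct species with at least one read (assembled or not)."""
    return {r.gi for r in assembly.iter_reads()}


def species_fragmentation(
    assembly: ContigAssembly,
    genome_lengths: dict[str, int],
    unassembled_as_fragments: bool = True,
) -> dict[str, float]:
    """Per-genome F over every species present in the dataset.

    A species whose reads all vanished from the fragment set (possible
    under the contigs-only policy) scores 0: total absence is maximal
    loss of information.
    """
    frags = _fragments_by_genome(assembly, unassembled_as_fragments)
    out = {}
    for gi in sorted(_genomes_in_dataset(assembly)):
        if gi not in genome_lengths:
            raise ValueError(f"no genome length for {gi}")
        lengths = frags.get(gi, [])
        # contig consensus may exceed L only via grafted foreign reads; cap
        lengths = [min(l, genome_lengths[gi]) for l in lengths]
        out[gi] = genome_fragmentation(lengths, genome_lengths[gi]) if lengths else 0.0
    return out


def mean_fragmentation(
    assembly: ContigAssembly,
    genome_lengths: dict[str, int],
    unassembled_as_fragments: bool = True,
) -> float:
    """Sum of genome fragmentations over the number of distinct species
    present in the dataset."""
    per_gi = species_fragmentation(assembly, genome_lengths, unassembled_as_fragments)
    if not per_gi:
        raise ValueError("no species with reads")
    return float(np.mean(list(per_gi.values())))


def species_coverage(
    assembly: ContigAssembly, genome_lengths: dict[str, int]
) -> dict[str, float]:
    """C_g = (read bases in contigs assigned to g + unassembled read bases
    of g) / genome length."""
    bases: dict[str, int] = {}
    for c in assembly.contigs:
        gi = c.modal_gi()
        bases[gi] = bases.get(gi, 0) + c.read_bases
    for r in assembly.unassembled.values():
        bases[r.gi] = bases.get(r.gi, 0) + r.length
    out = {}
    for gi in sorted(_genomes_in_dataset(assembly)):
        if gi not in genome_lengths:
            raise ValueError(f"no genome length for {gi}")
        out[gi] = bases.get(gi, 0) / genome_lengths[gi]
    return out


def penalized_coverage(coverage: float, fragmentation: float) -> float:
    """P = C x F; F = 1 leaves coverage untouched, F = 0 voids it."""
    if not 0.0 <= fragmentation <= 1.0:
        raise ValueError("fragmentation must be in [0, 1]")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    return coverage * fragmentation


def contig_coverage_spectrum(assembly: ContigAssembly) -> pd.Series:
    """Per-contig coverage vector, indexed by contig id in contig order."""
    from .assembly_metrics import contig_coverages

    if not assembly.contigs:
        raise ValueError("assembly has no contigs")
    return pd.Series(
        contig_coverages(assembly), index=[c.contig_id for c in assembly.contigs]
    )


def species_spectra(
    assembly: ContigAssembly,
    genome_lengths: dict[str, int],
    unassembled_as_fragments: bool = True,
) -> pd.DataFrame:
    """Per-species panel: coverage, fragmentation, penalized coverage,
    fragment count, genome length. One row per species in the dataset."""
    cov = species_coverage(assembly, genome_lengths)
    frag = species_fragmentation(assembly, genome_lengths, unassembled_as_fragments)
    nfrag = _fragments_by_genome(assembly, unassembled_as_fragments)
    rows = []
    for gi in sorted(cov):
        rows.append(
            {
                "gi": gi,
                "coverage": cov[gi],
                "fragmentation": frag[gi],
                "penalized_coverage": penalized_coverage(cov[gi], frag[gi]),
                "n_fragments": len(nfrag.get(gi, [])),
                "genome_length": genome_lengths[gi],
            }
        )
    return pd.DataFrame(rows).set_index("gi")
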