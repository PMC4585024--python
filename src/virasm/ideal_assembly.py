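"""Best-attainable ("ideal") assembly from known read coordinates.

Reads are grouped by origin genome, coordinate-sorted, and merged into
contig-like structures wherever consecutive reads overlap. Half-open
intervals that merely touch (next start == current end) share no base
and do NOT merge.
"""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import pandas as pd

from .types import Contig, ContigAssembly, Read, reads_from_provenance


def merge_sorted_reads(reads: list[Read]) -> list[list[Read]]:
    """Partition start-sorted reads into maximal overlap runs.

    A run extends while the next read starts strictly before the running
    maximum end. Input must already be sorted by (start, -end, read_id).
    """
    if not reads:
        return []
    runs: list[list[Read]] = [[reads[0]]]
    cur_end = reads[0].end
    for r in reads[1:]:
        if r.start < cur_end:
            runs[-1].append(r)
            cur_end = max(cur_end, r.end)
        else:
            runs.append([r])
            cur_end = r.end
    return runs


def build_ideal_assembly(
    provenance: pd.DataFrame, genome_lengths: dict[str, int]
) -> ContigAssembly:
    """Merge reads per genome into the best attainable contig set.

    Every read lands in a contig (an isolated read seeds a single-member
    contig), so the ideal assembly has no unassembled reads. Ties on
    start position break by end descending, then read id, making the
    output deterministic.
    """
    if provenance.empty:
        raise ValueError("provenance table is empty")
    reads = reads_from_provenance(provenance)
    by_gi: dict[str, list[Read]] = {}
    for r in reads:
        if r.gi not in genome_lengths:
            raise ValueError(f"no genome length for {r.gi} (read {r.read_id})")
        if not (0 <= r.start < r.end <= genome_lengths[r.gi]):
            raise ValueError(
                f"read {r.read_id} coordinates ({r.start},{r.end}) exceed "
                f"genome {r.gi} of length {genome_lengths[r.gi]}"
            )
        by_gi.setdefault(r.gi, []).append(r)

    contigs: list[Contig] = []
    k = 0
    for gi in sorted(by_gi):
        gi_reads = sorted(by_gi[gi], key=lambda r: (r.start, -r.end, r.read_id))
        for run in merge_sorted_reads(gi_reads):
            contigs.append(
                Contig(
                    contig_id=f"contig_{k:08d}",
                    members=run,
                    gi=gi,
                    start=run[0].start,
                    end=max(r.end for r in run),
                )
            )
            k += 1
    asm = ContigAssembly(contigs=contigs, unassembled={})
    asm.validate()
    return asm


def export_contigs(assembly: ContigAssembly, genomes, path) -> int:
    """Write ideal contigs as FASTA; sequence = genome substring of the span.

    Headers carry contig id, origin gi and span. Returns the number of
    records written; an empty assembly writes an empty file.
    """
    records = []
    for c in assembly.contigs:
        if c.gi is None or c.start is None or c.end is None:
            raise ValueError(f"contig {c.contig_id} lacks an ideal span")
        genome = genomes[c.gi]
        if not (0 <= c.start < c.end <= genome.length):
            raise ValueError(f"contig {c.contig_id} span outside genome {c.gi}")
        records.append(
            SeqRecord(
                Seq(genome.sequence[c.start : c.end]),
                id=c.contig_id,
                description=f"gi={c.gi} span={c.start}-{c.end}",
            )
        )
    return SeqIO.write(records, path, "fasta")
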