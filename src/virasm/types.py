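"""Core containers shared across the pipeline.

Coordinates are 0-based, half-open, and always expressed on the forward
strand of the origin genome, regardless of the strand a read was sequenced
from. Genomes are treated as linear: no read spans the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

PROVENANCE_COLUMNS = ["read_id", "mate", "gi", "start", "end", "strand"]


class Read(NamedTuple):
    """A sequenced read with its known origin on a reference genome."""

    read_id: str
    gi: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Contig:
    """A contig-like structure: a set of member reads with coordinates.

    ``gi``/``start``/``end`` describe the genomic span for ideal contigs;
    degraded or real contigs keep ``gi=None`` until classified by the modal
    species of their members.
    """

    contig_id: str
    members: list[Read]
    gi: str | None = None
    start: int | None = None
    end: int | None = None

    @property
    def n_reads(self) -> int:
        return len(self.members)

    @property
    def read_bases(self) -> int:
        return sum(r.length for r in self.members)

    @property
    def length(self) -> int:
        """Consensus length: merged-interval span of the members, summed per
        origin genome (a chimeric contig contributes one block per species)."""
        total = 0
        by_gi: dict[str, list[Read]] = {}
        for r in self.members:
            by_gi.setdefault(r.gi, []).append(r)
        for reads in by_gi.values():
            intervals = sorted((r.start, r.end) for r in reads)
            cur_s, cur_e = intervals[0]
            for s, e in intervals[1:]:
                if s < cur_e:
                    cur_e = max(cur_e, e)
                else:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
            total += cur_e - cur_s
        return total

    def modal_gi(self) -> str:
        """Origin species holding the plurality of member reads.

        Ties break lexicographically for determinism.
        """
        counts: dict[str, int] = {}
        for r in self.members:
            counts[r.gi] = counts.get(r.gi, 0) + 1
        return min(counts, key=lambda g: (-counts[g], g))


@dataclass
class ContigAssembly:
    """Contigs plus the reads that did not assemble.

    Every read of the dataset appears in exactly one contig or in the
    unassembled set; ``unassembled`` maps read id -> Read so that
    unassembled sequences keep their provenance for coverage accounting.
    """

    contigs: list[Contig]
    unassembled: dict[str, Read] = field(default_factory=dict)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def n_member_reads(self) -> int:
        return sum(c.n_reads for c in self.contigs)

    @property
    def n_reads(self) -> int:
        return self.n_member_reads + len(self.unassembled)

    def iter_reads(self) -> Iterable[Read]:
        for c in self.contigs:
            yield from c.members
        yield from self.unassembled.values()

    def validate(self) -> None:
        seen: set[str] = set()
        for r in self.iter_reads():
            if r.read_id in seen:
                raise ValueError(f"read {r.read_id} appears more than once")
            seen.add(r.read_id)
        ids = [c.contig_id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError("contig ids are not unique")


def reads_from_provenance(provenance: pd.DataFrame) -> list[Read]:
    """Materialize per-read records from a provenance table.

    The table carries one row per retained read (both mates), with the
    columns of :data:`PROVENANCE_COLUMNS`. Read ids are made unique per
    mate as ``<read_id>/<mate>``.
    """
    missing = [c for c in PROVENANCE_COLUMNS if c not in provenance.columns]
    if missing:
        raise ValueError(f"provenance table missing columns: {missing}")
    return [
        Read(f"{row.read_id}/{row.mate}", row.gi, int(row.start), int(row.end))
        for row in provenance.itertuples(index=False)
    ]
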