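"""Readers/writers for the pipeline's interchange formats.

Native synthetic-run interchange is a provenance TSV (ground truth needs
no alignment step); SAM/BAM ingestion exists for real-data mode, where
reads were mapped back to assembled contigs. All coordinates in files
are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import pysam
import yaml

from .types import PROVENANCE_COLUMNS, Contig, ContigAssembly, Read


def write_provenance(provenance: pd.DataFrame, path) -> None:
    provenance.to_csv(path, sep="\t", index=False, columns=PROVENANCE_COLUMNS)


def read_provenance(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "gi": str, "strand": str})
    missing = [c for c in PROVENANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"provenance file missing columns: {missing}")
    return df


def write_fastq_pair(reads: pd.DataFrame, path1, path2) -> None:
    """Write the two mate files (Sanger/Phred+33 qualities)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for row in reads.itertuples(index=False):
            fh = f1 if row.mate == 1 else f2
            fh.write(f"@{row.read_id}/{row.mate}\n{row.sequence}\n+\n{row.quality}\n")


def read_alignments(path, provenance: pd.DataFrame | None = None) -> ContigAssembly:
    """Build a ContigAssembly from read-to-contig alignments (SAM/BAM).

    Only primary alignments assign reads to contigs; secondary and
    supplementary records are ignored; unmapped reads go to the
    unassembled set. When a provenance table is supplied, origin species
    (gi) and forward-strand genome coordinates attach to each read so
    chimera and coverage metrics can be computed; without it, reads keep
    the contig coordinates of their alignment and a placeholder species.
    """
    prov_idx: dict[str, tuple[str, int, int]] = {}
    if provenance is not None:
        for row in provenance.itertuples(index=False):
            prov_idx[f"{row.read_id}/{row.mate}"] = (row.gi, int(row.start), int(row.end))

    members: dict[str, list[Read]] = {}
    unassembled: dict[str, Read] = {}
    seen: set[str] = set()
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            name = aln.query_name
            if aln.is_paired:
                name = f"{name}/{1 if aln.is_read1 else 2}"
            if name in seen:
                raise ValueError(f"duplicate primary alignment for read {name}")
            seen.add(name)
            if name in prov_idx:
                gi, start, end = prov_idx[name]
            else:
                gi = "unknown"
                start = aln.reference_start if not aln.is_unmapped else 0
                end = aln.reference_end if not aln.is_unmapped else (aln.query_length or 1)
                end = end if end and end > start else start + (aln.query_length or 1)
            read = Read(name, gi, start, end)
            if aln.is_unmapped:
                unassembled[name] = read
            else:
                members.setdefault(aln.reference_name, []).append(read)
    contigs = [
        Contig(contig_id=ref, members=reads) for ref, reads in sorted(members.items())
    ]
    asm = ContigAssembly(contigs=contigs, unassembled=unassembled)
    asm.validate()
    return asm


def load_taxonomy(path) -> pd.DataFrame:
    """Taxonomy TSV: gi, species, genus, family, order (blank = missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("gi")
    return df


def write_taxonomy(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


@dataclass
class RunConfig:
    """Parameters of a full synthetic evaluation run.

    Persisting this object re-runs the pipeline to identical outputs.
    """

    seed: int = 0
    n_genomes: int = 100
    genome_length: tuple[int, int] = (3_000, 300_000)
    abundance_model: str = "power_law"
    abundance_alpha: float = 1.0
    n_pairs: int = 25_000
    read_len: int = 300
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    error_rate: float = 0.001
    qc_loss: float = 0.015
    degradation_grid: list[dict] = field(default_factory=list)
    chimera_threshold: float = 0.9
    unassembled_as_fragments: bool = True
    outdir: str = "virasm_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.genome_length = tuple(cfg.genome_length)
        return cfg

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["genome_length"] = list(self.genome_length)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
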