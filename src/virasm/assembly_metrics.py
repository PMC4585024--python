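"""Per-assembly statistics panel: contig lengths, read usage, chimera rates.

The chimera rule follows a 90% plurality criterion: a contig is
chimera-free at a taxonomic rank iff at least 90% of its member reads
belong to a single taxon at that rank. Viral taxonomies are patchy, so
missing ranks are first filled by inheriting the nearest defined
neighboring rank with an ``n_`` prefix per step, which keeps genuinely
unclassified taxa distinguishable from one another.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .types import ContigAssembly

RANKS = ["species", "genus", "family", "order"]
CHIMERA_LEVELS = ["gi"] + RANKS


@dataclass
class AssemblyStats:
    n50: float
    largest_contig: float
    num_contig: int
    pct_reads_assembled: float
    mean_contig_coverage: float
    pct_chim_gi: float
    pct_chim_species: float
    pct_chim_genus: float
    pct_chim_family: float
    pct_chim_order: float
    mean_fragmentation: float

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


def n50(contig_lengths) -> int:
    """Length at which descending-sorted contigs reach half the total bases."""
    lengths = sorted((int(x) for x in contig_lengths), reverse=True)
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2.0
    acc = 0
    for x in lengths:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def contig_coverages(assembly: ContigAssembly) -> list[float]:
    """Per-contig coverage: member-read bases / consensus contig length."""
    out = []
    for c in assembly.contigs:
        L = c.length
        if L <= 0:
            raise ValueError(f"contig {c.contig_id} has zero length")
        if c.n_reads == 0:
            raise ValueError(f"contig {c.contig_id} has no member reads")
        out.append(c.read_bases / L)
    return out


def mean_contig_coverage(assembly: ContigAssembly) -> float:
    covs = contig_coverages(assembly)
    if not covs:
        raise ValueError("assembly has no contigs")
    return float(np.mean(covs))


def pct_reads_assembled(assembly: ContigAssembly) -> float:
    total = assembly.n_reads
    if total == 0:
        raise ValueError("assembly holds no reads at all")
    return 100.0 * assembly.n_member_reads / total


def inherit_taxonomy(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing ranks from the nearest defined rank, ``n_`` per step.

    ``table`` is indexed by gi with columns species/genus/family/order
    (missing entries None/NaN). For each hole the nearest defined rank
    below (more specific) wins; ties go below; a fill k steps away gets k
    ``n_`` prefixes. Idempotent. A gi with every rank missing is refused.
    """
    out = table.copy()
    for c in RANKS:
        if c not in out.columns:
            raise ValueError(f"taxonomy table lacks rank column {c!r}")
    for gi, row in out.iterrows():
        defined = [i for i, c in enumerate(RANKS) if pd.notna(row[c])]
        if not defined:
            raise ValueError(f"gi {gi} has no defined rank to inherit from")
        for i, c in enumerate(RANKS):
            if pd.notna(row[c]):
                continue
            below = [j for j in defined if j < i]
            above = [j for j in defined if j > i]
            j = max(below) if below else min(above)
            out.at[gi, c] = "n_" * abs(i - j) + str(row[RANKS[j]])
    return out


def chimera_rates(
    assembly: ContigAssembly, taxonomy: pd.DataFrame, threshold: float = 0.9
) -> dict[str, float]:
    """Percentage of chimeric contigs at gi/species/genus/family/order level.

    A contig is chimera-free at a level iff its modal taxon holds at
    least ``threshold`` of the member reads; unassembled reads are not
    counted. Requires an inherited taxonomy (no missing labels).
    """
    if not assembly.contigs:
        raise ValueError("chimera rates of an empty assembly are undefined")
    if taxonomy[RANKS].isna().any().any():
        raise ValueError("taxonomy has missing labels; run inherit_taxonomy first")
    label_maps = {"gi": None}
    for r in RANKS:
        label_maps[r] = taxonomy[r].to_dict()

    chimeric = dict.fromkeys(CHIMERA_LEVELS, 0)
    for c in assembly.contigs:
        gis = [r.gi for r in c.members]
        for level in CHIMERA_LEVELS:
            mapping = label_maps[level]
            labels = gis if mapping is None else [mapping[g] for g in gis]
            top = Counter(labels).most_common(1)[0][1]
            if top / len(labels) < threshold:
                chimeric[level] += 1
    n = assembly.n_contigs
    return {lvl: 100.0 * k / n for lvl, k in chimeric.items()}


def compute_assembly_stats(
    assembly: ContigAssembly,
    taxonomy: pd.DataFrame,
    genome_lengths: dict[str, int],
    chimera_threshold: float = 0.9,
    unassembled_as_fragments: bool = True,
) -> AssemblyStats:
    """Fill the whole statistics panel for one assembly."""
    from .spectra import mean_fragmentation  # avoid import cycle

    lengths = [c.length for c in assembly.contigs]
    chim = chimera_rates(assembly, taxonomy, threshold=chimera_threshold)
    return AssemblyStats(
        n50=n50(lengths),
        largest_contig=max(lengths),
        num_contig=assembly.n_contigs,
        pct_reads_assembled=pct_reads_assembled(assembly),
        mean_contig_coverage=mean_contig_coverage(assembly),
        pct_chim_gi=chim["gi"],
        pct_chim_species=chim["species"],
        pct_chim_genus=chim["genus"],
        pct_chim_family=chim["family"],
        pct_chim_order=chim["order"],
        mean_fragmentation=mean_fragmentation(
            assembly, genome_lengths, unassembled_as_fragments=unassembled_as_fragments
        ),
    )


def aggregate_stats(stats: dict[str, AssemblyStats]) -> pd.DataFrame:
    """Mean and SD of every statistic over a set of assemblies."""
    df = pd.DataFrame({name: s.as_series() for name, s in stats.items()}).T
    return pd.DataFrame({"mean": df.mean(axis=0), "sd": df.std(axis=0, ddof=0)})
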