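"""Synthetic viral metagenome generation with known read provenance.

Emulates the study design the pipeline evaluates: hundreds of viral
genomes with a skewed (power-law) species abundance distribution,
fixed-length paired-end reads (2 x 300 bp by default) with i.i.d.
substitution errors, and a small quality-control loss applied to whole
pairs (~1.5% of reads). Every retained read carries a provenance record
(origin genome, forward-strand coordinates, strand) that downstream
stages use as ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .types import PROVENANCE_COLUMNS, Contig, ContigAssembly, Read
from .ideal_assembly import merge_sorted_reads

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")

RANKS = ["species", "genus", "family", "order"]


def revcomp(seq: str) -> str:
    return seq.encode()[::-1].translate(_COMPLEMENT).decode()


@dataclass
class Genome:
    """A reference viral genome keyed by a unique GI-style identifier."""

    gi: str
    sequence: str
    taxonomy: dict[str, str | None] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.gi} has empty sequence")


class GenomeSet:
    """An ordered collection of genomes with unique GIs."""

    def __init__(self, genomes: list[Genome]):
        gis = [g.gi for g in genomes]
        if len(gis) != len(set(gis)):
            raise ValueError("duplicate GI in genome set")
        self.genomes = list(genomes)
        self._by_gi = {g.gi: g for g in genomes}

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self):
        return iter(self.genomes)

    def __getitem__(self, gi: str) -> Genome:
        return self._by_gi[gi]

    def __contains__(self, gi: str) -> bool:
        return gi in self._by_gi

    @property
    def lengths(self) -> dict[str, int]:
        return {g.gi: g.length for g in self.genomes}

    def taxonomy_table(self) -> pd.DataFrame:
        """Five-rank taxonomy as a DataFrame indexed by gi (labels may be
        missing/None)."""
        rows = {g.gi: [g.taxonomy.get(r) for r in RANKS] for g in self.genomes}
        return pd.DataFrame.from_dict(rows, orient="index", columns=RANKS).rename_axis("gi")


def _synthetic_taxonomy(
    n: int, rng: np.random.Generator, missing_frac: float
) -> list[dict[str, str | None]]:
    # Nested hierarchy: ~2 species/genus, 3 genera/family, 3 families/order.
    out: list[dict[str, str | None]] = []
    for i in range(n):
        genus_i, family_i, order_i = i // 2, i // 6, i // 18
        tax: dict[str, str | None] = {
            "species": f"Species_{i:04d}",
            "genus": f"Genus_{genus_i:04d}",
            "family": f"Family_{family_i:04d}",
            "order": f"Order_{order_i:04d}",
        }
        # Viral taxonomy is patchiest at order and genus level.
        if rng.random() < missing_frac:
            tax["order"] = None
        if rng.random() < missing_frac:
            tax["genus"] = None
        out.append(tax)
    return out


def generate_genomes(
    n_genomes: int,
    length_distribution: tuple[int, int] = (3_000, 300_000),
    seed: int | None = None,
    read_len: int = 300,
    missing_rank_frac: float = 0.15,
) -> GenomeSet:
    """Generate random genomes with uniform base composition.

    Lengths are uniform on ``[min, max]``; taxonomy labels come from a
    nested synthetic five-rank hierarchy with a fraction of order/genus
    labels left missing, to exercise rank inheritance downstream.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    lo, hi = length_distribution
    if lo > hi:
        raise ValueError("length_distribution min must be <= max")
    if lo < read_len:
        raise ValueError(
            f"minimum genome length {lo} is shorter than the read length "
            f"{read_len}; no read could be placed"
        )
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genomes)
    taxa = _synthetic_taxonomy(n_genomes, rng, missing_rank_frac)
    genomes = []
    for i, (L, tax) in enumerate(zip(lengths, taxa)):
        seq = rng.choice(_BASES, size=int(L)).tobytes().decode()
        genomes.append(Genome(gi=f"gi_{i:06d}", sequence=seq, taxonomy=tax))
    return GenomeSet(genomes)


def sample_abundances(
    n_species: int,
    model: str = "power_law",
    alpha: float = 1.0,
    seed: int | None = None,
    gis: list[str] | None = None,
) -> dict[str, float]:
    """Draw a relative-abundance profile over ``n_species`` species.

    ``power_law`` assigns rank i the weight i**(-alpha) before
    normalization (rank order shuffled over species when a seed is given
    and gis are supplied in non-rank order is not needed; ranks follow gi
    order for determinism). ``uniform`` gives every species 1/n.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if gis is None:
        gis = [f"gi_{i:06d}" for i in range(n_species)]
    if len(gis) != n_species:
        raise ValueError("gis length must equal n_species")
    if model == "uniform":
        w = np.ones(n_species)
    elif model == "power_law":
        if alpha < 0:
            raise ValueError("power-law alpha must be >= 0")
        w = np.arange(1, n_species + 1, dtype=float) ** (-alpha)
    else:
        raise ValueError(f"unknown abundance model: {model!r}")
    w = w / w.sum()
    return dict(zip(gis, w.tolist()))


def load_abundances(path) -> dict[str, float]:
    """Load a two-column species/abundance TSV and renormalize to sum 1.

    Zero-abundance rows are dropped with a warning (they can emit no
    reads); duplicate ids or non-numeric abundances are refused with the
    offending row index.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str}, comment="#")
    if df.shape[1] < 2:
        raise ValueError("abundance table needs two columns: id, abundance")
    ids = df.iloc[:, 0].astype(str)
    raw = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = raw.index[raw.isna()]
    if len(bad):
        raise ValueError(f"non-numeric abundance at row {bad[0]}")
    if (raw < 0).any():
        row = raw.index[raw < 0][0]
        raise ValueError(f"negative abundance at row {row}")
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate id {dup.iloc[0]!r} at row {dup.index[0]}")
    zero = raw == 0
    if zero.any():
        logger.warning("dropping %d zero-abundance row(s)", int(zero.sum()))
        ids, raw = ids[~zero], raw[~zero]
    if raw.empty:
        raise ValueError("abundance table has no positive rows")
    w = raw / raw.sum()
    return dict(zip(ids, w))


def bundled_profile_path():
    """Path to the bundled synthetic 578-species abundance table.

    A synthetic stand-in for a gut-virome species-abundance profile:
    578 species with power-law (alpha=1) relative abundances.
    """
    return resources.files("virasm").joinpath("data/species_abundance_synthetic.tsv")


def simulate_paired_reads(
    genomes: GenomeSet,
    profile: dict[str, float],
    n_pairs: int,
    read_len: int = 300,
    insert: tuple[float, float] = (500.0, 50.0),
    error_rate: float = 0.0,
    qc_loss: float = 0.015,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate 2 x ``read_len`` paired-end reads from an abundance profile.

    Returns ``(reads, provenance)``: one row per retained read in both.
    ``reads`` carries read_id, mate, sequence, quality; ``provenance``
    the PROVENANCE_COLUMNS ground truth. Fragment genomes are drawn from
    the profile, fragment starts uniformly over valid positions; mate 1
    is the forward fragment start, mate 2 the reverse complement of the
    fragment end. Substitutions are i.i.d. at ``error_rate``. A fraction
    ``qc_loss`` of PAIRS is removed at the end (both mates; no
    singletons), flooring to whole pairs.
    """
    if not profile:
        raise ValueError("empty abundance profile")
    if not 0 <= qc_loss < 1:
        raise ValueError("qc_loss must be in [0, 1)")
    gis = sorted(profile)
    missing = [g for g in gis if g not in genomes]
    if missing:
        raise ValueError(f"profile species absent from genome set: {missing[:3]}")
    for g in gis:
        if genomes[g].length < read_len:
            raise ValueError(f"genome {g} shorter than read length")

    rng = np.random.default_rng(seed)
    p = np.array([profile[g] for g in gis])
    p = p / p.sum()
    gi_idx = rng.choice(len(gis), size=n_pairs, p=p)
    mean_ins, sd_ins = insert
    frags = rng.normal(mean_ins, sd_ins, size=n_pairs)

    reads_rows = []
    prov_rows = []
    qual = "I" * read_len
    for k in range(n_pairs):
        gi = gis[gi_idx[k]]
        genome = genomes[gi]
        L = genome.length
        frag = int(round(frags[k]))
        frag = max(read_len, min(frag, L))  # clamp insert to the genome
        start = int(rng.integers(0, L - frag + 1))
        end = start + frag
        pid = f"pair{k:08d}"
        # mate 1: forward, fragment start
        s1, e1 = start, start + read_len
        seq1 = genome.sequence[s1:e1]
        # mate 2: reverse complement of the fragment end
        s2, e2 = end - read_len, end
        seq2 = revcomp(genome.sequence[s2:e2])
        if error_rate > 0:
            seq1 = _mutate(seq1, error_rate, rng)
            seq2 = _mutate(seq2, error_rate, rng)
        reads_rows.append((pid, 1, seq1, qual))
        reads_rows.append((pid, 2, seq2, qual))
        prov_rows.append((pid, 1, gi, s1, e1, "+"))
        prov_rows.append((pid, 2, gi, s2, e2, "-"))

    n_keep = math.floor(n_pairs * (1.0 - qc_loss))
    if n_keep < n_pairs:
        keep = np.sort(rng.choice(n_pairs, size=n_keep, replace=False))
    else:
        keep = np.arange(n_pairs)
    rows = [i for k in keep for i in (2 * k, 2 * k + 1)]
    reads = pd.DataFrame(
        [reads_rows[i] for i in rows],
        columns=["read_id", "mate", "sequence", "quality"],
    )
    prov = pd.DataFrame(
        [prov_rows[i] for i in rows], columns=PROVENANCE_COLUMNS
    )
    return reads, prov


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if len(hits) == 0:
        return seq
    # substitute with one of the three alternative bases
    for i in hits:
        alts = _BASES[_BASES != arr[i]]
        arr[i] = alts[rng.integers(0, 3)]
    return arr.tobytes().decode()


def goodness_of_fit(observed, expected) -> tuple[float, float]:
    """Chi-squared goodness of fit on raw category counts."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    stat, p = stats.chisquare(observed, expected)
    return float(stat), float(p)


def verify_abundance(
    provenance: pd.DataFrame, profile: dict[str, float]
) -> tuple[float, float]:
    """Chi-squared test that simulated reads match the abundance profile.

    Counts are taken per FRAGMENT (pair): both mates of a pair always come
    from the same genome, so counting reads would double the statistic and
    invalidate the null calibration. Expected counts are profile x number
    of pairs, over every profile species (including unobserved ones).
    """
    if len(profile) < 2:
        raise ValueError("need >= 2 species for a goodness-of-fit test")
    pairs = provenance[provenance["mate"] == 1]
    counts = pairs["gi"].value_counts()
    unknown = set(counts.index) - set(profile)
    if unknown:
        raise ValueError(f"provenance species absent from profile: {sorted(unknown)[:3]}")
    gis = sorted(profile)
    obs = np.array([counts.get(g, 0) for g in gis], dtype=float)
    total = obs.sum()
    p = np.array([profile[g] for g in gis])
    exp = total * p / p.sum()
    return goodness_of_fit(obs, exp)


def degrade_assembly(
    ideal: ContigAssembly,
    split_rate: float = 0.0,
    loss_rate: float = 0.0,
    chimera_rate: float = 0.0,
    seed: int | None = None,
    chimera_block_frac: float = 0.2,
) -> ContigAssembly:
    """Emulate real-assembler degradation of an ideal assembly.

    Three independent error modes, applied in order: each read is dropped
    with ``loss_rate`` (dropped reads become unassembled); each internal
    read junction of each remaining contig is cut with ``split_rate``
    (sub-contigs are rebuilt by the overlap-merge rule on the surviving
    read subsets); each resulting contig, with probability
    ``chimera_rate``, receives a block of reads grafted from a contig of
    a different species. Deterministic for a fixed seed.
    """
    for name, r in [("split_rate", split_rate), ("loss_rate", loss_rate), ("chimera_rate", chimera_rate)]:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)

    unassembled: dict[str, Read] = dict(ideal.unassembled)
    pieces: list[list[Read]] = []
    for contig in ideal.contigs:
        survivors = []
        for r in contig.members:
            if loss_rate > 0 and rng.random() < loss_rate:
                unassembled[r.read_id] = r
            else:
                survivors.append(r)
        if not survivors:
            continue
        survivors.sort(key=lambda r: (r.start, -r.end, r.read_id))
        # cut junctions, then re-merge each segment (losses may have
        # broken overlaps inside a segment)
        segments: list[list[Read]] = [[survivors[0]]]
        for r in survivors[1:]:
            if split_rate > 0 and rng.random() < split_rate:
                segments.append([r])
            else:
                segments[-1].append(r)
        for seg in segments:
            for merged in merge_sorted_reads(seg):
                pieces.append(merged)

    if chimera_rate > 0 and len(pieces) > 1:
        gi_of = [Contig("tmp", p).modal_gi() for p in pieces]
        order = rng.permutation(len(pieces))
        for i in order:
            recipient = pieces[i]
            if not recipient or rng.random() >= chimera_rate:
                continue
            donors = [
                j
                for j in range(len(pieces))
                if j != i and pieces[j] and gi_of[j] != gi_of[i]
            ]
            if not donors:
                continue
            j = donors[rng.integers(0, len(donors))]
            donor = pieces[j]
            block = min(len(donor), max(1, math.ceil(chimera_block_frac * len(recipient))))
            start = int(rng.integers(0, len(donor) - block + 1))
            grafted = donor[start : start + block]
            del donor[start : start + block]
            recipient.extend(grafted)

    contigs = [
        Contig(contig_id=f"contig_{k:08d}", members=p)
        for k, p in enumerate(pieces)
        if p
    ]
    out = ContigAssembly(contigs=contigs, unassembled=unassembled)
    out.validate()
    return out
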