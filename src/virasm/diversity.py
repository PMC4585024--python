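"""Alpha diversity under contig-as-OTU versus species-as-OTU accounting.

Counting every contig as its own operational taxonomic unit (OTU)
overestimates diversity relative to grouping sequences by their species
of origin (GI), because fragmentation splits one species into many
contigs. Both accountings are computed here from the same assembly:

* contig mode — each contig is an OTU weighted by its member read count
  (unassembled reads count as singleton OTUs by default, mirroring the
  coverage accounting of contigs-plus-unassembled sequences);
* gi mode — each species is an OTU whose weight sums the contigs
  assigned to it (modal species of member reads) plus its unassembled
  reads.

The contig partition refines the species partition, so contig-mode
Shannon entropy and richness can never fall below the gi-mode values.

Estimators: Shannon entropy H = -sum p_i log_b p_i; Chao1
S_obs + n1^2/(2 n2) with the standard bias-corrected fallback when no
doubletons exist; ACE with the rare set at <= 10 observations; and the
plain observed species number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ContigAssembly

RARE_CUTOFF = 10


def shannon(weights, base: float = math.e) -> float:
    """H = -sum p_i log_b p_i over nonzero weights."""
    w = np.asarray(list(weights), dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("all-zero spectrum")
    p = w / w.sum()
    return float(-(p * (np.log(p) / math.log(base))).sum())


def spec_number(counts) -> int:
    """Number of OTUs observed at least once."""
    c = np.asarray(list(counts))
    return int((c > 0).sum())


def chao1(counts) -> float:
    """S_obs + n1^2 / (2 n2); bias-corrected S_obs + n1(n1-1)/2 if n2 = 0."""
    c = _as_counts(counts)
    s_obs = int((c > 0).sum())
    n1 = int((c == 1).sum())
    n2 = int((c == 2).sum())
    if n2 > 0:
        return s_obs + n1 * n1 / (2.0 * n2)
    return s_obs + n1 * (n1 - 1) / 2.0


def ace(counts, rare_cutoff: int = RARE_CUTOFF) -> float:
    """Abundance-based coverage estimator.

    Rare OTUs are those with <= ``rare_cutoff`` observations (consistent
    with the k = 1..10 summations of the coverage and variation terms).
    Returns S_obs when nothing is rare, and NaN when the estimator is
    undefined (every rare OTU a singleton, so sample coverage is 0).
    """
    c = _as_counts(counts)
    c = c[c > 0]
    rare = c[c <= rare_cutoff]
    s_rare = rare.size
    s_rest = int((c > rare_cutoff).sum())
    if s_rare == 0:
        return float(s_rest)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return float("nan")
    ssum = sum(k * (k - 1) * int((rare == k).sum()) for k in range(1, rare_cutoff + 1))
    gamma2 = max((s_rare / c_ace) * ssum / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    return s_rest + s_rare / c_ace + (f1 / c_ace) * gamma2


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(list(counts))
    if c.size and not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("count-based estimators need integer counts")
        c = np.round(c).astype(int)
    if c.size and (c < 0).any():
        raise ValueError("counts must be non-negative")
    return c


def otu_weights(
    assembly: ContigAssembly,
    mode: str,
    weighting: str = "reads",
    include_unassembled: bool = True,
) -> pd.Series:
    """OTU abundance weights for one assembly.

    ``mode``: 'contig' (each contig an OTU; unassembled reads singleton
    OTUs when included) or 'gi' (species OTUs by modal-species contig
    assignment plus unassembled reads). ``weighting``: 'reads' (member
    read counts, integer) or 'coverage' (per-contig coverage; contig
    mode only, Shannon only downstream).
    """
    if mode not in ("contig", "gi"):
        raise ValueError(f"unknown OTU mode {mode!r}")
    if weighting not in ("reads", "coverage"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "coverage":
        if mode != "contig":
            raise ValueError("coverage weighting is defined for contig mode only")
        from .assembly_metrics import contig_coverages

        w = {c.contig_id: cov for c, cov in zip(assembly.contigs, contig_coverages(assembly))}
        if include_unassembled:
            for r in assembly.unassembled.values():
                w[r.read_id] = 1.0
        return pd.Series(w, dtype=float)

    w: dict[str, float] = {}
    if mode == "contig":
        for c in assembly.contigs:
            w[c.contig_id] = c.n_reads
        if include_unassembled:
            for r in assembly.unassembled.values():
                w[r.read_id] = 1
    else:
        for c in assembly.contigs:
            gi = c.modal_gi()
            w[gi] = w.get(gi, 0) + c.n_reads
        if include_unassembled:
            for r in assembly.unassembled.values():
                w[r.gi] = w.get(r.gi, 0) + 1
    if not w:
        raise ValueError("assembly yields no OTUs")
    return pd.Series(w, dtype=float)


def contig_spectrum_phaccs(
    assembly: ContigAssembly, include_unassembled: bool = True
) -> tuple[dict[int, int], float]:
    """Contig spectrum (q -> number of contigs made of q reads) and the
    mean contig length, the latter for the PHACCS ``genlengths`` input."""
    if not assembly.contigs and not (include_unassembled and assembly.unassembled):
        raise ValueError("empty assembly has no contig spectrum")
    spectrum: dict[int, int] = {}
    for c in assembly.contigs:
        spectrum[c.n_reads] = spectrum.get(c.n_reads, 0) + 1
    if include_unassembled and assembly.unassembled:
        spectrum[1] = spectrum.get(1, 0) + len(assembly.unassembled)
    genlengths = float(np.mean([c.length for c in assembly.contigs])) if assembly.contigs else 0.0
    return dict(sorted(spectrum.items())), genlengths


def write_phaccs_spectrum(spectrum: dict[int, int], path) -> None:
    """Write a contig spectrum in PHACCS text form: one count per line,
    line q holding the number of contigs with q reads."""
    qmax = max(spectrum)
    with open(path, "w") as fh:
        for q in range(1, qmax + 1):
            fh.write(f"{spectrum.get(q, 0)}\n")


@dataclass
class DiversityReport:
    assembly_id: str
    mode: str
    weighting: str
    shannon: float
    chao1: float
    ace: float
    spec_number: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "assembly": self.assembly_id,
                "mode": self.mode,
                "weighting": self.weighting,
                "shannon": self.shannon,
                "chao1": self.chao1,
                "ace": self.ace,
                "spec_number": self.spec_number,
            }
        )


def diversity_report(
    assembly: ContigAssembly,
    mode: str,
    weighting: str = "reads",
    assembly_id: str = "assembly",
    include_unassembled: bool = True,
) -> DiversityReport:
    """All four estimators under one OTU accounting.

    Chao1/ACE are count-based; requesting coverage weights for them is
    refused (Shannon alone admits coverage weighting).
    """
    w = otu_weights(assembly, mode, "reads", include_unassembled)
    if weighting == "coverage":
        h = shannon(otu_weights(assembly, mode, "coverage", include_unassembled))
    else:
        h = shannon(w)
    return DiversityReport(
        assembly_id=assembly_id,
        mode=mode,
        weighting=weighting,
        shannon=h,
        chao1=chao1(w),
        ace=ace(w),
        spec_number=spec_number(w),
    )
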