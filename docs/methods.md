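# Methods

`virasm` evaluates how well a viral-metagenome assembly reconstructs the
community it came from, and how the assembly's quality distorts
alpha-diversity estimates. Because real assemblies lack ground truth, the
package works from simulated reads whose origin (genome, coordinates,
strand) is recorded, builds the best assembly those reads admit, and then
degrades it in controlled ways.

## Read simulation

Reads are fixed-length paired-end (default 2 x 300 bp, the Illumina MiSeq
V3 regime). For each fragment a genome is drawn from a relative-abundance
profile, a fragment length from a normal insert distribution (default
mean 500 bp, SD 50 bp, clamped to [read length, genome length]), and a
start position uniformly over valid positions. Mate 1 reads the fragment
start on the forward strand; mate 2 is the reverse complement of the
fragment end. Genomes are linear: no fragment spans the origin. All
coordinates are 0-based half-open on the forward strand, for both mates.

Sequencing error is i.i.d. substitution at a configurable rate with flat
quality strings; indels, homopolymer artifacts and GC/amplification bias
are not modeled. Quality-control loss removes a fraction (default 1.5%)
of whole pairs uniformly at random, flooring to whole pairs — no
singletons survive, matching paired-end filtering practice.

Abundance profiles are either uniform, power-law (rank i weighted
i^-alpha, normalized), or loaded from a two-column TSV. The bundled
`data/species_abundance_synthetic.tsv` is a synthetic stand-in for a
gut-virome profile: 578 species with power-law (alpha = 1) abundances.

Simulation fidelity is checked with a chi-squared goodness of fit of
per-species counts against the profile. Counts are taken per fragment
(pair), not per read: mates are perfectly correlated, so a read-level
test would double the statistic and its p-values would not be uniform
under the null.

## Ideal assembly

Per genome, reads are sorted by start (ties: end descending, then read
id) and merged while the next read starts strictly before the running
maximum end. Touching half-open intervals share no base and do not
merge. Every read lands in a contig; the ideal assembly therefore
assembles 100% of reads and its contig spans are exactly the pairwise
interval union of the read intervals (verified against a brute-force
oracle in the tests).

## Degradation model

Real assemblers fragment genomes, discard reads, and join reads across
species. Rather than running external assemblers, `degrade_assembly`
applies the three failure modes directly to the ideal assembly:

1. read loss — each read independently dropped with `loss_rate`
   (dropped reads become unassembled);
2. splitting — each internal read junction of each contig cut with
   `split_rate`; sub-contigs are rebuilt by the overlap-merge rule, so
   `split_rate = 1` isolates every read;
3. chimera grafting — each contig, with probability `chimera_rate`,
   receives a contiguous block of reads moved from a contig of a
   different species. The block is ceil(0.2 x recipient reads), capped
   at the donor's size, so the grafted fraction (~1/6 of the result)
   exceeds the 10% chimera threshold and the measured chimera rate
   responds to the dial.

All randomness flows from one seed; identical seeds give identical
assemblies.

## Assembly statistics

The panel comprises N50 (first descending-sorted length at which the
cumulative sum reaches half the total), largest contig, contig count,
percent reads assembled, mean contig coverage (per contig, member-read
bases over consensus length, averaged unweighted), chimera percentages
at five taxonomic levels, and the mean fragmentation score.

Degraded or real contigs have no single genomic span; their consensus
length is the merged-interval span of their member reads, summed per
origin species for chimeric contigs. For pure contigs this reduces to
the ideal span rule.

A contig is chimera-free at a level iff its modal taxon holds at least
90% of member reads (configurable threshold; the boundary 9/10 counts as
chimera-free). Because the species-to-genus-to-family-to-order map is
nested, coarsening the rank can only lower the chimera percentage.
Missing taxonomy labels are first filled by inheritance: a hole takes
the nearest defined rank (more-specific rank wins ties) prefixed with
one `n_` per step, so unclassified taxa remain distinguishable — e.g. a
family of *Poxviridae* with no order yields the order `n_Poxviridae`,
and a genus G under missing family and order yields `n_G` / `n_n_G`.

## Coverage, fragmentation, penalized coverage

For a genome with fragments l_1..l_n on length L:

* fragmentation F = (Σ l_i / L) / n, clamped to [0,1] — 1 for a single
  complete fragment, near 0 for many small scattered ones; splitting any
  fragment strictly decreases F;
* coverage C = total read bases attributable to the genome / L;
* penalized coverage P = C x F, deflating coverage for incomplete,
  scattered reconstructions (P = C iff F = 1).

Fragments of a genome are the contigs assigned to it (modal species of
member reads) plus, by default, each unassembled read of the genome as a
fragment of its own length; `unassembled_as_fragments=False` restricts
to contigs. The mean fragmentation of an assembly averages F over every
species with at least one read in the dataset; species whose fragments
all vanished score 0 and stay in the denominator. Coverage likewise uses
read bases (not consensus lengths), keeping its meaning as sequencing
depth.

## Alpha diversity

Shannon entropy (natural log by default), Chao1, ACE, and the observed
species number are computed under two OTU accountings. In contig mode
every contig is an OTU weighted by its member read count, and each
unassembled read is a singleton OTU (configurable); in gi mode each
species' weight sums its contigs and unassembled reads. The contig
partition therefore refines the species partition, which makes the
central inequality — contig-mode H and S never below the gi-mode values
— exact rather than merely statistical.

Chao1 uses the classic S_obs + n1²/(2 n2); with no doubletons it falls
back to the bias-corrected S_obs + n1(n1-1)/2 rather than divide by
zero. ACE treats OTUs with ≤ 10 observations as rare (consistent with
its k = 1..10 summations; a strict-< cutoff is available), returns S_obs
when nothing is rare, and is reported as NaN when all rare OTUs are
singletons (sample coverage 0). The implementation agrees with
scikit-bio's estimators to 1e-9 on random count vectors (tested).

The contig spectrum (count of contigs composed of q reads, for each q)
is exported in the simple text form the PHACCS tool ingests, together
with the mean contig length for its `genlengths` parameter; the
power-law fitting inside PHACCS is not re-implemented.

## Comparison and association

Coverage and penalized-coverage profiles are compared with Bray-Curtis
distances; fragmentation profiles with Hellinger distances (Euclidean on
square-rooted, row-normalized vectors). Assemblies are clustered with
average linkage; bootstrap support of an internal node is the fraction
of column-resampled (species-resampled) replicates reproducing its leaf
set — plain bootstrap probabilities, not multiscale AU values.
Note a subtlety of the Hellinger row normalization: when the ideal
assembly is itself fragmented (shallow depth), heavily split assemblies
converge in profile *shape* and their distance to the ideal is not
monotone in the split rate; the monotonicity property holds in the
deep-coverage regime (ideal mean F near 1), which is where the
corresponding test operates.

Group comparisons use Kruskal-Wallis with Benjamini-Hochberg q-values
(significance at q < 0.05 throughout). The association of the nine
assembly statistics with a diversity estimator uses three methods:
Spearman correlation (support: q < 0.05), a Gaussian GLM with L1 (lasso)
penalty chosen by cross-validation on standardized predictors (support:
nonzero coefficient), and random-forest permutation importance computed
on held-out folds — the % increase in out-of-fold MSE when a predictor
is permuted, normalized by the response variance (support: importance
z-score > 2). Held-out (rather than in-bag) evaluation keeps the null
calibrated: on pure noise the forest otherwise flags every feature it
overfits on. A predictor supported by ≥ 2 of 3 methods is
consensus-flagged.

## Problem sizes and defaults

Defaults mirror the study design: 2 x 300 bp reads, 1.5% QC pair loss,
power-law abundances, and the three depth scenarios (0.05 / 0.5 / 5 M
reads) reachable through `n_pairs` (25 k / 250 k / 2.5 M pairs). The
test suite and the acceptance script exercise the same machinery on
smaller communities (20-100 genomes of 2-30 kb, 2-30 k pairs, 30-assembly
degradation grids), sizes at which every qualitative claim above is
already observable while a run stays desktop-friendly.

## Limitations

* The degradation model is a stochastic caricature of assembler error;
  it reproduces fragmentation, read loss and chimerism rates, not any
  particular assembler's graph-driven error structure.
* Synthetic genomes are i.i.d. uniform sequence; there are no repeats,
  so the ideal assembly is better-posed than on real viral genomes and
  absolute statistic values are not comparable to published ones — the
  package's claims are about orderings and relationships, which the
  tests assert.
* The substitution-only error model ignores indels and quality decay
  along the read.
* ACE is undefined (NaN) when every rare OTU is a singleton; downstream
  aggregation must tolerate that.
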