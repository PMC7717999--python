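# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `gstprofiler`. Problem sizes quoted below are the package's
defaults for desk-scale analysis and testing.

## Strain types on a core-genome phylogeny

A **GST** (genome-based strain type) is a clade of isolate genomes whose
all-against-all pairwise SNV distance on the core-genome reference stays
below a cap. Clustering is greedy: the current clade starts at a seed leaf
(first the type strain, afterwards the highest-priority unclustered
genome) and is repeatedly replaced by its parent clade — absorbing the
sister subtree — while (a) every leaf of the enlarged clade is still
unclustered and (b) the maximum pairwise distance in the enlarged clade is
*strictly below* the cap. The frozen clades partition the leaves, each is
connected, and GST labels follow creation order.

Choices the procedure leaves open, fixed here:

* **Rooting.** "Sister" and "parent" need a root. Rooted input trees are
  used as-is; the neighbor-joining helper for synthetic pipelines roots at
  the midpoint. Results on real data can depend on the rooting.
* **Merge refusal.** A merge that would absorb already-clustered leaves is
  refused even when the distance condition holds, preserving the
  partition property implied by sequential clustering.
* **Tie-breaks.** Genome priority is (assembly level, −N50, id); equal
  priorities resolve lexicographically, so outputs are deterministic but
  can differ from other implementations on tied inputs.
* **Threshold scale.** The cap is an absolute SNV count and therefore
  tied to the core length: 20,000 SNVs on a ~1.1 Mb core is ~1.8%
  divergence. Synthetic configurations keep the analogous ratio (e.g. a
  cap of 200 on a ~55 kb core); using an absolute cap with a much shorter
  core would change the meaning of a GST.

The core reference concatenates the type strain's core genes in
lexicographic family order (the order is otherwise arbitrary; fixing it
makes coordinates reproducible), 1-based positions. The SNV caller
anchors each core gene by family id and compares copies positionally —
exact for the indel-free generator. Real-data users supply variant tables
(TSV: genome_id, position, ref, alt) produced by their own aligner;
re-implementing whole-genome alignment is out of scope. Positions inside
a gene missing from either genome are excluded from a pairwise distance —
absence is not a single-nucleotide variation — and two genomes sharing the
same alternate allele at a position do not differ there.

## k-mer LCA classification and abundance

The database maps every canonical k-mer (k = 31, odd so canonicalization
by lexicographically smaller strand is unambiguous) of the GST
representatives' core genes to the LCA of the GSTs carrying it, on the
taxonomy obtained by collapsing GST clades to leaves, suppressing unary
nodes and attaching a species root. Reads are scored per root-to-leaf
path (sum of hit counts on path nodes); the read takes the deepest node
of the best path, ties resolve to the LCA of the tied paths' deepest
nodes, zero hits means unclassified. No k-mer spans an ambiguous base;
reads shorter than k are unclassified; the confidence threshold is 0.

Abundance re-estimation redistributes each internal node's read count to
its descendant GST leaves proportionally to the leaves' direct counts
(uniformly when all are zero), then normalizes over leaves. This is a
deliberate simplification of Bayesian k-mer-derived redistribution
probabilities: it preserves the fixed point when leaf assignments
dominate, conserves the classified total exactly, and is fully testable
without per-database read simulation. A sample with zero classified reads
yields an explicitly flagged empty profile, not a zero vector.

## Pan-genome

Greedy incremental clustering: CDSs are visited longest-first (gene-id
tie-break) and join the first (oldest) cluster whose representative they
match at ≥90% identity over ≥90% of **both** sequences, otherwise found a
new cluster. Identity is matches/columns of a banded edit-distance
alignment (edlib, infix mode with the shorter sequence as query);
"bidirectional coverage" is the aligned span over each sequence's full
length, so a fragment covering 80% of a family representative is not a
hit at any identity. An exact 15-mer candidate filter restricts which
representatives are aligned; at the 90% identity floor matching pairs
always share seed 15-mers, so the filter changes no result at these
scales. Core families must appear in strictly more than 95% of genomes
(19 of 20 genomes is 95% exactly and is **not** core); singletons have
exactly one member. An optional decoy-genome exclusion drops clusters
containing members from non-target-species genomes, standing in for
species-specificity filtering of the full database.

## Host association

Sample filters are strict removals (<20,000 classified reads or <500 gene
hits). Host groups are dominant-GST groups of size >5; dominant-GST ties
break to the smallest label and are flagged. Fisher's exact test
(scipy) is two-sided with an added directionality requirement — a
host-specific gene must be *more* prevalent inside the group — because
two-sided p-values alone would also flag depletion. No multiple-testing
correction by default (matching the plain p < 0.01 rule); Benjamini–
Hochberg is available but off. An optional minimum-prevalence filter
(default off) can exclude genes seen in very few samples.

Weighted UniFrac is the raw variant, Σ_b ℓ_b |A_b − B_b| over branches,
with a normalized option (divide by Σ_b ℓ_b (A_b + B_b)); branch lengths
come from the supplied GST tree (NJ lengths for synthetic pipelines).
PERMANOVA is one-way, free label permutation, pseudo-F from among/within
sums of squared distances, p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) with
9,999 permutations by default and a caller-supplied seed. Both omnibus and
pairwise-group variants are exposed, as either analysis design is
defensible. Note that with small balanced designs a sampled permutation
occasionally reproduces the observed grouping, so the attainable minimum
p is 1/(1+n_perm) only up to that coincidence.

## MAGs

Completeness and contamination are inputs, not estimated here (marker-set
estimation is orthogonal to this package). Tiers: high = completeness
>90 and contamination <5; medium = completeness ≥50 and contamination
<10; otherwise rejected. Species assignment uses fragment-based
reciprocal ANI: both genomes are cut into 1,020 bp fragments, each
fragment is mapped to the other genome (contig joins are masked with Ns
so no alignment bridges them), reciprocal best pairs contribute their
mean identity, and membership requires ANI > 95%. With no reciprocal
pairs the ANI is undefined and the MAG is not a member.

Placement replaces likelihood-based tree insertion with the mean pairwise
SNV distance to each GST's members, restricted to core positions the MAG
covers; the clade cap is scaled by the covered fraction before deciding
"outside all GSTs", and placement is refused below 10% core coverage.
This reproduces the qualitative within-clade / outside-clade behavior
deterministically at desk scale; it is not an evolutionary placement.
Novel genes are MAG CDSs with no 90/90 pan-genome hit, clustered at the
same thresholds into novel families (fresh ids, disjoint from pan-genome
cluster ids; the contract also excludes any novel family already recorded
in the sample's matched profile, which the id scheme makes vacuous).

## Synthetic data

The generator emulates a clonal, host-adapted species:

* One ancestral genome: `n_genes` genes (lengths uniform in
  `gene_length_range`, default 600–1,500 bp) separated by evenly split
  intergenic spacers up to `genome_length` (default 0.5 Mb, ~400 genes —
  a 1/4-scale bacterial genome).
* Each of `n_gsts` GST ancestors receives `between_gst_snv` substitutions
  at GST-private core positions, so any cross-GST pair differs at ≥
  2×`between_gst_snv` sites; each strain adds `within_gst_snv // 2`
  private substitutions, so within-GST pairs differ at ≤ `within_gst_snv`
  sites. Substitutions are drawn without replacement from core-gene
  positions only, so SNV distance equals Hamming distance on aligned core
  genes and the calling oracle is exact. An infeasible budget fails
  loudly rather than clamping.
* `accessory_fraction` (default 0.15) of ancestral families are
  accessory: each GST retains each with probability 1/2, and gains
  `novel_genes_per_gst` (default 2, ≥1 enforced) private novel families
  of random sequence. Content is clonal within a GST, which gives clean
  planted truth for host-specific gene testing; per-sample dropout can be
  layered on top where noise is wanted.
* Reads: uniform starts, random strand, per-base substitution errors at
  `error_rate` (<5%), constant Q30 qualities, ids carrying no origin
  information (truth is returned separately). Paired-end emission is a
  flag that changes nothing downstream. Abundance draws are log-normal
  (σ=1) or exponential, alternating across cohort samples; cohort samples
  contain ~5 GSTs each (the low-complexity design) with an optional
  dominant GST receiving 50–90% of the mass.
* Pseudo-assembly: a Lander–Waterman coverage model — uniform read starts
  at the requested fold coverage; maximal covered runs are contigs,
  contigs <500 bp are dropped, true gene intervals clipped to contigs
  with fragments <100 bp dropped are the "predicted" CDSs.

What the generator does **not** emulate: realistic Illumina error
profiles, indels, recombination, host-DNA contamination, plasmids,
assembly chimeras, or inter-species reads. Passing accuracy suites
therefore demonstrate correctness of the algorithms under clonal,
substitution-only evolution with well-separated strain types — the regime
the method assumes — not robustness to those real-data complications.

## Problem sizes and determinism

Default test/validation scales: 12 genomes × 0.5 Mb for gene-profile
TPR/F1 (5× and 10× coverage), 10–20k reads per sample for classification
accuracy, 200 random (tree, distance) instances for the clustering-rule
replay, 200 null datasets (12 samples, 499 permutations) for PERMANOVA
calibration. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configuration and seed reproduce
byte-identical FASTA/FASTQ output.
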