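# Methods

This note documents the models, parameter choices, numerical details and
known limitations of each stage. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Homology screen

Protein homology is assessed by optimal Smith–Waterman local alignment
under BLOSUM62 with affine gaps, executed by Biopython's exact
`PairwiseAligner`. Gap penalties follow the BLAST convention — a gap of
length L costs `open + extend·L`, with defaults open = 11, extend = 1 —
mapped onto the aligner as `open_gap_score = −(open+extend)`,
`extend_gap_score = −extend`. The unknown residue X is tolerated and
scored 0 against everything (the matrix is patched accordingly). An
independently coded brute-force affine DP oracle in the test suite
confirms score agreement on random pairs.

Two summary percentages are computed over the full local-alignment
length (gap columns included, the BLAST tabular convention):
**identity** (exact matches; this is what the distribution matrix
displays) and **similarity** (positive-scoring pairs, BLAST
"positives"; this is what the acceptance filter uses). Query coverage
is the aligned query span over query length.

Expectation values use the Karlin–Altschul form `E = K·m·n·e^(−λS)`
with documented, overridable constants K = 0.041, λ = 0.267 (ungapped
BLOSUM62 regime) and n = total residues in the searched proteome. The
gapped-regime corrections of a production BLAST are deliberately out of
scope; the constants only need to rank and filter hits consistently.
The acceptance filter is inclusive on similarity (≥ 40%) and coverage
(≥ 70%) and strict on the E-value (< 10⁻⁴), mirroring how the cut-offs
are phrased ("40% of similarity" attained vs "< 0.0001").

MCL follows the classical alternation of expansion (matrix squaring)
and inflation (elementwise power, default 2.0, then column
normalization), with unit self-loops added internally, convergence when
the matrix changes by < 10⁻⁶, and a 100-iteration cap. Clusters are
read off the converged matrix by assigning each node to its strongest
attractor and merging attractors that share members, which guarantees a
disjoint, exhaustive partition.

## Cluster presence calling

A genome carries an intact *rib* operon when (i) all four biosynthetic
queries (RibD/E/AB/H) have passing hits, (ii) the four subject genes
are co-located — same contig, within a window of ≤ 10 consecutive
annotated genes (configurable) — and (iii) their mean percent
similarity is strictly above 40%. "Same genomic region" has no formal
definition in comparative-genomics practice; a 10-gene window admits an
operon with a few intervening ORFs while rejecting scattered paralogs.
The subject gene order is recorded for inspection but not enforced,
since operon rearrangements would not abolish biosynthetic capacity.
Absence is a verdict, not an error.

The distribution matrix holds best-hit percent identity (0 where no hit
passes) with an isolation-niche label per row; two-way hierarchical
clustering uses average linkage on Euclidean distances. Rows are sorted
by label before linkage so the dendrogram is invariant to input order
and distance ties resolve deterministically.

## Phylogenetics and entanglement

Distances are p-distances with pairwise deletion (sites where either
sequence is gapped are skipped per pair); Jukes–Cantor correction is
available behind a flag but is not the default, as the desk-scale
divergences involved stay well below saturation. Gene alignments are
concatenated end-to-end with gap-filling for missing taxa.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion with Studier–Keppler updates, deterministic tie-breaking on
the lexicographically smallest label pair, and negative branch-length
estimates clamped to zero with a warning. On additive matrices NJ is an
exact reconstruction, which the suite verifies against both hand-built
matrices and `skbio.tree.nj`. Bootstrap supports resample alignment
columns with replacement and score each reference bipartition by its
replicate frequency (default 100 replicates, seeded).

The entanglement score of two trees over the same leaf set is the mean
absolute difference of leaf ranks between the two drawn leaf orders,
divided by the maximum achievable mean displacement for n leaves (n/2
for even n, (n²−1)/(2n) for odd — attained by the reversal
permutation), after minimizing over child-order flips of internal
nodes. When the combined internal-node count is at most 16 the
minimization is exhaustive (and therefore exactly symmetric in its
arguments); larger trees use repeated greedy single-flip sweeps over
both trees until no flip improves, still deterministic and seed-free.
The exhaustive small-tree path was chosen over a purely greedy
definition so that the score is a well-defined optimum rather than a
heuristic artifact at the scales where exactness is affordable. Note
that rotation optimization makes some intuitively "reversed" pairs
score 0 — flipping every internal node of a caterpillar tree reverses
its entire leaf order — so a score of 1 requires genuinely
incompatible constraints, not just reversed input orders.

## Riboswitch analysis

The 5′-UTR is the 500 bases immediately upstream of the target gene on
its coding strand (reverse-complemented for minus-strand genes),
truncated with a warning at contig edges. Motif detection is a literal
scan for the antiterminator (TTCAGGGC) and the two anti-antiterminators
(CATCTTC, GAAGATG) with an optional Hamming-mismatch fallback (default
tolerance 0; exact hits always rank first). A covariance-model or
secondary-structure search is deliberately not attempted: the
regulatory elements are specified as literal sequences and the package
targets their coordinates, not RNA folding. Scanning is on the given
strand only, since the UTR is already oriented 5′→3′ relative to the
regulated gene.

Point mutations are mapped by positionwise comparison of equal-length
sequences (the mutant set contains no indels, so a length mismatch is
an input error), classified as transition (purine↔purine or
pyrimidine↔pyrimidine) or transversion, and assigned the region of the
motif span containing their position, else "other".

The synthetic wild-type UTR places CATCTTC at 70–76, GAAGATG at
102–108 and TTCAGGGC at 130–137 and pins the documented wild-type base
at every mutant-table coordinate; position 105 (the strongest
overproducer's mutation) thereby falls inside an anti-antiterminator
span, and positions 102/105 both do. Which further mutants fall inside
regulatory elements is a fixture choice, not an assertion.

Conservation profiles report per-column base frequencies (normalized
over non-gap characters) and information content IC = 2 − H bits, with
all-gap columns flagged and assigned IC 0.

## Expression

qPCR fold changes use 2^(−ΔΔCt): technical replicates are averaged per
sample and gene, ΔCt = Ct(target) − mean Ct of the reference genes
(arithmetic mean over groEL and gyrA, equivalent to a geometric mean of
reference expression — standard dual-reference practice), ΔΔCt
contrasts group means against the calibrator, and the SD propagates the
replicate ΔCt spread onto the fold scale by the delta method.
Swapping test and calibrator inverts the fold exactly.

The count stage is a transparent re-implementation, not a shrinkage
clone of a production DGE package; it is validated by parameter
recovery on simulated data rather than by matching any package's
output. All-zero genes are discarded. Size factors are median-of-ratios
over genes with positive counts in every sample (library-size fallback
with a warning otherwise). Fold changes are ratios of normalized group
means with a 0.5 pseudocount. The test statistic is a Wald z on log2
normalized counts: each group's per-gene variance is the larger of the
observed sample variance and a delta-method prediction
`(α + 1/μ)/ln²2` from a common method-of-moments NB dispersion α
(median over genes of `(s²−μ)/μ²`, clipped at 0). Because that floor is
pooled across all genes rather than estimated from 2 samples, a normal
reference distribution is appropriate, and taking the maximum makes the
test conservative under the null — the suite verifies that the
significant fraction over 500 null matrices stays ≤ 5%. P-values are
BH-adjusted; the significance rule is FDR < 0.05 together with
log2FC > 3, one-sided for up-regulation by default with a symmetric
|log2FC| mode behind a flag.

## Kinetics and statistics

μ(t) = d ln OD/dt and dP/dt are central finite differences
(`np.gradient` on the possibly non-uniform grid) after optional
odd-window moving-average smoothing; maxima are taken over interior
points to avoid one-sided edge estimates. Finite differences were
chosen over parametric fits because they are assumption-free and
testable against closed-form derivatives of generated curves; a
sliding-window log-linear regression mode for μmax is also provided for
the classical exponential-phase fit. Rates are shift-invariant in time
and scale inversely with time units.

Bioassay quantification inverts a monotone piecewise-linear standard
curve (0–300 ng/mL range); responses below the lowest standard return
an explicit below-detection flag carrying the 0.2 ng/mL quantification
limit (never a zero), and responses above the top standard raise with a
suggestion to assay a higher dilution.

The two-way ANOVA uses type-II sums of squares (OLS fit; interaction
included when every cell has ≥ 2 replicates) with Tukey HSD on the
factor-cell means using studentized-range p-values and the pooled error
df. A constant response short-circuits to F = 0, p = 1 rather than a
0/0 NaN.

## Synthetic data

The generators are pure functions of a `GeneratorConfig` (fixed seed ⇒
identical output) and each returns a truth object for recovery tests.
Default scenario parameters mirror the study system: an 83-genome panel
with 16 carriers (mostly primate-associated), ribCF/ribU (and
rpoB/groEL) homologs in every genome, a 500-nt UTR with the seven
mutant coordinates, triplicate qPCR with 0.15-cycle noise, duplicate
RNA-seq with NB dispersion 0.05 and an 18-fold 4-gene cluster, logistic
growth at μmax 0.31 h⁻¹ toward carrying capacity 3.0 (the observed
final OD) with stationary phase at substrate exhaustion, and
Luedeking–Piret riboflavin formation whose analytic peak rate (αμK/4
for growth-associated formation) is set to 13.9 ng mL⁻¹ h⁻¹.

Protein divergence is planted by substituting a target fraction of
residues; substitutions are drawn from the positive-scoring BLOSUM62
pool with probability 0.5 (keeping similarity above identity — the two
statistics stay distinguishable) and uniformly otherwise. Decoy
clusters in some non-carriers are mutated to ~10% identity with
non-conservative substitutions so they must fail the filter. Query
protein lengths (140–240 aa) are compressed relative to the real
enzymes to keep a full-panel screen around ten seconds; count-matrix
gene means are log-uniform on (100, 5000) so the 0.5 pseudocount is
negligible against the planted fold. The acceptance script averages the
cluster-fold recovery over 25 replicate matrices to shrink Monte-Carlo
error on the reported mean; the suite's recovery test uses a single
matrix at the prescribed tolerance.

What the generators do **not** emulate — and hence what passing tests
do not show about real data: realistic sequence evolution (substitution
rates are i.i.d. across sites, no indels in proteins, no GC/codon
structure), genome-scale gene content (a dozen genes per genome),
read-level RNA-seq artifacts (the pipeline starts from counts),
between-gene dispersion trends, assay drift in qPCR, and diauxie or pH
effects in fermentation. Headline counts tied to the real RefSeq panel
(16 of 83 species; ~90 taxa in nr) are consequently scenario templates
for recovery tests, not reproduced facts.

## Limitations

- E-values use ungapped Karlin–Altschul constants; hit borders and
  E-values will not numerically match a production BLAST.
- The DGE stage has no per-gene dispersion shrinkage; with more
  replicates a dedicated package is preferable.
- The entanglement heuristic beyond the exhaustive regime is a local
  optimum; scores for trees with > 16 combined internal nodes are upper
  bounds on the optimal displacement.
- Bootstrap replicates that lose all comparable sites for a pair are
  skipped, slightly deflating supports on tiny alignments.
- The 5′-UTR extractor requires contig sequences in memory; it targets
  fixture-scale genomes, not chromosome-scale FASTA streaming.
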