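# riboscreen

Desk-scale analytics for riboflavin (vitamin B2) biosynthesis in
*Bifidobacterium*: where the *rib* operon occurs across the genus, how the
FMN riboswitch that regulates it is mutated in overproducing strains, and
how strongly deregulated mutants express and produce the vitamin.

Most bifidobacteria cannot synthesize riboflavin de novo and rely on
uptake (*ribU*) and conversion (*ribCF*); only a minority of species carry
the intact four-gene biosynthetic cluster *ribDEABH*. Spontaneous
roseoflavin-resistant mutants acquire single point mutations in the FMN
riboswitch upstream of *ribD* that break feedback repression and turn the
strain into a riboflavin overproducer. This package implements the full
analysis chain behind that biology, plus seeded synthetic-data generators
so every stage is testable without any external downloads.

## What it computes

- **Homology screen** (`homology`, `cluster_call`) — optimal
  Smith–Waterman local protein alignment (BLOSUM62, affine gaps),
  Karlin–Altschul expectation values `E = K·m·n·e^(−λS)`, the acceptance
  filter *similarity ≥ 40% over ≥ 70% of the query with E < 10⁻⁴*, and
  Markov clustering (MCL) of the similarity graph. A genome is called a
  *rib*-cluster carrier when all four query proteins (RibD, RibE, RibAB,
  RibH) have passing hits co-located within a ≤ 10-gene window on one
  contig and their mean similarity exceeds 40%. A per-genome × per-gene
  percent-identity matrix with two-way average-linkage clustering
  reproduces the distribution-heatmap ordering.
- **Phylogenetics** (`phylo`) — p-distances with pairwise deletion,
  neighbor joining (Saitou–Nei), column-bootstrap supports, and a
  quantitative tanglegram **entanglement** score in [0, 1]: the mean
  absolute leaf-rank displacement between two facing trees after
  rotation optimization, normalized by the maximal achievable mean
  displacement. Used to compare housekeeping (rpoB+groEL) against
  riboflavin-associated (ribU+ribCF) gene trees.
- **Riboswitch analysis** (`riboswitch`) — 500-nt 5′-UTR extraction
  upstream of *ribD*, literal-motif detection of the antiterminator
  (`TTCAGGGC`) and both anti-antiterminators (`CATCTTC`, `GAAGATG`),
  point-mutation mapping against the wild type, transition/transversion
  classification, and per-column conservation profiles (information
  content in bits).
- **Expression** (`expression`) — qPCR relative quantification by
  2^(−ΔΔCt) with dual reference genes (groEL, gyrA), and a transparent
  count-based differential-expression stage: median-of-ratios size
  factors, log2 fold changes of normalized group means, a Wald test on
  log2 counts with a pooled method-of-moments negative-binomial
  dispersion, Benjamini–Hochberg FDR, and the significance rule
  *FDR < 0.05 and log2FC > 3*.
- **Kinetics and statistics** (`kinetics_stats`) — specific growth rate
  μ(t) = d ln(OD)/dt and volumetric production rate dP/dt by central
  finite differences (closed-form-checkable), monotone calibration-curve
  quantification for the microbiological riboflavin assay (0–300 ng/mL,
  below-detection flagging at 0.2 ng/mL), two-way ANOVA with Tukey HSD,
  and summary statistics.
- **Synthetic data** (`synthetic_data`) — seeded generators for the
  83-species / 16-carrier pangenome with planted divergence and layout,
  the riboswitch mutant set matching the packaged mutant table, qPCR Ct
  tables, negative-binomial count matrices, logistic fermentation
  curves, and fecal donor tables — each with a machine-readable truth.

## Worked example

```python
from riboscreen.synthetic_data import GeneratorConfig, make_pangenome, \
    make_ct_table, make_timecourse
from riboscreen.cluster_call import CORE_QUERIES, best_hits, call_rib_cluster
from riboscreen.expression import ddct_fold_change
from riboscreen.kinetics_stats import specific_growth_rate, production_rate

config = GeneratorConfig(seed=1, panel_size=20, n_carriers=5)
panel, truth, queries = make_pangenome(config)
core = {name: queries[name] for name in CORE_QUERIES}
calls = [call_rib_cluster(g, best_hits(g, core)) for g in panel]
print(f"rib cluster present in {sum(c.present for c in calls)}/{len(panel)} genomes")

fc = ddct_fold_change(make_ct_table(config, target_fold=15.0), "ribD")
print(f"ribD fold change (2^-ddCt): {fc.fold:.2f} +/- {fc.sd:.2f}")

tc, _ = make_timecourse(GeneratorConfig(seed=1, sampling_interval=0.05))
print(f"mu_max = {specific_growth_rate(tc).max_rate:.3f} h^-1")
print(f"peak production = {production_rate(tc).max_rate:.2f} ng/mL/h")
```

prints

```
rib cluster present in 5/20 genomes
ribD fold change (2^-ddCt): 15.53 +/- 0.63
mu_max = 0.305 h^-1
peak production = 13.90 ng/mL/h
```

The screen recovers exactly the five planted carriers; the qPCR estimate
scatters around the injected 15-fold change because the default Ct table
carries 0.15-cycle Gaussian noise; the growth and production maxima land
on the generator's logistic parameters (μmax slightly below 0.31 h⁻¹
here, since interior-point logistic growth never quite attains μmax).

A command-line pipeline wraps the same functions:

```bash
riboscreen all --seed 0 --out-dir results/demo        # full synthetic demo
riboscreen screen --panel panel.tsv --queries queries.fasta --out-dir results/screen
riboscreen riboswitch --wt wt.fasta --variants variants.fasta --out-dir results/rs
```

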