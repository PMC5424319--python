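# codonpairs

Genome-scale association analysis between **inhibitory adjacent codon
pairs** and gene expression in *Saccharomyces cerevisiae*.

Seventeen adjacent codon pairs (CGA-CGA, AGG-CGA, CTG-ATA, ...) strongly
inhibit translation elongation in yeast reporter assays. This package
asks what that means for endogenous genes: is the content of these
pairs in a coding sequence associated with mRNA decay, mRNA synthesis,
translation efficiency or protein stability — and is any association
attributable to the codon pairs *as pairs*, rather than to correlated
sequence properties (GC content, codon optimality, encoded dipeptides,
coding length) or to the corresponding hexanucleotides regardless of
reading frame?

It is written for computational biologists who want to run or extend
this style of analysis on their own sequence/expression compendia, with
every statistical step exposed as a tested library function.

## What it computes

**Features** (per gene, from the CDS): in-frame inhibitory-pair count
and fraction (count/(L−1) over the L−1 adjacent sense-codon positions),
presence flag, hexamer occurrences in the +1/+2 shifted frames, 3'UTR
hexamer presence, gene-level tAI (geometric mean of per-codon relative
adaptiveness w), GC content, inhibitory-dipeptide fraction, coding
length, and the pair position for single-pair genes.

**Statistics**: Spearman and Kendall correlation and partial
correlation via the inverse covariance matrix,

    r_ij|S = − d_ij / (√d_ii √d_jj),   D = C⁻¹,

where C is the Pearson covariance of rank-transformed variables
(Spearman) or the sign covariance
c_ij = Σ_k Σ_l sign(x_ik − x_il)·sign(x_jk − x_jl) (Kendall).
Significance comes both from analytic t/normal statistics and from
permutation tests: the predictor is permuted N times and
P = (B+1)/(N+1) with B the number of permutations at least as extreme
as the observed coefficient (two-sided on |r| by default).

**Suites**: primary associations (marginal + covariate-controlled
partials), reading-frame and 3'UTR negative controls, the
codon-optimality suite including the zero-pair gene subset, the
position-effect analysis, and an unbiased scan of all 61×61 = 3721
sense-codon pairs with a rank-sum comparison of the 17 inhibitory pairs
against the 3704 others.

**Synthetic data**: a generator producing coding sequences, UTRs and
expression tables with planted, tunable effects under realistic
pair/optimality confounding, so the whole pipeline is testable with no
downloads. Real data plug in as FASTA + TSV (see `codonpairs features
--help`).

## Worked example

```python
from codonpairs import (
    AnalysisConfig, GeneratorConfig, PermutationConfig,
    generate_genes, generate_expression, run_primary_associations,
)

config = GeneratorConfig(n_genes=1000)          # study-shaped defaults
records, features = generate_genes(config, seed=7)
expression = generate_expression(features, config, seed=7)

analysis = AnalysisConfig(
    methods=("spearman",),
    permutation=PermutationConfig(n_permutations=1000, seed=7),
)
table = run_primary_associations(
    features, expression, analysis, dataset="sim", outcomes=("decay_rate",)
)
cols = ["predictor", "covariates", "coefficient", "permutation_p", "n"]
print(table[table.predictor == "pair_fraction"][cols].to_string(index=False))
```

prints

```
    predictor                              covariates  coefficient  permutation_p   n
pair_fraction                                             0.405703       0.000999 867
pair_fraction                                      gc     0.374871       0.000999 867
pair_fraction                                     tai     0.202219       0.000999 867
pair_fraction                      dipeptide_fraction     0.294184       0.000999 867
pair_fraction                           coding_length     0.404674       0.000999 867
pair_fraction gc+tai+dipeptide_fraction+coding_length     0.202559       0.000999 867
```

Reading it: the marginal Spearman correlation between inhibitory-pair
fraction and mRNA decay rate is ρ = +0.41 over the 867 genes with a
measured decay rate (pair-rich mRNAs decay faster). Controlling for
codon optimality (tAI) — which is confounded with pair content in this
generator, as in the real genome — attenuates the coefficient to
ρ ≈ +0.20, but it stays positive and at the permutation floor
P = 1/(N+1) ≈ 1.0E-03 at N = 1000: the association is not explained by
the covariates. The same run from a shell:

```bash
codonpairs simulate --out-dir sim --seed 7
codonpairs features --fasta sim/genome.fasta --weights sim/weights.tsv \
    --annotation sim/annotation.tsv --utr-fasta sim/utrs.fasta --out-dir feat
codonpairs associate --features feat/features.tsv \
    --expression sim/expression_sim_a.tsv --out-dir assoc --seed 7
```

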