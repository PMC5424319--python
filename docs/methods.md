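# Methods

## Scientific setting

In *Saccharomyces cerevisiae*, 17 adjacent codon pairs (e.g. CGA-CGA,
AGG-CGA) strongly inhibit translation elongation in reporter assays.
`codonpairs` implements a genome-scale association analysis asking
whether the content of these inhibitory pairs in coding sequences is
linked to mRNA synthesis and decay rates, translation efficiency
(protein per mRNA, ribosome occupancy) and protein stability — and
whether any such link is attributable to the pairs themselves rather
than to correlated sequence properties (GC content, codon optimality,
encoded dipeptides, coding length) or to the corresponding
hexanucleotides independent of reading frame.

## Feature definitions

For a coding sequence with L sense codons (terminal stop excluded,
start codon included):

* **pair count / fraction** — occurrences of member pairs at the L−1
  adjacent sense-codon positions; overlapping occurrences each count
  (CGA CGA CGA holds two CGA-CGA pairs). The fraction divides by L−1.
  This denominator convention reproduces published reporter arithmetic
  (3 pairs in a 59-codon construct → 3/58 = 5.2E-02).
* **frame +1/+2 counts** — occurrences of the member hexamers at
  nucleotide offsets ≡1 or ≡2 (mod 3) over the raw nucleotide string.
  The frame-0 hexamer scan may exceed the codon-pair count when a
  member hexamer overlaps the stop codon; the in-frame *pair* count is
  defined over sense codons only.
* **3'UTR presence** — frameless substring search (UTRs are
  untranslated, so no reading-frame restriction applies).
* **tAI** — geometric mean of per-codon relative adaptiveness weights,
  the standard gene-level tRNA adaptation index; "average" is the
  geometric, not arithmetic, mean. Weights must be strictly positive.
* **GC content** — over the full CDS including the stop codon.
* **dipeptide fraction** — fraction of adjacent residue pairs in the
  encoded protein matching a dipeptide encodable by a member pair.
  This decouples codon-pair identity from peptide identity: ATG AGA AGA
  encodes an RR dipeptide but contains no member codon pair.
* **coding length** — L in codons. Any monotone transform (nucleotides
  vs codons) leaves all rank statistics unchanged.
* **single-pair position** — 1-based codon index of the 5' codon of the
  unique member pair, defined only for genes with exactly one
  occurrence; used for the position-effect analysis.
* **reporter summaries** — the optimal-codon fraction divides by L (the
  convention that reproduces 58/59 = 0.983 and 208/220 = 0.945 in the
  published reporter series); the pair fraction divides by L−1.

## Statistical core

All associations are rank-based; no distributional form is assumed for
the expression variables (parametric regression on these data violates
homoscedasticity).

One covariance construction drives both correlation families. For
columns x_1..x_p:

* Spearman: columns are average-ranked and the Pearson covariance
  c_ij = (1/n) Σ_k (x_ik − μ_i)(x_jk − μ_j) is taken over ranks.
* Kendall: the sign covariance
  c_ij = Σ_k Σ_l sign(x_ik − x_il) · sign(x_jk − x_jl), sign(0) = 0.

The marginal Kendall ratio c_xy/√(c_xx c_yy) is algebraically identical
to the tie-corrected tau-b: every unordered pair is counted twice in
numerator and denominator, so the ratio reduces to
(n_c − n_d)/√((n_0 − n_1)(n_0 − n_2)). The test suite exploits this to
cross-check the sign-covariance implementation against an independent
tau-b implementation; no separate tau variant is needed.

Partial correlation comes from the inverse covariance D = C⁻¹:

    r_ij|S = − d_ij / (√d_ii √d_jj)

which reduces exactly to the marginal coefficient when no covariates
are supplied. Analytic P values use t = r·√((n−2−k)/(1−r²)) with
n−2−k degrees of freedom (Spearman) and the normal statistic
r/√(2(2(n−k)+5)/(9(n−k)(n−1−k))) (Kendall), k being the number of
controlled covariates — the standard analytic forms for rank partial
correlations.

**Permutation P values.** The predictor column is permuted N times
(default 10000) with outcome and covariates fixed; the partial
coefficient is recomputed each round and P = (B+1)/(N+1), where B
counts permutations at least as extreme as the observed value. The
default tail is two-sided on |r|: a literal one-sided "exceeds the
observed value" rule would return P ≈ 1 for any negative observed
correlation, which cannot produce the 1/(N+1) floor that strong
negative associations in these data reach; the tail remains
configurable (`greater`, `less`). Exceedance uses a 1e-12 tolerance so
ties with the observed statistic count as exceedances (conservative).
The smallest reportable P is 1/(N+1) — 1.0E-04 at N = 10000.

**Numerical choices.** Covariance matrices with condition number above
1e12 raise a singularity error naming the most collinear column pair
rather than returning an unstable coefficient; a permutation that
happens to produce a singular matrix is resampled (logged, capped at 50
attempts). Constant predictors or outcomes yield missing coefficients
with a warning, and suites continue past them. Listwise deletion is
applied per association over exactly the variables involved, so n
varies across rows of a result table. Per-association child seeds are
derived by hashing (master seed, predictor, outcome, covariate set,
method), making every table cell reproducible independent of execution
order. Kendall permutations cost O(n²) per covariance entry; above an
operation budget of 2e10 the permutation count is reduced with a logged
warning rather than silently running for hours.

## Analysis suites

* **primary** — pair fraction and pair presence vs each outcome:
  marginal, partial per covariate individually, and partial controlling
  all of {GC, tAI, dipeptide fraction, coding length}.
* **frame-shift controls** — the same layout with frame +1/+2 hexamer
  features; frame-0 rows are emitted alongside and are numerically
  identical to the primary rows. Partials control the frame-0 covariate
  set, including the in-frame dipeptide content.
* **UTR controls** — marginal correlations only (matching how UTR
  results are conventionally reported; no silent covariate injection).
* **optimality suite** — tAI vs outcomes: marginal; partial controlling
  {GC, pair fraction or presence, dipeptide fraction, length}; and the
  marginal association recomputed on the zero-pair gene subset. If
  optimality acted only through the inhibitory pairs, the zero-pair
  subset would show no association.
* **position effect** — pair position vs decay among genes with exactly
  one pair.
* **all-pairs scan** — the per-gene fraction of each of the 61×61 =
  3721 sense-codon pairs, marginally correlated with decay outcomes,
  followed by a one-sided rank-sum test of whether the 17 inhibitory
  pairs' coefficients exceed those of the 3704 other pairs. Pairs
  present in very few genes are retained with their gene counts
  reported (marginal correlations at n < 10 are noise; filtering is
  left to the user). Partial-controlled scanning exists behind the
  config but is off by default.

## Synthetic-data generator

The generator emulates the structure of the real inputs, not their
letter-level statistics:

* **Sequences.** Gene lengths are lognormal (median 400 codons,
  σ = 0.45, floor 10), matching the scale of the yeast proteome; the
  default 4879 genes matches the verified nuclear ORF set. Codons are
  drawn from a two-component optimal/nonoptimal mixture with a per-gene
  Beta(6,3) weight toward optimal codons, inducing a smooth tAI
  distribution. The bundled synthetic weight table always classifies
  the ten constituent codons of the inhibitory pairs as nonoptimal, as
  they are in vivo.
* **Pairs.** Planted insertions arrive at per-gene Poisson rate 0.3,
  coupled by default to the nonoptimal mixture weight so pair content
  and codon optimality are confounded, as in the real genome — the
  scenario in which marginal and partial correlations genuinely
  diverge. Insertions are spaced at least three codons apart so no two
  insertions merge into an unplanned member pair. Spontaneous pairs
  arising from background sampling are counted as real: ground truth is
  recomputed from the emitted sequence, never from the insertion log
  (with the background alphabet restricted to non-pair-forming codons,
  emitted counts equal planted counts exactly, which the tests use as
  an oracle). Total pair content averages about one pair per gene,
  somewhat above the real genome's density.
* **Expression.** log(value) is linear in pair fraction, (1 − tAI), GC,
  log-length and UTR presence plus Gaussian noise, exponentiated so all
  rates are positive; rank-based analyses are invariant to the marginal
  transform, so the log-normal choice matters only for producing
  realistic positive rates. Per-outcome missingness (default 15%)
  emulates partial dataset coverage. Default effect sizes are chosen so
  a default-condition run reproduces the genome-scale sign pattern and
  approximate magnitudes reported for the real data (pair-decay
  marginal ρ ≈ +0.36 attenuating to ≈ +0.15 after covariate control;
  synthesis and protein-decay associations that vanish once tAI is
  controlled, because those outcomes are generated from optimality
  alone; genuine negative pair effects on both translation-efficiency
  proxies).

What the generator does **not** emulate: real codon-usage frequencies
beyond the two-component mixture, amino-acid composition constraints,
secondary structure, UTR regulatory motifs, correlated measurement
error between datasets, and selection-driven covariance between length,
expression and codon bias. Passing tests therefore demonstrate that the
machinery recovers planted effects of realistic size under realistic
confounding and is calibrated under the null — not that any particular
biological conclusion holds.

## Problem sizes used in validation

Calibration and power checks run at sizes chosen to estimate the
relevant rates tightly while staying desk-scale: type-I error over 200
null replicates (300 genes each, 1000 permutations); planted-effect
recovery over 100 replicates at 2000 genes; frame-shift centering over
30 replicates at 500 genes; the acceptance script uses the same designs
with somewhat fewer replicates plus one full-size (4879-gene) run. At
these sizes the binomial error on a 5% rate is ~1.5%, and a planted
partial correlation of ~0.15 at n ≈ 1700 complete cases corresponds to
z ≈ 6, so recovery failures indicate implementation defects rather than
sampling noise.

## Known limitations

* Real genome-derived counts (the verified ORF total, per-pair
  occurrence counts) require the actual genome release and annotation;
  the package computes them when given those files but ships no genome.
* The Kendall permutation path is exact but O(n²) per covariance entry;
  at genome scale, Spearman permutations (O(np) per round) are the
  practical default, with Kendall N auto-reduced under a budget.
* Multiple annotated UTR isoforms collapse to the longest; the
  convention used by the original annotation compilations is not
  recoverable.
* No multiple-testing correction is applied across result rows; the
  analysis convention is a 0.05 threshold on permutation P values.
* Reporter optimal-codon fractions follow the convention that divides
  by all L sense codons; one published reporter series appears to use a
  different denominator (excluding the start codon), which this package
  deliberately does not special-case.
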