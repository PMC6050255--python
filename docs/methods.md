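# Methods

`stressmeth` implements a genome-wide association analysis between a
continuous childhood-stress exposure score and two salivary molecular
read-outs: array-style CpG methylation (beta values) and RNA-seq count
matrices at gene and isoform level.  This note documents the statistical
models, the synthetic-data generator used to validate them, the numerical
choices, and the known limitations.

## Differential methylation

### Per-probe linear model

Beta values `b` (methylation fractions) are mapped to M-values,
`M = log2(b / (1 - b))`, with betas clamped into `[eps, 1 - eps]`
(`eps = 1e-6`) so boundary values stay finite without changing the matrix
shape.  Each probe is fit by ordinary least squares,

    M_i ~ intercept + lsi_score + age + batch,

where `lsi_score` is the continuous stress severity rating (a 5-point scale
that may take fractional values), `age` is in years and `batch` is the array
chip.  Probes with zero residual variance receive `p = NA`, are logged, and
are excluded from all downstream stages.

### Empirical-Bayes variance moderation

Residual variances are shrunk toward a scaled-inverse-chi-square prior whose
parameters `(d0, s0^2)` are estimated by the method of moments on log sample
variances (digamma/trigamma inversion; the trigamma inverse is solved by
Newton iteration to 1e-12).  The posterior variance is
`(d0*s0^2 + df*s^2) / (d0 + df)`; the moderated t uses it with `df + d0`
degrees of freedom.  When the observed spread of log variances does not
exceed its sampling variability the moment equations give `d0 = infinity`
and every posterior variance collapses to `s0^2`; this is the common outcome
for the homoscedastic synthetic generator and is exercised explicitly via a
`prior_df` override (0 reproduces the raw t, infinity equalises variances).
The estimator agrees with the Bioconductor reference implementation to
better than 1e-6 on shared inputs (checked in the test suite).

### Signed z-scores

Two-sided moderated p-values are mapped to signed z-scores,
`z = sign(b) * Phi^-1(1 - p/2)` with p clamped at 1e-300.  Signing by the
coefficient keeps hyper- and hypo-methylation effects on opposite sides of
zero so the HMM's two alternative mixture components can separate them.  The
unsigned (folded) alternative was rejected because it discards direction.

### Spatial HMM and the local index of significance

Methylation levels are locally correlated along the genome, so evidence is
borrowed across neighbouring probes: the z sequence, ordered by chromosome
and position, is modelled by a two-state hidden Markov chain
(null / alternative) with homogeneous transitions.  The null emission is
fixed at N(0, 1); the alternative emission is a two-component normal
mixture.  The chain restarts independently at every chromosome boundary.

Constraints on the alternative components: a z-score at a true effect is
the standardized effect plus N(0, 1) sampling noise, so the alternative
emission SD is floored at 1; the component means are constrained to
magnitude >= 1 (one null SD).  Without the mean constraint an unconstrained
mixture can split the null distribution itself when signal is sparse or
absent, inflating the alternative occupancy; with it, global-null occupancy
stays below ~2%.  Both constraints are exact projections in the M-step, so
the EM log-likelihood is non-decreasing at every iteration (asserted in
tests to 1e-8 relative tolerance).

Fitting: scaled forward-backward in the three-state expansion of the
mixture chain, EM until the relative log-likelihood change is < 1e-8 (cap
1000 iterations), three restarts (the first from null prior 0.95,
transitions [[0.95, 0.05], [0.3, 0.7]], means ±2, unit SDs, equal weights;
the others jittered from the run seed) with the best final likelihood
winning.  The local index of significance at probe i is
`LIS_i = P(state_i = null | z_1..z_n)`.

### aLIS thresholding

LIS values are sorted ascending; the adjusted LIS at rank k is the running
mean of the k smallest LIS values.  Probes with `aLIS < alpha` (default
0.05) are called differentially methylated; by construction the called set
is a prefix of the LIS ranking, and thresholding the running mean controls
the marginal false discovery rate for dependent tests.  On the default
synthetic conditions the realized FDR averages ~0.05 over 20 replicates
while recovering essentially all planted probes, exceeding probe-wise
Benjamini-Hochberg at matched realized FDR.

### Direction and mQTL proximity

Each called DML is classified by the sign of the Pearson correlation
between its beta row and the stress score (beta rather than M because the
methylation fraction is the interpretable scale; the two are monotone so
the sign is identical).  `r = 0` or a zero-variance row falls back to the
regression-coefficient sign with a warning.  Each probe is also flagged
when a SNP lies within 200 bp (boundary inclusive) on the same chromosome,
separating candidate genotype-driven sites from environment-driven ones.

## Permutation enrichment

Called DMLs are tested for over/under-representation in gene structures
(TSS1500, TSS200, 5'UTR, first exon, body, 3'UTR, intergenic), CpG-island
relations (island, shores, shelves, open sea) and chromosomes, separately
for all, positively and negatively correlated DMLs.

* Structures: a probe contributes one tally per structure it carries.  The
  null pools the annotation multiset of *all* tested probes and draws the
  DML set's total annotation count without replacement, 10,000 times by
  default.
* Island relation: same machinery with exactly one annotation per probe,
  making the permutation p equal (up to Monte-Carlo error) to a
  hypergeometric tail — used as the oracle in tests.
* Chromosomes: whole probes are drawn and per-chromosome *proportions*
  compared.  The default family-wise mode compares each chromosome's actual
  proportion with the most extreme permuted proportion over all
  chromosomes (a built-in multiplicity correction over the 23 chromosomes
  of an array design); a marginal per-chromosome mode is provided because
  either reading of the rule is defensible.

Both tails include ties (`>=` for enrichment, `<=` for depletion) so a
degenerate universe yields p = 1 rather than 0; strict inequality and
add-one smoothing are available as options.

## Differential expression

Gene and isoform count matrices are `log2(x + 1)`-transformed and quantile
normalized: every column is forced onto the cross-column rank-mean
distribution, ties receiving the mean of the reference values they span.
No low-count filter is applied by default.  The same moderated linear model
as the methylation stage is then fit per feature, and features with
moderated `p < 0.05` (raw, uncorrected — matching the calling convention
this stage models) are flagged.  The unique DE gene set is the union of
genes called at gene level and parent genes of called isoforms.  Under a
global null the called fraction sits at the nominal 5% and the p-values are
approximately uniform (verified over 20 seeds).

## Integration

DMLs are assigned to the nearest gene: containment in the gene span wins,
otherwise minimum distance to either gene boundary on the same chromosome
(TSS-distance mode available); equidistant ties break to the
alphabetically first gene id, and probes on geneless chromosomes stay
unassigned (excluded from gene-level sets, retained in locus-level
enrichment).  A gene enters the positive (negative) set if it hosts at
least one positive (negative) DML; genes hosting both appear in both sets,
so `|union| = |P| + |N| - |P ∩ N|` is enforced on every run.  Three-way
Venn counts against the DE genes and a curated stress-gene list are
recomputed with plain set algebra and re-verified against the union
cardinality.  List enrichment uses a Yates-corrected chi-square on the 2x2
membership table over the gene universe; the correction term is
`min(0.5, |O - E|)` so the corrected statistic never exceeds the
uncorrected one (the convention of R's `chisq.test`, against which the
degenerate no-association case behaves sensibly).  The universe includes
the gene set itself (membership dichotomy).

## Motif stage

Flanks of ±250 bp around each called DML are written as FASTA for external
discriminative motif tools.  The internal check counts sequence-level
presence (one count per sequence, k-mer and reverse complement collapsed)
of every foreground k-mer for k = 4..8 against a per-sequence
dinucleotide-preserving shuffle (Altschul-Erickson Eulerian-walk shuffle;
a mononucleotide mode exists), computes one-sided Fisher exact p-values via
the hypergeometric tail, and reports `E = p * (number of distinct k-mers
tested)` below a cutoff (default 1e-3 for desk-scale detectability; the
cutoff is configurable because discovery-scale runs warrant stricter
values).  Sequence-level presence rather than occurrence counting follows
discriminative-motif convention.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the raw assay:

* Genome: a few chromosomes with non-overlapping genes (>= 2 kb intergenic
  space) and CpG islands near most promoters.
* Probes: uniform positions annotated to every structure window they
  overlap (TSS200 = 200 bp upstream of the TSS, TSS1500 the next 1300 bp,
  strand-aware; the gene span split 10% 5'UTR / 10% first exon / body /
  10% 3'UTR), island relations by distance (shores ±2 kb, shelves 2-4 kb),
  SNP/cross-reactive flags drawn independently (defaults 2% / 1%), and a
  random 501 bp flank.
* Samples: default 22, ages 9-12, stress scores spanning 1-5 with half the
  cohort in each half of the range, alternating chip batches.
* Methylation: base-2 logit of beta is linear in the score inside planted
  clusters (default 10 clusters of 12 probes, slope magnitude 0.2-0.5 per
  score unit, constant sign within a cluster), plus a bimodal baseline
  (±3 ± 1 on the M scale), small age/batch effects, and AR(1) noise along
  probe order within chromosome (rho = 0.3, marginal SD 0.35) supplying the
  local correlation the HMM exploits — AR(1) is the simplest stationary
  choice for it.  Detection p-values are Uniform(0, 0.01) except planted
  failures (rate 0.002 per probe-sample) which are Uniform(0.01, 1).
* Expression: negative-binomial counts (default dispersion 0.1, mean depth
  500) whose log2 mean is linear in the centred score for DE features
  (default 10% of genes, half drawn from genes hosting methylation
  clusters); 1-3 isoforms per gene share the gene mean through Dirichlet
  splits.
* Gene list: genes with true effects enter at `enrichment_factor` (default
  3) times the 20% base rate, capped at 1.
* Motif: an optional 4-12 bp motif replaces bases at a random offset in a
  configured fraction of designated probe flanks.

Effect sizes have no published reference scale, so the defaults were chosen
once for testability: strong enough that a 22-sample design detects
clustered effects, weak enough that betas stay inside (0, 1).  What passing
tests show is therefore that the machinery is correct and calibrated under
the assumed generative model — AR(1)-correlated logit-linear effects,
NB counts — not that real saliva data meet those assumptions; in particular
the generator has no cell-composition structure, no probe-type chemistry
differences, and no genotype-methylation coupling beyond the independent
SNP table.

## Problem sizes and determinism

Validation studies use 2,000 probes x 22 samples with 20 replicates for FDR
and power, 200 flanks over 10 seeds for motif recovery, and 200 genes x 20
seeds for null DE calibration; these sizes give stable Monte-Carlo
estimates at desk scale.  Every stochastic routine takes an explicit seed
and is byte-reproducible; pipeline runs write a SHA-256 manifest of their
outputs.  Sub-seeds are spawned from the master seed, so stages can be
re-run in isolation.

## Known limitations

* Homogeneous HMM transitions: probe spacing does not modulate transition
  probabilities (a distance-dependent kernel is a possible extension).
* The aLIS threshold controls FDR marginally; very short chromosome
  segments provide little information to the chain.
* Quantile normalization assumes most features are non-differential;
  with few features or narrow baseline spread it compresses large effects.
* No surrogate-variable analysis, array normalization, read alignment, or
  gene-ontology database access: the pipeline starts from normalized beta
  values and count matrices, and curated lists are plain text inputs.
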