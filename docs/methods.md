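# Methods

## Deterministic cross prediction

The core computation treats a biparental cross between fully inbred parents
as a distribution over RIL progeny genomes. Assumptions: bi-allelic loci,
full homozygosity of parents and progeny, additivity (no dominance or
epistasis), selfing to fixation, no crossover interference, no mutation, and
a genetic map in centiMorgans from which all recombination fractions derive.

For loci where the parents differ ("segregating" loci), effects are re-signed
to the first parent's alleles, which handles coupling and repulsion phase in
one convention. The progeny variance of a trait is the sum over segregating
loci of α², plus twice the phase-signed cross-products weighted by
w = (1 − 2c)/(1 + 2c). This weight is the expected two-locus origin
correlation of selfed-to-fixation RILs (the complement of twice the
Haldane–Waddington RIL recombinant fraction R\* = 2c/(1 + 2c)), so the
per-chromosome weight matrix is a correlation matrix — positive
semi-definite — and the implied progeny trait covariance matrix is PSD as
well. The cross-trait covariance is the full double sum over the two traits'
segregating sets, including same-locus terms with weight 1 (ordered pairs,
no factor 2): this is the term through which a pleiotropic locus contributes
α⁽¹⁾α⁽²⁾. The cross mean of a trait is the mid-parent predicted genotypic
value. Superior and correlated progeny means add k_sp·σ_G and k_sp·r_G·σ_G(2)
respectively, with k_sp the standardized selection differential
φ(Φ⁻¹(1−p))/p of the selected tail p.

Loci on different chromosomes have c = 0.5 exactly, hence weight 0, so the
genomewide double sum decomposes into per-chromosome blocks. The batched
implementation evaluates g'Wg per chromosome with one dense weight matrix per
chromosome shared across all crosses; a test checks bit-level agreement with
the naive genomewide double sum. Predicted variances are clipped at zero
(they can go ~1e-16 negative in floating point); a correlation is reported
NaN when either variance is zero, and such crosses are excluded pairwise from
accuracy summaries.

Mapping function: Haldane, c = ½(1 − e^(−2d/100)), consistent with the
no-interference meiosis model used everywhere; a Kosambi implementation is
provided behind the same contract but is not used by the simulator.

## Meiosis and RIL simulation

Under no interference, crossovers are a Poisson process along the
chromosome, so parental origin across ordered markers is Markov with
transition probability equal to the adjacent-interval recombination
fraction. The bulk simulator uses this Markov walk (vectorized across
individuals); a literal implementation drawing Poisson crossover counts and
uniform positions exists alongside it and the two are cross-checked on
recombinant fractions. RIL families are generated either `direct` — one
Markov walk per progeny with transition R\* = 2c/(1 + 2c), i.e. selfing to
fixation — or by explicit single-seed descent for g generations followed by
doubling of a final gamete (default g = 5, F6-equivalent). The two methods
agree within sampling error on all two-locus statistics; `direct` is the
default for speed (the selection experiment simulates 1,000 progeny × 10
cycles × replicates).

## Synthetic founder panel

The generator emulates an elite inbreeding-crop panel: fully homozygous
lines, bi-allelic SNPs placed uniformly at random on a multi-chromosome cM
map (coincident positions jittered by 1e-6 cM), and — critically —
haplotype-block LD persisting over tens of cM, as selfing crops show because
their effective recombination rate is low. Each base haplotype is a Markov
mosaic of two deeply diverged ancestral chromosomes with ancestry
autocorrelation exp(−d/λ); lines descend from the base haplotypes through
`n_mixing_generations` of random mating whose final gamete is doubled.

Defaults: 1,500 lines × 2,300 markers, 7 chromosomes × 150 cM, 30 base
haplotypes, 1 mixing generation, λ = 300 cM. These were chosen once so that
the two-trait architectures below realize their target correlations: the
realized founder correlation is attenuated by roughly the RMS LD correlation
between paired QTL, so tight-linkage pairing (≤ 5 cM) needs r ≈ 0.9 at short
range and loose-linkage pairing (25–35 cM) needs substantial LD even at
30 cM. Fewer mixing generations and larger λ both lengthen LD; the knobs are
exposed so users can match an empirical LD-decay curve.

What the panel does not emulate: a realistic allele-frequency spectrum
(frequencies cluster near 0.5 because alleles track a two-ancestor mosaic),
population substructure, selection footprints, genotyping error, and
short-range LD heterogeneity. Consequences worth knowing: marker–QTL LD is
stronger and more uniform than in real panels, so absolute prediction
accuracies here run higher than in empirical data, and selection in the
breeding-program experiment exhausts variance faster; orderings and signs
(which parameter is predicted best, bias directions, strategy rankings) are
the meaningful outputs, not absolute levels. Because near-unit short-range
LD leaves almost no standing recombinants inside tightly linked QTL pairs,
the protective effect of CPM cross selection on an unfavorably correlated
trait expresses under loose linkage but not under tight linkage, where pairs
behave almost pleiotropically.

## Trait architectures

QTL are drawn from the genotyped SNPs and remain visible to the prediction
models (they are not masked). Effect magnitudes follow the geometric series
a^k with a = (L − 1)/(L + 1) for the L effective QTL (L = 1 degenerates to a
zero effect and warns); the favorable allele is randomized independently per
QTL and per trait, so only the magnitude convention matters. The target
correlation r_G(0) is induced by post-multiplying the L×2 effect matrix by
the (transposed) lower Cholesky factor of [[1, r_G0], [r_G0, 1]] — written in
a limit-safe form so |r_G0| = 1 yields exactly proportional columns — which
preserves trait-1 effects exactly. Linkage architectures pair each trait-1
QTL with a partner marker on the same chromosome inside the distance window
(≤ 5 cM tight, 25–35 cM loose); trait-1 QTL are sampled only among markers
that have at least one admissible partner (map edges and gaps can empty the
window), and trait-2 effects are then scaled by the signed LD correlation r
(not r²) with their partner in the founder panel. Variances use the
population convention (divide by n) throughout the simulation bookkeeping.

## Phenotypes and marker-effect models

Entry-mean phenotypes average `n_env` (default 3) per-environment values,
each the genotypic value plus independent normal noise with variance
n_env·σ²_G·(1 − h²)/h², calibrated against the realized population genetic
variance recomputed per call; residuals are independent between traits.
h² = 1 returns genotypic values exactly.

RR-BLUP estimates the shrinkage λ = σ²_e/σ²_u by REML: the criterion is
profiled onto one dimension using the eigendecomposition of the centered
marker cross-product matrix, scanned on a 121-point log grid over
[1e-6, 1e6] and refined by bounded scalar minimization. Marker coding is
used as-is ({−1, 0, 1}); no allele-frequency centering. BayesCπ is a Gibbs
sampler with per-marker inclusion indicators, a common effect variance,
scaled-inverse-χ² priors (4 df; scales split the phenotypic variance
50/50 between genetic and residual), and a uniform prior on π; defaults are
12,000 iterations with 2,000 burn-in, and the π = 0 limit reproduces RR-BLUP
(tested). A split-chain R̂ on the genetic-variance chain above 1.2 warns but
does not fail. The kernel is compiled with numba; chains are reproducible
under a fixed seed.

## Experiments

**Prediction accuracy.** Each replicate samples a fresh training population
(TP) from the panel, builds a fresh architecture, simulates phenotypes, fits
the model per trait, and scores 50 random parent pairs: accuracy is the
Pearson correlation across crosses between predictions (estimated effects)
and expectations (true QTL effects) for the mean, variance and correlation;
bias is the mean difference for r_G and the covariance. Replicates whose
valid-cross count drops below 3 are dropped and counted. An `oracle` model
option injects the true effects (all accuracies 1 by construction) as a
driver self-test.

**Recurrent selection.** Marker effects are fit once on the TP (n = 600) and
held fixed. Cycle-1 parents are the top 30 TP lines on predicted trait-1
values; each cycle predicts all non-reciprocal crosses among the parents,
selects 20 by strategy — CPM: z-score (within the candidate set) of μ̂_sp(1)
plus z-score of μ̂_spC(2), FM: predicted trait-1 cross mean, random: uniform —
simulates 50 RILs per cross, and takes the top 50 of the 1,000 candidates
(predicted trait-1) as next parents. Per cycle the candidates' true
genotypic values give the standardized responses (in cycle-0 TP genetic SD
units, fixed baseline), variances, correlation, favorable / unfavorable /
antagonistic two-locus QTL haplotype frequencies, and per-trait fixation
proportions. The index response is the sum of the two standardized
responses. Strategies share each replicate's TP, architecture and fit
(paired comparisons); summaries report the mean and mean ± 1.96·SE over
replicates.

## Within-family validation

A validation family is modeled as y_p = 1μ_p + g_p + ε_p with identity
relatedness. For balanced line × environment data the REML solution has the
closed form Σ_e = W/(l(e−1)), Σ_g = (B/(l−1) − Σ_e)/e in the between/within
mean cross-product matrices; an explicit EM-REML iteration (with the
fixed-effect uncertainty entering both E-steps) is implemented and agrees to
machine precision on interior cases. Unbalanced data are rejected rather
than approximated. Estimates with non-positive genetic variance yield NaN
with a flag; |r_G| > 1 estimates are reported unclamped and flagged.
Predictive ability is the Pearson correlation of predicted vs. estimated
family r_G with a percentile bootstrap interval (families resampled, default
1,000 draws); the interval is widened, if ever needed, to contain the point
estimate.

## Problem sizes used by the test suite and acceptance script

The full-scale defaults (1,500 × 2,300 panel; 100 replicates for the
accuracy experiment, 250 for the selection experiment) are what the config
files describe and what the CLI runs. The automated tests and
`scripts/acceptance.py` run the same code on a desk-scale preset chosen
once: an 800-line × 700-marker panel on the same 7 × 150 cM map, 30
replicates for accuracy cells, 14 replicates for the selection comparison,
2×10⁵ progeny for the two-locus Monte-Carlo checks and 4,000 progeny per
cross for the deterministic-vs-MC agreement. At these sizes every
qualitative result (orderings, bias signs, protection of the indirect trait)
is stable across seeds; absolute accuracy levels are higher than a real
panel would give, for the LD reasons above.

## Known limitations

Two traits only; biparental crosses of fully inbred parents (no three/four-
way crosses, no intermediate selfing generations); univariate prediction
models only; marker effects are not retrained across breeding cycles; the
multi-environment genomic-relationship bivariate model is out of scope — the
identity-relatedness family estimator is the supported validation path.
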