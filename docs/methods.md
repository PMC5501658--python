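# Methods

## Model

The classifier is a two-class Logistic Model Tree (LMT) aggregated by a
class-balanced bootstrap. Labels are coded y = ±1 with +1 = neutral and
−1 = pathogenic; the positive class for all reported metrics is
*pathogenic*.

**Leaf models.** Writing F for the additive logistic function of the
neutral class, the two per-class functions are F_neutral = F and
F_pathogenic = −F, which enforces the sum-to-zero constraint Σ_k F_k = 0
identically, and the posterior is the canonical softmax
P(neutral | x) = e^F / (e^F + e^{−F}) = 1/(1 + e^{−2F}). (A published
variant of this posterior normalises by 1 + Σ_k e^{F_k}; that expression
cannot sum to one under the sum-to-zero constraint with J = 2 and is
treated as typographical — the softmax is used throughout.)

**LogitBoost.** Each iteration computes working responses
z_i = (y*_i − p_i)/(p_i(1 − p_i)) and weights w_i = p_i(1 − p_i) from the
current probabilities (y* ∈ {0,1}), fits one weighted least-squares simple
regression per candidate variable, and adds the best (minimum weighted
SSE) to F with factor ½. Variables never chosen keep zero weight, so each
leaf model uses only a selected subset V_t of the predictors. Numerical
safeguards: probabilities are clamped to [1e−12, 1 − 1e−12] before the
working-response computation (which also bounds z); a step that would
increase the training log-loss is halved up to 12 times and, failing that,
boosting stops — this makes the training log-loss non-increasing by
construction, which raw LogitBoost does not strictly guarantee. The
working response is deliberately *not* clamped to the small constant some
implementations use (±3): that clamp destroys the descent-direction
property of the fitted step, and with the monotone-loss guard in place it
caused premature convergence far from the logistic-regression optimum.

**Tree induction.** Top-down binary axis-aligned splits; recursion stops
when a node is pure (majority fraction ≥ `purity_stop`, default 1.0),
smaller than `min_node_size` (default 15), or at `max_depth` (default
unlimited; depth 0 degenerates to a single LogitBoost model). Candidate
thresholds are midpoints between consecutive distinct sorted values; the
shortlist per feature holds the best information-gain midpoint and the
most balanced midpoint, and the chosen split minimises the pooled training
log-loss of LogitBoost models fitted to the two children
(`split_eval_iterations` warm-started iterations, default 10). Scoring
splits by the fit of the actual leaf-model class rather than by label
entropy alone matters when the first split carries no label information by
itself — an XOR-patterned score space is carved correctly into its 2- or
4-leaf solution, where pure information gain picks an arbitrary noisy cut.
Ties break deterministically toward the lower feature index, then the
lower threshold; points equal to a threshold route left (≤). Each node's
model is warm-started from its parent and boosted `boost_iterations` more
iterations (default 30); alternatively `cv_select=True` chooses the
iteration count once at the root by stratified 5-fold cross-validation
(capped at `cv_max_iterations`, default 200) and reuses it down the tree.
The fixed-iteration mode is the default because it keeps a 100-member
ensemble fit at interactive speed with indistinguishable OOB accuracy on
the corpora the tests use. A pure node becomes a leaf whose model receives
intercept-only boosting toward the node's Laplace-smoothed class
frequency, so single-class regions yield confident but finite
probabilities.

**Bootstrap aggregation.** Per iteration, m = round(0.7 · n_pathogenic)
indices are drawn with replacement from the pathogenic class and m more
from the neutral class; every index never drawn is out-of-bag. The
expected inclusion frequency of a class-size-n variant is 1 − (1 − 1/n)^m
— 50.4% and 21.6% at the 223/641 corpus sizes, the scheme that reproduces
the published 50%/22% figures analytically. 100 iterations are run; each
member scores its OOB rows, and the per-variant mean OOB probability is
thresholded strictly at 0.5 (a mean of exactly 0.5 is neutral). Variants
never out-of-bag — vanishingly rare at 100 iterations — fall back to the
full-ensemble mean and carry a `never_oob` flag. The master seed spawns
one child seed per iteration (`numpy.random.SeedSequence`); an iteration
whose in-bag sample is single-class is redrawn with the next child seed
and logged. Runs are bit-reproducible from the master seed.

## Feature layer

Upstream predictor outputs enter as raw numeric scores, categorical calls,
or p-value/FDR pairs. Dichotomization rules are strict everywhere a
published threshold says "exceeds": CADD phred > 12, MToolBox disease
score > 0.4311, COVEC weighted-majority score > 0 (0 is neutral), and the
joint significance rule p < 0.05 AND FDR < 0.2. Categorical maps are total
over each predictor's published category set (PolyPhen2 ships in two
variants that route "possibly damaging" to neutral or harmful
respectively; MutationAssessor maps low/neutral to harmless and
medium/high to pathogenic); unknown categories raise rather than guess.
By default the learner consumes numeric scores raw and categorical calls
dichotomized (harmful = 1, neutral = 0) — which representation fed the
original learner is not recorded, so both paths are provided and the
numeric-threshold rules can be applied explicitly. Missingness is an
explicit mask (sentinels "", "NA", "." configurable); dense consumers
impute per column — training-sample mean for numerics, 0 (neutral) for
dichotomized — and imputation statistics are fitted on each bootstrap
in-bag sample only, never on OOB rows. Entirely missing columns are
dropped with a provenance log line.

Coevolution features summarise a symmetric per-protein matrix of
mutual-information Z-scores: per site, the fraction of partner sites with
Z strictly greater than 6.5 and the mean Z over those partners (undefined
when there are none). Matrices are consumed precomputed; asymmetry beyond
1e−9 is rejected.

## Metric suite

All statistics are computed over predicted variants only (tools that make
no call shrink N): specificity TN/(FP+TN), sensitivity TP/(TP+FN),
accuracy (TP+TN)/N, precision TP/(TP+FP), FDR FP/(TP+FP) (the complement
of precision, not a multiple-testing quantity), MCC, and MCR =
100·(FP+FN)/N. Zero denominators yield NaN sentinels, except MCC where a
zero denominator yields 0 by the common convention. Display rounding is
half-up to two decimals; full precision is kept internally. ROC curves
sweep the distinct probability values from (0,0) to (1,1) with
trapezoid-rule AUC, which equals the Mann–Whitney concordant-pair fraction
with ties counted ½. Pairwise predictor concordance is percent agreement
over jointly called positions.

## Missense enumeration

Given a genome sequence and a 5-column coordinate table (gene, start, end,
strand, codon_start; 1-based inclusive, ND6 being the only reverse-strand
protein gene), every single-nucleotide substitution at every coding
position is translated under the vertebrate mitochondrial genetic code and
emitted when the encoded amino acid changes. Codons are translated
literally (no initiator-codon special-casing); stop gains/losses count as
amino-acid changes by default behind an `include_stop_changes` flag, since
the convention behind the published genome-wide count is not stated.
Overlapping genes are evaluated independently, one record per gene.
Coding lengths not divisible by 3 after the codon_start adjustment are
annotation errors — genes with incomplete terminal codons should be
trimmed in the coordinate table.

## Synthetic corpus generator

The generator emulates the statistical shape the classifier assumes: two
classes of 223 pathogenic and 641 neutral variants (the curated-corpus
composition), per-predictor class-conditional distributions — normals for
numeric scores, Bernoulli harmful-call rates for categorical callers —
independent given the class, and per-column missingness mirroring the
shortfall of available predictions in real score tables (e.g. 3% for the
consensus caller, 12% for the panel member with the fewest predictions).
The default panel of eight numeric and two categorical predictors uses
moderate (≈1 SD) class separations chosen once as realistic analogues of
the aggregated tools. Variant identities are synthesized over the 13 real
gene symbols with positions inside the real rCRS coding spans and unique
(position, alt) keys.

What the generator does *not* model: the strong correlation structure
among real predictors (many are built on the same alignments), per-gene
pathogenicity base-rate differences, and heavy-tailed score distributions.
Passing tests therefore demonstrate that the machinery recovers
class-conditional signal of the stated size and is honest in its absence
(label permutation drives OOB MCC to ≈0) — not that real-corpus accuracy
would match.

## Problem sizes used in the checks

The behavioural checks run at desk scale, chosen so the full suite
completes in about a minute: 100-member ensembles on 864-variant corpora
(5 informative features at 2-SD class separation) for the signal-recovery
check, a 400-variant label-permuted corpus for the null check, 20,000
Monte-Carlo replicates for the inclusion-frequency check, and toy genomes
of a few codons for enumeration oracles.

## Known limitations

* Two classes only (J = 2); no cost-complexity pruning beyond the stopping
  rules; no .632/.632+ bootstrap estimators (plain leave-one-out-bootstrap
  OOB aggregation).
* Mutual information is not recomputed from alignments; coevolution
  matrices arrive precomputed.
* Curation tables are consumed as files; no querying of variant databases
  or of the upstream predictors themselves.
* The model-based split criterion costs roughly 4p child fits per internal
  node; for very wide feature tables `split_eval_iterations` can be
  lowered or `max_depth` bounded.
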