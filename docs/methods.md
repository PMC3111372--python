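# Methods

## Problem and model

`grncop2` mines putative gene regulatory relationships from one or more
gene-expression time series.  The data model is a matrix **X** of n genes by
m ordered time points (log-ratio expression values).  Each gene has two
discrete states relative to a threshold: *upregulated* (+1, value strictly
above) and *downregulated* (−1, value at or below).  A rule

    <symbol> gene_r  w ->  <symbol> gene_i

states that the side of gene_r's threshold at time j predicts the state of
gene_i at time j + w.  Seven integer codes describe the possible logical
forms: ±1 are two-sided (every sample constrained; −1 is the
anti-correlated form), ±2 and ±3 are one-sided implications (only samples on
one side of the regulator threshold are constrained), and 0 means no
interaction.  The method is model-free: it fits no dynamical system, only
searches the combinatorial space of per-pair rules.

## Discretization

**Target thresholds (TDT).**  Each target gene is discretized by the
one-dimensional two-cluster problem on its own samples: sort the samples
into an array L, scan every split position e ∈ {1, …, |S|−1}, and minimize
var(L[1..e]) + var(L[e+1..|S|]).  Variances are population variances
(divide by count): the objective only ranks splits, the population form is
defined for the size-1 parts met during the unconstrained scan, and it
matches the within-cluster criterion of k-means with k = 2, of which this
scan is the exact 1-D solution.  The threshold is the midpoint
(L[e] + L[e+1])/2.  The scan itself is unconstrained; if the *global*
optimum isolates fewer than two samples on either side, the gene is treated
as outlier-dominated and excluded from inference at that delay (searching
only constrained splits could never trigger this guard).  Ties go to the
smallest e.  At least 4 samples are required, which bounds the delay window
(below).

**Regulator thresholds (RRT).**  A regulator does not get one global
threshold: the expression level at which gene_r acts on gene_i1 need not be
the level at which it acts on gene_i2.  For each (regulator, target) pair,
every distinct observed regulator value is a candidate threshold t.  The
candidate partitions the aligned samples into Do (value ≤ t) and Up
(value > t); its quality is the weighted binary class entropy of the
target's states,

    E(t) = |Do|/N · H(Do) + |Up|/N · H(Up),

with H the base-2 Shannon entropy of the ±1 target labels inside a side
(0·log 0 = 0, H(∅) = 0).  Base 2 makes the stated [0, 1] range exact for
binary labels: 0 for a label-pure split, 1 when both sides are 50/50.  The
candidate minimizing E is the RRT; ties break to the smallest threshold
value (determinism).  Candidates leaving Do or Up empty are skipped — the
maximum observed value always empties Up — so a constant regulator has no
informative threshold and is assigned rule type 0.  A useful consequence:
discretizing a regulator at its RRT always yields both states at least
once.

## Time-lagged inference

For delay w, regulator sample j is paired with target sample j + w: the
first w target samples and the last w regulator samples are dropped,
leaving m − w aligned samples.  TDTs are recomputed per delay on the
target's retained samples; RRTs are computed per delay on the regulator's
retained samples.  Since a TDT needs 4 samples, the delay window is bounded
by W ≤ m − 4.  When K datasets with sampling intervals Δt_k and sample
counts m_k are given, a biological hypothesis "regulation acts within at
most Δt_H minutes" converts to

    W = min( floor(Δt_H / min_k Δt_k),  min_k m_k − 4 ),

flooring because a partial sampling step cannot be inferred.

## Classifier optimization

For a fixed target i and delay w, the gene-profile classifier is the vector
assigning a rule-type code to every candidate regulator.  Because rules are
pairwise, components are independent and each is optimized greedily: all
six non-zero codes are scored with

    σ = [TP/(TP+FP)] · [TN/(TN+FN)]

for the two-sided codes — the product of the rule's positive and negative
predictive values — and with the single factor named by the premise for the
one-sided codes.  The per-type confusion mapping takes "positives" to be
the samples matching the rule's "+"-side premise and "negatives" those
matching its "−"-side premise; any 0/0 factor scores 0.  Two filters apply:
the **Accuracy** parameter (minimum σ; survivors below it become type 0) and,
for one-sided codes only, the **SCP** (sample coverage percentage): TP
(codes 2, −3) or TN (codes 3, −2) must cover at least an SCP fraction of
the aligned samples, guarding against one-sided rules that are right on a
handful of samples.  The SCP denominator is the number of *aligned* samples
(m − w), since both the counts and the sample set shrink together under
lagging.  With SCP = 1 no one-sided rule can be emitted: RRT discretization
guarantees both regulator states occur, so TP (TN) is always < m − w.

Score ties break toward two-sided codes (strictly more informative), then
toward positive codes; both choices are pure determinism conventions.
Self-pairing is skipped at w = 0 (trivial identity) and allowed at w ≥ 1
behind a flag that defaults to off.  The discrete matrices are never
materialized: states are computed on demand from **X** through the stored
thresholds.  The cost is O(K·W·m·n²) overall.

## Consensus across datasets

Each of the K datasets yields per-delay rule sets.  A rule — identified by
its full statement (regulator, target, delay, type); the same pair matching
as type 1 in one dataset and type 2 in another is *not* merged — survives
iff it appears in at least ceil(RCA · K) datasets, the "at least" reading of
the consensus fraction (RCA 0.60 over 10 datasets means at least 6, no
matter which).  Datasets are unweighted; the accuracy carried forward is the
minimum score across supporting datasets, the most conservative choice.
Delays are abstract units when datasets have different sampling rates: no
resampling is performed, so a consensus delay means "the same number of
sampling steps later in every dataset", an ordering statement rather than a
clock time.  A gene excluded by its TDT in some dataset simply contributes
no rules there, which counts against support (the strictest reading of the
intersection).

Recommended operating point, used as package defaults: Accuracy 0.75,
SCP 0.95, RCA 1.0.

## Evaluation conventions

Reference association resources record undirected, delay-free gene pairs.
Inferred rule sets are therefore projected onto undirected pairs —
direction, delay and type collapse; self-loops drop — before computing
precision, sensitivity and specificity over the n(n−1)/2 pairs of the
analysis universe (20 genes give 190 pairs), so one benchmark association
can never validate several rules at once.  For scored references, the
average score is reported two ways: over matched pairs only (default) and
dividing the same total by all predicted pairs (unmatched predictions count
0); the choice matters only when precision < 1, and both numbers appear in
every metrics report.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets: K
replicate datasets over one shared gene list (so gene-universe
harmonization is the identity and consensus logic is exercised in
isolation), with known rules planted.  Each gene g has a latent threshold
θ_g ~ U(−0.5, 0.5) shared across datasets and expresses at θ_g ± margin
(margin 0.5 by default) according to a per-dataset random ±1 state
sequence, plus N(0, noise_sd) noise.  Two-level signals were chosen over
smooth dynamics because they make the planted thresholds analytically
recoverable — at zero noise the inferred TDT equals θ_g exactly and the RRT
is the regulator's low level — and because requiring at least two samples
per state side by construction keeps the TDT outlier guard from firing
accidentally.  Discretization is recoverable whenever noise_sd < margin/4;
pushing noise past that degrades recovery, which is what the monotone-noise
tests measure.  Planted rules overwrite target states at the planted delay
from the regulator states per the rule's logic, then flip each constrained
position with probability 1 − fidelity; an optional global state-flip
probability adds label noise on top.  Infeasible draws (a window losing
state balance) are re-drawn a bounded number of times from the same seeded
stream, so regeneration with one seed is bit-identical.

What the generator does *not* emulate: autocorrelated or periodic
dynamics, amplitude heterogeneity across genes, correlated measurement
error, missing values from array artifacts, or indirect (chained)
regulation.  Passing recovery tests therefore demonstrates correctness of
the search and consensus machinery under the stated conditions, not
performance on real microarray data.

Default study conditions for recovery checks: n = 12 genes, m = 20 time
points, K = 3 datasets, five two-sided rules at delays 0–3, zero noise.
Only two-sided (±1) rules are planted by default: with balanced regulator
states a one-sided rule covers about half the samples and cannot satisfy an
SCP near 1, so under the recommended operating point the recoverable
planted vocabulary is ±1.

**Recovery is scored at the pair level.**  A noiseless two-sided rule at
delay 0 makes its mirror (target and regulator swapped) exactly inferable
in every dataset, and a noiseless one-sided rule makes its contrapositive
inferable; these are logical consequences of the planted truth, not errors.
Directed precision against the bare planted list would therefore be
structurally below 1.  Recovery metrics consequently use the same
undirected-pair projection as the benchmark evaluation; directed identity
checks are additionally applied to lagged (w ≥ 1) planted rules, whose
mirrors are not implied.

## Numerical choices and edge cases

- Population variance throughout the TDT objective; ties to the smallest
  split index.
- RRT ties to the smallest threshold; candidate values are deduplicated.
- Entropy in base 2; 0·log 0 = 0; H of an empty side = 0.
- The consensus threshold ceil(RCA·K) is computed with a 1e-12 epsilon
  guard against the binary representation of RCA; it never changes an
  exactly-representable case.
- Thresholds compare with "> is up, ≤ is down" everywhere; a value exactly
  at a threshold is downregulated.
- Missing values must be resolved before inference: `drop_gene` (default,
  conservative: never invents values that feed the threshold search) or
  `row_mean`.  Genes missing everywhere are an error under `row_mean`.
- Duplicate gene identifiers are rejected, not aggregated: replicate-probe
  resolution is a preprocessing concern with no principled default here.
- Matrices with fewer than 5 time points are rejected outright.

## Known limitations

- Pairwise rules only; no conjunctive (multi-regulator) rules.
- No multiple-testing control over emitted rule sets; the Accuracy/SCP/RCA
  filters are the only guards against chance rules, and short series at
  large delays (m − w near 4) raise the chance-rule risk.
- Non-equidistant time points are the caller's responsibility: the package
  neither detects nor truncates them, it only assumes column order is
  temporal order.
- The evaluation layer assumes reference pair sets fit in memory as Python
  sets; it is not designed for genome-scale all-pairs scoring of millions
  of predictions.
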