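# Methods

## Reference scheme and variant space

A variant is identified by its *signature*: the residues at the targeted
interface positions, in ascending position order. The default scheme
targets positions 4, 35, 38, 68, 71, 97, 99 with WT residues S, I, N, S, V,
H, T over the fixed alphabet ACDEFGHIKLMNPQRSTVWY (alphabetical; the order
matters only for reproducible encodings and enumeration order). Residue
numbering is 1-based on the mature protein. The true WT scaffold sequence
is a user input (FASTA/YAML); the synthetic module fabricates a 127-residue
stand-in with the canonical letters planted at the seven positions, since
nothing outside the targeted positions affects any computation here.

Two variant-space conventions coexist and are used deliberately:

* `theoretical_variant_count(k) = C(n, k) * 20^k` — the library-inventory
  convention for the size of the k-mutation stratum. It admits the WT
  letter at a "mutated" position and therefore double-counts lower-order
  strata (k=1 gives 140, not 133); it is retained because published library
  inventories use it. The genuinely disjoint convention `C(n, k) * 19^k`
  sums to exactly 20^7 over k = 0..7, which the tests assert.
* The *fully mutated* space (19^7 = 893,871,739 signatures, every position
  non-WT) is the design-search space; the *full* space (20^7) is the
  percentile-ranking space.

Enumeration of the fully mutated space is streamed in (19)^2 = 361 batches
of 19^5, fixing two positions per batch (default: the last two targeted
positions). Any batch-position pair yields the same union, which is tested
on reduced schemes against brute-force enumeration.

## Enrichment ratios

Frequencies, WT-normalized frequencies, and enrichment ratios follow the
standard sort-seq chain (see README). Decisions where the procedure is
underdetermined:

* **Zero counts.** Variants absent from either fraction are excluded and
  tallied (`NOT_IN_PRESORT` / `NOT_IN_GATE`) rather than imputed; an
  optional pseudocount alpha adds alpha to every count before the frequency
  step and waives the presence requirement. Default alpha = 0, minimum
  raw count 1 (presence only).
* **WT anchoring.** WT must be present in both fractions; its NF is exactly
  1 and its log2 ER exactly 0 by construction (computed in double
  precision; log2 of an exact ratio of equal NFs returns exactly 0).
* **Filters.** Reads shorter than WT, with off-target mutations, or with
  non-alphabet characters are rejected with per-reason tallies;
  accepted + rejected equals input (tested as a conservation property).
* Multiple sequencing lanes per gate should be summed before analysis.

Scale invariance (all counts x c leaves every ER unchanged) and gate-swap
antisymmetry (log2 ER negates) are property-tested.

## Affinity model

* **Inputs**: one-hot signature, position-major blocks of 20 (140 features).
* **Architectures**: `Lib` (32 units, 20% dropout; 4 units, 10% dropout)
  and `Ala` (8 units, 0%; 2 units, 30%); ReLU hidden activations, single
  linear output. Parameter counts on 140 inputs: 4,649 (`Lib`) and 1,149
  (`Ala`), asserted in tests.
* **Loss/optimizer**: the training objective is not fully determined by the
  procedure being reproduced, so the package uses weighted mean squared
  error with Adam (beta1 = 0.9, beta2 = 0.999, eps = 1e-8) at the
  configured learning rate, fixed epoch count, no early stopping, no weight
  decay. Per-example weights multiply squared errors inside the minibatch
  mean.
* **Sample weighting**: optional weight = log2(presort reads + gate reads).
  A variant seen once in each gate gets weight log2(2) = 1; a variant with
  weight_raw = 1 would get weight 0 (no training influence) — under the
  presence-in-both-gates rule weight_raw >= 2 always.
* **Determinism**: every stochastic element (Glorot-uniform init, minibatch
  shuffling, inverted-dropout masks) is drawn from one per-member
  `numpy` generator seeded with the member seed; training is reproducible
  bit-for-bit given (data, hyper-parameters, seed). This is the reason the
  nets are hand-implemented in NumPy rather than delegated to a framework;
  at a few thousand parameters there is no performance argument against it.
* **Divergence**: a non-finite epoch loss, or one above 1e100, aborts that
  training run (Adam's normalized steps bound the update size, so runaway
  losses stay finite rather than producing NaN).
* **Ensemble**: 10 members with consecutive seeds base..base+9; the model
  prediction is their arithmetic mean. Tests verify the mean is exact, that
  the ensemble's seed-to-seed variance is below a single member's, and that
  a degenerate all-zero-label task regresses to ~0.
* **Split**: sort by summed read count descending (tie-break: signature
  ascending), first floor(0.1 N) to test, next floor(0.1 N) to validation.
  Deepest-read variants carry the least label shot noise, so they make the
  most reliable held-out sets. The split is frozen before any grid search;
  the test set is scored exactly once, for the winning combination.
* **Grid search**: full declared grid is 6 batch sizes x 5 epoch counts x
  6 learning rates x 2 architectures x 2 weighting modes = 720
  combinations; the selection criterion is validation Pearson (first-in-
  grid tie-break). The grid is configurable and tests exercise small grids
  through the same code path.

## Selective design

`top_k_fully_mutated` keeps a global top-k heap over the streamed batches
(ties broken lexicographically), equal by construction to the full sort,
which is tested on reduced schemes. The selectivity percentile of a
candidate under a model is the percentage of the evaluated space with
prediction *strictly greater* than the candidate's (ties count as not
exceeding). Exhaustive evaluation of 20^7 is supported but impractical on a
desktop; the default is Monte-Carlo with n = 1,000,000 seeded samples,
reported with its binomial standard error. The design report contains raw
predictions and percentiles for every supplied model and makes no automatic
final pick: near-ties on the primary objective are legitimately resolved by
the user (e.g., preferring the candidate with the larger off-target
percentile gap).

## Kinetics

The Morrison relative-velocity expression is evaluated in the
cancellation-safe form `1 - 2EI / (b + sqrt(b^2 - 4EI))`, `b = E + I +
Kiapp`, clipped to [0, 1]. Kiapp is the sole free parameter of each
replicate fit (scipy `curve_fit`, positivity bound, initial guess = the
inhibitor concentration nearest half-maximal inhibition); replicates are
fit independently and reported as mean +/- sample SD. Ki = Kiapp /
(1 + S/Km) with S and Km fixed assay constants (defaults: S = 7.5 uM;
Km = 3.607, 3.771, 4.75 uM for MMP-1, MMP-3, MMP-9; E = 0.325 nM).
Concentrations are handled in nM internally; S and Km enter in uM.
Initial rates from raw fluorescence traces use the least-squares slope over
the first 300 s by default, or an automatic best-R^2 prefix window.
Fold-change selectivity is Ki(enzyme)/Ki(reference), displayed as an
integer at >= 10 and to two significant digits below (raw ratios are
retained). Equilibration of the enzyme-inhibitor preincubation is assumed,
not modelled.

Independent validation against purified-protein measurements correlates
predicted log2 ER with log2(Ki / Ki_WT), normalizing each study by its own
WT to remove inter-study scale. The correlation is reported signed: gates
enriched for weak binders legitimately produce negative correlations, and
no sign convention is hard-coded.

## Synthetic data: what it emulates and what it does not

The generator plants an additive per-position energy landscape (i.i.d.
normal(0, 1) effects, WT letters fixed at 0; optional sparse pairwise
epistasis) and sorts variants into High/Low gates with probability
logistic((energy - mu)/tau), mu = 0, tau = 1, so WT sits at gate
probability 0.5 and log2 ER 0. Gate tables are multinomial draws at 10^6
reads per gate over a library of 5,000 distinct variants whose
mutation-number mix matches a published single-mutation-centred library
inventory (2.7% singles, 64% doubles, 31% triples, 1.7% quadruples, one
quintuple in expectation). These defaults are the stated world of the
end-to-end tests.

In the deep-read limit the measured log2 ER converges to log2 p_gate(v) -
log2 p_gate(WT), which `true_log2_er` returns as ground truth; at the
default depth labels carry realistic shot noise (roughly 0.1-0.3 in log2
units for typical variants).

Not emulated: sequencing errors and quality scores, PCR amplification bias,
codon-level mutagenesis statistics, cell-sorting impurities, and any
epistasis beyond sparse pairwise terms. A green end-to-end test therefore
establishes that the pipeline recovers a planted landscape under multinomial
sampling noise — not that the model family suffices for real epistatic
binding landscapes.

## Numerical and testing notes

* Published worked-example checks: recomputing the intrinsic-Ki column from
  *printed* apparent constants reproduces the printed values to one unit in
  the last printed digit (the original values were rounded from unrounded
  fits); selectivity folds 106x/121x and the ~2572-fold WT-to-variant
  affinity loss for MMP-1 reproduce from the printed Ki values.
* The exhaustive 19^7 design scan is exercised exhaustively only on reduced
  schemes (<= 4 positions, <= 5 letters) against brute-force oracles; the
  full-size path is the same code streaming larger batches.
* Pearson correlation is implemented from its definition and cross-checked
  against `numpy.corrcoef` to 1e-12; constant vectors raise rather than
  returning NaN.
* All generators, training runs, and sampled design modes are reproducible
  given seeds; report files are byte-identical across reruns.

## Known limitations

* Training is single-threaded NumPy; a full 720-point grid search with
  10-member ensembles on a ~5,000-variant dataset is hours of CPU, not
  minutes. The default pipeline trains one configuration.
* The sampled percentile mode estimates, rather than enumerates, the 20^7
  ranking; its Monte-Carlo standard error is reported and should be quoted
  with the percentile.
* `fit_ki` assumes pre-normalized relative velocities or raw slopes with an
  I = 0 anchor; it does not model substrate depletion over the assay
  window or slow-binding kinetics.
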