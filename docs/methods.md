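# Methods

## The ordering model

All statistics in `reosig` are functions of within-sample orderings only.
For a gene-by-sample matrix X (any strictly monotone scale — raw intensity,
log2, ranks), the primitive observation is the indicator
1[X(A, s) > X(B, s)] for a gene pair (A, B) in sample s. Everything built on
it — stable pairs, concordance, rank-difference scores, majority votes — is
therefore exactly invariant under any strictly increasing per-sample
transform, which is the formal content of "insensitive to batch effects and
normalization". The package never rescales input values.

**Ties.** Equal values are counted as "not higher" for *both* directions.
A tie can therefore reduce support for both orderings but can never create
reciprocal stability, and in classification a tied signature pair is not a
class-1 vote. Data on a continuous scale rarely tie; heavily rounded data
will bias supports downward symmetrically.

## Stable and characteristic pairs

An ordered pair (A, B) is stable at threshold t when
count(A > B) / n_samples > t, strictly. The default t = 0.95 means support
exactly 0.95 (19 of 20 samples) fails. Because t > 0.5 and ties count
against both directions, at most one direction per unordered pair can be
stable. Characteristic pairs of a class are the direction-preserving
intersection of the stable sets of all its datasets; cross-dataset
comparisons require an explicit prior `intersect_gene_universe` step — the
package never intersects implicitly, so each dataset's stable set is always
defined on its own gene universe.

The all-pairs scan is O(G² · S) comparisons. It is blocked over gene chunks
under a `max_block_bytes` ceiling (default 64 MB of boolean workspace) and
the blocked result is bit-identical to the naive double loop — a contract
enforced by test, not an approximation.

## Concordance and its null

For two stable-pair lists sharing k unordered pairs with s direction
agreements the score is s/k × 100%. Chance agreement is modelled as
X ~ Binomial(k, P_e) with P_e = 0.5 by default (each shared pair agrees by
coin flip), and the reported p-value is the upper tail P(X ≥ s), evaluated
through the regularized incomplete beta (`scipy.stats.binom.sf`), which
remains accurate for k ~ 10⁸. s = 0 returns exactly 1. The log10 tail is
stored alongside so underflowing values (the display floor is "< 2.2e-16")
remain comparable. If the lists share no pair, the score is reported as
not-applicable with p = 1 rather than as 0%.

Per-sample concordance applies the same counting to one profile against a
reference direction set: pairs with a gene absent from the profile are
excluded from the denominator and reported, and zero evaluable pairs is a
hard error rather than a silent 0.

## Signature selection

Reversed pairs — stable as (A, B) in class 1 and as (B, A) in class 2 — are
scored two ways: each gene's appearance frequency across all reversed
pairs, and each pair's ΔavgR, the mean absolute within-sample rank
difference over all training profiles of both classes (ranks 1..G ascending
per sample, ties averaged; the direction of ranking is irrelevant to the
absolute differences). Genes are visited in decreasing frequency order and
each contributes its maximal-ΔavgR reversed pair; a pair already
contributed by an earlier gene is skipped rather than replaced, so the
candidate list has one entry per contributing gene and no duplicates. All
tie-breaks (equal frequencies, equal ΔavgR) are lexicographic on gene
identifiers: the input gives no other canonical order and determinism is a
requirement, not a preference.

Odd sizes n = 1, 3, …, max_n (default 43, clamped to the candidate count)
are scanned by classifying the pooled training samples of both classes with
the first n candidates; the chosen size is the smallest n attaining the
scan's maximum pooled accuracy. On data where a single reversed pair
already separates the classes perfectly this rule picks n = 1 — the scan
curve is flat at 100% from the start, so there is no plateau onset to
detect. Larger signatures still matter for robustness to flipped orderings
in new samples (see the metastasis results), which is why downstream
application in the bundled study uses the full candidate list rather than
the minimal chosen size; the scan result reports both.

## Majority voting

A sample is predicted class 1 iff strictly more than half of the evaluable
signature pairs show the class-1 ordering. With an odd number of evaluated
pairs no tie is possible; with an even number (some signature genes missing
from the platform) an exact half-split falls to class 2 by strictness.
Missing-gene pairs are skipped and counted by default — the intended
cross-platform use case — and `strict=True` refuses such samples instead.
Columns are classified independently; there is no cross-sample coupling of
any kind.

## The synthetic generator

The generator emulates the statistical structure the pipeline consumes, not
microarray physics:

- Baseline gene means are uniform on [4, 12] (a log2-like scale), shared by
  both classes, so most pairs order stably in both classes.
- Each of `n_reversed` planted pairs occupies an exclusive mean window of
  width equal to the planted margin, centred at evenly spaced positions;
  the two genes sit at the window edges and their means are swapped between
  classes. The exclusivity is essential: any background gene with a mean
  strictly between the swapped values would itself reverse against both
  planted genes, so without reserved windows a handful of planted pairs
  induces hundreds of collateral reversed pairs and exact recovery of the
  planted set would be impossible by construction.
- The margin is max of (i) √2 · noise_sd · Φ⁻¹(stability), which makes a
  single sample realize the planted ordering with probability `stability`
  under iid Gaussian noise (the within-sample difference of the two genes
  is N(margin, 2·noise_sd²)), and (ii) the `rank_gap` target converted to
  mean units through the baseline density G / (base_high − base_low) and
  capped at 0.9 · range / n_reversed so the windows always pack. With the
  defaults (rank_gap 60, noise_sd 0.2) the gap term dominates and planted
  orderings are near-deterministic; setting rank_gap = 0 hands control to
  the stability calibration, which the tests verify empirically.
- Noise is iid additive Gaussian per entry; `batch_shift` adds a constant
  to one dataset (a monotone change, so provably inert); monotone
  distortions (exp, positive affine, random increasing piecewise-linear
  curves) model scale differences between laboratories.
- Metastasis-like samples draw from the class-1 model, then
  round(admixture · n_planted) randomly chosen planted pairs per sample
  have their two genes' values swapped — a clean ordering flip toward
  class 2 that leaves all other orderings intact (the swapped values stay
  inside the pair's exclusive window). The default admixture 0.2 flips one
  of the five planted orderings per sample.

Everything is a deterministic function of the config; the mean model, the
class noise, and the metastasis stream use separate seeded substreams so
metastasis generation can reconstruct the class-1 means without replaying
the class noise.

**What passing synthetic tests does not show.** The generator's noise is
iid and Gaussian, its reversed pairs are disjoint and cleanly separated,
and its gene universes are identical across "datasets". Real cohorts have
correlated genes, hub-structured reversed pairs (one gene reversing against
many partners), probe-level artifacts, and partially overlapping platforms;
recovery and accuracy results on the synthetic cohorts bound the method's
behaviour only under the stated model.

## Study sizes

The bundled study (`scripts/acceptance.py`) and the test suite run at desk
scale — 500 genes (124 750 pairs), 50–150 samples per class, 20
metastasis-like samples, 100-seed sweeps — chosen so the complete pipeline,
including the blocked all-pairs scans, runs in seconds to a few minutes on
one CPU while still exercising every stage at non-trivial size.

## Numerical and degenerate-input policy

- Stability comparisons use the correctly rounded quotient count/n against
  the user threshold; oracle and blocked implementations share the same
  arithmetic, so equality is exact.
- Binomial tails are computed in the beta representation; log-space values
  accompany linear ones.
- Missing expression values are rejected by default (ordering counts have
  no NA semantics); an explicit flag drops incomplete genes instead.
  Duplicate gene or sample identifiers, non-numeric cells (reported with
  row/column coordinates), matrices with fewer than two genes, empty gene
  intersections, empty pair sets where counts are required, and
  unclassifiable samples are all hard errors.
- Probe collapsing keeps the highest-mean probe per gene by default
  (averaging log-scale probes can invert orderings); `mean` is available.
  Ambiguous probes (mapping to several genes) are dropped during annotation
  cleaning. Gene identifiers are opaque case-sensitive strings; no symbol
  aliasing is attempted.

## Known limitations

- Two classes only; no multi-tissue panels, no probabilistic outputs.
- The stability threshold is a hard cutoff; near-threshold pairs are
  sensitive to single samples at small n (19/20 vs 20/20 at t = 0.95).
- Signature selection offers no cross-validation; the size scan is
  evaluated on the training pool and will overfit small cohorts.
- The generator does not simulate probe effects, saturation, RNA
  degradation, or normalization pipelines; it is a stand-in with explicit,
  documented structure.
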