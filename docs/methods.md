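# Methods

This note documents the statistical model behind `anchorcorr`, the
conventions and defaults it adopts where the procedure is genuinely
open, what the synthetic generator does and does not emulate, and the
numerical choices that make runs reproducible.

## The meta-analytic model

The unit of evidence is one expression dataset: a genes × samples
matrix on log2 scale whose samples fall into cancer, non-cancer disease
and normal classes. Analyses never pool samples across datasets; every
statistic is computed per dataset and only the *decisions* (significant
/ selected / called) are combined, which is what makes the procedure
robust to platform and cohort effects.

**Anchor differential expression.** Per dataset and comparison, the
anchor's log2 fold change is the difference of class means
(equivalently the log2 ratio of geometric means). Inference uses a
paired t-test (one-sample t on differences, df = n−1) when explicit
cancer/normal pairing metadata exists, and Welch's unequal-variance
t-test with Welch–Satterthwaite df otherwise — the dispatcher records
which ran, so mixed collections are handled without guessing per-dataset
intent. Degenerate inputs resolve deterministically: equal means with
zero variance give p = 1; unequal means with zero variance give p = 0
with a warning. Cross-dataset tallies report k of d datasets significant
at α = 0.05 with percentages rounded half-up (14 of 21 → 67%). Only the
anchor is tested, so no gene-wise multiple-testing correction arises.

**Correlation.** For each gene, the Pearson coefficient with the anchor
is computed over pairwise-complete observations pooled across *all*
samples of the dataset (classes mixed — part of the correlation may be
driven by shared differential expression, which is intended by the
design; a `center_by_class` generator switch exists to study the
alternative convention). Significance uses the Fisher z transformation:
z = atanh r, two-tailed p = 2·(1 − Φ(|z|·√(n−3))). Genes with fewer
than 6 pairwise-complete values or zero variance are dropped with a
logged count. Ranking is by ascending p with ties broken by descending
|r| and then gene symbol, making ranks unique and runs reproducible.

The Fisher z p-value is a large-sample normal approximation. Measured
against the exact t-based test it stays within 10% relative error
wherever the p-value is moderate (p ≥ 0.01 for n ≥ 50; within 15% at
n = 20), but the relative error grows without bound in the far tail
(already ~12% at n = 200, r = 0.5). Because both p-values are strictly
monotone in |r| at fixed n, rankings and threshold selections are
unaffected; only literal interpretation of extreme p-values should be
avoided. The test suite pins this with an exact-rank-equivalence check
and a seeded 10⁵-draw permutation oracle at n = 28, where the two agree
within 5%.

**Selection.** Candidates are genes with p below a cutoff, 0.001 by
default — on real tumor collections that cutoff yields several hundred
candidates per dataset, and a warning fires when fewer than 600 appear.
From the candidates, a per-tissue top fraction is selected (defaults
0.20 / 0.15 / 0.10 / 0.05 for thyroid / colon / liver / lung,
reflecting how candidate abundance differs by tissue); "fraction of
candidates" is the default reading, with `fraction_base="all_genes"`
exposing the alternative. A fraction of 1.0 reduces selection to the
p-cutoff alone.

**Consensus.** Within one cancer type with d datasets, a gene selected
in k datasets is called when k ≥ 2 and |r| ≥ 0.6 in at least one
qualifying dataset. Each call carries the binomial presence p-value
P(X ≥ k), X ~ Binomial(d, f), where f is the per-dataset selection
probability of a background gene — the tissue's top fraction under
quota selection, or the p-cutoff when selection is by p alone. The
presence rule, not the binomial test, governs calling by default: with
the default fractions the literal test cannot reach p < 0.05 at k = 2,
d = 3, f = 0.20 (p = 0.104), so enforcing it would silently empty some
tissues; a `strict_binomial` flag enables the literal rule, and the
p-value is always reported. Sign classes (positive / negative / both)
are computed over qualifying records, globally across tissues for the
overall tally, and positive + negative + both partitions the called set
by construction.

**Pathway clustering.** Keyword families over lower-cased bio-function
terms, matched in the fixed precedence cancer > cell_cycle > growth >
death (anything unmatched is "other"); cell_cycle, growth and death
roll up to "cancer related". Short keywords ("growth", "death") and the
phase patterns ("m phase", "s phase", "g2 phase") match at word
boundaries to avoid hits inside longer words. The families live in an
editable YAML file; the packaged default covers the standard
tumor-biology annotation vocabulary, with "G2/M/S phase" expanded to
its constituent patterns. Composition reports filter to enrichment
p < 0.01 and print half-up integer percentages.

**Validation scoring.** IHC score tables carry case counts at three
staining levels with ++/+++ as the overexpression level; percentages
are half-up at one decimal. Group comparisons use a frequency-weighted
Welch test (weighted means; variance with denominator Σw − 1; weighted
Welch–Satterthwaite df) that reduces exactly to the unweighted Welch
test at unit weights — a declared convention, since marginal score
counts do not determine the original per-case analysis. qRT-PCR
knockdown records hold expression in knockdown (shR) cells relative to
control (shN ≡ 1); the knockdown fold change is the reciprocal, and a
record is consistent when the fold direction matches the predicted
correlation sign. A band of ±0.1 around fold 1 is scored "unchanged" so
the classifier is total on arbitrary inputs; none of the bundled
thirty-gene panel falls inside it. Predicted signs are inputs, not
outputs: the bundled panel carries the sign assignment implied by its
published consistency labels under the reciprocal-fold convention.

## The synthetic generator

`simulate_collection` emulates the statistical skeleton the pipeline
assumes: several datasets per tissue (default 3/4/3/3, thirteen in
all), each with cancer/disease/normal samples (default 50 cancer + 50
normal), one anchor gene with a class mean shift of
log2(anchor_fold_change), optional planted genes with an exact target
population correlation to the anchor, and independent Gaussian
background genes.

Planting uses the closed form β = r·σ_ε / (σ_a·√(1−r²)) for
gene = β·anchor_dev + ε, which makes the population Pearson r equal the
target exactly; `anchor_dev` is the anchor's pooled deviation by
default (matching the pooled correlation convention) or its
within-class deviation under `center_by_class`. Defaults and their
rationale:

| parameter | default | why |
|---|---|---|
| anchor_fold_change | 1.75 | mid-range of the 1.25–2.43 folds reported for the motivating anchor across cancers |
| noise_sd (log2) | 1.0 | typical residual SD of normalized array log-intensities; not a claim about any specific platform |
| batch_sd | 0.0 | no batch structure is asserted by default; paired designs share the pair's batch offset when enabled |
| baseline_log2 | 8.0 | mid-scale intensity; cancels from every statistic the pipeline computes |
| samples | 50 + 50 | 100-sample datasets, within the 50–300 range typical of public collections |

Per-dataset seeds are derived as SeedSequence(master_seed,
CRC32(dataset_id)) — platform-independent and stable, so a fixed config
is bit-reproducible file for file. Matrices are emitted as linear
mono-channel intensities (2^log2) by default so the log2 preprocessing
step is exercised; `output_scale="log2"` emits analysis-ready values.

What the generator does **not** emulate: probe-level structure beyond
an optional duplicate-probe mode (two probes per gene, for collapse
tests), heavy-tailed or intensity-dependent array noise,
platform-specific missingness, correlated background modules, or the
thousands of genuinely co-regulated genes real tumors contain. Passing
recovery benchmarks therefore demonstrates that the *procedure* is
correct and calibrated — not that any particular biological gene list
would be recovered from real data.

## Reference studies and their problem sizes

The `studies` module fixes the benchmark designs used by the tests and
the reproduction script; sizes are chosen to give tight Monte-Carlo
error while running in seconds to a few minutes on one CPU.

* **Consensus recovery** — 13 datasets (3/4/3/3), 5,000 background
  genes, 50 planted at |r| = 0.8 (35 positive, 15 negative), 100
  samples each. Selection is by p < 0.001 alone (top fraction 1): with
  only 50 truly correlated genes the candidate lists hold ~55 genes,
  so per-tissue quotas of 5–20% — sized for real collections with
  hundreds of correlated genes — would discard most planted genes by
  construction; the quota mechanics are exercised separately on
  engineered fixtures. Expected recovery is effectively 100% (a planted
  |r| = 0.8 at n = 100 has sampling SD ≈ 0.036, far from both the
  0.001-cutoff boundary and the 0.6 rule); the binomial-null
  expectation of background calls is ~0.08 genes, and the observed
  count is compared against 3× that expectation.
* **Anchor test calibration** — 200-replicate designs at fold 1.0
  (type-I error) and fold 1.25 with noise SD 0.5 (power). The exact
  noncentral-t power of the fold-1.25 design is 0.890, so observed
  rates are judged against binomial confidence bounds rather than point
  values; pooled over 14,000 replicates the measured type-I error is
  0.047.
* **Permutation oracle** — n = 28 fixtures constructed with exact
  sample correlations 0.2 / 0.3 / 0.45 (noise orthogonalized against
  the predictor), compared to a seeded 10⁵-draw permutation null; these
  sit where the permutation p-value is resolvable and the Fisher z
  approximation is accurate.
* **Null uniformity** — 2,000 independent genes at n = 100, KS test
  against Uniform(0,1).

## Known limitations

* Enrichment p-values for pathways are consumed, not computed; the
  clustering reproduces a keyword characterization, not any annotation
  engine's output.
* The weighted IHC group test is a convention (see above); published
  tissue-array p-values computed from per-case data are generally not
  reconstructible from marginal score counts.
* Two-channel ratio orientation (cancer/normal vs normal/cancer) is
  taken from configuration, never guessed from data.
* The Fisher z p-value's far-tail behavior (above) makes extreme
  per-gene p-values approximate; all selection logic is rank- and
  threshold-based and unaffected.
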