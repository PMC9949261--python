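# Methods

## Measurement model

A multiplex TCRβ PCR with `|V|` forward and `|J|` reverse primers defines
`|V|·|J|` primer pairs (20 × 13 = 260 by default), each with its own
amplification efficiency. An equimolar mix of synthetic templates (ST) —
one 200-bp double-stranded template per pair, carrying a 9-bp barcode
common to all templates and a 16-bp pair-specific barcode — is spiked
into the reaction, so the post-sequencing ST counts measure per-pair
efficiency directly.

Replicate counts for a fixed template *i* across a batch of *n* samples
are treated as i.i.d. negative binomial in the mean-dispersion
parameterization:

    C_ij ~ NB(m_i, d),   E C = m,   var C = m + d·m².

`d = 0` reduces to Poisson; over-dispersion is measured relative to
Poisson. On a log-log mean-variance plot the model line `v = m + d m²`
has slope → 2 for large m (`log v ≈ log d + 2 log m`), which is the
quantity `scripts/acceptance.py` recomputes by simulation.

Key estimators:

* `m_i` — arithmetic mean of template *i*'s counts (this is the exact NB
  MLE of the mean, independent of d).
* `d_i` — maximizer of the profile log-likelihood in d with `m_i` fixed
  at its MLE, on `[0, d_max]` with `d_max = 10`, using a bounded Brent
  search at absolute tolerance 1e-8. Under-dispersed data clip to the
  Poisson boundary `d = 0` (the Poisson log-likelihood is compared
  against the interior optimum explicitly).
* common dispersion — the **median** of the per-template `d_i`, not a
  pooled MLE; the median is robust to the handful of templates whose
  20-replicate dispersion estimate is erratic.

## Scaling factors and normalization

* Batch-mean factors: `SF_i = C_i• / C••` (template batch mean over the
  grand mean of template means). Distribution-free, unit mean by
  construction.
* NB-mean factors: `m_i / m•` with `m• = mean_i(m_i)`. Numerically
  identical to batch-mean factors on the batch they were fitted from
  (the MLE-mean identity), but applicable to samples sequenced without
  spike-ins.
* Pooling across batches ("combined estimates"): each batch's mean
  vector is divided by its own grand mean — removing the batch's overall
  spike-in concentration — then averaged across batches with weights
  proportional to batch sample counts and rescaled to unit mean. This
  rule is scale-invariant per batch (multiplying any batch's counts by a
  positive constant changes nothing) and reduces to the single-batch
  relative means; it is the package's own pooling choice.

Normalization divides each primer-pair total by its factor,
`C'_i = C_i / SF_i`, and assigns each clonotype the same proportion of
the normalized pair total that it held of the raw one — algebraically,
every clone count is divided by its pair's factor. Consequences asserted
as exact identities in the tests: the ST grand total is conserved under
batch-mean factors applied to the generating matrix; within-pair clone
proportions never change; re-deriving factors from an already-normalized
matrix yields factors ≡ 1. Normalized counts are real-valued and are
not re-rounded (downstream metrics are frequency-based; rounding would
break conservation). Templates with zero counts receive *no* factor;
normalizing a pair that carries clonotype reads but has no factor raises
an error rather than silently passing raw counts through.

## Demultiplexing

Merged reads are classified by the universal 9-bp barcode, then assigned
by the 16-bp specific barcode, both at Levenshtein distance ≤ 1 — the
operational reading of "one mismatch or indel". The window search is a
semi-global DP (vectorized over read offsets) that reports the globally
minimal-distance window, leftmost on ties; the 260-way specific-barcode
scan uses edlib's infix mode with an early cutoff at distance 1. Reads
are searched in both orientations by default (merged reads can be
reverse-complemented); the better-scoring orientation wins, forward on
ties. Flagged reads without a unique specific match — a tie at minimal
distance, or no match within tolerance — are counted as ambiguous and
dropped, never fractionally allocated. Random barcode designs are
rejection-sampled to pairwise edit distance ≥ 3 (and universal-to-window
distance ≥ 3), which makes ties impossible for generated designs; the
ambiguous path exists for user-supplied designs.

## Dependence diagnostics

Per-pair means arranged on the V × J grid are treated as a contingency
table; deviation from row/column independence is measured by signed
Pearson residuals `(O − E)/√E` with `E = row total × column total /
grand total`, positive = over-represented. The sum of squared residuals
equals the classic chi-squared statistic (cross-checked against
`scipy.stats.chi2_contingency` in the tests). The default input is the
pooled mean matrix rather than a single sample, to suppress sampling
noise. Rows and columns are ordered by average-linkage hierarchical
clustering on Euclidean distances of residual profiles; linkage and
metric are pinned for determinism. The chi-square ≈ degrees-of-freedom
calibration property is exercised with Poisson sampling (`d = 0`): under
NB over-dispersion the statistic scales like `(1 + d·E)` per cell and
exceeds the nominal df even without interaction, so the Poisson regime
is the one where the classic calibration is informative.

The independence floor on post-normalization spread is estimated by
Monte Carlo: replicate matrices of *independent* equimolar NB counts are
normalized with factors estimated from themselves, and the within-sample
Q3/Q1 fold and CV are summarized across replicates (for Poisson counts
the CV floor is ≈ 1/√m, used as a closed-form cross-check). Observed
spreads below this floor indicate positive dependence between templates.

## Repertoire metrics

Shannon diversity `H = −Σ p ln p` in nats (base-2 via a flag); clonality
as the normalized-entropy complement `1 − H/ln R`, clipped to [0, 1]
against float round-off, with the degenerate single-clone repertoire
defined as clonality 1 (with a warning). Hyperexpanded fraction sums
frequencies above a configurable threshold, default 0.01. Dropout
tabulation keys clones by the exact (CDR3 nucleotide, V, J) triple, no
fuzzy CDR3 clustering; with a `top_fraction`, the union of each
replicate's most frequent fraction is scored against full replicate
membership.

## Simulator: what it emulates, and what it does not

`BiasModel.separable` draws per-pair log-efficiencies as a sum of
uniform V and J effects spanning `log_spread` natural-log units (default
4, ≈ 55-fold between weakest and strongest pair), recentred to a grand
mean of `mean_level` (default 5000 reads per template per sample — the
order implied by a mid-output sequencing run split over tens of samples
and 260 templates); dispersion defaults to 0.125. Counts are sampled as
a gamma-Poisson mixture (shape 1/d, scale m·d), which reproduces
`var = m + d m²` exactly; `d = 0` short-circuits to `Poisson(m)`. An
optional multiplicative V × J interaction matrix layers dependence on
the separable effects. Repertoire sampling scales clone frequencies by
their pair's efficiency and conserves total depth in expectation;
FASTQ fixtures embed universal + specific barcode at random offsets with
uniform substitution errors and constant placeholder qualities.

Features of real data the generator does **not** model: correlated
(non-independent) template counts within a sample beyond the optional
interaction layer, ST-gDNA competition and depth loss, PCR chimeras,
indel sequencing errors, quality-score structure, and paired-end reads
(reads are pre-merged singles). Passing tests therefore demonstrate the
correctness of the estimators and the normalization algebra under the
stated NB model — not that real libraries meet the model's assumptions;
the mean-variance diagnostic exists precisely to check that on data.

## Problem sizes and numerical choices

Simulation-based tests run at the design scale of 260 templates × 20
samples where the property depends on it (dispersion recovery over 50
seeded replicates; the sub-two-fold normalized spread), and on small
panels (4–12 pairs) everywhere the property is algebraic. Quantiles are
type-7 (numpy default) throughout, pinning the "two-fold" Q3/Q1 reading.
All randomness flows through `numpy.random.default_rng` seeds; identical
seeds give byte-identical outputs, including pipeline TSVs.

## Known limitations

* The dispersion MLE is biased low at small replicate counts (the usual
  ML bias); at n = 20 the median common dispersion sits a few percent
  below truth, well inside the ±25 % recovery band asserted in tests.
* The pooling rule and the independence floor are simulation-backed
  design choices, not closed forms.
* Clonality/diversity definitions follow the field-standard
  normalized-entropy forms; other tools' variants may differ in
  normalization details.
* V/J name matching is exact (after whitespace trimming); no IMGT
  nomenclature or allele-level resolution.
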