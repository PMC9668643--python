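# Methods

`sigreverse` implements signature-reversal drug repurposing: the hypothesis
that a compound whose transcriptional perturbation profile *negates* a
disease expression signature may counteract the disease. The pipeline runs
in five stages — differential expression, signature extraction,
connectivity scoring against a perturbagen compendium, pre-ranked gene-set
enrichment, and validation-annotation counting — with a synthetic-data
generator standing in for the public expression series, the perturbagen
compendium, and the pathway collections the real workflow would download.

## Differential expression

The input is a log2-scale gene × sample matrix with each sample labelled
`normal` or `disease` (the label `Psoriasis` is accepted as a synonym of
disease, case-insensitively). A matrix whose 99th-percentile value exceeds
50 is judged to be on the raw intensity scale and is transformed by
log2(x + 1) with a warning, mirroring the auto-detection of common
microarray front-ends.

Per gene, the log2 fold change is defined as disease mean − normal mean, so
a positive value means up-regulated in disease. Two test modes are offered:

- **moderated** (default): the empirical-Bayes moderated t. Per-gene pooled
  residual variances s²_g with d = n₁ + n₂ − 2 degrees of freedom are
  shrunk toward a prior: s̃²_g = (d₀·s₀² + d·s²_g)/(d₀ + d), with the prior
  (d₀, s₀²) estimated by method of moments on log s²_g — the standard
  scaled-F hierarchical model, with the trigamma moment equation solved by
  Newton iteration. The moderated t uses s̃²_g and is referred to a t
  distribution with d + d₀ degrees of freedom (normal when d₀ is infinite,
  which happens when the observed spread of log variances does not exceed
  what a single common variance explains).
- **welch**: the Welch unequal-variance t with Welch–Satterthwaite degrees
  of freedom, implemented explicitly so the degenerate-variance rule below
  can be applied; it is cross-checked against `scipy.stats.ttest_ind` in
  the tests.

Genes with exactly zero variance are not dropped: their variance is floored
at the smallest positive per-gene variance × 10⁻³ with a warning, so a gene
that is constant within groups but shifted between them still surfaces
(with an extreme statistic) rather than silently disappearing. P-values are
two-sided throughout; multiple testing uses Benjamini–Hochberg step-up
(via `statsmodels`), which the test suite checks against a literal
quadratic-time step-up oracle.

## Signature extraction

A disease signature is a pair of ordered "tag" lists. Genes qualify upward
when adjusted p < 0.05 and log2FC ≥ 1, downward when adjusted p < 0.05 and
log2FC ≤ −1; the absolute fold-change window (−1, 1) is treated as an
*exclusion* zone, since selecting genes inside it would contradict the
notion of up-/down-regulated genes. Each direction is ranked by log2 fold
change (the stated ranking quantity; adjusted p-value and then gene ID
break ties so the output is bit-stable) and truncated to the top 100.
Filtering precedes ranking and truncation. A direction with fewer than 100
passing genes yields a shorter list with a warning; an empty direction is
an error naming the direction. All three thresholds are parameters
(`SignatureParams`).

## Connectivity scoring

Each perturbagen is a full ranking of the gene universe, rank 1 = the gene
the drug up-regulates most. The enrichment of a tag set in a ranking uses
the classic unweighted two-sample KS construction: with sorted hit ranks
r(1) < … < r(t) in a profile of n genes,

    a = max_i [ i/t − r(i)/n ],   b = max_i [ r(i)/n − (i−1)/t ],
    ES = a if a ≥ b else −b.

Ties between a and b resolve to the positive branch. The unweighted form is
used because the scoring here follows the plain KS statistic, not the
L1000 weighted variant. Query tags absent from the universe are dropped
with a warning; a direction reduced below 10 tags warns (the practical
minimum of connectivity-map queries), below 1 errors.

The bidirectional **raw connectivity** is (ES_up − ES_down)/2, clamped to 0
whenever both directional scores share a strict sign (a profile that moves
both tag sets the same way carries no reversal information). This places
the score in [−1, 1], negative when the profile reverses the signature.

**τ normalization.** Each perturbagen carries a stored set of reference
("touchstone") scores: raw connectivities of n_ref random reference queries
(default 100; minimum 20) against that same profile. τ is the signed strict
percentile

    τ = sign(raw) · 100 · #{reference r : |r| < |raw|} / n_ref,

hence in [−100, +100] with τ = 0 for raw = 0; a score dominating every
stored reference attains ±100. |τ| is monotone in |raw| for a fixed
reference set. The most negative τ is the strongest reversal candidate;
candidates are ranked by τ ascending with ties broken by raw score
ascending and then perturbagen ID, and the ranked table is truncated to the
top 150 by default.

**Permutation p-values.** The null draws random signatures with the query's
tag-list sizes (up- and down-tags sampled jointly without replacement, so
they are disjoint, like real signatures) and uses the plus-one estimator
(1 + #{|raw_perm| ≥ |raw|})/(n_perm + 1). Because the hit positions of a
uniformly random tag set in *any* fixed permutation are a uniformly random
rank subset, the null law depends only on the universe size and tag sizes —
`score_compendium` therefore draws a single null pool per call and shares
it across perturbagens, which is distributionally identical to per-profile
permutation and removes a factor of n_perturbagens from the cost.
`permutation_pvalue` for a single profile keeps the literal construction.
FDR is Benjamini–Hochberg over all perturbagen p-values.

One calibration subtlety follows from the same-sign rule: a random
bidirectional query has raw score exactly 0 with probability ≈ 1/2 (the two
directional scores agree in sign), so the null has an atom at 0 and the
permutation p-value has a matching conservative atom at p = 1. Conditional
on a nonzero raw score the p-values are uniform; the calibration test
checks exactly that conditional uniformity plus the atom mass.

## Pre-ranked gene-set enrichment

Genes are ranked by a signed metric — by default the moderated t-statistic,
which folds the two stated ranking ingredients (significance and fold
change) into one standard quantity; raw log2FC is selectable. The weighted
running sum with exponent 1 walks the ranked list: a hit increments by
|metric|/Σ_hits|metric|, a miss decrements by 1/(N − N_hits); the ES is the
signed maximum deviation from zero (positive-branch tie-break; ES = 1 by
definition when the set is the whole universe; an all-zero-weight hit set
falls back to equal increments). The null is gene-set permutation — random
same-size sets from the ranked universe — matching pre-ranked semantics:
NES = ES / mean(|null ES| of the matching sign), p is the plus-one fraction
of same-sign null scores at least as extreme. Sets with no overlap are
skipped with a warning. The ES definition is verified in the tests both
against a literal O(N) running-sum oracle and against gseapy's pre-ranked
implementation.

## Synthetic data

The generator supplies every external input with planted ground truth, all
pure functions of `SimulationConfig` (each generator derives its RNG stream
from the config seed, so generators can recompute each other's planted
choices).

- **Expression** is simulated directly on the log2 scale — per-gene
  baseline means ~ N(8, 1.5²), within-gene Gaussian noise with sd
  `noise_sd` — matching the post-normalization behavior of microarray
  data; no raw-intensity model. Planted up/down genes shift the
  disease-group mean by ±`effect_size`.
- **Compendium**: planted reversers place the query's down-tags at the top
  ranks and up-tags at the bottom (mimics the opposite); the rest are
  uniform random permutations. `profile_noise` then applies
  round(fraction × n_genes) random adjacent transpositions per profile — a
  deliberately simple degradation that is monotone in severity. Reference
  scores are generated by scoring n_ref random queries per profile.
- **Gene sets** are sampled without replacement within each set; when
  genes are planted, the first set (`SET_PLANTED_UP`) is built from the
  planted up-regulated genes as a downstream positive control. The
  collection round-trips through standard GMT.

Defaults are desk scale, chosen as what a two-group skin-biopsy microarray
study and a drug-screening compendium look like when shrunk to seconds of
compute: 5,000 genes, 20 + 20 samples, 500 perturbagens with 10 reversers
and 10 mimics, effect size 2 log2-units at noise sd 0.5 (a strong but
realistic microarray effect; detection power near 1 at n = 20 per group),
profile noise 0.02, 50 gene sets of 100 genes. The real series have tens
of samples per group and 10⁴–10⁵ probes; no source states their noise or
effect magnitudes, so these defaults are simulation conditions, not
estimates of any real dataset. What passing tests show is therefore that
the *machinery* is correct and calibrated — planted signal of stated size
is recovered, null inputs are not called — not that any real-data result
is reproduced: the generator has no probe-level artifacts, no correlated
genes, no batch structure, and no dose/cell-line replicate structure.

## Pipeline and reproducibility

`run_all` chains the stages, writing per-stage CSVs, each with a header
comment carrying the seed and a hash of the analytic configuration
(output directory excluded), plus a `manifest.json` echoing the config,
seed, library versions and per-stage row counts. The manifest carries no
timestamp, so a rerun with identical inputs and config is byte-identical.
With a fixed seed every stochastic quantity (permutation p-values,
reference queries) is reproducible; the τ of a noiseless planted reverser
is deterministic — it does not move with the seed at all.

The validation stage implements only the decision rule of the two-step
literature check: a user-supplied annotation CSV (drug_id, supported,
denied) is joined to the ranked candidates; supported-only → validated,
supported-and-denied → contradicted (excluded from the validated count),
otherwise untested; the summary reports validated/candidates. Automating
the underlying literature/EHR/patent search is out of scope.

## Known limitations

- The moderated model assumes exchangeable per-gene variances from one
  scaled-F prior; no covariates, pairing, or batch correction.
- Connectivity uses the unweighted KS statistic on full rankings; no
  replicate summarization across cell lines, doses, or times, and no
  inference of unmeasured genes.
- τ percentiles rest on n_ref stored reference scores; at the default
  n_ref = 100 the τ grid has 1-point resolution, and a null drug can reach
  ±100 by chance with probability ≈ 1/(n_ref + 1) (the rank tie-break by
  raw score keeps genuine reversers ahead of such drugs).
- The adjacent-transposition noise model degrades rankings locally; it is
  not a model of biological or assay variability in perturbation profiles.
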