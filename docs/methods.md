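# Methods

## Scope and model

`seedcorr` implements a seed-gene co-expression screen over a normalized,
log-scale, probes × samples expression matrix. The statistical chain is:

1. per-probe Jarque–Bera normality QC with a χ²(df = 2) decision;
2. Pearson correlation of every probe against one seed probe with a two-tail
   t significance filter at a Bonferroni-adjusted α;
3. probe → gene resolution with audited exclusions;
4. a nested ladder of signed correlation-threshold gene lists;
5. hypergeometric over-representation of each signed list against a disease
   gene-set library with Benjamini–Hochberg adjustment;
6. a disorder-selection algorithm (inclusion rule, smallest viable list,
   unique discrimination, optimal parent list);
7. causal-gene augmentation and ontology co-membership novel-gene calling;
8. bootstrap cluster robustness of the sign structure.

The pipeline assumes the matrix is complete (no missing cells) and already
normalized; normalization from raw array files is out of scope, as are live
queries to web enrichment services or disease databases — libraries are
consumed as GMT files and causal-gene maps as TSV.

## Statistical details and conventions

**Jarque–Bera.** Population (divide-by-n) moments, no small-sample
correction: `S = m₃/m₂^{3/2}`, `K = m₄/m₂²` (non-excess),
`JB = (n/6)(S² + (K−3)²/4)`, `p = exp(−JB/2)` — the exact survival function
of χ² with two degrees of freedom. Exclusion is strict (`p < α_norm`,
default 0.05); ties are retained. Constant rows get their own ledger
criterion rather than a silent NaN. The seed probe is QC-exempt: it is
tested but never dropped, since dropping the reference would abort the
entire screen.

**Correlation significance.** `t = ρ√((n−2)/(1−ρ²))`, two-tail p from
t(n−2) (`scipy.stats.t`). The Bonferroni divisor is configurable and
defaults to the **sample count** n, reproducing the published
`α_cor = 0.05/2158 ≈ 2.3×10⁻⁵` convention of the motivating screen; dividing
by the probe count (≈ 5.5×10⁴ probes, giving ≈ 9.1×10⁻⁷) is the stricter
alternative a user can select with `bonferroni_divisor`. Exclusion is strict
(`p > α_cor` and `|ρ| < τ_min` excluded; boundary values retained), with
`|ρ|` compared on values rounded to 10 decimals to avoid float boundary
flapping. The significance filter runs before the ρ threshold; at n = 2158
the ρ threshold dominates (|ρ| = 0.34 gives t ≈ 16.8), so the order is
immaterial in practice and is kept only for ledger comparability.

**Ladder.** Thresholds τ ∈ {0.34, …, 0.41} in 0.01 steps (8 full lists),
numbered ascending by gene count (equivalently descending τ, by nesting).
Signed splits give 24 lists. The seed gene is added to every full/positive
list with ρ ≡ 1.

**Probe resolution.** Four exclusion steps in fixed order: no symbol,
non-specific, non-coding, duplicates. Chip-internal probe-quality scoring is
*not* reimplemented; a best-probe map input (gene → probe TSV) carries such
choices when available, and the self-contained fallback keeps the probe with
the largest expression IQR (ties broken lexicographically by probe ID). A
map entry naming an upstream-excluded probe triggers a warning and the
fallback.

**Enrichment.** One-sided hypergeometric upper tail
`p = P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` (equivalently one-sided Fisher
exact), computed by `scipy.stats.hypergeom`; q-values are BH-adjusted
(`statsmodels`) across the library's terms with non-empty overlap, matching
the "adjusted p-value" convention of web enrichment engines. The background
universe defaults to the union of the tested library's genes; a fixed
integer size (e.g. 20,003 to mimic a genome-wide background) or an explicit
gene set may be supplied instead — the published p-values of any specific
web engine are not reproducible without its background, so the choice is
explicit. No "combined score" is computed (it requires engine-specific
precomputed rank statistics).

**Disorder selection.** Inclusion: `q < 0.05` and, on positive lists, seed
∈ overlap and |overlap| ≥ 3; on negative lists |overlap| ≥ 3. Unsigned lists
are ineligible (signed lists achieve the same overlap with fewer genes and
hence greater significance). Each disorder is attached to the smallest
(fewest-gene) same-sign list where it first meets inclusion; positive and
negative ladders are scanned independently. Disorders with identical
(overlap set, causal set) pairs are indistinguishable and excluded, unless
an optional synonym table maps all of them to one canonical name (the
hereditary/non-hereditary-forms-with-one-identifier case), in which case
they merge into a single call. "Optimal overlap/significance" is resolved
lexicographically: overlap count descending, then q ascending, then list
size ascending.

**Novel genes.** The disorder's optimal list ∪ causal genes is enriched
against each ontology library; a term with `q < 0.05` whose overlap contains
at least one causal gene and at least one list gene that is neither causal
nor in the disorder's disease-term overlap yields those genes as candidates.
An option relaxes the co-membership anchor from "causal gene" to "causal or
disease-overlap gene" (both readings of the selection rule are defensible;
the stricter is the default). Headline tallies count per-disorder candidates
with repetition ("total") and distinct genes overall ("unique").

**Robustness.** Correlation distance `d = 1 − ρ`, average linkage
(configurable), plain bootstrap proportion over nboot = 1000 column
resamples: a cluster's support is the fraction of resampled dendrograms
containing the identical leaf set. The multiscale-bootstrap AU probability
is deliberately not computed — BP at a 0.95 threshold answers this
pipeline's only clustering question (do the sign blocks hold?) without
Shimodaira's multiscale machinery. Sign separation asks whether the 2-cut of
the observed dendrogram equals the positive/negative partition exactly;
single-sign lists are vacuously separated.

## Synthetic data: what it emulates, and what it does not

The generator emulates the structure of a large one-channel microarray
compendium (default n = 2158 samples): a normal seed probe; genes planted at
chosen population correlations ρ via `x = ρ z_seed + √(1−ρ²) ε`; independent
normal background genes; log-normal contaminant probes that fail the JB
screen (≥ 90% at n ≥ 500); attenuated noisy duplicate probes with smaller
dispersion (so the IQR fallback prefers the primary); annotation rows
exercising every exclusion criterion; a disease library whose planted terms
hold causal genes, the seed, and member genes (plus background padding) next
to background-only decoys; and an ontology library whose planted terms pair
causal genes with designated novel genes.

Two generator choices matter:

- **Sample correlation is not forced.** The linear-mixture construction
  fixes the population ρ; the estimated ρ carries the real estimation noise
  (sd ≈ (1−ρ²)/√n ≈ 0.019 at n = 2158), so threshold-boundary behaviour is
  genuinely stochastic.
- **Signal rows are rank-inverse-normal transformed.** After mixing, each
  signal row is replaced by its normal scores (the standard inverse-normal
  transform used before Pearson screens). This preserves the rank-borne
  correlation noise but fixes the row's sample moments, so signal rows pass
  the JB gate by construction — emulating real post-RMA screens, where JB
  attrition among retained probes is a fraction of a percent, far below the
  test's nominal 5% type-I rate on ideal white noise. Background rows remain
  raw i.i.d. normal, so the JB stage still shows genuine type-I exclusions.

Default planted structure: 20 genes spanning both signs of the ladder
(|ρ| = 0.35…0.62), with all disorder member and novel genes at |ρ| ≥ 0.48 —
at least 4 estimation standard deviations above the 0.41 ladder top — so
end-to-end recovery is a property of the construction rather than of lucky
seeds; three planted disorders (two positive, one negative, with 1–2 causal
genes and 2 novel genes each), 20 decoy disease terms and 15 decoy ontology
terms over 300 background genes.

What passing the synthetic benchmark does **not** show: behaviour under
batch effects, array artefacts, correlated background structure (background
genes here are mutually independent), non-trivially overlapping disease
terms, or annotation error — real libraries and platforms are messier than
the planted ones, and the published screen's specific gene lists and
p-values depend on data and library snapshots this package does not ship.

## Numerical and degenerate-input choices

- Hypergeometric tails and t survival functions are computed in log-space by
  scipy; the test suite pins them against exact integer-combinatorics
  enumeration on every table with N ≤ 60 and against one-sided Fisher exact.
- Ties: |ρ| and p-value boundary ties are retained everywhere (strict
  exclusion); optimal-list ties break by q then list size; duplicate-probe
  IQR ties break lexicographically.
- ρ = 0 members cannot reach the signed split (their p-value is 1, removed
  at α_cor); the splitter still hard-errors on them defensively.
- Empty matrices after QC, absent seed probes, constant seed rows, ragged or
  non-numeric input files, inconsistent hypergeometric counts, and
  zero-variance rows in clustering are all hard errors naming the offender.
- All randomness (generator, bootstrap) flows from explicit integer seeds;
  fixed seeds give byte-identical matrices and reports.

## Problem sizes in the shipped checks

The test suite and acceptance script run the study-scale sample count
(n = 2158) throughout, with 10⁴-probe null matrices for filter calibration,
20 seeded replicates for parameter-recovery and end-to-end recovery checks,
nboot = 1000 for the bootstrap, and the exhaustive N ≤ 60 oracle sweep
(~1.2M tables) for the hypergeometric tail. These sizes were chosen so the
statistical assertions have comfortable margins while a full run stays in
the minutes range on one CPU.
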