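# Methods

This note records the statistical models, defaults and numerical choices
behind `cernet`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Moderated differential expression

Per feature, the effect is `log2FC = mean(case) − mean(control)` of
log2-scale intensities, with pooled within-group variance `s_g²` on
`d_g = n₁+n₂−2` degrees of freedom. The empirical-Bayes prior `(d₀, s₀²)`
is fitted by method of moments on `z_g = log s_g²`: with
`e_g = z_g − ψ(d_g/2) + log(d_g/2)`, the prior solves
`ψ′(d₀/2) = var(e) − ψ′(d_g/2)` (Newton inversion of the trigamma
function) and `s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`. When the
observed spread of `log s_g²` does not exceed chi-square sampling noise,
`d₀ = ∞` and every variance shrinks fully to `s₀²` (normal reference for
p-values). `prior_df=0` reproduces the classical pooled two-sample t
exactly; the test suite verifies both limits and checks the full fit
against limma's `lmFit`/`eBayes` to ~1e-10 on a shared matrix.

Calibration caveat: with an *estimated* prior under an exactly
homoscedastic null, the moderated t is very slightly conservative — the
measured rejection fraction at nominal 0.05 is ≈0.0495 (3 vs 3, 2000
features). This is a property of the moment estimator (the reference
implementation shows it identically), not an implementation artifact.

Screening uses strict inequalities, `p < 0.05` and `|log2FC| > 0.585`,
the latter equivalent at two-decimal reporting precision to fold changes
beyond 1.5× (2^0.585 = 1.50004; the two formulations can disagree only for
log2FC inside a 4×10⁻⁵-wide window). No multiple-testing correction is
applied at this stage — the screen deliberately mirrors the raw-p practice
of the study design it implements, so its false-discovery fraction depends
on DE prevalence (≈3% at 20% prevalence, ≈7% at 10%, under the default
effect size and 10 vs 10 samples). DE lists from replicate cohorts are
combined by union; a feature with conflicting directions across cohorts is
excluded and reported in a sidecar rather than resolved, because the
downstream sign rule needs unambiguous directions. Ties are broken toward
the record with the smaller p.

## ceRNA assembly

Identifiers are case-folded and the frequent `has-`→`hsa-` miRNA typo is
repaired before matching; triples keep the DE lists' original spellings.
A miRNA–mRNA pair needs ≥ `min_db` (default 3) *distinct* source databases;
duplicates within one database count once. miRNA–lncRNA pairs require
presence in the single provided table — that edge type typically has one
evidence source. A triple is emitted iff both edges exist, all three
members are DE, and the lncRNA and mRNA share a direction opposite to the
miRNA's; both polarity patterns (miRNA up and miRNA down) are emitted into
one table with a polarity column. Assembly is verified against exhaustive
L×M×G enumeration on random instances. Networks derive from triples;
hub ranking is degree with ties at the k-th rank fully expanded, the same
statistic used for the PPI network (combined score ≥ 0.7 inclusive;
STRING-style 0–999 integer scores are divided by 1000; duplicate unordered
pairs keep the maximum score, a conservative resolution of the dialect's
bidirectional listings).

## Enrichment

One-sided upper-tail hypergeometric per set (equivalent to one-sided
Fisher on the 2×2 table), computed within an explicit universe — the genes
measured on the platform, not the genome. Benjamini–Hochberg q-values are
reported alongside, but ranking is by raw p. The plotted-style
"enrichment score" is the ratio of proportions `(k/n)/(K/N)`.

## Time-course clustering

Per-gene timepoint means (chronological column order taken from first
appearance in the metadata) are screened by population SD ≥ 0.05 and then
standardized to mean 0, SD 1 per gene. The SD filter runs *before*
standardization, a deliberate ordering: workflows of this kind are often
described with standardization first, but after standardization every
profile has SD 1 and the filter could no longer remove anything; filtering
first preserves its purpose of discarding near-flat genes.

Fuzzy c-means minimizes `J = Σᵢ Σⱼ u_ij^m ‖xᵢ−cⱼ‖²` (Euclidean distance on
the standardized 3-point profiles) by the classical alternating updates,
centroids initialized from seeded random gene rows. Convergence is
`max|ΔU| < 1e-6` or 300 iterations; non-convergence returns the best state
with a flag rather than raising. A gene coinciding exactly with one or
more centroids receives full membership in the first of them. The
objective after each iteration is recorded and non-increase is asserted in
tests (1e-9 relative slack for floating point). The default cluster count
is 10 with config override; the fuzzifier defaults to the data-size
heuristic `m = 1 + 2·(1/D + 1/√G)` clamped to [1.05, 4] — softer
partitions for smaller problems — with an explicit override honoured
unchanged. Centroid trends over (0 h, 3 h, 20 h) are classified from the
centroid alone: strict middle maximum → rise-fall, strict middle minimum →
fall-rise, otherwise monotone by endpoint comparison. Genes join their
argmax-membership cluster only at membership ≥ 0.5 (ambiguous genes stay
unassigned); trend-class gene lists are unions over same-label clusters,
so all assertions are label-permutation invariant.

## Synthetic data

The generator emulates the *statistical* structure the chain assumes:
Gaussian log2-scale noise (default SD 0.5) around per-feature baselines
(N(8, 1.5)), planted DE features shifted by ±2.0 log2 units, two
case/control cohorts per RNA class (a 10 vs 10 and a 3 vs 3 replicate,
single miRNA cohort), member-disjoint planted triples obeying the sign
rule by construction, interaction databases containing each true pair
independently with probability `db_coverage` plus Poisson decoys per
database, uniform-score random PPI edges, gene sets over-sampling a query
at a stated enrichment factor, and a 31/31/34-sample three-timepoint
series with unit-amplitude trend shapes. Flat time-course genes carry only
small technical noise (SD 0.02) so the SD of their timepoint means stays
below the 0.05 filter — they exist to be removed. One global seed drives
independent named substreams per generator, so adding a generator never
perturbs another's draws; identical configurations are byte-reproducible.

What passing these benchmarks does **not** show: robustness to probe-level
artifacts, batch effects, heteroscedastic or heavy-tailed noise,
correlated features, or sequence-level plausibility of the interaction
tables — all explicitly outside the generative model. Recovery rates under
the defaults (effect size 2.0 at SD 0.5 is a 4-SD shift) characterize
correctness of the set logic, not the power of the screen on subtle real
effects.

Where the study design leaves choices open, the defaults are
engineering choices, recorded here: feature pools of 300/100/600
(lncRNA/miRNA/mRNA) keep the full pipeline in milliseconds while leaving
all stages non-degenerate; `db_coverage=0.9`, `db_noise=50` decoys per
database make the evidence filter consequential; the benchmark problem
sizes (200 simulations of 2000 features for calibration, 1000 pairs for
the coverage law, 20 simulations elsewhere) give Monte-Carlo standard
errors comfortably inside the asserted bands.

## Numerical and degenerate-input choices

Matrices judged linear-scale (max > 50) get `log2(x+1)`; negatives there
are an error. An all-zero-variance matrix falls back to the unmoderated t
with a warning; a zero-variance feature with zero difference yields p = 1,
with nonzero difference p = 0. Probe collapsing averages probes per gene
and errors (rather than returning empty) when annotation and matrix are
disjoint. All outputs are deterministically ordered (lexicographic) and
floats are written at %.6g, so identical inputs reproduce identical bytes.
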