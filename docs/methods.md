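# Methods

## Model and procedure

`protnorm` formalises a three-condition proteome comparison. One pooled
sample per condition (normal reference, disease line, treated line) is
measured as technical replicate injections; quantification is label-free,
from spectral peak intensities. The analysis is deliberately rule-based —
fold-change thresholds with an evidence filter — rather than
test-statistic based: with pooled biological material and technical
replicates only, replicate-level inference would misstate biological
variance, so no t-tests or moderated statistics are computed.

Stages:

1. **Scaling.** Each sample is multiplied by one scalar so that its total
   intensity equals a common target (default: the mean of per-sample
   totals, which makes the operation idempotent). This single step stands
   in for the multi-stage amount equalisation of the wet-lab workflow
   (gel-lane totals, peptide assays, spectral-intensity normalisation),
   which cannot be replayed from an exported table. Note an inherent
   property of total-intensity scaling: it multiplies every
   disease/reference ratio by the ratio of condition totals. It removes
   per-sample loading differences (the tested invariance) but is not
   ratio-preserving when the conditions genuinely differ in composition.
2. **Aggregation.** Technical replicates are collapsed per replicate group
   (mean by default, median by config). A protein is detected in a group
   iff detected in at least `min_detected` members (default 1).
3. **Ratios.** r_D = disease/reference and r_T = treated/reference, each
   present only when both sides are detected with positive abundance. No
   imputation and no pseudo-counts anywhere: a protein missing on one side
   becomes an *exclusive* case with a categorical verdict
   (`exclusive_disease` / `exclusive_reference`), mirroring the separate
   treatment such proteins receive in practice. Imputation would fabricate
   ratios that were never measured.
4. **Classification.** See the decision rules below.
5. **Clustering, enrichment, triage.** Downstream characterisation of the
   classified sets.

## Decision rules and boundary choices

- Regulation uses **strict** inequalities: r_D > `fc_high` (default 2) or
  r_D < `fc_low` (default 1/`fc_high`). A ratio of exactly 2.0 is
  unregulated. The unique-peptide evidence minimums are **inclusive**:
  UP ≥ 2 (standard tier) and UP ≥ 5 (strict tier), following the symbolic
  "(UP) ≥ 2 / ≥ 5" convention. The evidence filter precedes everything:
  below the minimum the verdict is `insufficient_evidence` regardless of
  detection pattern.
- The normalised band is **inclusive**: `fc_low` ≤ r_T ≤ `fc_high`. The
  band edges belong to the "comparable to reference" region on both
  readings of the threshold definitions.
- **Trend** is formalised as: outside the band, same sign of log-ratio as
  the disease line, and strictly closer to 1 in log space
  (|log₂ r_T| < |log₂ r_D|). Overshoot past the opposite cutoff is *not*
  a trend — the abundance did not "continue" in a corrective direction,
  it crossed to the opposite dysregulation — and is classed
  `not_normalised`, as is an unchanged or worsened ratio.
- The biomarker triage bound is **inclusive** (r_D ≥ 5 or ≤ 0.2 by
  default, "at least 5-fold"), deliberately unlike the strict 2-fold
  regulation bound; both conventions are stated side by side here because
  they differ.
- All logs are base 2; reported fold changes are raw ratios.
- Summary percentages use as denominator the regulated proteins carrying a
  treated ratio (non-`not_applicable` outcome); the reproduction profile
  reports them at the strict tier, with the standard-tier summary emitted
  alongside.

Two published figures this pipeline's summary relates to are mutually
inconsistent at the margin (a 297 vs 295 normalised count between abstract
and results; a 48% vs 41% "not differentially expressed" figure). The
package always reports its own computed counts and makes no attempt to
reconcile the discrepancy.

## Clustering

Profiles are z-scored per row with the sample standard deviation (n−1);
constant rows map to all-zeros rather than erroring — they carry no
signal but legitimately occur. Distances are Euclidean (default) or
Pearson correlation distance (1 − r); both are exposed because published
descriptions of such heatmaps name either metric depending on the panel,
and the reproduction profile uses Pearson. Agglomeration is unweighted
average linkage maintained exactly via the Lance–Williams update; merges
are fully deterministic, ties broken by the lowest (row, col) index pair
in the current cluster ordering (original leaf order, merged clusters
appended). Tie-broken orders are only permutation-invariant when all
pairwise distances are distinct. Heatmap rendering is a thin presentation
layer excluded from every numeric contract.

The pipeline reports the treated column's first merge partner twice: over
the whole regulated set, where a partially effective treatment sits
between reference and disease (a transition state), and over the
normalised subset, where it should group with the reference. The second
is the testable form of the qualitative "treated groups with normal"
claim.

## Enrichment

Over-representation only (one-sided upper tail); depletion is out of
scope. The default universe is the set of proteins quantified at the
active evidence tier — the defensible background for a selection drawn
from a quantified proteome, rather than the whole annotation space.
Gene-set members are intersected with the universe before the set size K
is computed. Sets overlapping the selection by fewer than `min_overlap`
members (default 2) are excluded *before* Benjamini–Hochberg correction,
so m equals the number of sets actually tested. P-values come from the
hypergeometric survival function (log-factorial based; verified exact to
1e−12 relative against rational-arithmetic enumeration for all N ≤ 30).

## Synthetic data

The generator emulates the statistical structure of the three-line
design: log-normal reference abundances (ln-scale sd 1.8, median ≈ 10⁶ —
a realistic label-free dynamic range of several orders of magnitude); a
planted dysregulated fraction (default 0.60, 55% of it upregulated); a
planted normalised / trend split among the dysregulated (defaults 0.47 /
0.05); effect sizes |log₂ r_D| = log₂ `fc_high` + max(0.1, |N(1.5, 0.8)|),
i.e. strictly beyond the cutoff with a margin so that truth labels are
well defined under the strict boundary rules; mean-one multiplicative
log-normal technical noise at CV 0.10 across 3 replicate injections; 2%
exclusive proteins (one of reference/disease zeroed, side uniform); and a
unique-peptide marginal putting 5% of proteins below the standard tier
and 20% below the strict tier so both filters are exercised.

Placement margins keep planted ratios away from decision boundaries
(band interior ±0.8·log₂ `fc_high`; trend ratios at least 0.2 log₂ units
outside the band and 0.1 short of the disease ratio; not-normalised
ratios at least 0.2 beyond it), so that moderate replicate noise rarely
flips a call: at the default conditions the recovered normalised fraction
sits within a few tenths of a percentage point of each run's planted
fraction. Trend placement needs room between the cutoff and the disease
ratio, so trend-labelled proteins redraw their effect until the margin
exceeds 0.35 log₂ units; a configuration whose effect distribution cannot
provide that room raises a config error.

What the generator does **not** emulate: peptide-level structure,
intensity-dependent (missing-not-at-random) dropout, batch effects, or
correlated biological variation between proteins. Passing recovery tests
therefore demonstrate the correctness and calibration of the decision
rules under multiplicative technical noise — not robustness to every
artefact of real LC-MS/MS data.

Because the generator emits injections already on a common scale
(mean-one noise around the true pools), synthetic runs are configured
with `scaling.enabled: false`; enabling total-intensity scaling on data
whose condition totals genuinely differ would shift all ratios by the
condition-total ratio (see Scaling above). On real exports the scaling
default is on.

Recovery is evaluated per run against the *realized* planted fraction of
that run's truth table. Matching instead against the nominal planted
parameter would conflate decision-rule errors with the binomial sampling
noise of the labels themselves (sd ≈ 1.6 percentage points at the default
scale), which no classifier can remove.

## Numerical and interface choices

- Parsing is locale-independent: decimal points only; comma decimals are
  rejected loudly. Empty/NA cells mean "not detected"; a literal 0 is a
  measurement unless `zero_is_missing` is set — whether exported zeros
  denote absence is vendor-dependent, so both conventions are reachable.
- Identifiers are case-preserved and matched case-sensitively; gene-set
  membership matches accession first with gene-symbol fallback
  (`match_on`), since annotation sources mix UniProt accessions and
  symbols.
- Results TSVs round-trip at 12 significant digits; missing values are
  empty cells, never the text "None".
- One seeded NumPy generator per simulation run; identical config + seed
  reproduce byte-identical tables. Pipeline reports are byte-reproducible
  given identical inputs and config.
- The default test suite and the acceptance script run the simulation at
  2000 proteins × 9 injections (100 seeds for the recovery benchmark),
  the clustering oracle at n ≤ 10 × 200 instances, and the hypergeometric
  verification over the complete N ≤ 30 grid — sizes chosen to keep the
  whole verification comfortably interactive while leaving every
  statistical check well powered.

## Known limitations

- The exact column layout of any given search-engine export must be
  supplied by the user as a column map; no vendor dialect is assumed.
- Exclusive proteins receive categorical verdicts only; the pipeline
  neither ranks them nor tests them for enrichment separately.
- External concordance of biomarker candidates (expression atlases,
  literature) is a manual step; the candidate report leaves those columns
  blank rather than scraping version-dependent web services.
- STRING-style interaction networks and GO-graph-aware enrichment are out
  of scope; the local ORA treats gene sets as flat.
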