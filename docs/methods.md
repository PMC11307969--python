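# Methods

## Reference-cohort k-NN classification

For a query profile and a labelled reference cohort, Spearman's rank
correlation is computed over the genes the two matrices share (restricted
to coding genes when an annotation table is supplied). Spearman's ρ is
implemented as the Pearson correlation of average fractional ranks, so
ties are handled by mid-ranks and the statistic is invariant to strictly
monotone transforms of either profile. A constant vector has no defined
rank correlation; such reference samples are excluded from a ranking with
a warning and a constant query is an error — silently substituting ρ = 0
would place the sample mid-ranking with false confidence.

Rankings sort by ρ descending with exactly equal values ordered by
reference sample id, making results reproducible across platforms. The
classifier takes the plurality label among the top k neighbours; when the
plurality is tied it drops the single worst-correlated neighbour of the
current window and re-votes, iterating until the winner is unique (window
size 1 guarantees termination). A single removal is the common case, but
one removal alone cannot resolve every tie for k > 3, hence the
iteration. The agreement score — the fraction of the top 10 neighbours
carrying the final prediction — is reported per query as a confidence
measure, and the top-10 label histogram is available for composition
displays.

k is chosen by leave-one-out cross-validation: each labelled sample is
held out and classified against the rest, per metadata category.
"Best across categories" is operationalised as the *mean* accuracy over
categories, with ties going to the smallest (most conservative) k.
Samples lacking a subgroup label in a category are excluded from that
category's cross-validation entirely, both as queries and as voters,
since metadata rarely covers a full cohort. The pairwise correlation
matrix is computed once per cohort, which makes the LOOCV loop linear in
cohort size rather than quadratic in correlation computations.

Default k is 6 for broad tumor-type classification and the library leaves
k fully configurable; typical subtype analyses on smaller, noisier
metadata benefit from larger k (~15).

The classification default input is RPKM. Within one sample the
count→RPKM map is not monotone when gene lengths differ, so the choice is
not a no-op for rank correlations; RPKM is used because cross-sample
comparability of within-sample gene rankings is what the reference
compendia provide.

## RPKM normalisation

RPKM(g, s) = counts(g, s) / (library_size(s)/10⁶) / (length(g)/10³) with
length the maximal mature transcript length per gene, supplied as a
precomputed table. Library sizes are supplied externally rather than
inferred from column sums, because intersection-strict read counting
drops multi-feature reads and the column sum therefore under-counts the
sequencing depth.

## Deconvolution benchmarking

The package consumes fraction tables produced by external tools and never
re-implements the deconvolution itself. Fractions can be renormalised
after excluding an "uncharacterized" compartment (each row rescaled to
sum to 1; a row with no remaining mass is an error naming the sample).
Cell-type names from different tools are harmonised through an explicit
user-supplied mapping; no fuzzy name matching is attempted.

The marker-panel score is the per-sample mean of log₂(RPKM + 1) over the
panel genes present in the matrix (missing genes are logged and skipped).
The log transform keeps a single very highly expressed marker from
dominating the panel mean; since the panel is fixed across samples this
choice does affect the downstream Spearman correlation, so it is the
documented default rather than an arbitrary detail. Score-vs-fraction
correlations use the exact permutation distribution of ρ for n ≤ 9 —
at the ~10-sample cohorts this package targets, the t approximation is
unreliable — and the t approximation above that. Reported p-values are
two-sided.

The shipped fibroblast panel (COL1A1, COL1A2, COL3A1, DCN, LUM, FAP,
PDGFRB, ACTA2, THY1, POSTN) and macrophage panel (CD68, CD163, CSF1R,
MRC1, AIF1, ITGAM) are canonical, illustrative marker sets wired to the
synthetic mixture generator; real analyses should substitute curated
panels.

## Somatic-variant filtering

Population filtering is variant-level: a gnomAD or ExAC allele frequency
strictly above 0.001, or a dbSNP rsID, removes that variant — not every
variant in its gene, which would discard well-known hotspot mutations.
The whitelist overrides population evidence: a Cancer Gene Census
oncogene variant whose exact mutation is catalogued in COSMIC, or any
variant in a CGC tumor suppressor, is kept. "Has a dbSNP identifier" is
read as the variant itself carrying an rsID. The thresholds are shared
between gnomAD and ExAC by default and independently overridable.

The PDX-recurrence filter then removes variants observed in at least two
distinct PDX samples but in no patient biopsy — a pattern suggesting an
engraftment or mouse-read artifact rather than patient somatic biology.
It counts distinct sample ids by default (configurable to patients) and,
by default, removes even whitelisted variants, since it targets artifacts
that annotation databases cannot vouch for; a flag lets the whitelist
shield variants from it. Recurrence is assessed among the survivors of
the population filter, which makes the two-stage pipeline idempotent and
row-order independent.

## Growth and survival statistics

Tumor volume from calipers is width² × length / 2 in mm³, with
length ≥ width enforced on read (swapped with a warning). Two arms are
compared per shared measurement day on volumes — not raw calipers — by
Welch's t test (pooled-variance optional), requiring at least two animals
per arm per day; p-values are corrected across days by Holm–Šídák
step-down (no-correction mode available). This reproduces the family of
"multiple t test" analyses common in growth-curve software; Welch plus
Holm–Šídák is the default because per-day variances differ strongly as
tumors diverge.

Fisher's exact test is computed from integer binomial coefficients: the
one-sided p is the hypergeometric tail in the direction of the observed
association, the two-sided p the sum over all tables with the observed
margins whose probability is at most the observed table's. Exact integer
comparison avoids the floating-point tolerance fudge needed when pmf
values tie (e.g. symmetric tables).

Survival uses Kaplan–Meier estimates per group and the log-rank test for
the pair (the test the package defaults to because no assumption on the
censoring-time distribution is needed; a Wilcoxon-style weighting can be
run directly through lifelines if early differences matter more).

## Synthetic data: what it emulates

The generator produces inputs with the statistical structure the
analyses assume, with every record covered by a ground-truth object.

*Reference cohorts.* Expression is 2^(baseline + shifts + noise):
baseline log₂ levels ~ N(5, 1.5) per gene, class-specific signature
blocks shifted by `log2_effect`, each class split into two nested
subgroups whose own half-size blocks are shifted by half the effect, and
i.i.d. N(0, noise_sd) log-scale noise. Defaults — 3 classes × 20
samples, 600 genes, 50 signature genes per class, effect 4, noise 0.5 —
give a cleanly separable cohort: within-class rank correlations dominate
between-class ones, so LOOCV is perfect for every k below the class
size. Lognormal noise preserves non-negativity and makes separation
controllable by a single effect parameter.

*Bulk mixtures.* Each bulk sample is a convex combination of component
profiles with Dirichlet-drawn fractions (summing to 1 exactly before
noise), followed by multiplicative lognormal noise (sd 0.1, the low-noise
setting). All marker panels are present in the gene set; a component's
markers are elevated (~2⁸ RPKM) only in its own profile, so a marker
score tracks its component's true fraction and stays flat for absent
components. Default concentrations (uncharacterized 8, CAF 4, T cell and
macrophage 1.2, B cell and endothelial 0.6, n = 40 samples) let the CAF
fraction span roughly 0.05–0.6.

*Variant tables.* The default scenario emits 10 records: 2
population-filtered (high gnomAD AF, high ExAC AF or rsID in rotation),
1 rsID-carrying oncogene hotspot rescued by the COSMIC whitelist, one
variant shared by two PDX samples with no biopsy support, and 5 clean
somatic records — so exactly 6 survive the pipeline.

*Growth and survival.* Volumes follow per-arm exponential growth with a
rate switch at the infusion day (default: both arms grow at 0.07/day;
the TIL arm switches to −0.06/day after day 7, mimicking a responding
model), lognormal measurement noise (sd 0.15 log₂), 5 animals per arm,
weekly measurements over 28 days from ~100 mm³ — the size at which
infusion typically happens. Width/length pairs are reconstructed from
volume under the fixed convention length = 1.5 × width; any consistent
convention works because the analyses use volume. Survival times are
exponential per group (default: 8 vs 13 subjects with equal hazards
0.002/day, matching a cohort where tumor take did not stratify
survival); a configurable fraction of subjects is censored at a uniform
fraction of its event time.

What the generator does **not** emulate: read-level artifacts, batch
effects, gene–gene correlation structure, compositional RNA-seq noise,
annotation-version mismatches, or real marker biology. Passing tests
therefore demonstrate correctness of the algorithms under their stated
assumptions, not field performance on patient data.

## Numerical choices and edge cases

- Spearman ρ values are clipped to [−1, 1] after the vectorised Pearson
  step to absorb floating-point overshoot.
- Exactly equal correlations order by sample id; votes iterate removal as
  described above; `removed_for_tiebreak` is reported per query.
- Fraction-table row sums are validated to 10⁻⁶ on input and reproduced
  to 10⁻⁹ after renormalisation.
- The exact-permutation p uses a ≥ comparison with 10⁻¹² slack so that
  permutations tying the observed |ρ| count as extreme.
- Degenerate inputs fail loudly: constant vectors, empty rankings, zero
  library sizes, non-positive calipers, zero-mass proportion rows and
  malformed MAF rows (reported with line numbers) all raise with the
  offending identifier.

## Problem sizes

The test suite and the acceptance script run on the generator defaults:
60-sample cohorts, 30 held-out queries, 40-sample mixtures, 10-record
variant scenarios, 5 animals per arm, and 500–1000 replicate null
simulations for calibration checks — sizes at which every documented
property is measurable with stable margins while the full suite runs in
well under a minute of compute.
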