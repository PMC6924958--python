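# Methods

## The design and its statistical model

The analysis assumes a 2 x 2 x 2 design: fraction (TRAP
immunoprecipitate vs total tissue transcriptome) x compartment (axon
target area vs cortical source area) x condition (control vs trained),
with a small number of biological replicates per cell. Counts are
modeled as negative binomial with a gene-wise dispersion on the
mean/dispersion parameterization, `var = mu + alpha * mu^2`; the same
convention is used by the simulator and the test, so planted and
estimated quantities are directly comparable.

Twelve two-group comparisons are run: axon-vs-cortex within each
condition and trained-vs-control within each compartment, both on TRAP
and on transcriptome samples (8), plus TRAP-vs-transcriptome within
each compartment x condition cell (4). Orientation is fixed globally
and carried in the table names: axon over cortex, trained over control,
TRAP over transcriptome. Sign conventions are the main reproduction
hazard in this kind of pipeline, so they are never inferred from data.

## Differential expression

Per comparison: median-of-ratios size factors (computed once on the
full matrix so all twelve comparisons share one normalization),
gene-wise method-of-moments dispersion from the pooled within-group
variance of normalized counts (floored at 1e-8), and a Wald statistic
`log2FC / SE` with the delta-method SE

    SE^2 = Var(mean_A)/mean_A^2 + Var(mean_B)/mean_B^2) / ln(2)^2,
    Var(mean_G) = (1/n^2) * sum_s ( mu_G / sf_s + alpha * mu_G^2 ).

Two numerical choices matter at the replicate numbers this design
uses:

- **Dispersion moderation.** Raw method-of-moments dispersions at
  n = 4–6 replicates are noisy enough that plugging them into a normal
  reference inflates the null tail (empirically ~8% of null genes at
  p < 0.05 instead of 5%). Gene-wise dispersions are therefore shrunk
  linearly toward the across-gene median with prior weight
  `prior_df = 10` (an empirical-Bayes squeeze; the median prior is
  robust to the dispersion inflation of true DE genes; no
  mean-dispersion trend is fitted), and the statistic is referred to a
  t distribution with residual + prior degrees of freedom. Under the
  simulator's global null this yields 4.4–4.7% of raw p-values below
  0.05 at both n = 4 and n = 6 — calibration the test suite checks by
  Monte Carlo.
- **Zero group means.** When either group mean is zero, 0.5 is added
  to both means for the fold change and its variance floor, keeping the
  statistic finite and deterministic; genes with zero counts across
  both groups are flagged untested and carry no p-values.

BH adjustment is the exact step-up procedure, implemented in-package
(it is load-bearing for the filter) and cross-checked in tests against
both a literal brute-force evaluation and statsmodels. No fold-change
shrinkage, independent filtering, or outlier handling is applied: the
scientific content of this pipeline is the *filtering logic*, and a
transparent test keeps every downstream decision auditable. External
DGE tables (gene_id, log2fc, padj at minimum) can be substituted
anywhere a result table is consumed.

## The stringent filter and classification

Per gene and TRAP comparison, three rules in order:

1. include iff padj < alpha in the TRAP comparison (alpha = 0.05);
2. exclude iff the transcriptome twin shows a significant **same-sign**
   effect (an opposite-sign transcriptome change does not exclude — a
   literal reading of "the same effect");
3. exclude iff the design cell on the enriched (upregulated) side is
   not itself significantly enriched (padj < alpha, log2FC > 0) over
   its tissue transcriptome.

Rule 3's scope is genuinely ambiguous between "all four TRAP
comparisons" and "the area-enrichment comparisons only"; the package
defaults to the strict reading and exposes
`strict_enrichment_confirm=False` for the lenient one rather than
hiding the choice. Genes untested (all-zero) in a comparison actually
required by the rule sequence are excluded with a distinct `untested`
audit code; a gene already excluded by rule 2 keeps that audit code
even if its rule-3 table is untested, matching the rule ordering.

A surviving gene is **axonal** if it is learning-regulated in axons or
axon-side enriched in either condition; **cortical** flags are
symmetric; the labels axonal_only / shared / cortex_only / none
partition the universe, and the summary additionally splits the
translatome into learning-regulated vs enrichment-only compartments.
Percentages are rounded half-away-from-zero to integers. Note that
904/1482 = 60.9987%, so the reference-coverage percentage in reports is
61 under this rule even though a truncating convention would print 60.

A background-control audit (`background_overlap_audit`) compares two
classifications (e.g. a main run against an IP-background control run)
and reports the axonal/cortical overlap under both candidate
denominators — the full translatome and the axonal set — plus the
cross-run intersections of regulated sets, since which denominator a
"percent overlap" refers to is itself a reporting ambiguity.

## What the simulator emulates — and what it does not

`generate_counts` plants, per gene, one label: axon_up / axon_down
(learning effects in TRAP axons, with probability `opposite_coupling`
mirrored in the opposite direction in TRAP cortex), axon_enriched
(axon-vs-cortex enrichment in both conditions), cortex_up /
cortex_down, background, or null. Effects live in the TRAP fraction
only; the tissue transcriptome stays flat. Genes carrying planted
effects are additionally TRAP-enriched over the transcriptome
(`trap_enrichment_lfc`, default 1.0) — they are neuron-expressed by
construction — while background genes are TRAP-depleted
(`trap_depletion_lfc`, default 2.0) and null genes carry no IP bias.
This last point is structural, not cosmetic: because median-of-ratios
normalization anchors on the majority (null) gene, a *uniform*
enrichment of all neuronal genes would be absorbed by the size factors
and the enrichment-confirmation rule could never fire; tying enrichment
to the effect-carrying genes keeps the normalization anchored and the
planted fold changes recoverable.

Defaults are chosen as study-like conditions: 5000 genes, 4 replicates
per group (the study pooled animals into fewer replicates; 4 gives
testable power), baseline means log-normal(4, 1) on the natural-log
scale (~55 counts median), dispersion 0.05, |log2FC| 2 for both
learning and enrichment effects, label fractions 5/5/5/10/25% (rest
null), opposite coupling 0.4 (matching the observed ~40% both-area
regulation), and log-normal(0, 0.2) library size factors.

`expected_labels` derives the *ideal* classification from the planted
group means — including the enrichment-confirmation rule in
expectation. This is the correct ground truth for false-discovery
accounting: a cortex-downregulated gene whose trained-condition drop
creates a genuine axon-side enrichment is truly *shared* under the
analysis's own definition, not a false axonal call.

What the simulator does **not** model: read-level artifacts (alignment,
GC bias), batch effects, correlated gene-gene structure, the pooling
variance of multi-animal replicates (replicates are i.i.d.), or
mean-dependent dispersion trends. Passing recovery tests therefore
demonstrates the pipeline's logic and calibration under its own model
assumptions, not robustness to those real-data complications.

The transcript-table generator plants per-gene learning effects with
opposite signs in the two areas, splits them across 1–3 transcripts by
Dirichlet weights, and perturbs the cortex weights around the axon
weights (`contribution_noise_sd`, default 0.1) so inter-area score
correlation is high but imperfect; gene FPKM is the transcript sum by
construction. The image generator places 2-D Gaussian puncta
(amplitude 100, sigma 1.5 px) on a clipped Gaussian background; a
fraction of channel-2 puncta sit exactly on channel-1 centers and the
rest are rejection-sampled at least 5 sigma away from every channel-1
punctum, so the planted Manders M2 is the colocalization fraction up to
background residue.

## Transcript contribution scores

Gene-level dFPKM per area is defined as the sum of its transcripts'
dFPKM (trained minus control, means over replicates), which guarantees
scores sum to 1 per valid gene and area (checked to 1e-9) and matches
the "contribution" semantics; scores are only computed where
|gene dFPKM| >= 1e-6 FPKM (division guard; flagged genes are listed,
not silently dropped). Scores fall outside [0, 1] when transcripts move
in opposite directions — that is signal, not error. A gene is
*divergent* when some transcript's axon and cortex scores differ by
more than 0.3 (i.e. >30% of the learning effect is carried by different
transcripts in the two areas).

## Colocalization

The Costes threshold search fits channel 2 on channel 1 by orthogonal
(total least squares) regression over ROI pixels, then scans t1
downward over the *distinct observed* channel-1 intensities (not a
fixed step — determinism) with t2 = slope * t1 + intercept, stopping at
the first pair whose strictly-below-threshold pixels have Pearson
r <= 0 or an undefined r (fewer than two pixels, or constant);
undefined counts as stopped because the method's behavior at degenerate
tails is otherwise implementation-defined. When the slope is positive,
set membership below the moving thresholds is monotone in t1, so the
scan is evaluated exactly with prefix sums over per-pixel exit
thresholds (O(N log N)); a literal per-candidate loop covers the
degenerate non-positive-slope case. Thresholds are computed per ROI
(the regions were segmented before thresholding), background is
subtracted as a scalar mean with clipping at zero, and
M1 = sum(ch1 | ch2 > t2) / sum(ch1) within the ROI (M2 symmetric).
Region effects are compared by one-way ANOVA with
η² = SS_between / SS_total.

## Determinism and reporting

All randomness flows through `numpy.random.default_rng` seeded from the
configuration; `run_all` with the same config and seed produces a
byte-identical `summary.json` (no timestamps in the report; sorted
keys). Every stage either reports or is marked skipped; a failing stage
records its diagnostic and aborts with a nonzero exit from the CLI.

## Problem sizes used in the test suite

Simulation-backed checks run at 2000–5000 genes with 10–20 Monte-Carlo
seeds, recovery checks at 6 replicates per group with |log2FC| 2 and
dispersion 0.05, and image recovery at 256 x 256 px with 200 puncta per
channel over 10 seeds — sizes at which the sampling error of each
checked quantity is comfortably below its test tolerance.

## Known limitations

- The DGE stage is deliberately minimal; it is calibrated under its own
  NB model but does not reproduce the numerics of shrinkage-based
  packages (no LFC shrinkage, no Cook's-distance outlier handling, no
  independent filtering). For real data, external DGE tables can be
  dropped in.
- The classifier's ground-truth accounting is only as good as the
  planted-mean oracle; with real data there is no such oracle and the
  false-discovery proportion is not observable.
- Manders recovery assumes background well below punctum amplitude;
  heavy residual background inflates the denominator and biases M2
  downward.
- The eYFP-IP style background audit compares two classifications on
  the same gene universe; it does not model the control experiment's
  distinct library composition.
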