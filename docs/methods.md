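# Methods

This note documents the models behind each pipeline stage, the parameter
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## Species-of-origin deconvolution

**Model.** A xenograft library is a two-component mixture: each read
originates from the graft or the host transcriptome. The scorer assigns each
read the maximum exact-match base count over all ungapped, fully contained
placements on a reference that share at least one exact k-mer with the read;
placements without a shared k-mer are inadmissible, so a read with no seed
scores 0. The species call compares the two scores: graft if
`score_graft − score_host ≥ margin`, host symmetrically, otherwise
ambiguous. Ambiguous reads (including reads shorter than k, which carry no
species evidence) are excluded from gene counts but retained in the
partition, so `n_graft + n_host + n_ambiguous` always equals the library
size; the graft fraction is computed over assigned reads only.

**Parameters.** `k = 21` (seed length, standard short-read seed size; at 10%
interspecies divergence an ortholog placement of a 100 bp read still carries
an error-free 21-mer with high probability, while chance 21-mer collisions
between unrelated sequences are negligible at 4⁻²¹). `margin = 2` matched
bases: at 10% divergence the true-species score exceeds the ortholog score
by ~10 bases on a 100 bp read, so 2 is far from the signal but absorbs
single-base flukes. Ties in gene assignment break to the lexicographically
smallest gene id for reproducibility. Precomputed per-read score pairs from
an external aligner can be classified with `classify_scores`.

**Deliberate simplifications.** Ungapped, substitution-only scoring (matched
to the simulator's error model — no indels), no spliced alignment, no
multi-mapping rescue. The seeded scorer is exactly reproducible by dense
all-offset enumeration under the same admissibility rule, which is how the
test suite verifies it.

## Cross-species enrichment

**Normalization.** log2 counts-per-million with a pseudocount:
`log2(1e6·(count + pc)/(libsize + pc·n_genes))`, `pc = 0.5`. The pseudocount
keeps fold-changes finite at zero counts; with `pc = 0` the transform is
exactly scale invariant.

**Test statistic.** Each contrast (core:rim within species; tumor:host
within compartment, on ortholog-mapped genes) uses a moderated two-sample t
on log-CPM: per-gene pooled variances are shrunk toward a scaled-inverse-
chi-square prior whose scale and degrees of freedom are fitted across genes
by matching the moments of log s², and the statistic gains the prior's
degrees of freedom. Moderation is the decisive design choice here: with 5
samples per group a plain Welch t has ~8 degrees of freedom and must exceed
|t| ≈ 11 to survive Benjamini–Hochberg at FDR 0.01 across 2000 genes, so a
genuinely 32-fold-enriched gene fails the dual-FDR selection in a majority
of simulations; with thousands of genes informing the variance prior the
same gene is recovered essentially always, and the null distribution stays
calibrated (verified by the type-I-error and label-permutation tests). A
plain Welch t remains available (`moderate=False`), and the test sits
behind one interface so a count-model test can be swapped in.

**Multiple testing.** Benjamini–Hochberg within each contrast. Direction
convention, stated in every output header: log2FC core:rim > 0 means
core-enriched, log2FC tumor:host > 0 means tumor-enriched.

**Dual selection and folds.** `select_dual_significant` intersects the two
axes at one FDR threshold (default 0.01) with optional sign filters; by
default the core:rim axis is evaluated in the graft transcriptome and the
tumor:host axis in the core compartment — the natural axes for a
tumor-specific, core-enriched secreted factor — and both are configurable.
Set members are ordered by combined (sign-adjusted) log2FC. Single-gene
folds are `2^log2FC` on the same axes. Gene-set scores are mean log2FC over
members with a size-matched permutation p (two-sided, add-one smoothing);
sets overlapping the table in fewer than 5 genes are refused.

**Ortholog mapping.** Host genes are re-keyed by their graft ortholog before
the tumor:host contrasts; many-to-one mappings are summed, unmapped host
genes dropped and recorded. The simulator builds 1:1 length-matched pairs;
many-to-one inputs are supported at the mapping step only.

## Perinecrotic spatial statistics

**Distances.** Boundary distances are unsigned minimum Euclidean distances
to polygon rings (inside/outside is a separate flag; points exactly on a
boundary count as inside — a deterministic tie rule). A scene with no
necrotic zone yields a NaN "no interface" sentinel, never 0.

**Profile.** Viable detections are binned by distance to the necrotic
interface (default band width 100 µm). Band viable areas come from
rasterizing the scene at `pixel_size` (default 2 µm) and applying a
Euclidean distance transform — analytic band areas are intractable for
general polygons, and at 2 µm pixels the discretization error is three
orders of magnitude below the band width. The enrichment statistic is
first-band density over overall viable density; its permutation null
resamples detection locations uniformly over viable pixels (999 rounds,
one-sided, add-one smoothing). Observed detection distances are exact
polygon distances; permuted draws use the raster distances (sub-pixel
discrepancy, negligible at these band widths). Profiles require at least
one necrotic zone and 20 viable detections.

**Necrosis and vessels.** Necrosis area fraction is the union of necrotic
polygons over the tumor polygon area (or a labeled-pixel ratio on the mask
route; the two agree to within rasterization tolerance). The high/low rule
is strict: > 15% is high. Vessels are label-mask components with equivalent
diameter 2·sqrt(area/π); "dilated" is an explicit threshold, default 50 µm,
because no quantitative definition is standard. Dilated density is per mm²
of viable area.

## Clinical analytics

CTC transitions flag a consecutive pair when the later count is at least
`fold_threshold` (default 10) times `max(earlier, 1)` — the floor of one
count makes the fold well defined at zero baselines, where a ratio rule is
otherwise undefined; an absolute-increase mode is available since a bare
"increase of 10 or more" is ambiguous between fold and difference. Samples
with ≥ 20 CTCs are flagged high. Waterfall summaries compare first vs last
timepoint by default (consecutive-pair mode available) and sort by
descending delta, ties by subject id. Prevalence percentages are rounded
half-up, with unrounded values reported alongside so complementary
categories reconcile exactly; "any CTC" counts singles and clusters,
making "no CTCs ever" its exact complement.

The BKY two-stage FDR is implemented as a linear step-up: stage 1 is BH at
q/(1+q); with 0 < r1 < m rejections, stage 2 re-runs BH at
q/(1+q)·m/(m−r1). Adjusted q-values are defined so that *discovery iff
q-value ≤ q* (like BH adjusted p-values, they depend on the adaptive null
estimate and hence on q). The implementation is cross-checked in the tests
against a naive-loop oracle on an exhaustive grid and against an
independent reference implementation.

Plasma group comparisons use the same moderated t as the enrichment module:
at the default 3-vs-13 group sizes a plain Welch t is anticonservative in
the extreme tail (the small group's sample variance occasionally collapses,
inflating the statistic), which an across-protein variance prior corrects.
Paired analyses average the per-subject linear late/early fold per protein
and report the half-up-rounded percentage of ≥ 2-fold-increased proteins
found in a user-supplied annotation set (e.g. a curated necrosis-associated
list — curation is outside the pipeline's scope).

Tumor volume is the caliper formula V = W²·L/2 (mm³) with W the shorter
axis; swapped axes are rejected rather than silently reordered.

## Synthetic-data generators

All generators are pure functions of their seed and parameters
(byte-identical outputs), and every simulated read/detection/subject has
exactly one truth record.

**Defaults encode the study conditions.** Graft read fractions 0.84 (core)
and 0.76 (rim). The planted marker uses graft core/rim means 320/20 against
host 10/10 — a 32× tumor:host ratio in the core and 16× core:rim in the
graft. Counts are negative binomial with gene-shared dispersion 0.1
(variance = µ + 0.1µ², a typical bulk RNA-seq value; dispersion 0 recovers
Poisson). Baseline genes share one lognormal mean (median 30 expected
counts, log-sd 1) across species and compartments, so they are exact nulls
for every contrast and library compositions stay balanced between species.
Interspecies divergence defaults to 0.10 in the tests, approximating
rodent–rodent transcriptome divergence. Sequencing errors are i.i.d.
substitutions at 0.005 (no indels, no quality modeling), matching the exact
scorer. Tissue scenes place detections with density
1 + strength·exp(−d/scale) above uniform (scale 100 µm, strength 10 in the
recovery tests). CTC series are Poisson with a planted last-timepoint fold;
plasma tables are Gaussian in log2 with within-group sd 0.3 — typical
isobaric-label plasma replicate variability, and a level at which a planted
4-fold enrichment is detectable at 3-vs-13 group sizes, consistent with the
sized discovery lists such studies report.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: isoform/splicing structure, paired-end reads,
positional or quality biases, aligner-specific artifacts, gene–gene
correlation, batch effects, immune or stromal composition shifts, 3-D
tissue geometry, cell segmentation error, and informative dropout in
clinical sampling. Recovery results certify the pipeline's statistical
machinery, not robustness to these real-data complications.

## Problem sizes

The recovery suites use 2000 genes × 5 samples/group × 100 seeds for
enrichment, 10,000-read libraries over 40 transcripts for deconvolution,
2 mm scenes at 2 µm rasterization with 999 permutations for spatial
statistics, and exhaustive p-vector grids to m = 6 for the FDR procedures —
sizes at which every stated sampling bound is computable and the whole
suite runs in minutes on one core.

## Known limitations

The scorer is exact only for substitution-type differences; indel-rich
references require an external aligner (scores can be imported). The
moderated t assumes roughly shared variance structure across genes/proteins
on the log scale. Band areas and the permutation null are raster
approximations. Survival analysis and ontology enrichment are intentionally
out of scope; output schemas keep the columns external tools need.
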