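# necroseq

Analysis pipeline for studying tumor dissemination from the necrotic core in
xenograft models, built for researchers working with graft-in-host tumor
transplants (e.g. mouse tumor cells grown in a rat host), digital-pathology
annotations, and longitudinal liquid-biopsy cohorts. All stages are
exercisable end-to-end on synthetic data with known ground truth.

## What it computes

**Species-of-origin deconvolution** (`necroseq.deconvolve`). In a xenograft,
bulk RNA-seq reads mix graft (tumor) and host (stroma) transcripts. Each read
is scored against both references with a k-mer-seeded, ungapped exact-match
counter (default k = 21); a read is called for the species whose score wins
by at least the ambiguity margin (default 2 matched bases), yielding per-
species gene-count matrices and the graft read fraction
n_graft / (n_graft + n_host).

**Cross-species core/rim enrichment** (`necroseq.enrich`). With host genes
re-keyed to their graft orthologs, each gene gets log2 fold-changes on two
axes — tumor core vs rim, and tumor (graft) vs host — from moderated
two-sample t tests on log2 CPM (empirical-Bayes variance shrinkage across
genes), with Benjamini–Hochberg q-values per contrast. Genes significant on
*both* axes at FDR ≤ 0.01 (optionally sign-filtered, e.g. core-up AND
tumor-up) form the tumor-specific core program; gene sets can be scored
between conditions with a size-matched permutation test.

**Perinecrotic spatial statistics** (`necroseq.spatial`). From QuPath-style
GeoJSON scenes (tumor-border polygon, necrotic-zone polygons, point
detections, µm coordinates): distance of every detection to the nearest
necrotic interface and tumor border, detection density in distance bands
(band areas by rasterized distance transform), an enrichment statistic
(first-band density / overall density) with a uniform-resampling permutation
p-value, necrosis area fraction with the strict >15% high/low rule, and
vessel morphometrics (equivalent diameter 2·sqrt(area/π), dilated at a
configurable threshold) from label masks.

**Clinical CTC / plasma analytics** (`necroseq.clinical`). Low-to-high CTC
transition detection (≥10-fold rise between timepoints; ≥20 CTCs marks a
high-count sample), waterfall summaries, cohort prevalence, the
Benjamini–Krieger–Yekutieli two-stage adaptive FDR, high-vs-low-CTC plasma
protein enrichment, paired ≥2-fold protein fractions, and the caliper
volume V = W²·L/2.

**Synthetic data** (`necroseq.simulate`). Generators with truth sidecars for
every input: ortholog-paired transcriptomes at a chosen divergence, mixed-
species FASTQ libraries (default graft fractions 0.84 core / 0.76 rim),
negative-binomial count matrices with an optional planted marker gene
(320/20 graft core/rim means vs 10/10 host: 32× tumor:host, 16× core:rim),
tissue scenes with exponential perinecrotic detection enrichment, Poisson
CTC series with planted transitions, and plasma tables with planted
enrichment.

## Worked example

```python
from necroseq import simulate as sim, deconvolve as dec, enrich as enr
from necroseq.containers import default_program

# --- deconvolve a rim-like mixed-species library -------------------------
tx = sim.generate_transcriptomes(n_genes=40, length=500, divergence=0.10, seed=1)
prog = default_program(sorted(tx.graft), seed=1)
reads, truth = sim.simulate_reads(tx, prog, n_reads=10_000, read_length=100,
                                  error_rate=0.005, seed=2, compartment="rim")
result = dec.deconvolve_library(reads, tx, margin=2, k=21)
print(result.report)
print(f"graft fraction: {dec.species_fraction(result):.4f}")

# --- find the planted tumor-specific core marker --------------------------
genes = [f"g{i:04d}" for i in range(2000)]
prog = default_program(genes, marker_gene="g0000", seed=4)
graft, host = sim.simulate_counts(prog, n_samples_per_group=5, seed=104)
table = enr.differential_enrichment(graft, host)
selected = enr.select_dual_significant(table, 0.01,
                                       {"core_rim": "up", "tumor_host": "up"})
print("dual-significant genes:", selected.genes)
s = enr.gene_fold_summary(table, "g0000")
print(f"tumor:host fold {s['fold_tumor_host']:.1f} (q={s['q_tumor_host']:.1e}); "
      f"core:rim fold {s['fold_core_rim']:.1f} (q={s['q_core_rim']:.1e})")
```

prints

```
{'n_reads': 10000, 'n_graft': 7524, 'n_host': 2476, 'n_ambiguous': 0, 'n_too_short': 0}
graft fraction: 0.7524
dual-significant genes: ['g0000']
tumor:host fold 31.4 (q=1.0e-10); core:rim fold 11.1 (q=1.3e-07)
```

The estimated graft fraction (0.7524) recovers the simulator's rim-like
mixing proportion of 0.76 to within binomial sampling error on 10,000 reads.
The dual-FDR selection returns exactly the planted marker, and its estimated
tumor:host fold (31.4×) recovers the planted 32× ratio; the core:rim fold
estimate is noisier at n = 5 per group but correctly flags strong core
enrichment (truth 16×).

A `necroseq` CLI mirrors the library
(`necroseq simulate ... | deconvolve | enrich | spatial | clinical`); run
`necroseq --help` for the full tree. Model details, parameter defaults, and
numerical choices are documented in `docs/methods.md`.

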