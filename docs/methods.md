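# Methods

## Model

A TFBS at genomic midpoint *m* contributes a unit-height Gaussian
`k(x; m) = exp(−(x − m)²/(2σ²))` to the per-chromosome density; a TFCR is
a strict local maximum (summit) of the kernel sum. The kernel is
deliberately **not** normalized: with unit height the contribution
threshold (intensity 0.1 at the summit) is scale-free and equivalent to a
fixed distance cutoff σ·√(2·ln 10) ≈ 2.146σ, independent of local site
counts. "Bandwidth 300 bp" is interpreted as σ = 300; users who read
bandwidth as full width can set σ accordingly (`TfcrParams.sigma`).

The contribution rule is read as *selecting* the sites whose kernel
intensity at the summit exceeds 0.1: the selected set is what the window
definition ("maximum distance to a contributing TF, plus half the
bandwidth") operates on. The literal alternative — discarding
high-intensity sites — would leave summits without contributors and make
the window undefined. A site may contribute to more than one TFCR;
exclusive assignment would need an arbitrary tie rule and is not implied
by the definitions.

Scores: TC = |{distinct tf_name among contributors}|; SC = arithmetic mean
of the signal of accessibility peaks overlapping the half-open window, 0
when nothing overlaps (dropping such TFCRs would change motif-only counts).
Tumor TFCRs are scored against ATAC-seq peaks, normal TFCRs against
DNase-seq peaks.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `sigma` | 300 | bp | kernel SD; sets cluster resolution |
| `grid_step` | 10 | bp | density evaluation spacing; summits are grid coordinates. At σ = 300 sub-10 bp structure is negligible; tests verify against a 1 bp oracle |
| `contrib_threshold` | 0.1 | — | kernel intensity for membership (≈ 643.8 bp at σ = 300) |
| `window_pad` | 150 | bp | half the kernel width, added to the max contributor distance |
| `min_summit_density` | 0 | — | optional sensitivity floor; the noiseless kernel sum needs none |
| `promoter_upstream` | 2000 | bp | gene-coverage extension upstream of the TSS (strand-aware), the usual regulatory-genomics default — the screen's "covered by" is otherwise undefined |
| `fpkm_min` | 5 | FPKM | candidate expression filter |
| `tc_split` | 170 tumor / 50 normal | TC | correlation-breakpoint cutoffs of the bladder landscape; any cutoff is accepted |

## Numerical choices

* **Grid and truncation.** Density is accumulated per chromosome on a
  regular grid spanning [min midpoint − 4σ, max midpoint + 4σ]; kernels
  are truncated where the tail falls below 1e−13, keeping every grid value
  within 1e−9 of exact summation (verified against a brute-force per-bp
  oracle).
* **Summit floor.** Truncation and float rounding produce ~1e−13 ripples
  in far tails that would register as strict local maxima. Any genuine
  maximum of a sum of equal-width unit kernels has a site within σ
  (beyond σ from every site all kernels are convex, so the sum is convex
  and admits no interior maximum) and therefore density ≥ e^(−1/2) ≈ 0.61;
  summit calling discards maxima below 1e−6, which removes only numerical
  artifacts.
* **Plateaus and ties.** A plateau maximum is reported at its midpoint
  (floor on even lengths); decile binning breaks value ties by
  (chromosome, summit); candidate output is sorted by descending γ then
  gene id. All outputs are deterministic and byte-stable across reruns.
* **Degenerate inputs.** Empty TFBS input yields an empty profile/TFCR
  list with a warning; an empty condition makes the differential partition
  degenerate (everything gain or lost) with a warning; correlation strata
  with n < 3 or constant values are flagged undefined rather than given a
  fabricated r.

## Decile binning and γ

Bins are equal-frequency: bin = ⌊10·(rank − 1)/n⌋ on the ascending axis
rank, computed within one condition at a time (tumor TFCRs are ranked
against tumor TFCRs). Rank-based bins keep every decile populated whatever
the TC/SC distribution shape, and make the bin index monotone in the value.
The γ formula is not part of the published record; the default
`γ = (tc_bin+1)(sc_bin+1)/100` is the simplest score that is strictly
monotone in each bin and attains 1 exactly on TC9 ∧ SC9, so "γ = 1"
coincides with the operational top-decile selection. It is pluggable
(`screen_candidates(gamma=...)`) and should be treated as a ranking device,
not a calibrated probability.

## Synthetic landscape

The generator emulates the statistical structure the analysis relies on:

* clusters with `TC_true = 1 + Poisson(cluster_tc_mean)` distinct TFs,
  each TF with `1 + Poisson(sites_per_tf_mean − 1)` sites at
  `Normal(center, 75 bp)`;
* one accessibility peak per cluster with the saturating score law
  `sc_base + sc_slope·min(TC_true, sc_saturation_tc) + N(0, sc_noise_sd)`,
  truncated at 0 — the minimal mechanism that produces a TC–SC correlation
  below the saturation point and none above it;
* shared / gain / lost condition memberships (shared clusters reuse the
  same sites in both conditions, with independent peak noise);
* expression: lognormal FPKM, boosted ×8 for genes hosted by top-quartile-TC
  clusters; driver genes planted with TSS within 500 bp of selected gain
  clusters and FPKM ≥ 5;
* regulatory elements: ±500 bp promoters at every TSS, enhancers at
  top-decile-TC clusters, CpG-island analogues at top-decile-score
  clusters, plus unannotated background intervals;
* variants: per-bp Bernoulli at `base + slope·TC_true` inside cluster
  windows and `base` elsewhere.

The standard benchmark is 200 clusters (100 shared / 50 gain / 50 lost) on
a 4 × 2 Mb genome, background 0.05 TFBS/kb, σ-identifiable spacing
(centers ≥ 5 kb apart, enforced ≥ 10σ). Two design choices keep the
ground truth well defined. First, cluster centers sit on a separation grid
with small jitter, so recovery (summit within 300 bp of a center, greedy
nearest-first 1–1 matching) is unambiguous. Second, background sites of
one condition are kept 1.5 kb clear of the *other* condition's exclusive
cluster centers: otherwise a chance background TFCR would occasionally
overlap a planted gain/lost window from the opposite condition and the
planted label would be wrong by construction rather than by pipeline
error.

Driver genes are planted under gain clusters *verified* to fall in both
top deciles: the generator runs identification, binning and
classification on its own sites and peaks (genes, elements and variants
play no role in TFCR calling, so this is well defined and deterministic)
and selects hosts among the matched TC9 ∧ SC9 gain clusters. Predicting
decile membership analytically from the planted parameters is unreliable
exactly at decile boundaries, which is where a screen test must be exact.

### Breakpoint study conditions

The magnitude of a null Pearson correlation concentrates as 1/√n, so the
saturated stratum must be large before |r_high| is reliably small.
`breakpoint_config()` therefore uses 400 tumor-side clusters with
`cluster_tc_mean = 55`, putting ≈ 320 clusters above the TC = 50
saturation point; at that size 0.2 is ≈ 3.6 null standard deviations, so
the decorrelation check is stable across seeds. This is a power
calculation, not a fit to data.

### What the benchmark does not show

The generator plants idealized structure: well-separated clusters,
Gaussian site scatter, exactly one peak per cluster, no mappability or
copy-number artifacts, no motif sequence content, and condition
differences that are purely presence/absence. Passing recovery tests
demonstrates the pipeline's internal correctness — density, summit,
window, scoring, binning, classification and screening logic — not that
real tumor/normal landscapes will yield comparable recall, nor that the
published gene lists would be reproduced; those depend on the original
ATAC/DNase data, motif database and scan settings, which are external
inputs. The published dataset-level figures (tens of thousands of TFCRs,
their overlap percentages, the final candidate list) are likewise not
desk-reproducible; the downstream expression/survival triage of candidates
against web databases is a documented manual step outside the pipeline.

## Known limitations

* Kernels are strand-agnostic and unweighted by motif score (deliberate:
  the clustering definition counts sites, not match strength).
* SC averages peak scores without length weighting; a short high peak and
  a long one count equally.
* The FIMO reader ingests whatever hit list it is given; motif-scan
  thresholds (score, q-value) are upstream policy, with only an optional
  `max_qvalue` convenience filter.
* Chromosome names are matched as exact strings; harmonize "chr"
  prefixes upstream.
* The overlap rule for the differential partition is ≥ 1 shared bp;
  `min_overlap_frac` is available but 0 is the default because no minimum
  fraction is part of the method's definition.
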