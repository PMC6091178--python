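# Methods

## The procedure

The package implements a guide-gene co-expression screen over an ordered
expression gradient. Inputs are a genes × samples matrix of nonnegative
FPKM-scale values, a list of guide genes of known function, and a
gene → TF-family annotation. The screen itself is a plain sample Pearson
correlation between each guide profile and every gene profile, followed by
hard cutoffs on |r|. Two cutoffs are used for two purposes:

* **τ = 0.8 (family screen).** Strong co-expression; the TF families of the
  survivors are tallied per guide and the top 5 most abundant families are
  intersected across guides. The intersection nominates a candidate family.
* **τ = 0.6 (network).** A laxer cutoff for the bipartite guide–TF network,
  with edges signed by sign(r). Per-TF sign classification is the majority
  sign of the TF's edges; a tie is "mixed" and logged.

Both cutoffs are strict (`>`), reflecting the "greater than" reading of a
threshold; both are configurable, as is a `positive`/`negative`-only mode.
Correlation is computed on values as read; an optional log2(x+1)
pre-transform (`log_transform: true`) documents the sensitivity of the
screen to scale, but the default mirrors the plain procedure.

### Assumptions and scope

* Co-expression is linear similarity over the gradient. No rank-based or
  partial correlation, no soft thresholding, no significance testing: the
  method thresholds the coefficient, and family ranking uses raw counts,
  not an enrichment test.
* The network is strictly bipartite. Guide–guide and TF–TF edges are never
  emitted, and a guide that is itself an annotated TF is removed from the
  TF pool; a TF needs |r| > τ with at least one guide to enter.
* Genes with zero-variance profiles have no defined correlation. They are
  flagged, logged and excluded; they are never treated as r = 0.
* Gene identifiers are opaque case-sensitive strings; no ID mapping is
  attempted. Missing cells and negative values in the matrix are hard
  errors, not imputed.

### Numerical choices

* r is computed from centered profiles via a symmetric sum, clipped to
  [−1, 1] against floating-point overshoot; a guide's self-correlation is
  pinned to exactly 1 when defined. The engine agrees with a naive
  two-pass covariance implementation to 1e−12 (tested).
* Family-ranking ties are broken lexicographically, and a tie truncated at
  the top-K boundary is logged; candidate ordering is by negative-partner
  count descending, then gene id. All exports (SIF, GraphML, TSV) are
  byte-for-byte deterministic: edges sorted by (guide, TF), r printed with
  6 decimals (round half to even).
* The run manifest echoes the config, checksums the inputs and records
  per-stage counts; its timestamp is the one intentionally
  non-reproducible field and is excluded from determinism comparisons.

## The synthetic-data generator

The generator emulates the kind of study the pipeline targets: an
11-section immature-to-mature leaf gradient with guide anchors, planted
co-expression partners and noise background.

* **Anchor profiles** are smooth nonnegative gradients: strictly
  increasing (random positive increments normalized to an amplitude),
  strictly decreasing (the exact reverse), or unimodal ("peaked", a
  Gaussian bump with an interior off-grid center).
* **Planted partners** use the classical construction
  y = ρ·z + √(1−ρ²)·ε on the standardized anchor z, with ε independent
  Gaussian of standard deviation `noise_sd`, then an affine shift to
  nonnegativity (correlations are unaffected). With `noise_sd = 1`
  (default) the population correlation equals the target ρ exactly; in
  general it is ρ/√(ρ² + (1−ρ²)·noise_sd²). At |ρ| = 1 the noise term
  vanishes and the sample correlation is exactly ±1 for every seed.
* **Background genes** are independent noise (Gaussian shifted to
  nonnegativity by default; a lognormal option exists for a more
  FPKM-like marginal shape). Background families cycle through a
  user-supplied list; `None` entries leave genes unannotated, emulating
  non-TF genes.
* **Randomness contract:** one root seed; each gene draws from its own
  substream derived by SHA-256 hashing of its gene id, so adding or
  removing a gene never perturbs any other gene, and identical specs are
  bit-for-bit reproducible across platforms.

### Study-condition defaults

`default_study_spec()` fixes the scenario used by the acceptance script
and the end-to-end tests: 11 sections; eight anchors named after the rice
photoperiodic flowering guides, all rising along the gradient (co-regulated
pathway genes on a maturation gradient are mutually positively correlated,
which also makes planted edge signs consistent across guides); a planted
G2-like complement of 28 TFs — 21 at ρ = +0.95 and 7 at ρ = −0.95,
round-robin across anchors — mirroring the network structure the screen is
meant to recover; smaller planted cohorts of MYB/bHLH/NAC/WRKY/ERF at
|ρ| = 0.92 so the family ranking has a realistic shape; and 400 background
genes, half unannotated and half in unrelated families. ρ = 0.95 was
chosen as a strong but noisy planted signal: comfortably above the 0.6
network cutoff in expectation, yet with real sampling variation at n = 11.

### What passing tests do and do not show

The generator controls correlation structure analytically, so tests show
that the pipeline recovers planted linear co-expression, classifies edge
signs correctly, controls background false positives at the rate implied
by the null distribution of r at n = 11 (about 5% per anchor at |r| > 0.6),
and is deterministic end to end. It does **not** emulate read-count noise,
library-size effects, heavy-tailed FPKM marginals, or correlated
backgrounds; agreement on synthetic data therefore validates the machinery
and its thresholds, not the biological truth of any particular real-data
network, and real TF counts shift if a different family-annotation version
is substituted.

## Design choices where the design was open

* **Sign classification of a multi-edge TF** is per-gene by majority over
  its edges, because the headline counts are per-gene, not per-edge; the
  tie case is explicit ("mixed") rather than silently assigned.
* **Venn scope:** the cross-guide family intersection defaults to all
  supplied guides; `venn_guides: paper` restricts it to the four guides
  (OsGI, Ghd7, OsMADS14, Hd3a) covered by the original supplementary
  analysis, since the remaining guides' family tables were not reported.
* **Candidate cutoff:** `min_negative_partners` defaults to 2 — the
  weakest defensible reading of "negatively co-expressed with many
  regulators" — and is configurable; the OsPHL3 exemplar has 4.
* **Problem sizes in tests and the acceptance script** (20×11 oracle
  matrices, 200 recovery replicates of ~40 genes, 1000-gene null) were
  chosen so the whole suite runs in seconds while Monte-Carlo error stays
  far from the asserted margins.

## Limitations

* Pearson correlation on a monotone gradient rewards any monotone gene
  pair; the screen is a prioritization heuristic, not causal inference.
* With 11 samples the null |r| > 0.6 rate is a few percent per guide, so
  unfiltered all-family networks contain chance edges by design; the
  family restriction and the stricter 0.8 screen are what keep the
  candidate list short.
* The bundled TF-family file is a labelled synthetic stand-in for demos;
  real analyses must supply a genome-wide annotation, and results depend
  on its version.
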