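# Methods

This note documents the models, parameter choices, and numerical decisions
behind `spatomix`, and what the synthetic phantom does and does not show
about real tissue data.

## The synthetic tissue phantom

The phantom stands in for a pathologist-annotated gastric-cancer section.
Its raster carries ten region types (tumor, tumor/gland mixed, normal
epithelium, intestinal metaplasia, lymphoid follicle, muscularis mucosa,
peritumoral muscularis, lamina propria, blood-containing, connective
tissue) with target area fractions chosen as plausible for such a section
(tumor 18%, the rest 6–12%). Geometry is generated by growing regions from
nuclei placed with greedy max–min separation; each region's frontier is a
priority queue ordered by distance to its nucleus times a multiplicative
jitter in [1, 1.6], which produces irregular, histology-like boundaries.
Growth is scheduled by relative quota deficit, and a final boundary-flip
pass moves pixels down the area-deviation gradient until every region is
within max(1 pixel, 0.5%) of its quota — so area fractions conserve the
specification to well within 2%. Regions are grown as contiguous blobs;
the rebalancing pass can occasionally split off small satellites, which is
also true of real histological units (e.g. lymphoid follicles).

**Gene expression.** Counts are simulated directly at spot level (the
pipeline never sees cells) from a program table: each feature has a
baseline mean (log-normal with median 1, shape 0.8, frozen at the packaged
seed 20429) and each region elevates its marker genes by a planted log2
fold change of 2 (4×). The default panel of 2000 genes mixes biologically
named genes — polyamine/arginine-proline pathway members (GLS, GLUL, ASS1,
ALDH18A1, PYCR1, OAT, ODC1, SRM, SMS, AGMAT), fatty-acid synthesis genes
(ACACA, FASN, SCD, FADS2, ELOVL1), phospholipid genes, and curated
cell-type markers — planted in the regions where such genes are reported
elevated (tumor, lymphoid, etc.), plus 40 anonymous markers per region and
anonymous filler. Genes of three further pathways (glycolysis, TCA,
purine) enter at baseline only, providing genuinely tested null pathways
for enrichment. Counts are negative-binomial with shape (``dispersion``)
2.0 — variance µ + µ²/2, a typical overdispersion for spot-level data —
approaching Poisson as the shape grows.

**MSI intensities.** Each compound peak has baseline median intensity 20
(arbitrary units); five disjoint peak sets ("archetypes") are elevated 4×
in five region groups, mirroring the five spatial components the MSI
decomposition is expected to find (intestinal metaplasia + tumor;
connective; muscularis mucosa; tumor/gland mixed; blood). Polyamines and
arginine/proline intermediates are pinned to the tumor-containing
archetype and the de-novo-synthesis lipids to its lipid counterpart, so the
planted gene–tissue–metabolite colocalization is recoverable downstream.
Pixel intensity is LogNormal(median = programmed mean, shape σ = 0.25)
plus a baseline offset of 2 plus Gaussian technical noise (σ = 1),
truncated at zero. No instrument publishes its noise magnitudes; these
values are a modelling choice, stated here, that yields realistic ~25%
multiplicative spread. m/z values are fixture monoisotopic masses plus the
protonated-adduct mass; pitch presets are 100 µm (ambient ESI / Orbitrap)
and 50 µm (MALDI-TOF).

**What the phantom does not emulate:** spatial autocorrelation within a
region (spots are conditionally independent), cell-type mixtures at region
boundaries, count–depth covariation, isotope envelopes, chemical noise and
matrix clusters, or section-to-section registration error (all modalities
share one frame, so the landmark fit recovers the identity). Passing
tests therefore demonstrate correctness of the computations and
recoverability under the stated noise model, not robustness to every
artifact of real acquisitions.

## Spot grid and registration

The grid is a square lattice — spacing 100 µm, spot diameter 55 µm,
6.5 × 6.5 mm extent, 65 × 65 = 4225 spots — with labels `x{i}y{j}`
assigned row-major from the top-left spot (`x1y1`; `x2y1` is 100 µm to the
right, `x1y2` 100 µm down). The physical Visium chip is hexagonal with
about 5000 spots per capture area; the square lattice follows the
coordinate-labelling scheme used for integration at 100 µm, which a
hexagonal array cannot satisfy exactly. Registration is least-squares
affine on ≥ 3 landmark pairs (the manual image-fusion step made explicit
and testable); the fitted transform reports residual RMS and inverts to
1e-6 µm on round trips. Pixel-to-spot assignment defaults to Voronoi
(nearest spot center, ties to the lexicographically smaller label):
with 50 µm pixels and 55 µm discs a corner-aligned lattice leaves discs
empty, whereas Voronoi guarantees full coverage at the 100 µm integration
resolution; the circle rule is available when strict capture-area
semantics are wanted. Spot profiles are arithmetic pixel means; spots with
no pixels are flagged missing (NaN), never zero.

## MSI processing

*Peak alignment* pools all spectra, scans m/z ascending, chains values
closer than the 0.01 Da tolerance (single linkage), and recursively splits
chains wider than the tolerance at their largest internal gap — a
deterministic, order-independent rule; the aligned m/z is the
intensity-weighted cluster mean. *Deisotoping* removes a peak iff a peak
one ¹³C spacing (1.00336 Da) below exists with strictly greater intensity;
the base peak can never be removed. *TIC normalization* scales each pixel
to the cube-median TIC; all-zero pixels are flagged, not rescaled.

*pLSA.* Intensities are converted to pseudo-counts (TIC-normalized, total
rescaled to pixels × 1000 — EM is valid for arbitrary nonnegative
weights; no counting model for MSI intensities exists) and factorized as
P(i,j) = Σ_k P(k) P(i|k) P(j|k) by EM: E-step responsibilities
P(k|i,j) ∝ P(k)P(i|k)P(j|k); M-step re-estimates each factor from
responsibility-weighted counts. Initialization is Dirichlet(1) from the
given seed; iteration stops at relative log-likelihood change < 1e-6 or
500 iterations. The log-likelihood is non-decreasing (an EM guarantee,
asserted numerically with a 1e-6 relative allowance for round-off);
probability columns renormalize to 1 within 1e-9 every iteration. Whether
the original vendor analysis ran on raw or TIC-normalized intensities is
not documented; this implementation normalizes, and the recovery tests are
run under that convention.

*Segmentation.* The vendor segmentation algorithm is proprietary; the
package's defined equivalent is TIC normalization → PCA (default 10
dims) → k-means (k-means++, fixed seed, 10 restarts) → optional 3×3 modal
filter on the label raster.

## ST clustering

Counts are depth-scaled to 10 000 per spot and log2(x+1)-transformed;
zero-depth spots are excluded. The SNN graph takes each spot's
neighborhood as itself plus its 15 Euclidean nearest neighbors in
20-dimensional PC space, weights edges by neighborhood Jaccard overlap,
and prunes below 1/15. Communities come from seeded Louvain modularity
optimization (networkx), with cluster ids relabelled densely by decreasing
size for determinism. The proprietary vendor clustering publishes no
parameters; n_pcs = 20, k = 15 are the field's common defaults, and the
resolution default (1.0) was fixed by `scripts/calibrate_resolution.py` on
the packaged phantom, where every resolution in [0.25, 2.0] recovers the
ten planted programs at ARI 1.0 — the choice is insensitive over an
eightfold range.

## Differential screening

Tests are unpaired two-tailed t-tests; the Welch (unequal-variance) form
is the default since group variances differ by construction under the
negative-binomial model (Student's form is selectable). Fold changes are
ratios of raw group means; log2 fold changes add a per-feature
pseudo-value ε = half the smallest nonzero value of that feature, which
stabilizes zeros without distorting large means. When tests run on
log-normalized values, fold changes are computed on the raw scale via the
``fold_values`` argument, keeping the thresholds' meaning. Features
constant and equal in both groups get t = 0, p = 1 by convention.
Benjamini–Hochberg is the step-up rule implemented directly (q_(i) =
min_{j≥i} p_(j)·m/j, capped at 1) and cross-checked in tests against both
a brute-force oracle and statsmodels. Thresholds: fold-change bounds are
inclusive (≥), p/q bounds strict (<); "confidence intervals 0.95" is read
as the α = 0.05 reporting convention, not a different test.

## Annotation

MS1-only: a query matches a (compound, adduct) pair when |1e6·(query −
theoretical)/theoretical| is strictly below the instrument tolerance
(Orbitrap 5 ppm, MALDI-TOF 10 ppm). Adduct masses use CODATA proton and
electron masses (electron included — the observed species is the ion),
documented to 1e-5 Da; defaults are +H/+Na/+K (positive) and −H/+Cl
(negative) since the original adduct set is not stated. MS/MS confirmation
is out of scope; fixtures may set a ``confirmed`` flag instead. Cell-type
calls use the one-sided hypergeometric tail of the overlap between a
cluster's screened markers and each curated marker list, with the gene
universe = all genes in the count matrix (the original universe is
unstated); the smallest-p type is called, ties are all reported, empty
overlap yields "unassigned".

## Enrichment and the association network

Pathway over-representation is the one-sided hypergeometric upper tail
with BH correction across pathways — the standard computation behind
enrichment web services, substituted here for the external service the
original analysis used. The association network links each marker gene to
its tissue and each tissue to its marker metabolites/lipids; edge weight
defaults to |log2FC| (configurable to unit weights) — the original figure
defines "connection degree" only visually, so the weight definition is
this package's choice. Node degree is the incident weight sum. Tightening
any screening threshold can only remove nodes/edges (monotonicity,
tested).

## Determinism and problem sizes

Every stochastic step takes an explicit seed; a single pipeline seed
spawns per-stage sub-seeds. All writers fix column orders, float formats
and JSON key order, and community modularity is rounded at 1e-12 (the raw
sum's last ulp depends on hash order), so two runs with one seed are
byte-identical. Default problem sizes — 4225 spots × 2000 genes, 4225
metabolite pixels × 32 peaks, 16 900 lipid pixels × 12 peaks — run the
full pipeline in well under a minute on one CPU; tests use smaller
phantoms (up to 40 × 40 pixels) except the end-to-end checks, which run
the defaults.

## Known limitations

- Square, not hexagonal, spot geometry (see above).
- No image-based (mutual-information) registration; landmarks only.
- Peak picking from profile spectra is out of scope; cubes enter
  pre-centroided, and deisotoping uses the single-Δ rule only.
- No spatially aware clustering: expression-only, like the original.
- Annotation is MS1 mass matching only; isobars within tolerance are
  returned as ranked candidate lists, not resolved.
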