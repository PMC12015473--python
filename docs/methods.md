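# Methods

`budmetrics` implements a digital phenotyping and trait-genetics pipeline for
tea (*Camellia sinensis*) apical buds: morphometrics from flatbed-scanner
images, germplasm diversity statistics, phenotype clustering, a
trait-expression candidate screen, and GWAS candidate-interval construction.
This note records the models, the parameter choices that matter, the design
decisions taken where more than one reasonable convention exists, and what
the synthetic-data generators do and do not emulate.

## Image morphometrics

**Calibration.** A flatbed scanner samples at a fixed, known density, so the
only calibration is the scalar `s = 2.54 / dpi` cm per pixel (0.00423 cm/px
at the default 600 dpi). No fiducial markers are used; a scan whose dpi
metadata is wrong is wrong in all four features proportionally.

**Segmentation.** Buds lie on black light-absorbing cloth, so segmentation
thresholds the brightness channel `V = max(R, G, B)` — robust to bud hue,
which ranges from green to brown — with Otsu's method by default and a
fixed-threshold fallback for pathological histograms. The binary image is
cleaned by morphological opening then closing (default radius 2 px each),
holes are filled, and 8-connected components are labeled (with 4-connected
background, the standard complementary pair). Components smaller than
`min_area_cm2` (default 0.02 cm², about a 1.6 mm square) are treated as
debris; components touching the scan border are excluded by default because
they are likely truncated buds. Shapes are assumed non-overlapping, i.e.
buds were separated by hand before scanning.

**Features.** Per bud:

- **Area** `A` = foreground pixel count × s². Pixel counting is unbiased to
  first order for smooth shapes.
- **Perimeter** `P` = arc length of the sub-pixel iso-0.5 contour of the
  mask, computed by marching squares after light Gaussian smoothing
  (σ = 1 px). Counting boundary pixels instead would overestimate smooth
  perimeters by up to ~27% (staircase bias); the smoothed sub-pixel contour
  brings the error under ~0.5% at 600 dpi. The smoothing shifts a curved
  boundary inward by ≈ κσ²/2, below 0.02 px at bud curvatures.
- **Length and width** `(L, W)` = long and short side of the minimum-area
  rotated bounding rectangle of the contour's convex hull. This caliper
  definition is deterministic and exact for straight buds; a curved-bud
  medial-axis length is deliberately **not** implemented (tea apical buds at
  the harvested stage are close to straight, and a medial-axis length has no
  closed-form oracle to validate against).

Degenerate single-pixel masks return `L = W = s`, `P = 4s` by convention.
All features are reported in cm/cm².

Measured against closed forms of rendered stadium, ellipse and circle
shapes, all four features are within 2% at 600 dpi (typically within 0.5%),
and features are rotation-invariant to the same tolerance and
scale-equivariant across dpi within digitization error (≤ 2 px·s for L, W;
≤ 4 px·s for P).

## Diversity statistics

Computed on **accession means** (arithmetic mean over replicate buds),
except heritability, which needs the replicate level.

- **CV** = sample SD (n−1) / mean × 100.
- **Shannon–Wiener H′** = −Σ pᵢ ln pᵢ over 10 grading classes anchored at
  the sample mean: class 1 below μ−2σ, classes 2–9 in successive 0.5σ
  bands, class 10 above μ+2σ. This is the common germplasm-grading
  convention; it makes H′ invariant to affine rescaling, and for a
  near-normal trait of any scale it converges to ≈ 2.09 (the entropy of the
  normal band masses), with n = 280 panels typically scoring 2.0–2.1.
- **Broad-sense heritability h²** from clonal replicates by a one-way
  random-effects decomposition: accessions as groups, replicate buds within.
  `σ²g = max(0, (MS_between − MS_within) / n0)` with Snedecor's effective
  replicate number `n0 = (N − Σnᵢ²/N)/(a−1)` for unbalanced designs, and
  `h² = σ²g / (σ²g + MS_within)`, clipped to [0, 1]. Single-environment,
  single-year; no multi-environment variance components are attempted.
- **Normality** by Shapiro–Wilk (scipy's Royston implementation; 3 ≤ n ≤ 5000).

## Clustering

Accessions are clustered on the four trait means with Euclidean distances
under **Ward linkage** on **z-score standardized** traits (both
configurable). Standardization is the default because the four traits span
an order of magnitude in scale (width ~0.35 cm vs perimeter ~5.75 cm) and
would otherwise be dominated by perimeter; Ward is the default because on a
~280-accession standardized panel it produces merge heights of the magnitude
at which a small number of interpretable groups appear, where single or
complete linkage top out at a few units. The tree is cut at a height or
into exactly k groups; groups are labeled I, II, … by descending size.
Group summaries include per-group trait means and a region × group table
restricted to the top-N regions by count (default 15).

## Expression screening

For the 4-vs-4 extreme-accession design, each gene is screened per trait by

- Pearson r between expression and the per-sample trait value (the
  accession's mean bud phenotype), with the two-sided p-value from
  `t = r √((n−2)/(1−r²))`, df = n−2;
- `log2 FC = log2((mean TPM large + ε)/(mean TPM small + ε))`, oriented
  large-over-small so a gene higher in large buds has positive FC;
- pass ⇔ `p < α` (default 0.01) and `|log2 FC| > 1`.

Choices worth noting: the pseudocount ε = 0.1 keeps FC finite for
unexpressed genes without distorting moderately expressed ones; correlation
is computed on TPM by default with a `log` switch for log2(TPM+1); **no
multiple-testing correction is applied** — with n = 8 samples this is a
candidate screen whose output feeds orthogonal evidence (GWAS), not an
inference procedure, and it is documented as such. Genes with zero
expression variance are excluded (r = NA). Per-trait gene sets are
intersected with full Venn region counts; selected genes can be row
z-scored ((x − row mean)/row SD, ddof = 1) for heatmap export.

## Candidate intervals and genotype stratification

Association scans (`chrom, pos, p` per trait) come from an external
mixed-model engine; this package implements only the post-processing. A SNP
is a candidate if `p < α` in at least `min_traits` traits (defaults
α = 1e-6, min_traits = 2). Each candidate is flanked by 100 kb on either
side, clipped to the chromosome, and per-chromosome intervals are merged
when overlapping **or book-ended** (next start ≤ current end + 1, the
behavior of the standard BED merge tool; strict overlap is configurable).
Coordinates are 1-based inclusive internally; BED export is 0-based
half-open and round-trips exactly. Genes overlap an interval when their
inclusive spans share ≥ 1 bp. The merge is validated against a per-bp
union-then-scan brute-force oracle and is idempotent.

On the significance default: the common convention pairs a methods-stated
threshold near 6 × 10⁻⁶ with a plotted genome-wide line at −log₁₀P = 6;
these differ by a factor of 6. The package defaults to the plotted line,
1e-6 (the more conservative of the two), with `--alpha` override.

At a lead SNP, accessions are grouped by unphased genotype class (hom-ref /
het / hom-alt; missing excluded; multi-allelic sites restricted to the two
most frequent alleles with a warning). Per trait: one-way ANOVA, all-pairs
Tukey HSD from the studentized-range distribution (Tukey–Kramer under
imbalance, via `scipy.stats.tukey_hsd`), and a compact letter display at
0.05 built from maximal cliques of the non-significance graph.

## Synthetic data: what it emulates, and what it does not

Every generator plants a known truth so downstream stages are tested
quantitatively:

- **Scanner scenes**: straight stadiums/ellipses/circles rendered by 4×
  supersampled analytic rasterization, thresholded to crisp edges, on a
  near-black background with Gaussian noise (SD 4 gray levels). Closed
  forms: stadium `A = aW + π(W/2)²`, `P = 2a + πW` with `a = L − W`;
  ellipse `A = πab` and Ramanujan's perimeter approximation (relative error
  < 1e-6 at bud aspect ratios). Shapes are straight **by design** — a
  curved bud would break the caliper-length oracle. Not emulated: bud
  texture, trichomes, shadows, specular highlights, touching buds. Passing
  tests therefore demonstrate correctness of the geometry pipeline, not
  robustness to real-scan segmentation ambiguity.
- **Phenotypes**: `value = μ_t + g_i + e_ij`, `g ~ N(0, σ²g)`,
  `e ~ N(0, σ²e)`; defaults are the published panel scale — 280 accessions,
  15 replicate buds, per-trait means/SDs (e.g. length 2.65 ± 0.38 cm) and
  per-trait heritabilities used as targets to derive σe. Traits are drawn
  independently; real bud traits are strongly correlated, which matters
  only for multivariate uses (clustering uses a separate well-separated
  blob generator for planted-partition tests).
- **Expression**: linked genes follow `log2(TPM+1) = b + slope·z(trait)` ±
  noise (default slope 2, noise SD 0.25 log2 units ≈ 19% scatter); linked
  intercepts are drawn high enough that the planted relation is never
  clipped at zero TPM. Null genes are trait-independent log-normals. The
  null false-positive rate of the screen at α is α by construction,
  which the calibration test verifies.
- **Association**: uniform background p on a 10-kb SNP grid, planted peaks
  overwriting p for member traits, genes tiled along chromosomes in the
  GFF3, and a minimal VCF 4.2 with Hardy–Weinberg genotypes at lead SNPs
  (alt frequency 0.4) shifting phenotypes additively by 1 trait-SD per alt
  allele across 90 samples. No linkage disequilibrium is simulated, so
  planted peaks are single-SNP; real scans produce LD-smeared peaks whose
  flanked intervals merge more aggressively.

All generators are deterministic given a seed (byte-identical outputs).

## Problem sizes and numerical choices

Tests run the full pipeline at the panel scale where that is cheap
(280 × 15 phenotypes, 1000-gene screens, 280-accession clustering) and at
reduced raster sizes for imaging (single-shape scenes sized to the shape,
50-shape batches for the validation regression; multi-shape scenes on
2000 px canvases with small-to-mid bud lengths so rejection-sampled
placement always succeeds). Ties in clustering resolve to the lowest pair
index (SciPy's deterministic behavior); negative variance components
truncate at zero; Otsu degenerate histograms (all fore/background) yield an
empty segmentation with a warning rather than an error.

## Known limitations

- Length is a straight caliper measure; a strongly curved bud is
  under-measured. Medial-axis length is out of scope.
- h² from clonal replicates within one season confounds genotype with any
  accession-level micro-environment; it is an upper-bound-style estimate.
- The expression screen's p-values assume bivariate normality and n = 8;
  they rank candidates, nothing more.
- Interval counts on real data depend on SNP density and LD; the package
  reproduces the procedure, and its tests validate the procedure's
  invariants, not any particular real-data count.
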