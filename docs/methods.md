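# Methods

This note documents the models behind `spatialtme`, the parameters that
matter, the design choices that were genuinely open, and what the synthetic
validation does and does not establish.

## Phenotype gating

Cells are gated by boolean marker positivity with a priority-ordered rule
list (first match wins).  The default taxonomy:

| gate | definition |
| --- | --- |
| T cell | CD3⁺ |
| cytotoxic / helper | CD3⁺CD8⁺CD4⁻ / CD3⁺CD4⁺CD8⁻ |
| subset within each arm | highest-priority positive subset marker, FOXP3 > T-bet > GATA3 > RORγT > BCL6 > CD56, else "-other" |
| T-other | CD3⁺ but CD4⁺CD8⁺ or CD4⁻CD8⁻ |
| DC / NK | CD3⁻CD11c⁺ / CD3⁻CD56⁺CD11c⁻ |
| tumor / endothelium | CD3⁻panCK⁺ / CD3⁻CD31⁺ |

FOXP3 is ranked first so that regulatory identity dominates cells
co-expressing several transcription factors, the usual convention in T-cell
immunology; the ranking is configurable through `GatingRule` sets.  Placing
CD4⁺CD8⁺ double positives in their own bucket (rather than either arm) keeps
the subpopulation labels an exact partition of CD3⁺ cells, so fractions sum
to 100%.  Functional markers (TIM-3, PD-1, CTLA-4, GranzymeB, Ki67, HLA-DR,
CD27, CD45RA) never enter the gates; their per-subpopulation positive
fractions are separate read-outs.  Together with functional strata this
yields the usual ~45 distinguishable (functional) T-cell subpopulations.

Densities divide by the tissue area: the known disc area for a TMA core
(0.6 mm spot = π·0.09 ≈ 0.2827 mm²), a supplied area, or — as a mask-free
fallback for large sections — the convex hull of the cells.  Any ratio with
a zero denominator (a sample without T cells, an empty subpopulation) is
*excluded*, i.e. reported as missing and dropped per feature downstream,
never propagated as NaN arithmetic or silently zero-filled.

## Contact graph and interaction statistics

A contact is a pair of cell centres at Euclidean distance ≤ 8 μm (boundary
inclusive).  The graph is computed with a k-d tree but is defined — and
tested — by the all-pairs rule.  Contacts are unordered and counted once per
pair; within-type contacts count once.  With that convention the
*(p)-normalized interactions* `contacts(A,B)/total` sum to exactly 1 over
unordered pairs (including A = A), which the tests assert to 1e-9.  The
*normalized interaction* divides by the combined cell count `n_A + n_B`
(`n_A` for A = A).  Tumor and endothelial cells are excluded from the
contact totals; immune cells are the T lineages plus DC and NK.

Significance against the geometry-driven random background is a label
permutation: subpopulation labels are shuffled across the immune-cell
positions, the per-pair contact count is recomputed for each of `n_perm`
rounds (default 1,000), and `p = (1 + #{null ≥ obs}) / (1 + n_perm)`
one-sided for enrichment, with `z = (obs − mean₀)/sd₀` on the normalized
scale.  Holding positions fixed preserves exactly the random contact rate
the tissue geometry produces; the descriptive contacts-per-area rate is also
reported when an area is known.  Whether the original noise estimate was a
permutation, an analytic rate or density-matched resampling is not
something this implementation asserts — the permutation form is this
package's choice, made because it yields a proper finite-sample p value
under the stated null.

Permutation p values are discrete (resolution 1/(n_perm+1)) and
tie-conservative: pairs whose expected contact count is near zero almost
never reject.  The type-I-error calibration therefore uses a balanced
κ = 0 configuration (eight subpopulations at 500 cells/mm² each, i.e.
4,000 immune cells/mm² on a 0.6 mm core, ≈450 contacts) where every pair
has a non-degenerate null; pooled over 500 label-shuffle replicates the
rejection rate at α = 0.05 must lie in [0.03, 0.07].  On sparse pairs the
test is conservative by construction, not anti-conservative.

## Nest detection and Eps calibration

T-cell nests are DBSCAN clusters over T-cell coordinates with Eps = 40 μm
and MinPts = 27, the minimum nest size; neighbour counts include the point
itself (the R `dbscan` convention, matched by scikit-learn's
`min_samples`).  Equivalence with a plain brute-force DBSCAN — including
the 26-cell negative / 27-cell positive boundary controls — is asserted on
200 random configurations; border-point ties are resolved identically
(clusters are seeded at the smallest unlabelled core index and expanded
fully, so a border point joins the earliest-created adjacent cluster).

`calibrate_eps` reproduces the Eps-selection procedure: over an ascending
grid, sensitivity (true nest cells labelled in-nest) and specificity (true
non-nest cells labelled noise) are computed against an annotation, and the
grid value minimising |sensitivity − specificity| — the curve crossing — is
returned, smaller Eps on ties.

## Zoning and region splits

The tumor-stroma borderline is an open polyline with a declared tumor side.
Signed distance uses nearest-segment projection; at shared vertices the
side call comes from the segment with the least ambiguous cross product,
and cells exactly on the line count as tumor side.  Cells within 360 μm of
the line (inclusive) are the invasive margin (IM_TUMOR / IM_STROMA by
side); beyond the band, CT on the tumor side and OUTSIDE on the stromal
side.  `random_region_split` partitions a section into k = 48 spatially
contiguous tiles by k-means on coordinates with a fixed seed — contiguity
and near-equal counts on roughly uniform material, deterministic for a
seed.

## Cohort statistics

Group comparisons are Welch (unequal-variance) two-sided t-tests per
feature — the unequal-variance form is the safer reading of "t-test" for
groups of very different size — with Benjamini–Hochberg adjustment across
the feature family (Bonferroni selectable).  log2 fold-changes are finite
only when both group means are positive.  Samples excluded for a feature
(zero denominators) are dropped from that feature only.

Patient clustering is a simplified X-shift: standardize features (z-score;
fractions and interaction values differ in scale), estimate each point's
density as the inverse mean distance to its K nearest neighbours (K = 20
default), link each point to its *nearest* neighbour of strictly higher
density within that neighbourhood (ties broken toward the smaller index,
which makes the ascent acyclic and order-independent), and take the ascent
trees rooted at link-free points (modes) as clusters.  The nearest-denser
link is the published algorithm's rule; linking to the *densest* denser
neighbour instead lets a single high-density point inside a small
subgroup's neighbourhood absorb the whole subgroup, which destroys exactly
the subgroup-discovery use case this package targets.  Omitted from the
original algorithm: Mahalanobis-weighted distances and mode merging by a
density-gap test — so this implementation over-fragments diffuse clusters
relative to full X-shift, and cluster counts should be read per K.  K is
selected at the elbow of the cluster-count-vs-K curve: the K with the
maximum discrete second difference, ties to the smaller K, flat curves to
the smallest K with a warning.  Clustering of patients uses the
subpopulation-fraction features only; checkpoint fractions are reported but
not clustered on, keeping the subgroup definition purely compositional.

MSI-like flagging takes the cluster whose mean fraction profile is nearest
(Euclidean) to an MSI reference profile; ties go to the smaller cluster id,
and a single-cluster result flags everything with a warning.

## Synthetic data: what is planted and what it emulates

Each subpopulation is a homogeneous Poisson field at a stated intensity
(cells/mm²), generated on a 10% linearly enlarged region and clipped, so
intensities are unbiased at borders.  Pairwise attraction is a
parent-offspring (Neyman–Scott) coupling: a fraction κ of parent cells each
spawn one offspring at an isotropic Gaussian displacement (σ = 5 μm in the
presets, putting ~72% of offspring within the 8 μm contact radius).  The
offspring subpopulation's independent intensity is reduced by κ·λ_parent
(clamped at zero) so planted expected densities and fractions are exact
under attraction — this keeps binomial-interval recovery of fractions
valid.  Nests are uniform discs of fixed cell count; positivity vectors are
exactly consistent with the true subpopulation under the default gates, so
gating recovers truth with 100% accuracy and all downstream error comes
from the analysis itself, not the labels.

Preset study conditions (TMA cores, 0.6 mm):

| parameter | MSI | MSS |
| --- | --- | --- |
| total T density (cells/mm²) | 1,628 | 1,028 |
| between-patient density CV | 1687/1628 ≈ 1.04 | 1113/1028 ≈ 1.08 |
| dominant fractions (% of T) | Tc1 22, Th1 18 | Treg 13, Th2 10, Th17 10 |
| attraction (κ, σ) | Tc1→Th1 (0.5, 5 μm), Tc1→DC (0.3, 5 μm) | Treg→Th17 (0.5, 5 μm), Treg→DC (0.3, 5 μm) |
| TIM-3 / PD-1 / CTLA-4 rates | 0.35 / 0.30 / 0.25 | 0.15 / 0.12 / 0.10 |

The MSI_LIKE preset is the MSI composition emitted under an MSS label.
Cohorts add between-patient variability: a lognormal total-density
multiplier matching the stated mean ± SD, and per-sample fractions drawn
from a Dirichlet with concentration 150 around the preset composition —
roughly a ±3-percentage-point SD on a 20% fraction, a realistic
between-tumor spread that still leaves the MSI/MSS compositions clearly
distinct.  Both the full fraction vectors and the DC/NK/tumor/endothelium
intensities are package choices where only directions and totals are
externally fixed.

What the generator does **not** emulate: segmentation errors and marker
spillover (positivity is clean by construction), cell-size exclusion
effects (points are allowed arbitrarily close), anisotropic or gradient
tissue architecture beyond the CT/IM differential, and batch effects.
Passing the validation suite therefore shows the *analysis* is correct and
calibrated on data matching its assumptions — not that the assumptions hold
for any particular stained section.

## Validation problem sizes

The test suite validates: contact-graph equality with brute force (200
instances, up to 2,000 cells); Σ p-normalized = 1 (tolerance 1e-9);
permutation-null type-I error in [0.03, 0.07] (500 replicates × 1,000
permutations); per-sample attraction detection (100 cores per preset,
≥90% for planted pairs, ≤10% for unplanted); DBSCAN equality with a
reference implementation (200 configurations plus MinPts boundary
controls); Eps-calibration recovery within one grid step; binomial-interval
coverage of planted fractions and marker rates (200 cores); volcano
direction/significance recovery (100 cohorts of 30 + 30) and null-cohort
FDR control; MSI-like subgroup recovery at Jaccard ≥ 0.8 in ≥80% of 50
cohorts of 500 MSS patients with 8% planted; and analytic zoning plus
CT-only enrichment detection on 12 large sections.  The MSS arm size of
500 reflects that a K = 20 density ascent cannot stably retain a mode whose
basin holds many fewer than ~2K points under realistic cellularity noise —
at 8% planted prevalence that means an arm of several hundred patients,
consistent with the cohort scale the method is meant for.

## Known limitations

* The permutation null conditions on the observed label counts; it tests
  label exchangeability given the geometry, not goodness of fit of any
  point-process model.
* The simplified X-shift over-fragments diffuse clusters (no mode merging);
  `flag_msi_like` is robust to bulk fragmentation but assumes the subgroup
  itself stays whole.
* Convex-hull areas overestimate density denominators on concave sections.
* Zoning assumes a single open borderline per section; multiple tumor foci
  need one geometry each.
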