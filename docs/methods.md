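# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the passing tests do and do not establish.

## The maximum-entropy niche model

The estimator is presence-background Maxent.  Raw environmental variables
are clamp-scaled into [0, 1] using bounds from the calibration data and
expanded into feature classes (linear, quadratic, pairwise product, paired
forward/reverse hinges at five evenly spaced interior knots, step
thresholds).  With uniform prior Q over the background sample, fitting
minimizes the penalized negative mean presence log-likelihood of the Gibbs
density exp(z·I)/Z — a convex problem solved by L-BFGS-B on the standard
positive/negative coefficient split, which handles the L1 term exactly.
Per-feature penalty scales are the classic √(var_presence(f)/n_presence),
multiplied by the user's regularization multiplier.  Convergence: gradient
tolerance 1e-6, at most 500 iterations; the results object records the
projected-gradient norm and iteration count.

Presences are appended to the background for the normalization constant
(the standard convention; switchable).  Raw projections divide by the
*training* normalizer, so raw scores over the training background sum to 1
exactly; the suitability index is the entropy-calibrated logistic
c·r/(1 + c·r) with c = e^H, H the entropy of the fitted raw distribution —
a cell whose density equals the background-typical e^(−H) maps to HSI 0.5.
A complementary log-log output is not provided; the logistic is the
canonical choice and the only one used downstream.

Verification: a brute-force penalized-likelihood scan on a 5-cell instance
agrees with the optimizer to 1e-3; presences simulated from a known
one-feature Gibbs law (n = 2000) recover the generating coefficient within
10 % (the recovery experiment excludes presences from Q, since there they
are a third of the sample and would visibly tilt the prior).

## Ensembles of small models

One Maxent model per fixed-size variable subset: 4-of-5 for the hindcast
track (five members), 6-of-8 for the forecast track (twenty-eight).  Each
member is tuned by leave-one-fold-out spatial-block cross-validation —
folds follow the occurrence source polygons when at least k exist (k = 12
by default), otherwise coordinates are k-means clustered; held-out
presences are scored against the full background (the background is not
folded) with the tie-corrected Mann-Whitney AUC.  The best grid point by
mean held-out AUC is refit on all data; member weights are Somers' D,
2(AUC − 0.5), floored at 0 and normalized.  The full tuning grid is
{L, LQ, LQH, H} × {0.5, 1, 2, 4}; the workflow drivers default to the
2 × 2 subgrid {LQ, LQH} × {1, 2} (hindcast) and {LQ} × {1, 2} (forecast) to
keep a desk run to minutes — the selection machinery is identical and the
grid is an argument.

## Variable pre-processing

*Hindcast*: the five past-era layers (BIO10, BIO11, BIO18, BIO19, NPP) are
rotated by a correlation-matrix PCA fitted on the present grid; all five
components are kept (a rotation, not a reduction), with each loading
column's largest-magnitude entry made positive for reproducible signs.
*Forecast*: the 19 present bioclimatic layers are pruned by iteratively
removing the largest-VIF layer while any VIF exceeds 3 (worst-first,
name-order tie-break); on the default synthetic grid this retains 8 of 19.
*Transferability*: per-variable MESS similarity uses the standard
percentile form (100 at the reference median, negative exactly outside the
reference min–max, linear beyond it); a variable is dropped when its mean
out-of-range cell proportion across all projection bins exceeds 20 %.  The
MESS reference sample is the variable values at the calibration points
(presences + background); using the whole present raster instead is a
caller choice, since the definition accepts any reference sample.
Aggregation between resolutions is block-mean, ignoring missing cells, with
partial edge blocks averaged over their available cells.

## Range dynamics

The minimum useful threshold (MUT) scans candidates 0.01…1.00 (step 0.01)
and keeps the **largest** threshold at which every time bin retains at
least one in-range cell.  The defining purpose is to avoid a null range in
any bin while staying as restrictive as possible; the opposite reading
(smallest such threshold) is degenerate — it is always 0.01 — so the
restrictive reading is implemented, and `compute_mut` errors, naming the
bin, if even 0.01 empties some bin.  Binarization keeps cells with
HSI ≥ t; within the range, good-to-best (GB) cells have HSI > 0.5 and
good-to-worst (GW) cells HSI ≤ 0.5 (a cell at exactly 0.5 is GW).

Per-bin in-range HSI values are compared with the present's by rank-sum
tests (exact enumeration for tie-free samples of ≤ 20, tie-corrected
normal approximation otherwise): "better" is the one-sided greater test at
α = 0.05, "similar" the non-significant two-sided test; both flags are
reported per bin.  The present reference is the in-range sample of the
coarse present map, which shares its grid with the past series.  Range
variability between bins younger and older than the cycle-switch time is
compared with the Brown-Forsythe test (ANOVA on |x − group median|; the
statistic is +inf when groups differ with zero within-group deviation
spread, and undefined only when the deviations carry no variation at all).
Following the study procedure, the tested series is the per-bin mean HSI
within the range; the function accepts any two series.

Trend fits regress log10 range area on the per-bin territory-wide mean
temperature, and on log10 of the within-range mean altitude.  An OLS fit
is kept when its residuals pass a Ljung-Box test (lag min(10, n/5),
α = 0.05); otherwise the minimum-AIC model wins among (1) ARIMA-error
regressions with the AR order selected by ML on the OLS residuals,
d ∈ {0, 1}, MA 0…6, and (2) a small automatic (p, d, q) grid.  Verified by
slope recovery (±0.03 at n = 2000 under AR(1) φ = 0.7 errors) and by CI
coverage under the null.

## Landscape fragmentation and scenario statistics

HSI maps are classed at 0.25 / 0.5 / 0.75 (class 4 closed above).  Patches
are 4-neighbour components (rook; queen available).  AI uses single-count
like-adjacencies against the maximally compact arrangement (for class area
A with n = ⌊√A⌋, m = A − n²: 2n(n−1), +2m−1 if 0 < m ≤ n, +2m−2 if m > n);
AI is undefined for a single-cell class.  CLUMPY compares the double-count
like-adjacency proportion G with the class abundance P: (G−P)/(1−P) if
G ≥ P else (G−P)/P.  COHESION uses patch perimeters and areas with the
1 − 1/√Z normalization; DIVISION is 1 − Σ(a_j/Z)² against the full
landscape area.  All are checked against hand-computed oracles and a
flood-fill labeller.

The two-way PerMANOVA computes sequential (Type-I) sums of squares for
(emulator, period) from hat-matrix projections of the centred response —
with Euclidean distances this equals the distance-matrix formulation and,
univariately, the classical sequential ANOVA F.  Permutations shuffle rows
within ssp strata (repeated-measures restriction); p = (1 + #{F* ≥ F}) /
(1 + n_perm), default n_perm = 9999.  Standard exclusions before testing:
the overabundant worst-HSI class 1 and any zero-variance metric (division,
typically); metrics are log10-transformed except CLUMPY, which is signed.
Patch-area change over periods is OLS of log10 area_mn on period and class,
per emulator; the class–metric relationship is an ordinal (proportional
odds) logit per emulator with metric × period interactions, falling back to
a penalized multinomial under separation.

## Morphometrics

Log10 measurements, covariance-matrix PCA fitted on extant specimens only;
unknowns are projected passively.  Stepwise LDA is forward-only: the
candidate minimizing Wilks' λ = |W|/|T| enters while its partial
F = ((n − g − q)/(g − 1))(λ_q/λ_{q+1} − 1) exceeds 3.84.  The two-group
function is Fisher's direction scaled to unit pooled within-group score
variance with grand-mean-centred constant; the cut point (R0) is the
centroid midpoint (equal priors), and posteriors come from the
equal-variance Gaussian model on the score axis.  Leave-one-out
reclassification refits the coefficients per held-out specimen with the
selected variable set fixed (the SPSS convention).  Raw millimetre inputs
are the default — the magnitudes of published discriminant coefficients for
this problem imply mm-scale variables — with log10 as an option.  The
package ships the published six-variable wolf-vs-jackal reference function
(constant −14.966) for scoring new specimens directly.

BCA builds a UPGMA reference tree on Euclidean distances between taxon
centroids in PCA score space (first two components by default), then
resamples specimens within taxa with replacement 1000 times, reclustering
each replicate.  Node support is the percentage of replicates reproducing
the node's exact taxon set.  Cluster sharpness per partition level uses a
Rand-type G: the fraction of taxon pairs on which two partitions agree
(0–1, 1 = identical) — chosen as the simplest index meeting the stated
bounds, since the original similarity index is described only narratively;
the null G° compares the reference partition against a randomly relabelled
replicate partition of the same cluster sizes, and a level is sharp when
the estimated P(G° ≤ G*) exceeds α = 0.05.  "Bootstrap resampling of
observations" is the implemented reading of the resampling step.

## Synthetic study conditions

The generator fixes the study conditions; it is not tuned per experiment.

* **Grids.** Fine present grid 160 × 160 abstract-km cells; the coarse
  past/present grid aggregates by 4 (40 × 40).  Geometry is equal-area by
  construction: areas are cell counts × cell area, no projection math.
* **Past series.** 200 bins at a 10-ka step (a desk-scale stand-in for
  2000 × 1 ka; full scale is a config choice).  The temperature forcing is
  a cosine with period 41 ka and amplitude 0.6 °C in bins older than 1 Ma
  and period 100 ka, amplitude 1.8 °C, in younger bins — reproducing the
  mid-Pleistocene transition's longer, deeper cycles and hence the higher
  young-bin range variance the variance test targets.
* **Fields.** Altitude is a smooth Gaussian random field plus a broad
  central dome (peak 4500 m); temperature falls at 6.5 °C/km with smooth
  noise; precipitation rises with altitude; NPP saturates with rainfall
  and peaks at moderate temperature.  Derived BIO layers carry their own
  small noise so they are collinear without being singular.  Smoothing
  bandwidth (6 cells) is a free knob — the real rasters' autocorrelation is
  unknown — and only sets how smooth the maps look.
* **Futures.** 4 emulators with climate sensitivities 2.6 / 3.0 / 4.3 /
  4.8, ssp end-of-century warmings 1.6 / 2.6 / 3.8 / 5.0 °C (sensitivity-3
  reference) and period fractions 0.35 / 0.55 / 0.80 / 1.00 for
  2040–2100; warming adds to temperature layers and mildly dries
  precipitation and NPP, so zero warming reproduces the present exactly
  and severity ordering is monotone by construction.
* **Regions.** Twelve square range polygons on well-separated altitude
  peaks (so the 12 spatial folds map 1:1 to polygons), a prey polygon
  buffering their bounding box, ecoregions as a 5 × 5 tiling.
* **Morphometrics.** Eight species at the comparative sample sizes
  (simensis 20, aureus 19, adusta 21, mesomelas 21, latrans 21, lupus 22,
  pictus 19, alpinus 21) plus one fossil row.  Species means scale a
  common mandible profile; hypercarnivores are larger with relatively
  broader teeth (two PC1 clusters), the wolf has an elongated muzzle and
  slender premolars (separating it from the jackals), and the fossil is a
  slightly reduced wolf profile pulled 20 % toward the golden jackal —
  mirroring a fossil that classifies with the wolf but sits nearer the
  group boundary.  Within-species covariance is diagonal at ~4 % CV.

What the synthetic data do **not** emulate: real topography or climate
fields, observation error in occurrences, spatial sampling bias,
non-climatic range limits (prey dynamics, disease, humans), and realistic
measurement covariance structure (allometry is only coarsely present).
Passing tests therefore establish that the algorithms are implemented
correctly and behave as designed under controlled conditions — not that
the ecological conclusions transfer to any particular real dataset.

## Numerical choices and degenerate inputs

Inverse-distance background weights are 1/(d + ε) with ε = one cell size
(removes the singularity at presence cells); nearest-presence distance is
used.  On grids with fewer than twice the requested background cells the
sample scales down to half the eligible cells, with a warning.  Points sit
at cell centers — one-per-cell makes sub-cell position uninformative.
Constant layers get unit PCA scale with a warning; degenerate Maxent fits
(no feature variation) raise; all-zero ensemble weights fall back to the
unweighted mean with a warning; empty landscape classes yield np = 0 and
NaN metrics; all-tied rank-sum samples return p = 1.  Ties in the VIF
filter and tuning grid resolve to the first candidate in deterministic
order.  Every stochastic routine takes an explicit integer seed.

## Problem sizes

Defaults were chosen so the complete suite runs in a few minutes on one
CPU: the tuning subgrids above; permutation counts 9999 for the headline
PerMANOVA and 49–199 inside calibration simulations; 1000 bootstrap
replicates for BCA; 10⁴ null replicates (100 values per group, matching
the 100-bins-per-age-group comparison) for the variance-test calibration.
All are arguments, not constants.
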