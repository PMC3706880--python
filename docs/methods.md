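# Methods

## Scope and data model

`sock` consumes an existing spatial-ICA decomposition; it never computes
the ICA itself. The inputs are the MELODIC-style outputs: a 4D image of
unthresholded component z-maps, per-component thresholded z-maps
(signed z-values retained; any nonzero voxel is treated as
suprathreshold), the mixing matrix, plain-text power spectra, and the
repetition time TR. Binary edge and CSF masks on the same grid complete
the inputs. Masks are deliberately inputs rather than products of tissue
segmentation: segmentation is a separate problem, and the classifier only
consumes the masks. A morphological fallback (`sock.masks`) derives an
edge band from a brain mask as (dilation − erosion) with a 6-connected
structuring element applied `thickness` times per side — the inner and
outer boundary are treated symmetrically — and a ventricle region from
user-declared boxes/ellipsoids intersected with the brain.

## Smoothness ratio curves

Each unthresholded map is transformed with a 3D FFT; frequency
coordinates are physical (cycles/mm), built from the voxel dimensions, so
anisotropic voxels produce anisotropic spectral grids. For a sweep of
radii the spectrum is split into L(r) (magnitude sum strictly inside the
sphere of radius r) and H(r) (the rest), and the curve value is
L/max(H, ε).

Numerical conventions:

* **Magnitudes, not complex sums.** Summing complex spectral values
  would largely cancel and carries no order; magnitude sums are
  non-negative and make the curve non-decreasing in r (L grows, H
  shrinks), which is what the labeling exploits.
* **Radius grid.** 20 evenly spaced radii (default) from the smallest
  nonzero frequency step to the largest radius whose sphere is inscribed
  in the sampled frequency box. The zero-frequency bin lies strictly
  inside every sphere, so the DC term always belongs to L.
* **Degenerate maps.** A constant map has H = 0; its ratio is capped at
  10¹² so it sorts as maximally smooth instead of overflowing. An
  all-zero map yields a zero curve with a warning. Non-finite voxels are
  rejected outright.

The implementation bins voxels by spectral radius once and accumulates
cumulative magnitude sums, so the whole sweep costs one FFT plus one
pass per component; correctness of the partition (L + H constant in r,
agreement with a direct O(n²) DFT) is enforced by tests.

## Overlap features

Suprathreshold clusters are contiguous nonzero regions of the
thresholded map under 26-connectivity (default; 6 and 18 available).
Two distinct quantities are computed per mask:

* **activity** — the *full* volume of every cluster with at least one
  voxel in the mask, divided by the mask volume. A large cluster that
  merely touches the mask counts in full; activity can exceed 1. This is
  the quantity the adaptive High/Low clustering (edge) and the 10% CSF
  label threshold operate on.
* **overlap fraction** — suprathreshold voxels inside the mask over all
  suprathreshold voxels, in [0, 1]. This voxel-wise quantity feeds the
  50% (edge) and 30% (CSF) unconditional rejection rules.

The two readings are kept separate on purpose: "volume of clusters
overlapping the mask" and "volume of activity overlapping the mask" are
different measures, and conflating them would make the hard rules either
vacuous or far too aggressive.

## Temporal frequency noise

Spectra follow the MELODIC `FTmix` convention: F bins, bin k at
frequency k/(2·F·TR), k = 1..F — no DC bin, last bin exactly at Nyquist
1/(2·TR). TFN is the sum of bins at or above the cutoff (default
0.08 Hz, the ≈1/12 s⁻¹ dominant frequency of the hemodynamic response).
A cutoff at or above Nyquist yields TFN = 0 with a warning; negative
spectral values are rejected.

## Adaptive labeling

Smoothness uses a nested pair of 2-means splits: all curves → (Smooth,
rest); rest → (Subsmooth, Unsmooth); cluster order is by mean curve
height. Curves are log10-transformed and z-scored per radius first —
the raw ratios span many decades and the ε-capped values would otherwise
dominate the Euclidean metric. The split uses scikit-learn KMeans with
10 k-means++ restarts and the run seed, making it deterministic.

Edge activity and TFN use a scalar 2-means, solved *exactly*: in one
dimension the global k-means optimum is a contiguous split of the sorted
values, so the implementation scans all n−1 splits for the minimum
within-cluster sum of squares (ties resolved to the lowest split index).
This is deterministic by construction and provably optimal; tests verify
it against an exhaustive enumeration of all bipartitions. The
larger-centroid cluster is High. The CSF label uses no clustering at
all: a fixed 10% activity threshold.

Degenerate inputs never reject: fewer than 6 components (or identical
curves) ⇒ all Smooth; an unsplittable second-stage cluster ⇒ its members
Subsmooth; fewer than 4 scalars or zero variance ⇒ all Low. Each case
warns prominently. The rationale is the method's design goal of never
discarding plausibly neuronal components merely because a feature was
uninformative on a given decomposition.

## Decision rules

Artifact iff any of: R1 Unsmooth; R2 Subsmooth ∧ High TFN; R3 Smooth ∧
High edge ∧ High CSF; R4 edge overlap fraction ≥ 0.50; R5 CSF overlap
fraction ≥ 0.30. All boundary comparisons are inclusive ("X% or
greater"). Unlisted feature combinations are don't-cares. The TFN and
edge labelings are computed over *all* components before any rule is
evaluated, not over label subsets. Hard thresholds and the 10% CSF label
threshold are configurable; lowering a hard threshold can only move
verdicts toward Artifact (monotonicity is tested). A disabled feature
removes every rule that depends on it.

## Synthetic phantoms

The generator builds a 32 × 32 × 16 grid of 3 mm voxels (TR = 2 s, 200
timepoints), an ellipsoidal brain, a thickness-1 morphological edge band
and a small central "ventricle" ellipsoid, and five component classes —
three components each by default:

* **neuronal**: wide anisotropic Gaussian blob (σ = 2.0 voxels in-plane,
  flattened along z like the brain) on a mid-depth ring, clear of both
  masks; low-frequency time course (0.01–0.06 Hz).
* **spotty**: unsmoothed white noise — salt-and-pepper suprathreshold
  pattern.
* **edge**: the edge band lightly smoothed (σ = 0.8) as the activation
  template, so most suprathreshold voxels fall inside the band.
* **csf**: a narrow blob (σ = 1.2) centered in the ventricle region.
* **hf_smooth**: a blob at intermediate smoothness (σ = 0.6) with a
  0.10–0.25 Hz time course, so essentially all its spectral power lies
  above the 0.08 Hz cutoff.

Blob amplitudes are set so the structured signal dominates the smoothed
background field (scale 0.3); after per-map standardization, thresholding
at |z| ≥ 2.3 — a stand-in for MELODIC's mixture-model P < 0.05
thresholding — then isolates the intended support with few stray voxels.
The σ ladder orders the classes on the smoothness axis with gaps wide
enough for the nested 2-means to resolve. Time courses are band-limited
Gaussian processes; spectra are their raw periodograms on the `FTmix`
bin layout. Ground truth is verdict-level: neuronal ⇒ UnlikelyArtifact,
everything else ⇒ Artifact.

What the phantoms do **not** emulate: hemodynamic convolution,
physiological cycle structure, spatial autocorrelation of real BOLD
noise, registration/segmentation error in the masks, and the ICA
unmixing itself (maps are constructed, not estimated). Passing the
phantom-recovery check therefore demonstrates that the feature
extraction, adaptive labeling and rule table interlock correctly on
components with known signatures — not that the classifier's error rate
on real scans is zero.

## Problem sizes and runtime

The test suite and the acceptance script run on 32 × 32 × 16 phantoms
(15 components; 20 phantoms for the recovery estimate), 16³/8³ volumes
for the spectral property and oracle checks, 6³ volumes for the
connected-component oracle, and ≤ 12-point sets for the exact-clustering
oracle — sizes at which exhaustive reference computations (direct DFT,
flood fill, all bipartitions) are feasible, so every nontrivial kernel is
validated against an independent implementation. The full suite runs in
seconds on one CPU.

## Known limitations

* The smoothness labeling depends on the decomposition-wide curve
  distribution; with very few components (< ~10) the nested split is
  fragile, and below 6 it is skipped entirely (all Smooth).
* Edge/TFN High/Low labels are relative to the current decomposition: if
  *no* component has high edge activity, the 2-means will still label
  the upper group High; only the rule conjunctions (R3 needs High CSF as
  well) and the hard rules guard against over-rejection in that regime.
* The 10/30/50% thresholds are fixed constants inherited from the
  method's design; they are configurable but not adaptively estimated.
* Thresholded maps are consumed as given; the |z| ≥ 2.3 convention in
  the phantom writer is not applied to real MELODIC inputs, which carry
  their own mixture-model thresholding.
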