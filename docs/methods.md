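# Methods

This note documents the models, numerical choices and known limitations of
`corticarta`. Empirical figures quoted here are the ones the test suite and
`scripts/acceptance.py` themselves compute.

## Synthetic cortical sheets

Each hemisphere is a subdivided icosahedron (12 / 42 / 162 / 642 / 2,562 /
10,242 vertices; the smallest count meeting the request is used). The outer
surface folds radially by a sum of four random plane waves on the sphere
(wavenumbers 2–5), scaled to a peak amplitude of `folding_amplitude`
(default 2 mm around a 60 mm radius). The inner surface is displaced inward
along the radial direction by a smooth thickness field mapped into
`thickness_range` (default 1.5–3.5 mm, the physiological span of cortical
thickness). The right hemisphere is the mirror image of the left, and
per-vertex spherical coordinates are retained from the unfolded sphere —
exact inputs for spin permutation.

All generators are pure functions of their arguments including the seed.
Smooth fields are evaluated on left-equivalent coordinates for both
hemispheres, so homotopic vertices share values. This matters statistically:
with maps that are *not* homotopically symmetric, the mirrored-rotation spin
convention produces an anti-conservative null (we measured a false-positive
rate of ~0.17 at nominal 0.05), because the observed statistic couples the
hemispheres more strongly than any rotation can. With homotopic symmetry the
test is calibrated (see below).

## Atlases

Parcels: farthest-point sampling of `n_parcels/2` seeds per hemisphere on
mesh-graph geodesics, nearest-seed assignment, followed by a deterministic
repair pass that re-assigns stray components so every parcel is connected.

Cortical types: the six-level taxonomy of laminar differentiation
(koniocortical → eulaminate-III/II/I → dysgranular → agranular) is assigned
by binning a geodesic gradient from a "sensory pole" (the topmost vertex of
each hemisphere's sphere) plus smooth noise. The noise amplitude
(`type_noise_sd`, default 0.05) is exposed as a parameter because the
magnitude of type-assignment noise in real atlases is not known.

Networks: the default mode network is grown from four anchor parcels per
hemisphere placed at spread-out positions along the type gradient
(preferring mutually non-adjacent parcels), growing round-robin without
touching other subregions; this yields a distributed DMN with at least four
disjoint subregions per hemisphere that overlaps at least five of the six
types under default settings. Remaining parcels are clustered into six
other networks by k-means on mirror-symmetrised parcel centroids.

## Staining-intensity profiles

A profile at depth fraction d ∈ [0, 1] (0 = pial) is

    I(d) = 1 + a(p) · exp( -(d - μ(p))² / 2σ(p)² ) + ε,

with peakedness p ∈ [0, 1], centre μ(p) = 0.55 + 0.2 p (inside the mid–deep
band), width σ(p) = 0.12 − 0.04 p, amplitude a(p) = min(1, p/0.2), and
Gaussian noise ε (default sd 0.1). Peakedness 0 is exactly flat; as p grows
the density bump sharpens and moves deeper. The amplitude saturates because
in contrast-normalised staining data the *shape* of the profile, not its
dynamic range, carries laminar differentiation; a strictly proportional
amplitude makes the partial-correlation affinity collapse into a two-block
indicator that no longer tracks p linearly.

The default peakedness field (`peakedness_field`) is a smooth random field,
rank-uniformised and passed through a logistic of gain 6. The resulting
bimodal distribution emulates the cortex's division into well-laminated
(granular) and weakly laminated (agranular) territories separated by narrow
dysgranular transition strips. Both choices are deliberate: spectral
embeddings of a partial-correlation affinity with negatives zeroed are
near-binary between antagonistic profile families, so a unimodal peakedness
field cannot be recovered with high product–moment correlation by *any*
embedding of this affinity. Under the defaults, E1 recovers the planted
field with |r| ≈ 0.90–0.93 (|Spearman| ≈ 0.99).

What the generator does **not** emulate: gyral/sulcal anatomical geometry,
laminar boundaries or discrete layers within profiles, vasculature and
staining artefacts, or multi-subject variability. Passing tests therefore
demonstrate the correctness and statistical calibration of the machinery,
not the empirical claims made on histological data.

## Equivolumetric profiling

Per-vertex areas are one-third sums of incident triangle areas (the
standard discrete vertex-area estimator; the choice is not prescribed by
the equivolumetric model itself). The distance fraction is

    ρ(α) = (−A_in + √(α A_out² + (1−α) A_in²)) / (A_out − A_in),

evaluated in a numerically safe form that returns the equidistant limit α
when |A_out − A_in| vanishes to machine precision.

Depth-wise smoothing is an iterated three-point average (¼, ½, ¼) with both
endpoints held fixed, applied three times by default — endpoint fixing is
the standard anti-shrinkage device. Surface-wise smoothing is a geodesic
Gaussian with σ = FWHM/2.355 in units of the mean edge length, truncated at
3σ, and made doubly stochastic by symmetric (Sinkhorn) normalisation so
that constant fields pass through unchanged *and* total intensity mass is
conserved (both to 1e-6 or better); a one-sided row normalisation can
satisfy only one of the two.

## Cytoarchitectural axis

Decimation retains ⌈|mask|/factor⌉ vertices by farthest-point sampling;
assignment is lexicographic: fewest mesh-graph hops, then smallest
Euclidean distance, then lowest vertex id (for determinism).

The affinity is the partial product–moment correlation between
patch-averaged profiles controlling for the mask-mean profile; negative
values are zeroed and the diagonal is set to 1 (the treatment of the
diagonal is a convention; it only shifts the trivial eigenvalue).

Diffusion map embedding: density normalisation W' = D^{-α} W D^{-α}
(α = 0.5 by default), row normalisation to a Markov matrix, symmetric
eigendecomposition, trivial constant eigenvector dropped, components scaled
by λ/(1−λ) (the diffusion-time-aggregated convention of the common open
implementations). Variance fractions are reported as each eigenvalue's
share of the retained non-trivial spectrum — with this convention E1
explains ~67% on the synthetic affinity, which is structured more strongly
than histological data. E1's sign is anchored so that it correlates
positively with patch profile flatness (negative excess kurtosis over
depth): high E1 = flat profiles.

At the 214-patch desk scale the axis is robust: |r| between E1 at α = 0.5
and at α ∈ {0, 1} exceeds 0.999 across seeds, and diffusion maps, PCA and
Laplacian eigenmaps agree with min |r| ≈ 0.99 (PCA is always the binding
pair; the agreement dips to ~0.9897 for some seeds under profile noise).

## Landscape metrics

Flattening is classical MDS of mesh-graph geodesic distances (Isomap with
the mesh as the neighbourhood graph), two components, mean-centred. Graph
shortest paths on a lattice overestimate straight-line distances by a few
percent irrespective of resolution, so a planar patch is reproduced up to
that metric distortion, not to machine precision.

Smoothness is the adjusted R² of a least-squares fit on all monomials
x^a y^b with a + b ≤ order (2–4). Waviness mean-centres the field and
counts the fraction of edges whose endpoint values have strictly opposite
signs; zero-valued endpoints do not cross, and division by the edge count
makes the score resolution-comparable in [0, 1]. Synthetic landscape edges
are 4-neighbour grid edges. The subregion comparison is a one-way ANOVA
with one observation per hemisphere — two replicates per group, as in the
analysis it reproduces, despite the minimal power; a zero within-group
variance with non-zero between-group variance is reported as F = ∞, p = 0
and flagged degenerate.

Validation sweep: waviness increases strictly with sinusoid frequency, and
adjusted R² rises monotonically with the flatness of a noisy ramp (rank
correlations > 0.9 across both sweeps).

## Navigation

Weights map to lengths by L = −log10(W/(max W + min W>0)): the denominator
exceeds every weight, so all lengths are strictly positive and strictly
decreasing in W. Routing hops from the current node to its structurally
connected neighbour with minimal Euclidean distance to the target (ties:
lowest node id — the source method is silent, and determinism requires a
rule); failure is a revisit or a dead end, and failures score E_nav = 0
rather than missing, because failing to navigate is informative
inefficiency. Path length defaults to summed Euclidean hop distances; a
variant summing the transformed lengths L is available
(`metric="weighted"`) because the transform is defined upstream while the
efficiency itself is stated on distances. Routing is computed within each
hemisphere; cross-hemisphere entries are masked NaN.

## Effective connectivity

The generative model for simulation is dx/dt = A·x + w (white process
noise, no external driver — resting state), integrated by fixed-step Euler
at dt = TR/16, convolved with the canonical double-gamma HRF (response peak
6 s, undershoot 16 s, ratio 1/6, unit sum), sampled at TR, plus Gaussian
observation noise.

Estimation is a per-region Bayesian linear regression in the frequency
domain with Gaussian priors (off-diagonal mean 0, variance 1;
self-connection mean −0.5 Hz) and noise precision iterated to the
evidence-maximising fixed point. Three numerical choices matter:

1. **Hemodynamic deconvolution.** Regressing the derivative of the observed
   signal on the observed signal is biased when the dynamics are driven by
   process noise: the HRF-filtered innovation correlates with the
   regressors, and recovery plateaus near r ≈ 0.72 regardless of noise or
   duration. The known canonical HRF is therefore removed first by Wiener
   deconvolution (regularisation 1e-3 of the peak HRF power).
2. **Discrete-time correction.** First differences estimate
   (e^{A·TR} − I)/TR, not A; the estimate is mapped back through a matrix
   logarithm.
3. **Parametric-bootstrap bias correction** (optional, `n_bias_reps`): data
   are re-simulated from the stabilised estimate, re-fit, and the measured
   bias subtracted.

On 5-region, 10-minute simulations (TR 0.5 s, couplings 0.2–0.5 Hz) the
pooled off-diagonal correlation with the truth is ≈ 0.85 (per-seed range
0.70–0.93); the null model recovers mean |off-diagonals| < 0.05 Hz. The
full-featured variants of the method (sparsity priors, full hemodynamic
state equations) are out of scope. Signals are linearly detrended before fitting; input and
output strengths aggregate *absolute* couplings (signed aggregation is a
caller-side choice, as the source method does not state it).

## Spin inference and balance

Rotations are sampled uniformly from SO(3); the left hemisphere gets R and
the right its mirror conjugate M·R·M, the standard convention that keeps
homotopic points homotopic. Values are reassigned by nearest rotated point
within hemisphere. The p-value follows the one-sided counting formula and
admits p = 0 (report as < 1/n_perm); the two-sided value is the doubled
smaller tail capped at 1. Calibration: over 500 independent pairs of smooth
random maps at 500 rotations each, the one-tailed false-positive rate at
nominal 0.05 is ≈ 0.04.

KL balance normalises the type-mean connectivity vector to a distribution
and computes KL against the uniform distribution over the types present
(0·ln 0 = 0); it is invariant to positive rescaling. Bonferroni thresholds
for seven comparisons (0.004 two-sided, 0.007 one-sided) are exposed as
named constants; raw p-values are always reported.

## Problem sizes

Default study-scale conditions used by the tests and the reproduction
script: sheets of 2,562 vertices per hemisphere for the embedding analyses
(214 patches after 12-fold decimation), 642 for pipeline replicates, 162
for spin calibration; 500–10,000 rotations; 10-minute scans at TR 0.5 s for
coupling recovery. These sizes preserve the statistical structure of the
analyses while keeping a full run on a single CPU in minutes.

## Known limitations

- The synthetic profile family is low-dimensional; real staining profiles
  carry laminar structure the generator does not attempt.
- Graph-geodesic Isomap inherits lattice metric distortion (~2–3%).
- The rDCM core omits sparsity priors and hemodynamic state estimation;
  per-pattern recovery varies (hard sparse patterns recover at r ≈ 0.7).
- ANOVA with two replicates per group has minimal power and is reported
  as-is for fidelity; `compare_subregions(..., n_permutations=...)` adds a
  label-permutation p-value as an alternative.
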