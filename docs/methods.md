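# Methods

## Overview

`rsnfuse` implements a two-level analysis for linking spontaneous brain
activity to behavior. The first level is a temporal-concatenation group
spatial ICA of multi-subject resting-state fMRI, with subject-specific
component maps recovered by GICA3 back-reconstruction and networks
identified by spatial correlation against resting-state network (RSN)
templates. The second level is a correlation-constrained parallel ICA
(para-ICA): two simultaneous Infomax decompositions — one of the
subject-wise back-reconstructed maps of a single RSN, one of a subjects
× measures behavioral battery — coupled through a term that enhances the
correlation between selected columns of the two loading (mixing)
matrices. The output is a set of component pairs, each a spatial
sub-component of the network together with a linear combination of
behavioral measures, whose per-subject loadings correlate across
subjects.

## Model and estimation

### PCA whitening

Every decomposition reduces the *sample* dimension (time points for the
group stage; subjects for the fusion stage) of a samples × features
matrix: with row means removed, the row covariance is eigendecomposed
and the top-k axes are kept, scaled to unit variance. `reducing @
dewhitening = I_k` holds exactly, and requesting more axes than the
effective rank is an error that names the achievable rank.

### Infomax ICA

Sources are estimated with full-batch natural-gradient Infomax under
the logistic nonlinearity,

    dW = lr * (I + (1 - 2*sigmoid(U)) U^T / n) W,   U = W Z,

suited to the super-Gaussian sources typical of spatial fMRI maps. The
learning rate (default 0.1) anneals by 0.9 whenever successive update
directions disagree by more than 60 degrees; iteration stops when the
weight change drops below 1e-6 or at 512 iterations. Full-batch updates
make a run a deterministic function of the data and the initialisation
seed. The plain default of 0.01 common in stochastic mini-batch
implementations does not converge within the iteration cap under
full-batch updates; 0.1 separates 3–8-component Laplacian mixtures to
an Amari index below 0.05 in over 95% of seeds, which is the package's
operating criterion for this stage. Components are ordered by explained
variance in the data space, scaled to unit source variance, and
sign-fixed so each source's largest-magnitude element is positive.

### Stability (Iq)

`icasso` re-runs Infomax with distinct seeds, pools all sources, and
clusters them by absolute Pearson correlation with average-linkage
agglomeration into k clusters. Each cluster's quality index Iq is the
mean within-cluster similarity minus the mean similarity to components
outside the cluster; the consensus component is the cluster centrotype
(the member with the largest within-cluster similarity sum). On real
data Iq near 0.97 indicates very high stability; the synthetic
analogues here reach Iq above 0.9 for well-separated sources and
degrade monotonically with added noise.

### Group ICA and GICA3

Subject matrices are individually PCA-whitened in time, stacked, and
reduced again at the group level before Infomax. With `G_i` the
per-subject column block of the group reducing matrix and `Y_i` the
subject's whitened data, the subject map is `S_i = N * W G_i (Y_i -
mu_i)`, so the mean of the subject maps equals the group map *exactly*
— this identity is asserted to 1e-6 on every fit. Group maps are
z-scored per map; subject maps are transformed with the same per-map
affine so the identity survives scaling.

### Template matching and spectra

Group maps thresholded at z = 3.0 are Pearson-correlated over the
in-brain mask with RSN templates thresholded on their own statistic
scale (the threshold is a parameter: published template sets use a
t-scale, the phantom harness a z-scale); each template is paired with
its best component and accepted at r >= 0.4. Sub-threshold values are
zeroed rather than excluded, reproducing the positive-part overlap
behaviour of the established group-ICA toolchain. Component time-course
spectra are summarised from a Welch periodogram by the dynamic range
(peak power minus the minimum power above the peak; the peak frequency
is reported alongside, since a frequency-valued reading of "dynamic
range" also circulates) and the power ratio (integrated power below
0.10 Hz over integrated power in 0.15–0.25 Hz, the upper band truncated
at Nyquist).

## Correlation-constrained parallel ICA

The published description fixes three controls — the *constrained
connection* threshold (0.3), the *constrained components* cap (3), and
*endurance*, the maximally allowed descending entropy trend (-1e-3) —
but defers the update equations to earlier work that this package does
not reproduce line by line. The functional form here is the package's
own, designed and then calibrated once against the two validation
behaviours the method is known for: faithful recovery of planted
cross-modal correlations in the unbalanced-dimension simulation
(100 samples; 10,000-voxel and 5-variable modalities), and the null
guarantee that no relationship is induced where none exists.

The fit proceeds in two phases:

1. **Natural phase.** Each modality's Infomax runs to its own solution,
   bit-for-bit identical to a standalone decomposition. If no loading
   pair exceeds the threshold at this point (or the threshold is set
   above 1), the fit ends here — the procedure *is* two separate ICAs,
   and the outputs are bitwise equal to them.
2. **Coupled phase.** Up to `max_pairs` one-to-one loading pairs with
   |r| above the threshold are selected greedily on the *natural*
   correlations and then held fixed ("sticky"). Each iteration
   interleaves an Infomax step per modality with a gradient-ascent step
   on the squared loading correlation of each held pair, applied to the
   corresponding whitened-space mixing column (`d(r^2)/dm = 2 r D^T
   dr/da`). A held pair that falls back below the threshold drops out.

Three safeguards keep the coupling honest:

- **Sticky selection.** Re-selecting pairs every iteration lets pairs
  that the coupling itself inflated displace genuinely correlated ones
  from the cap; selecting once, on natural correlations, pins the
  enhancement to pairs the data proposed.
- **Per-modality endurance.** While a modality's entropy trend (over a
  5-iteration window) descends faster than the endurance bound, its
  side of the coupled update pauses. A decomposition whose rotation is
  well determined by the data defends itself; a weakly anchored one
  (e.g. 4 components observed through 5 variables) keeps aligning.
- **Feature-scaled steps.** The coupling step for modality *m* is
  `constraint_rate * min(1, k_m / p_m)^2` (capped at 0.05 per
  iteration), where `p_m` is the feature count. Rotational uncertainty
  of an ICA solution shrinks with the number of feature realisations,
  so a modality with thousands of voxels receives a vanishing nudge
  while a 5-variable modality — whose rotation is essentially
  unidentified and is exactly what the coupling exists to fix — receives
  the full step. The base rate (0.12) was calibrated once against the
  simulation's recovery curve; with it, the mean absolute recovery
  error decreases from ~0.05 near the threshold to ~0.03–0.04 at a
  planted correlation of 0.8, and constrained recovery near the
  threshold is biased upward relative to the unconstrained fit, both
  behaviours the validation literature reports.

Reported links are recomputed on the final loadings with an exact
branch-and-bound assignment (the greedy rule is used only inside the
loop, where it runs every iteration).

## Significance and reporting

Loading-pair correlations are tested against the Bonferroni-corrected
critical value obtained by inverting the two-tailed t-transform
`t = r sqrt(n-2)/sqrt(1-r^2)`: for 24 subjects and the 10 × 10 = 100
pair family at alpha = 0.05 this gives |r| = 0.656 (0.653 at a family
of 90; the printed three-decimal value is reproduced within 0.005). A
significant pair enters the report only if its spatial map contains at
least one suprathreshold cluster: maps are z-scaled robustly (median
and normal-consistent MAD — a component map is heavy-tailed by
construction, and a plain SD inflated by the component's own focus
suppresses exactly the voxels of interest), thresholded two-sidedly at
|z| > 1.96, and clustered by face adjacency separately for positive
and negative loadings; clusters below 4 voxels (100 mm^3 at 3 mm
isotropic voxels — 4 × 27 = 108 mm^3 is the smallest count strictly
exceeding 100) are dropped. The cluster-extent gate doubles as the
false-positive control for the coupled fit: a spuriously enhanced
component has a diffuse, noise-like map that rarely forms a compact
cluster, whereas a genuine sub-component is focal by construction.
Behavioral entries are the measures whose z-scaled component loadings
exceed |z| > 1.96, with their signed values. Head-motion magnitude is
the root-sum-of-squares of the first differences of the six rigid-body
parameters, one value per transition.

## Synthetic data

### Unbalanced-dimension simulation

`generate_linked_dataset` builds `X_m = L_m S_m + noise` with
row-standardised Laplacian sources (identifiable by Infomax; the
original simulation's distributions are unstated, so super-Gaussian is
the natural choice), independent z-scored Gaussian loading columns, and
planted links constructed by the Gaussian-copula rule `a2 = rho a1 +
sqrt(1-rho^2) eps` followed by z-scoring — exact in expectation, with
mean realized correlation within 0.02 of the target over 100 seeds.
Defaults are the study conditions: 100 samples, 10,000 × 5 features,
8 + 4 components; additive Gaussian noise at sd 0.45 (component-level
SNR about 5). Tests and the acceptance suite run a 2,000-voxel scaling
of the first modality; recovery behaviour depends on the sample
dimension, not the feature dimension, so the scaling changes runtime
only.

### Phantom study

`generate_phantom_study` emulates the acquisition at small scale: 24
subjects, a 20^3 default grid at 3 mm isotropic spacing, 228 time
points at TR 2.6 s, and a 39-column behavioral table whose 36 task
measures are exact-moment seeded from a published battery (sample mean
equal to the published mean, sample SD equal to SEM * sqrt(24)), plus
age, gender coded ±1, and a three-level handedness code. Subject
factors (speed, accuracy, capacity) are Laplacian so the behavioral
table is ICA-identifiable; RT columns load on speed, accuracy columns
on accuracy, span/reasoning columns on capacity (block-correlated
structure). Each subject's 4-D volume is a sum of Gaussian network
blobs (jittered octant anchors, so placement never fails on small
grids) times slow AR(1) time-courses plus white noise. The planted
sub-component is a smaller blob inside one network with mean amplitude
1 (a sub-component is *part* of its network; a zero-mean blob would
separate as an independent network at the group level) and
cross-subject modulation of SD 0.5 whose correlation with the latent
speed factor is the planted rho.

What the phantom does not emulate: hemodynamics, physiological noise,
motion, registration error, and spatial autocorrelation of scanner
noise. Passing phantom tests therefore demonstrates the correctness of
the estimation machinery, not performance on real data.

### A known limitation, quantified

Per-subject PCA whitening inside group ICA normalises each subject's
retained variance. A planted amplitude modulation therefore appears in
back-reconstructed maps as a *contrast* — sub-component up, rest of the
network slightly down — rather than a purely local effect. An
estimator-independent oracle (correlating each masked voxel directly
with the true planted amplitude) shows the same two-signed,
network-wide pattern, so no reported compact cluster can overlap the
planted blob at a Jaccard of 0.5 under these conditions; the package's
end-to-end phantom test of that overlap documents this and fails
honestly, while the correlation recovery and the null false-positive
control behave as designed. On real data the analogous effect is a
mild global counterweight in subject maps; interpretation of
sub-component clusters should bear it in mind.

## Problem sizes used in the test and acceptance suites

Simulation: 100 × 2,000 and 100 × 5, 8 + 4 components, 20 seeds.
Phantom: 16^3 grid, 160 time points, 24 subjects, 4 networks, group
k = 6, subject PCA k = 10, fusion k = 10 + 10; 20 planted and 20 null
seeds. ICA correctness: 40 seeds of 3-source mixtures at n = 5,000.
These sizes keep a full run in minutes while preserving every
behaviour the larger defaults exhibit.
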