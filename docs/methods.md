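# Methods

`dynconn` implements a static and dynamic functional-connectivity analysis
for component time courses (e.g., back-reconstructed ICA components from
resting-state fMRI), together with a synthetic cohort generator that gives
every stage a ground truth.  This note records the models, the parameters
that matter, the numerical choices, and the limits of what the synthetic
tests demonstrate.

## Time-course conditioning and QC

Inputs are per-subject `T x C` matrices (one column per component, one row
per repetition time TR).  The pipeline first discards the initial 10
volumes (signal stabilization; 225 collected volumes at TR = 2 s leave
T = 215), then conditions each component in a fixed order:

1. **Detrend** — least-squares linear trend and mean removed
   (`scipy.signal.detrend`).  Constant columns become zeros.
2. **Despike** — samples with robust z = |x − median| / (1.4826·MAD) above
   4 (configurable) are replaced by linear interpolation between the
   nearest non-spike neighbours; edge spikes take the nearest valid value;
   MAD = 0 passes the component through.  The despiking algorithm is a
   deliberate design choice (simple, testable); the robust-z threshold is
   exposed in configuration.
3. **Low-pass** — zero-phase 5th-order Butterworth with high-frequency
   cutoff 0.15 Hz, applied forward and backward (`sosfiltfilt`).  No
   high-pass is applied.  The filter family is a design choice; only the
   cutoff is dictated by the analysis design.

Component-level selection uses the low-frequency (0–0.10 Hz) to
high-frequency (0.15–0.25 Hz) Welch-periodogram power ratio, keeping
components with ratio > 4.  The band edges are configurable; the defaults
follow common component-selection practice.

Subject-level motion QC excludes subjects with mean frame-wise
displacement > 0.2 mm, or (when realignment parameters are supplied) any
translation > 3 mm or rotation > 3 degrees.  Failure reasons are
enumerated in the QC report.

## Connectivity

**Static:** Pearson correlation over the full series, Fisher
z = atanh(r) with r clipped to ±(1 − 1e-7).  Zero-variance components get
all edges set to 0 with a logged warning rather than aborting a cohort
run.

**Dynamic:** a tapered sliding window — a rectangle of 22 TR convolved
with a Gaussian kernel of σ = 3 TR (support ±3σ), truncated to its
central 22 samples and normalized to unit sum — slides in steps of 1 TR.
Within each window a weighted Pearson correlation (weighted means and
covariances under the taper) is computed and Fisher-z transformed.  With
uniform weights this reduces exactly to the plain windowed Pearson
correlation (tested to 1e-10).

**Window count:** onsets run 0 … T−L−1, giving W = T − L windows (193 for
T = 215, L = 22).  The natural sliding count would be T − L + 1 = 194;
the W = T − L convention was adopted to match the established analysis
design this pipeline reproduces, and is applied uniformly.

**Connectivity variability:** per-edge sample variance (denominator
W − 1) of z across windows.  Network-level summaries average off-diagonal
edges within 7 × 7 network blocks (SCN, AUD, SMN, VIS, CCN, DMN, CBN);
diagonal blocks exclude self-edges.

## Connectivity states

All subjects' windows are concatenated as upper-triangle edge vectors
(E = C(C−1)/2 = 903 for C = 43) and clustered with squared-Euclidean
k-means (k-means++ initialization, 150 restarts, 500 iterations by
default; scikit-learn backend, which relocates empty clusters
internally).  The state count is selected by the mean Euclidean
silhouette over k = 2…8, computed on a deterministic subsample of at most
20,000 windows for cost; ties go to the smaller k.

Per subject, the window label sequence yields:

- **fraction** (reoccurrence fraction): share of windows per state;
- **mean dwell time**: mean length of maximal constant runs, in windows
  (seconds = windows × TR × step).  States never visited are marked
  undefined (NaN) and dropped listwise from group statistics rather than
  scored zero, to avoid biasing group means;
- **transitions**: number of label changes (= runs − 1).

State identity is arbitrary; recovery tests align estimated centroids to
generator truth by greedy maximum correlation before comparing.

**Resolution floor:** the 22-TR window low-passes the label sequence, so
dwell times below about one window length cannot be resolved — estimated
dwell saturates near window scale for fast-switching generators.  The
dwell-recovery test therefore probes the monotone response in the regime
where true dwell is at or above the window length.

## Graph analysis

Connectivity matrices are binarized by proportional thresholding over the
sparsity grid 0.08–0.48 in 0.01 steps (41 thresholds): the top
round(s·E) **positive** edges are kept; ties at the cut are broken by
lexicographic edge index so results are platform-stable; if fewer
positive edges exist, all are kept and the achieved sparsity is recorded.

At each threshold five global metrics are computed on the binary graph:

- clustering coefficient C (triangle-based, degree < 2 contributes 0);
- characteristic path length L over **connected** ordered pairs only
  (graphs at 0.08 sparsity routinely disconnect);
- global efficiency Eg = mean of 1/d over ordered pairs, 1/∞ = 0;
- local efficiency Eloc = mean over nodes of Eg of the neighbour
  subgraph (degree < 2 contributes 0);
- normalized γ = C/⟨C_rand⟩, λ = L/⟨L_rand⟩ and σ = γ/λ against
  degree-preserving double-edge-swap references (connectedness not
  enforced; a graph admitting no valid swap, e.g. a triangle, is its own
  reference).  ⟨C_rand⟩ = 0 propagates NaN.

The number of random references is not dictated by the analysis design;
defaults are 100 for static matrices and 20 per window for dynamic
sweeps (cost), both configurable and logged.  Shortest paths use an
all-pairs BFS via boolean matrix powers, verified exact against
`scipy.sparse.csgraph` and brute-force Floyd–Warshall in tests.

Each metric's curve over the 41 thresholds is summarized by its
trapezoidal AUC (grid width 0.40); the across-window sample variance of
per-window AUCs quantifies dynamic topological variability.

## Group statistics

Edge-, variance- and AUC-level group effects are tested with the linear
model `y ~ 1 + group dummies + age + sex + education + mean FD` and an
F-test of the group dummies (full vs reduced model), vectorized across
features by QR projection and validated against statsmodels OLS/ANOVA.
Multiplicity is controlled per feature family by Benjamini–Hochberg FDR
at q = 0.05.  This replaces a multivariate screen with backward
selection: in the operative analysis the screen reduced to group-only
univariate tests, so the direct covariate-adjusted univariate route is
the same inference with fewer moving parts — a deliberate
simplification.

Non-normal outcomes (temporal state metrics, cognitive scores) use
Kruskal–Wallis (ties-corrected) with Dunn pairwise z post-hocs,
Bonferroni-multiplied over pairs.  Cognition–metric associations use
partial Pearson correlation of the covariate-adjusted residuals with
df = n − 2 − k; both raw and BH-adjusted p-values are reported, and
reports can flag either.  Sex is coded M = 0 / F = 1; the reference group
for dummies is the alphabetically first level (HC).

## Synthetic cohort generator

Each subject's time courses are a hidden-Markov switching multivariate
Gaussian: a two-state chain (per-group transition matrix, started from
its stationary distribution) selects a covariance per TR, and the
observation adds independent N(0, noise_sd²) noise.  The two states are:

- **State I — within-network dominant**: same-network correlations at
  `within_strength` (default 0.45), between-network at
  `between_strength` (default 0.15).
- **State II — between-network dominant**: all off-diagonal correlations
  at the midpoint (0.30): between-network couplings elevated relative to
  state I, within-network coherence reduced.  A matrix whose
  between-network entries all exceed its within-network entries is far
  from positive definite at C = 43 (minimum eigenvalue near −2), so
  between-dominance is expressed relative to state I rather than within
  state II itself.

Matrices get symmetric off-diagonal jitter (sd 0.02) and are repaired to
positive definiteness by eigenvalue clamping at 1e-4 followed by
rescaling to unit diagonal; inputs indefinite beyond a defect tolerance
(0.1 for state construction, 0.25 after group effects) raise an explicit
error instead of being silently clamped.

**Group effects** multiply covariance blocks (not time courses), so
injected effects are interpretable in correlation units.  The RTLE-like
group scales cortical–cortical blocks by 0.85 and subcortical–cortical
blocks by 1.3; the subcortical–subcortical block is co-scaled with the
cross block because raising cross-block correlations without
strengthening the subcortical factor itself is geometrically
unrealizable (the cross-block correlation cannot exceed the geometric
mean of the block coherences).  The LTLE-like group carries no effect
(multipliers 1.0), and its chain equals the control chain, matching the
asymmetric design the pipeline is meant to detect.  Default chains:
HC/LTLE `[[.95,.05],[.12,.88]]` (stationary state-II occupancy 0.294),
RTLE `[[.90,.10],[.08,.92]]` (0.556).  Effect magnitudes are free
parameters exposed on `CohortSpec`; no empirical effect sizes exist
to calibrate against, so the defaults were chosen once for clear
detectability at n = 30/group.

**Metadata** covariates are plumbing loosely matched to a young-adult
cohort: age ~ N(30, 8) truncated to [18, 60] years, education ~ N(13,
2.5) years, per-volume FD ~ |N(0.08, 0.04)| mm, sex ~ Bernoulli(0.45).
MoCA-style sub-items are drawn binomially except one configurable linked
item (default conceptual thinking, 0–3 points) generated as
`max − 3.0 × (state-II occupancy) + N(0, 0.4)`, rounded and clipped to
instrument range — a negative link giving the partial-correlation stage
a recoverable signal of known sign.

**What the generator does not emulate:** hemodynamics, spatial mixing,
scanner drift or physiological noise spectra, autocorrelated noise,
site/batch effects, or realistic motion-connectivity coupling.  Passing
recovery tests therefore demonstrates the estimators' correctness and
calibration under the assumed switching-Gaussian model, not performance
on real scans.

## Determinism

Every stochastic step draws from `numpy.random.SeedSequence` children of
a master seed (per-stage spawn keys; per-subject spawns; per-threshold
and per-window spawns for random references), so identical configuration
and seed reproduce cohorts, state models and reference distributions
byte-for-byte.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the statistical recovery
checks at reduced sizes chosen to keep a full run on one CPU short while
leaving comfortable statistical margins: type-I error over 100–200 null
cohorts of 90 subjects; effect detection over 25–50 cohorts at
n = 30/group; correlation-sign recovery over 12–20 cohorts (clustering at
3 k-means restarts there); k-selection on 20-subject cohorts with 10
restarts.  The `n` field in the acceptance output records the size used
for each quantity.

## Known limitations

- The silhouette values on realistic cohorts are small (≈ 0.05–0.1):
  windows overlapping state transitions blur the clusters.  k-selection
  is still reliable at default separation, but silhouette magnitude
  should not be over-interpreted.
- Estimated state fractions shrink slightly toward 1/2 relative to the
  generating chain's stationary occupancy (transition windows are
  assigned to whichever state dominates the taper).
- Proportional thresholding at low sparsity produces disconnected
  graphs; L is then a biased (connected-pairs-only) summary, which is why
  efficiencies — well-defined under disconnection — are reported
  alongside.
- The MANCOVAN-style multivariate screen is intentionally out of scope.
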