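# Methods

`mmgraph` implements a multi-modal graph analysis of simultaneous EEG-fMRI:
band-limited EEG and ROI-level resting-state fMRI time series are turned
into Pearson-correlation connectivity matrices, binarized over a sparsity
grid, summarized by null-normalized small-world metrics, compared across
groups with FDR-corrected t-tests, and finally fused by correlating
per-subject node clustering between modalities. This note describes the
models, the parameters that matter, the synthetic data the package ships
in place of patient recordings, and the numerical choices made where the
design was genuinely open.

## Study design being modeled

The emulated study records each patient twice — R1 before and R2
immediately after a single 1 Hz rTMS session over left premotor cortex —
with simultaneous 31-channel EEG and whole-brain fMRI (TR = 3 s,
185 dynamics of which the first five are discarded), plus a
healthy-control group (HC) recorded once. Default group sizes are 14
paired patients and 20 controls. EEG enters the analysis at 250 Hz;
fMRI as 160 ROI-averaged time series (5 mm spheres around supplied MNI
coordinates).

## Preprocessing

* **EEG**: 0.5–45 Hz broadband, then band splits theta (4–8 Hz), alpha
  (8–13 Hz), beta1 (13–20 Hz) and beta2 (20–30 Hz). All filters are
  forward-backward 4th-order Butterworth band-passes (zero phase, so
  epoch boundaries stay aligned across modalities; the squared response
  gives ≥ 20 dB stop-band attenuation one octave out). Recordings are cut
  into 3-s epochs; an epoch is rejected when any channel's peak-to-peak
  range within it exceeds 150 μV (an absolute-amplitude criterion is
  available). Survivors are concatenated; kept/rejected counts are
  recorded per recording rather than assuming a fixed 180 epochs survive.
  The gradient/ballistocardiogram correction and ICA screening applied to
  real MR-EEG happen upstream in vendor tools and are out of scope; the
  deterministic amplitude rule is the in-scope remnant of artifact
  rejection.
* **fMRI**: the first five dynamics are dropped, channels are
  residualized on an intercept plus optional confound regressors
  (white-matter/CSF signals) by least squares, and the residuals are
  band-passed 0.01–0.09 Hz. ROI extraction averages voxels within a 5 mm
  Euclidean radius of each center; ROIs that capture no voxel are flagged
  and zero-filled, never silently dropped (a zero-filled ROI later fails
  the constant-channel check by name).

## Connectivity and binarization

Connectivity is the N×N Pearson correlation of node time series (Fisher
z is stored for export; it is monotone in r, so binarized graphs are
identical). Graphs are formed by **sparsity thresholding**: at sparsity S
exactly round(S·N(N−1)/2) strongest edges are kept, which equalizes edge
count across subjects before topology is compared. The grid is
0.11 ≤ S ≤ 0.45 in steps of 0.01 (35 levels). Edge strength is |r| by
default — the treatment of negative correlations is not standardized in
the field, so a positive-only switch exists and the choice is recorded in
output metadata. Ties at the cut break deterministically by
(min-node, max-node) lexicographic order. Because each level keeps a
prefix of one fixed ranking, edge sets are nested across the grid.

## Small-world metrics and the null model

For each binary graph: node clustering C_i = 2t_i/(k_i(k_i−1)) (zero for
degree < 2), mean clustering C, and characteristic path length L as the
mean BFS distance over reachable ordered pairs. Disconnected graphs set a
fragmentation flag and average reachable pairs only (a harmonic-mean
efficiency variant is exposed but not default). Normalization uses
degree-preserving random references built by Maslov–Sneppen double-edge
swaps — 10 swap attempts per edge, illegal swaps skipped — with one
shared ensemble (default 100 references) serving both normalizations:

γ = C/C_rand, λ = L/L_rand, σ = γ/λ.

Ensemble SDs are kept for diagnostics; a null family with zero mean
clustering (e.g. star graphs) is an error rather than an infinite γ.
Randomness flows from explicit seeds; ensemble member j uses seed + j,
and sparsity level ℓ uses a disjoint seed block, so curves are exactly
reproducible.

**Per-node γ (region tables).** A recording's per-node normalized
clustering is summarized across the grid as a pooled ratio
Σ_ℓ C_i(ℓ) / Σ_ℓ C̄_i^rand(ℓ) over levels where the null mean is
positive. We first implemented the mean of per-level ratios; its variance
is dominated by sparse levels where the null mean approaches zero and a
single ratio can explode, which measurably swamped real between-session
differences. The pooled form is the package's default; the per-level
aggregation remains available (`aggregation="per_level"`).

## Group statistics

HC vs R1 and HC vs R2 use pooled-variance two-sample t-tests (unequal
group sizes allowed); R1 vs R2 uses a paired t-test over manifest-aligned
subjects. All tests are two-sided. Families — the 35 sparsity levels of
one metric and contrast, or the node set of one modality — are corrected
by Benjamini–Hochberg FDR at q = 0.05; the realized data-dependent p
threshold is reported alongside the mask, and contiguous significant
sparsity runs are rendered in percent notation ("11%–17%"). At dense
sparsity levels every graph and every reference reaches diameter 2, λ is
identically 1 across subjects, and the t-test's variance precondition
fails; such levels are marked untestable and excluded from the FDR family
rather than aborting. Effect sizes use the equal-n pooled form
d = (m₂−m₁)/√((s₁²+s₂²)/2) and r = d/√(d²+4); this form exactly
reproduces published region-level effect sizes from printed group
means/SDs, which is why it is used even for the paired contrast (the
paired-SD form is not recoverable from summary statistics).

## Cross-modal fusion

For each (electrode, ROI) pair, the per-subject **change scores**
(R2 − R1) of node γ are correlated across subjects (a switch correlates
R2 values instead); p comes from the exact t transform with df = n − 2,
pairwise-complete over subjects with both modalities. A pair is reported
when |r| > 0.4 **and** p ≤ 0.05. At n = 14 the p ≤ 0.05 leg implies
|r| ≥ 0.53, so the conjunction's null rate is α itself. Inputs are
restricted to the nodes that survived the group-level FDR in each
modality, mirroring the published analysis (2 electrodes × 7 ROIs there).
Display export writes BrainNet Viewer `.node` text files
(`x y z color size label`), sized by |effect r|.

## Synthetic cohorts

No patient recordings are distributable, so the generator plants a known
effect with the study's shape:

* Each subject owns a Watts–Strogatz graph (ring degree k, rewiring
  p = 0.1; k = 6 for 31 EEG channels, k = 12 for 160 fMRI ROIs). The
  ring-lattice closed form 3(k−2)/(4(k−1)) anchors the clustering tests;
  edge count n·k/2 is conserved for every rewiring probability.
* Signals are stationary multivariate Gaussians with covariance
  Σ = I + W, where W puts coupling c on planted edges (c = 0.22 EEG,
  c = 0.15 fMRI). c is bounded by positive definiteness: λ_min of a
  rewired WS adjacency approaches the random-graph −2√(k−1) limit, and
  the defaults were chosen with an empirical margin over hundreds of
  graph draws. White sensor noise (SD 0.5 of signal) is added; an
  optional AR(1) factor exercises the temporal filters without changing
  the stationary covariance.
* **Planted group effect.** Within-cluster edges are those closing at
  least one triangle. Patients (R1 and R2) carry a broad deficit: those
  couplings are scaled by 1 − deficit (default 0.5). R2 additionally
  rescales them by 1 + boost on triangle edges touching a fixed
  *affected* node subset (default 25% of nodes — the same nodes in every
  subject, an anatomically consistent stimulation site). Each subject's
  boost is drawn once (mean 0.8, SD 0.4), shared between that subject's
  EEG and fMRI, and truncated at full restoration of the healthy
  coupling — which both reads naturally (recovery toward, not beyond,
  the healthy level) and keeps the R2 covariance inside the
  positive-definite region verified for HC. The resulting ordering —
  R1 below HC broadly, R2 recovering focally with subject-variable
  magnitude — is what the per-sparsity curves, the node tables and the
  cross-modal change-score correlations are each able to find.
* One master seed per cohort; per-subject, per-modality and per-session
  sub-streams are spawned deterministically, so generation is
  bit-reproducible.

What the generator does **not** emulate: raw EEG artifacts (gradient,
ballistocardiogram, ocular), hemodynamic response shapes and
autocorrelated BOLD noise, head motion, volume conduction, and any
spatial correspondence between electrode and ROI coordinates. Passing
tests therefore demonstrate that the inference chain recovers planted
covariance structure at realistic sample sizes — not that real recordings
of this protocol would yield the published regions.

## Replication harnesses and problem sizes

Power and error control are measured by rerunning the core chain on many
independent cohorts (`pattern_recovery_rate`, `null_familywise_rate`).
These use a single EEG-like modality (31 channels, 60 s at 250 Hz,
n_null = 6) with the full 35-level grid and the study's group sizes, and
the strong-boost condition — within-cluster coupling halved by disease
and exactly doubled by stimulation, uniformly across subjects — so the
measured quantity is the power of the inference chain itself rather than
of responder heterogeneity. Success in one replicate requires, for γ and
σ separately, at least three consecutive FDR-significant levels with the
correct direction intersecting S ∈ [0.15, 0.35], for both HC > R1 and
R2 > R1. The null harness regenerates cohorts with deficit and boost
zero, making R1/R2 exchangeable, and records whether any level survives
FDR.

A deliberate limitation surfaced by these simulations: at the protocol's
180 fMRI volumes, the 0.01–0.09 Hz band leaves roughly 90 effective
samples, and with coupling capped by positive definiteness the per-node
γ changes are not detectable after FDR at n = 14 in this synthetic model
(real BOLD coupling is larger than Σ = I + W admits). The node-table and
cross-modal demonstrations therefore run on longer synthetic fMRI
recordings (740 volumes) with a 40-ROI parcellation; the per-sparsity
curve effects do not need this and replicate at protocol length.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| bands | 4–8, 8–13, 13–20, 20–30 Hz | theta/alpha/beta1/beta2; beta2 carries inference |
| epoch length / rejection | 3 s / 150 μV peak-to-peak | amplitude-based epoch rejection |
| fMRI band | 0.01–0.09 Hz | resting-state fluctuation band |
| sparsity grid | 0.11:0.01:0.45 | 35 levels, equalized edge counts |
| n_null / swaps per edge | 100 / 10 | random-reference ensemble |
| FDR q | 0.05 | per contrast × metric family |
| cross-modal rule | \|r\| > 0.4 and p ≤ 0.05 | change scores, pairwise-complete n |
| cohort | 14 paired + 20 HC | 31 channels, 160 ROIs |
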