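# Methods

This note documents the models, parameter choices, and numerical decisions
behind `retseq`, and what the synthetic-data tests do and do not establish
about real recordings.

## The sequential-recording design

Every cell is recorded twice for the full stimulus set. In a
control/control pair, the trace difference Δ(t) = rec2(t) − rec1(t)
measures *adaptational* drift — reproducible, type-specific response
changes that occur without any pharmacology. In a control/drug pair, Δ
mixes adaptation with the drug effect. The analysis assumes the two
components add linearly, so the drug-induced part of a per-type,
per-feature change is estimated as `mean(Δ_drug) − mean(Δ_ctrl)`, tested
feature-wise (6 chirp windows + 2 moving-bar windows) with a two-sided
Welch t-test and Bonferroni control over all type × feature comparisons
(α = 0.05 / (n_types·8); with 21 types this is 2.98·10⁻⁴). Only types with
more than 10 paired cells in both datasets enter testing. A parallel
one-sample family (control deltas vs zero, same per-test α) flags
*adaptational* features; a type is categorized drug-affected if any feature
passes the two-sample test, else adaptational if any feature passes the
one-sample test, else stable. Nonlinear interactions between adaptation and
drug effects are out of scope by design.

## Stimuli

The full-field chirp is 32 s at 50 frames/s: 2 s mean gray, 3 s bright (On)
step, 3 s dark (Off) step, 2 s gray, an 8 s frequency sweep (linear
instantaneous-frequency ramp 0.5→8 Hz at full contrast, phase = integral of
instantaneous frequency), 3 s gray, an 8 s contrast sweep (2 Hz sinusoid,
amplitude 0→100%), 3 s gray. All segment durations are configurable; the
feature windows are derived from the segment annotations (On/Off steps;
first/second halves of each sweep). The moving bar (0.3×1 mm at 1 mm/s,
8 directions 45° apart) is represented by its 4 s per-direction response
snippet; nothing downstream uses bar pixels. Dense noise is a 20×15
checkerboard of 40 µm checks at 5 Hz; "balanced" means every check shows an
exactly equal count of black and white frames in shuffled order.

## The synthetic-data generator

Cells are linear-nonlinear cascades with a subtractive contrast-suppression
term:

    v(t) = (k_τ ∗ s)(t)                        band-passed stimulus drive
    a(t) = max(0, b + g·max(0, p·v) − w_sup·|v|)
    c(t) = (a ∗ h_Ca)(t) + 𝒩(0, σ_n²)          h_Ca(t) = exp(−t/τ_Ca)

with polarity p ∈ {−1, +1}, tonic baseline b, gain g, biphasic temporal
kernel k_τ (time constant τ_k; the kernel doubles as the band-pass whose
rectified output |v| estimates temporal contrast energy), suppression
weight w_sup, and a single-exponential calcium kernel (τ_Ca = 0.8 s,
matching the pseudo-calcium bridge's kernel family). The calcium
convolution uses a steady-state initial condition (pre-stimulus padding at
a(0)) so the onset transient does not contaminate the 1 s baseline window.
Spatial receptive fields are difference-of-Gaussians on the noise grid;
spikes are an inhomogeneous Poisson process at rate `spike_scale · a(t)`
with a 2 ms absolute dead time. A cell with b > 0 and w_sup > 0 is
suppressed-by-contrast: tonically active on gray, driven below baseline
whenever the stimulus modulates.

Between the two recordings, an `EffectSpec` applies (i) adaptational
multiplicative gains per feature window, anchored at the baseline
(`a ← b + gain·(a − b)` inside the window) so suppressed and excited
responses scale symmetrically, and (ii), in the control/drug protocol only,
a drug effect: w_sup ← (1−ρ)·w_sup and τ_k ← τ_k/κ (suppression reduction
ρ ∈ [0,1], kinetic speed-up κ ≥ 1). Per-cell 5% log-normal parameter
jitter provides within-type variability. All randomness flows from one
master seed through named child streams; noiseless runs are
bit-reproducible.

Preset populations:

- `g32-default` — three SbC archetypes with tonic baselines, differing in
  suppression weight (0.6–3.2), kinetics (τ_k 0.08–0.5 s), and residual
  excitatory gain, emulating functionally distinct Off-suppressed
  sub-types. Noise levels are set so the chirp QI of simulated cells falls
  in ≈0.6–0.9, i.e. cells pass the inclusion gate but are far from
  noiseless. Drug effects ρ = 0.8/0.9/0.5, κ = 1.5/1.3/1.2 reproduce the
  qualitative sub-type differences (strong SI reduction in sub-types 1–2,
  weaker in 3); effect sizes in model units are not calibrated to any
  measured values.
- `mixed-population` — two stable types, two adaptational types (gain
  changes confined to specific feature windows, one decreasing and one
  increasing), and two drug-affected SbC types; ground-truth categories are
  stored per type.
- `ln-basic` — high-SNR On/Off LN cells without suppression, used mainly
  for receptive-field validation.

What the generator does *not* emulate: photoreceptor/network adaptation
within a recording, correlated (shared) noise across cells, sub-Poisson
spiking, indicator saturation, eye-position or field-placement artifacts,
and any circuit mechanism of the drug. Passing tests therefore show that
the *analysis* recovers effects of the assumed form at realistic SNR — not
that real data meet those assumptions.

## Preprocessing and quality control

Detrending subtracts a Savitzky-Golay smooth (3rd order, 60 s window,
window forced odd in samples, `mode="interp"` edge handling). Snippets are
aligned to the nearest sample (no sub-sample interpolation; at 7.8125 Hz
the alignment error ≤ 64 ms is negligible against the effects studied);
triggers whose snippet leaves the trace are dropped with a logged count.
Response averages subtract the mean of the first second and divide by the
maximum absolute amplitude; flat traces are flagged degenerate rather than
errored so population pipelines continue. The preferred bar direction
maximizes the energy of the mean snippet (ties go to the lowest direction
index) and is selected on rec1 and reused for rec2 to keep pairs matched.
The QI uses population variances (÷N) in numerator and denominator; the
inclusion gate applies the strict inequalities as printed (>, not ≥).
PSTHs are trial-averaged rates in 100 ms bins.

## Receptive fields

Calcium path: weights are the positive-clipped forward-difference
derivative of the detrended trace (length T−1, left-aligned). Stimulus
frames are zero-order-held on a grid at 10× the stimulus rate, weights
linearly interpolated onto it, and F(x,y,τ) = Σ_t w(t)·S(x,y,t−τ) is
computed for 80 lags spanning −0.20…1.38 s (positive lag = stimulus
preceding response; the 0.2 s acausal margin is a built-in sanity check).
Each lag slice is optionally blurred with a 5×5-pixel, σ = 1 pixel Gaussian.
Spike path: the classic STA over 40 samples at the native stimulus rate.

The rank-1 SVD decomposition is rescaled to max|Ft| = 1 and
max|Fs| = max|F|; the joint sign ambiguity is resolved so the spatial map
carries the polarity of F at the dominant lag. Separability is scored as
QI_RF = 1 − Var[F − Ft·Fs]/Var[F] with the gate QI_RF > 0.45.

The DoG fit ties center and surround mean and covariance up to one scalar
(surround covariance = c·Σ, c ∈ [1.2, 10]; surround amplitude fraction
∈ [0, 0.95]). Initialization from image moments of |Fs|, 5 random restarts,
`xtol` 1e-8; non-convergence returns a flagged failure with no partial
values. Polarity is the sign of the fitted model at its mean. The surround
index is computed in polarity-rectified space (G = p·Fs, Gc = max(0, G),
index = Σ(G−Gc)/Σ|G| ∈ [−1, 0]) so On and Off cells are treated
symmetrically and a surround-free map scores exactly 0. Center size: a
single Gaussian fit to Gc with the mean fixed, reported as the 2σ ellipse
area 4π·σ_major·σ_minor. Temporal FWHM interpolates half-extremum crossings
linearly; a boundary extremum or missing crossing yields the one-sided
width with an unreliable flag. A trigger-shuffle null utility
(`null_rf_threshold`) is provided but is not part of the gate.

## Clustering

Calcium path: per-stimulus sparse PCA (20 chirp + 10 bar components); the
sparsity penalty α is chosen from a small grid (0.5, 1, 2) by maximizing a
*localization score* — the mean, over components, of the fraction of
absolute loading mass inside the component's dominant contiguous support —
our formalization of "every part of the stimulus represented by one
feature". Columns are standardized. Clustering uses a full-covariance
Gaussian mixture (20 restarts, reg_covar 1e-2 in standardized feature
space; weaker regularization lets held-out likelihood collapse on
near-singular covariances at ~100 points/component in 30 dimensions). The
selection score is a BIC whose log-likelihood term is the summed held-out
log-likelihood from seeded 10-fold cross-validation (plain training BIC by
flag); chosen k is the argmin, with ties within 1 BIC unit between
adjacent k resolved toward the smaller k.

Population size for the sub-type analysis: the between-cluster structure of
three clusters is rank-2, so the held-out likelihood gain of an extra
component is only a few nats per cell (logarithmic in cluster separation),
against a per-component BIC penalty of ~500·ln n. At a few hundred cells
the criterion is therefore intrinsically ambiguous between k = 2 and 3 —
which is why close BIC values at that scale must be adjudicated with
coherence diagnostics (`cluster_coherence`: mean member-vs-cluster-mean
correlation, own vs other; coherent iff intra > inter for every cluster).
The packaged sub-type study uses 400 cells per archetype (n = 1200), the
scale at which the BIC argmin alone is decisive; at that size the chosen
k = 3 with perfect label agreement across seeds. An optional second-stage
cleanup (`reclean_cluster`) re-clusters one cluster and discards
sub-clusters whose mean member correlation falls below a threshold; it runs
after model selection and never alters the chosen k.

MEA path: per-cell vectors concatenate PSTH PCs up to 80% cumulative
variance (z-scored PSTHs), 2 temporal-STA PCs, and the min-max-normalized
RF ellipse area (~15 columns); agglomerative clustering (correlation
distance, average linkage) cuts the dendrogram at a configurable threshold
— the threshold is a free parameter set by inspection in practice.

## The pseudo-calcium bridge

PSTHs are causally convolved with a decaying exponential of unit peak
(truncated at 5τ). Peak (not area) normalization keeps traces in rate-like
units; downstream correlations are scale-invariant either way. The decay
constant is chosen on a grid (0.1–3.0 s, step 0.05 s) to maximize the
median best-template correlation. Cluster-template assignment is greedy
one-to-one in descending correlation, two rounds: round 1 with a
correlation floor (default 0.6), round 2 over the leftovers without a
floor; remaining clusters are flagged unassigned. The floor substitutes for
the manual mosaic/waveform curation used with real recordings, which is out
of scope here.

## Statistics

`gated_difference_test` routes by a Shapiro-Wilk gate at 0.05: normal →
t-test (one-sample vs 0, paired, or independent two-sided), non-normal →
Wilcoxon signed-rank or Mann-Whitney U. The gate switches only the test
family, never the sidedness or the comparison target, and the result logs
which test ran and the gate p-value. `multi_condition_test` runs a
Kruskal-Wallis omnibus (or one-way repeated-measures ANOVA for paired
designs) followed by Dunnett many-to-one comparisons against the control
condition — the parametric post hoc after the nonparametric omnibus is
reproduced as used in this literature. Dunnett's quasi-Monte-Carlo
integration is seeded so results are deterministic given the data. The
standard tests come from scipy/statsmodels; this module owns only the
gating, pairing, and multiplicity policy.

## Problem sizes and runtimes

The validation suites use: 1200 cells for sub-type clustering (~1 min);
20 seed pairs × 30 cells/type for disentangling power and 200 runs ×
12 cells/type for its null calibration (significant-test fraction ≤ the
0.05 family alpha; observed ≈10⁻³ because Bonferroni controls far below
the family level); 20 seeds of 300 s dense noise for RF recovery; 2000
null draws per branch for type-I calibration (binomial 95% band around
0.05). These sizes were chosen so each check is decisively powered while
the whole suite runs in a few minutes on one CPU.

## Known limitations

- The additive adaptation/drug model cannot represent interactions
  (e.g. adaptation that itself depends on the drug).
- The sparse-PCA α grid and the agglomerative threshold are free
  parameters; neither has a published value.
- The surround index is a ratio of sums on a finite grid; maps whose
  surround extends beyond the stimulus area underestimate it.
- Calcium-path FWHM values inherit the indicator kernel's low-pass and
  should only be compared within, not across, recording modalities.
- HDF5 containers store raw repetition matrices; for very large populations
  (≫10⁴ cells) a chunked layout would be preferable.
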