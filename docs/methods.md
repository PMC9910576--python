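# Methods

This note documents the models and procedures implemented in
`eegcomplexity`, the parameters that matter, and the design choices made
where the methodology left room.

## Preprocessing

Recordings are band-pass filtered 0.1–40 Hz (zero-phase Hamming-window
FIR; kernel length set by the 0.05 Hz low-end transition band, capped for
short inputs) and resampled to 250 Hz (polyphase).  Bad channels are the
union of four rules: NaN content; flat signal; amplitude outliers, where
a channel's amplitude is its robust SD (1.4826·MAD) over the whole
recording and a channel is flagged when
|(amp − median amp)/SD(amps)| > 5; and decorrelated channels whose
maximal Pearson correlation with any other channel falls below 0.4 in
more than 1% of non-overlapping 1-s windows.  Bad channels are replaced
by the inverse-distance-weighted mean of their 4 nearest good neighbors —
a deliberate simplification relative to spherical-spline interpolation,
adequate at this channel density and fully deterministic.  Signals are
re-referenced to the common average, the first and last 10 s discarded,
and the rest cut into contiguous non-overlapping 2-s epochs; epochs with
any |value| > 1e-4 V are dropped, and a subject is excluded when more
than one third of epochs are dropped.  Ocular/muscle independent-
component cleaning is out of scope: it requires human component labeling,
and the synthetic cohorts carry no ocular artifacts.  The epoch-rejection
threshold is applied after referencing (the ordering is not dictated by
the QC definition; applying it post-reference matches the data the
downstream stages actually see).

## Entropy measures

All SDs are population SDs (ddof = 0).  Retained epochs are concatenated
per channel before any entropy computation: coarse time scales need long
series, and the few joint discontinuities introduced by concatenation are
negligible against ~130 epochs — per-epoch computation would leave scale
20 with 25 points per epoch, far too few.

- **Shannon entropy**: 100 equal-width bins spanning [min, max], base-2
  logarithm, empty bins skipped.  A constant signal has H = 0 (one
  occupied bin).  The base only rescales values and is irrelevant for
  correlations.
- **Fuzzy entropy**: template length m = 2 (the field's standard; the
  embedding dimension must be chosen, and m = 2 is used for both fuzzy
  and sample entropy throughout), delay d = 1, fuzziness exponent n = 1,
  tolerance r = 0.2 applied as an absolute threshold to the z-scored
  channel signal.  Both template lengths use the same N − md vectors so
  that φ(m) and φ(m+1) average over identical index sets, matching the
  printed normalization 1/((N−md)(N−md−1)); each vector has its own mean
  removed before the Chebyshev distance, making the measure invariant to
  additive offsets.
- **Sample entropy / MSE**: identical scaffold without baseline removal
  and with the hard indicator similarity Δ ≤ r, r = 0.2·SD.  If no
  length-(m+1) pair matches, the value is an explicit NaN sentinel
  propagated as missing.  Coarse-graining averages non-overlapping blocks
  of length τ (remainder discarded), scales 1..20.  By default the
  tolerance is recomputed from each coarse-grained series
  (`r_mode="per_scale"`); whether "0.2 times the SD of the signal" means
  the original or the coarse-grained signal is genuinely ambiguous, so
  both are implemented.  The classical noise signatures (white-noise MSE
  decreasing in τ, 1/f MSE flat) appear under the fixed original-SD
  tolerance (`r_mode="global"`), which is what the reference-process
  tests pin; per-scale recomputation yields flat white-noise profiles by
  construction, which is equally correct but tests distribution shape
  rather than temporal structure.

The scan-based kernels (numba) are verified against independent
brute-force oracles that materialize all template vectors and full
pairwise distance matrices; agreement is required to 1e-12.

## Microstates

Scalp maps at GFP peaks (strict local maxima of the per-sample SD across
electrodes) are clustered with a polarity-invariant k-means: assignment
by maximal squared spatial correlation, template update by the first
principal component of assigned maps, restarted from random map subsets,
keeping the restart with the highest GEV
(Σ GFP²·corr² / Σ GFP², over peaks).  Polarity-invariance is the
established convention for spontaneous EEG topographies, where the
generator dipole's sign flips with the oscillatory phase.  The two-level
scheme clusters each subject's peak maps into k = 5 individual maps and
the pooled individual maps into 5 group maps.  No temporal smoothing is
applied to backfitted label sequences.  Group maps are ordered by
descending share of assigned GFP² weight; mapping to the classical A–F
nomenclature is left to the user.

Sequence measures: coverage (fraction of samples), lifespan (mean run
length, ms), frequency (count of runs; the first run counts even without
a preceding different state), lifespan at GFP peaks (mean consecutive-
peak run length), number of GFP peaks, and row-stochastic transition
matrices (self-transitions included) on the full sequence and on the
peak-restricted sequence.  A state that never occurs gets coverage 0,
NaN lifespan, and a uniform transition row.  Post hoc metrics: mean
absolute pairwise correlation between a subject's maps (map similarity)
and the GEV of the backfit labeling over all samples (explained
variance).

## Feature inventory and factor structure

The canonical 28-channel, 20-scale, 5-state configuration yields exactly
709 named features (2 + S + 2C + C·S + 1 + 4k + 2k², C=28, S=20, k=5).
For prediction, MSE is aggregated into 8 clusters × 4 bins (scales 1–5,
6–10, 11–15, 16–20) = 32 values; the candidate pool adds channel and GFP
Shannon/Fuzzy entropies and the 71 microstate measures (161 candidates;
GFP-MSE can be toggled in).  Subjects with missing features (entropy
sentinels) are dropped from affected analyses with a logged reason
rather than imputed.

Factor analysis: factor count by parallel analysis against the per-rank
95th percentile of eigenvalues from size-matched standard-normal data
(the conservative criterion; the per-rank mean — Horn's original rule —
is available but retains spurious factors on null data), extraction by
iterated principal-axis (unweighted least squares / minimum residual)
factoring, promax (power 4) rotation.  Heywood cases are reported, not
silently clipped.

## Association screening

Partial Pearson correlations control for age and the number of removed
epochs (plus sex in mixed-sex cohorts): both variables are residualized
on [1, confounds] and the residual correlation is tested against a t
distribution with df = n − 2 − n_confounds, two-sided.  Families of
channel-wise and microstate tests are corrected by Benjamini–Hochberg
FDR.  The channel×scale MSE grid is screened by a cluster-size
permutation test: cells with p < α are linked when they share a channel
and consecutive scales or a scale and Delaunay-adjacent channels (the
montage has no canonical neighborhood definition; Delaunay is parameter-
free and local), clusters keep a common correlation sign, and the null
distribution of the maximal cluster size over score permutations sets the
minimal significant size (cluster *size*, not mass, is the statistic).

The a priori power utility uses the classical bias-corrected Fisher-z
power formula for the two-sided zero-correlation test (Cohen, 1988 — the
method behind pwr.r.test and G*Power's correlation module), giving a
minimal n of 123 for ρ = 0.25, power 0.80, α = 0.05; an independent
Monte-Carlo check and pingouin's implementation agree.

## Prediction model

Candidates are confound-residualized and z-scored with training-set
parameters only; those with Pearson p < 0.05 against the residualized
score form X⁺/X⁻ by sign, and the prediction is the fixed-coefficient
combination ŷ = mean(X⁺) − mean(X⁻) (β₀=0, β₁=1).  The combination rule
is the one point where this implementation deliberately departs from the
printed absolute-value form |mean X⁺| + |mean X⁻|: taking absolute
values of per-subject means makes the predictor non-monotone (both
extremes of a feature mean map to large ŷ), and simulation shows it
yields null-to-negative cross-validated correlations even under strong
planted effects — it cannot produce the positive prediction performance
this class of models reports.  In the typical sign configuration the two
forms coincide (e.g., X̄⁺ = 2, X̄⁻ = −2 gives 4 either way).  The literal
absolute-value variant remains available (`signed=False`).

Internal validation: stratified 10-fold CV (sort scores with random
tie-breaks, deal consecutive blocks round-robin — deterministic given the
seed, equalizes score distributions across folds), everything fitted on
training folds only.  Significance: the mean CV correlation over
stratified divisions (100 by default) is compared with CV correlations
from full re-runs on permuted scores (1000 by default; one CV repetition
per permutation), p = (1 + #{null ≥ observed})/(1 + n_perm).  Runs where
no candidate survives selection predict a constant and score exactly 0,
producing the characteristic null spike at zero.  External application
freezes the full-sample selection, confound betas and z-parameters;
external features and scores are residualized within the external sample
(including sex), and significance comes from permuting external scores
under the frozen model.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline needs to
be exercised against, not the full physics of EEG:

- k = 5 smooth templates (low-order spherical-harmonic functions of
  electrode position plus a small seeded perturbation; rejection sampling
  enforces pairwise |r| < 0.7), zero-mean and unit-norm;
- a first-order Markov state sequence with geometric dwell times
  (subject-mean ~N(60, 8) ms);
- a unit-RMS alpha-dominant activation (mixture of 8–12 Hz band-limited
  noise, weight √alpha_power with alpha_power ~N(0.7, 0.08), and a 1/f
  broadband floor) multiplying the active template; average per-channel
  signal RMS 5 µV, so clean recordings never trip the 100 µV rejection
  bound;
- 1/f background noise (subject spectral exponent ~N(1.5, 0.2), shaped
  within 1–40 Hz) at per-channel SD = noise_scale × 5 µV
  (default noise_scale 0.5).  Spatially it is a mixture of a smooth
  component (Gaussian spatial kernel, width 0.7 chord units) projected
  onto the orthogonal complement of the template span — background
  activity in the spatial modes the microstates do not occupy, which
  gives neighboring channels the high mutual correlations real
  volume-conducted EEG shows — plus 40% channel-independent sensor noise.

Scores are planted through the generative parameters: for targets ρᵢ,
score = Σ ρᵢ·zᵢ + √(1−Σρᵢ²)·ε with zᵢ the population-standardized
parameter, so population correlations equal their targets exactly.
Defaults are conventional eyes-closed resting-state values; the study
this emulates reports no quantitative spectra, so they are assumptions.
What the generator does **not** model: ocular/muscle artifacts, volume-
conduction forward physics, event-related content, non-Markovian state
dynamics.  Passing tests therefore demonstrate correctness and
statistical validity of the *analysis machinery* under a plausible
generative model — not fidelity of any particular empirical effect size
in real recordings.

A feature-level generator (`simulate_feature_cohort`) plants the same
score model directly into a 161-candidate table (24 informative features
loading ±0.8 on the score-driving latent, alternating sign, the rest
noise); it is the fast path for statistical validation of the prediction
machinery, where simulating full recordings for hundreds of permutation
runs would be wasteful.  The ±0.8 loading reflects how strongly redundant
EEG complexity features track their generative spectral/dynamical
parameters over ~260 s of data; alternating signs mirror the coexistence
of positively and negatively score-related measures.

## Problem sizes used in the test suite

Simulation-based tests use deliberately scaled problem sizes chosen for
tight feedback loops while keeping estimates stable: per-subject
fixtures use 36-s recordings; the workflow smoke test runs 6 subjects at
32 s; microstate recovery uses the full 30-subject, 280-s cohort with 30
k-means restarts (the GEV surface at this noise level is benign — more
restarts change the solution only in degenerate cases); prediction
validity uses 20 planted and 50 null cohorts at n = 150 with 200
permutations and 20 stratified divisions per test.  Reference-process
entropy checks use 70 000-sample signals.

## Known limitations

- Inverse-distance interpolation is cruder than spherical splines;
  interpolated channels inherit no high-spatial-frequency structure.
- Concatenating epochs introduces joint discontinuities into the entropy
  estimates (shared by any epoch-rejecting pipeline that needs long
  series).
- The k-means labeling oracle guarantees only GEV-optimality on tiny
  problems; at scale, restarts make global optimality probabilistic.
- Group-map identity (A–F classes) is not established; measures are
  reported per coverage-ordered state index.
- The EFA returns unrotated-eigenvalue variance fractions; for strongly
  oblique solutions these are approximations to "variance explained".
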