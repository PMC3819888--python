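# Methods

`erpkit` implements a complete analysis chain for two-class ERP cohort
classification in a visual N-back working-memory paradigm: synthetic
cohort generation, ICA-OEMD signal cleaning, four-feature ERP
quantification, and a genetic-programming-evolved multiple-kernel SVM
(EMK-SVM) evaluated under subject-grouped cross-validation with LDA/QDA
baselines. This note records the models, the tunable parameters and
their defaults, the numerical choices, and the limits of what the
synthetic validation can show.

## Synthetic N-back cohorts (`erpkit.synth`)

The generator emulates the recording conditions the pipeline assumes:
18 channels (2 EOG + 16 scalp electrodes of the 10-20 montage), 256 Hz
sampling, 0.5 s stimuli with 2.5 s inter-stimulus interval, 3 sessions
of 40 trials with a 1:1 target/nontarget ratio. Each recording is a
sum of four parts:

1. **Background noise** — 1/f (pink) noise, independent per channel,
   default SD 6 µV. Chosen as a realistic ongoing-EEG amplitude that
   leaves single-trial responses clearly sub-threshold (SNR < 1) while
   40-trial averages resolve them.
2. **P300-like deflection** on target trials — a Gaussian bump with
   FWHM 120 ms, peaking at the subject's latency parameter after
   stimulus onset, projected through a fixed centro-parietal
   topography with maximum at Pz. A Gaussian was chosen because the
   feature definitions only require a smooth unimodal deflection
   peaking between 200 and 450 ms.
3. **Stimulus-locked theta burst** — a 6 Hz oscillation under a
   Gaussian envelope (FWHM 240 ms) centered on the response peak,
   fronto-central topography (maximum Fz), amplitude
   `theta_base_uv x theta_scale` (default base 3 µV). The burst's
   phase is locked to the response peak, not to raw stimulus onset:
   onset-locked phase makes the interference between the bump's own
   theta-band content and the burst flip sign with the group latency
   difference, which is a simulation artifact rather than a
   physiological effect.
4. **Blink artifacts** — Poisson-arriving 300 ms raised-cosine
   transients (default 12/min, 120 µV) on the EOG channels, leaking
   into frontal scalp channels through fixed weights.

Group structure enters through per-subject parameters drawn from group
distributions: patients have prolonged latency (390 vs 330 ms, SD
15 ms), reduced amplitude (6 vs 10 µV, SD 1.5 µV) and reduced theta
scale (0.6 vs 1.0, SD 0.1) — the canonical directions for cognitive
impairment. Trial-level jitter (latency SD 10 ms, amplitude SD 1 µV)
decorrelates single trials. All parameters are independently settable,
so a zero-effect null cohort is expressible (`null_effects`).

All randomness flows through one `numpy.random.Generator` (PCG64);
identical spec + seed reproduce recordings bit-for-bit. Amplitude
scales are conventional µV values, not fitted to any recording system.

**What the generator does not emulate:** head-volume conduction beyond
fixed projection vectors, per-subject anatomy, non-stationary drift,
alpha rhythms, muscle/line noise, and behavioral (reaction-time)
structure. Passing the end-to-end tests therefore shows the chain
recovers group structure *of the assumed form* at realistic SNR — not
that it would do so on clinical recordings.

## Extended Infomax ICA (`erpkit.ica`)

The unmixing matrix W is learned on PCA-whitened, centered data by the
natural-gradient rule `dW = [I - K tanh(u) u' - u u'] W` with the
diagonal switching matrix K selecting the super-Gaussian (+1) or
sub-Gaussian (-1) nonlinearity per source. Updates use mini-batches of
512 samples in randomized order; one sweep visits every sample once.

- **Step size** `mu` defaults to 0.01 with two safeguards: halving and
  restart when the weights diverge, and a 0.95 downward annealing when
  successive sweep updates point in sharply different directions
  (oscillation around an optimum). A default of 1e-3 was tried first
  and converges too slowly to reach Amari index < 0.05 on 20 000-sample
  benchmark mixtures within the 512-sweep cap.
- **Switching criterion.** The exposed operator `kurtosis_sign`
  implements the excess-kurtosis sign and defines the reported final
  `K_diag`. During learning, however, the signs are re-estimated each
  sweep from the nonlinearity-stability criterion
  `sign(E[sech^2 u] E[u^2] - E[u tanh u])`, whose moment simplification
  the kurtosis sign is: raw kurtosis switching admits stable spurious
  attractors in which a still-mixed pair of sources receives
  self-consistent wrong labels and the separation freezes (observed in
  roughly 5% of 4-source mixtures, independent of initialization).
  Sign estimation uses a fixed 8192-sample subsample for speed; the
  sign of a fourth-order moment needs far fewer samples than the
  unmixing itself.
- **Convergence** is declared when the Frobenius norm of the per-sweep
  weight change drops below `tol` (default 1e-6), with a 512-sweep cap.
- **Exactly zero excess kurtosis** maps to +1. The measure of signals
  hitting this tie is zero; any choice is defensible and this one is
  frozen and documented.
- **Artifact rejection** flags sources whose absolute Pearson
  correlation with any EOG channel reaches 0.6 (configurable).
  Back-projection uses `A = pinv(W @ whitening)`, so keeping all
  sources reproduces the centered input to machine precision and
  component removal is exactly linear.

Rank-deficient input is rejected with an error naming the most
collinear channel pair.

## Orthogonal EMD (`erpkit.oemd`)

Sifting uses cubic-spline envelopes through the local extrema with a
mirror-symmetric extension of two extrema per side, a Cauchy-type SD
stop criterion (`sum((h_prev - h)^2)/sum(h_prev^2) < 0.2`) and a
10-iteration cap per IMF. A signal with fewer than two maxima and two
minima is a residue; the caller stops decomposing (`max_imfs` default
10; the cohort pipeline uses 7, which reaches below the theta band at
256 Hz).

Each newly sifted IMF is orthogonalized against **all** previously
accepted IMFs (the unique extension of the two-mode beta
orthogonalization that preserves full pairwise orthogonality), using
two passes of modified Gram-Schmidt so normalized inner products stay
at machine precision even for ill-conditioned mode sets. Because the
orthogonalized modes differ from the sifted ones, reconstruction
coefficients `c_k = 1 + sum_{j>k} beta_jk` are derived from the stored
beta matrix; `sum_k c_k g_k + r = f` then holds to ~1e-15 relative and
is asserted in tests. A degenerate mode (norm below 1e-12 of the
signal) is folded whole into the residue so the identity survives.

**IMF of interest.** Among IMFs whose event-locked average has a local
maximum 200-450 ms after target onset, the one with the largest
fraction of spectral energy (periodogram) in 4-8 Hz is selected; if no
IMF has such a peak, the pure theta-fraction maximizer is returned
with an explicit fallback flag.

A known property of this reduction: a sparse bump train (one smooth
deflection every 3 s) is not a narrowband mode, so sifting splits the
P300 deflection over 2-4 IMFs and the single retained IMF carries only
its theta-adjacent part. The cleaned target average tracks the
programmed waveform's shape (correlation ~0.7 in near-noiseless
simulations) with attenuated amplitude; group contrasts survive
because the attenuation is common to all subjects.

## Features (`erpkit.features`)

Computed per scalp channel on the baseline-corrected target-locked
average (epoch -200..+800 ms, baseline -200..0 ms):

- **P300 peak latency and amplitude** — maximum inside 200-450 ms
  post-stimulus; ties break to the earliest sample.
- **RMS** — over 0-800 ms post-stimulus (the window is a package
  choice; it is not defined by the feature's standard usage).
- **Theta band power** — sum of squared wavelet-packet coefficients
  (db4, periodization mode) of the terminal nodes intersecting 4-8 Hz,
  weighted by fractional overlap, with nodes taken in frequency order.
  The natural (Gray-code) node ordering of the packet tree does not
  coincide with frequency order; using it unscorrected silently selects
  the wrong band. The default depth is 5, making terminal bands 4 Hz
  wide at 256 Hz so the 4-8 Hz band is exactly one node; depth 4 (8 Hz
  bands) remains usable through the overlap weighting.

Two measured limitations of the db4 packet energy, both reproducible
from the analytic `|H|^2` product of the filter cascade: (i) the
4-8 Hz node captures only ~85% of a 6 Hz tone (the transition band of
the 0-16 to 0-8 Hz split, shared by every deeper level, caps the
in-band fraction at 0.8517 — no db4 depth reaches 0.9); (ii) the
measure is shift-variant for broadband transients, so the bump's
leakage into the theta node depends on its latency. The pipeline is
insulated from (ii) because theta power is computed after the cleaning
stage has reduced each source to a band-limited IMF.

Each feature type forms its own 16-channel table (one row per
subject-session) because each type is classified separately.

## EMK-SVM (`erpkit.emk`)

Kernel expression trees over function set {+, x, exp} and terminal set
{K_Poly, K_RBF, alpha}, with `K_Poly(x,y) = <x,y> + 1`,
`K_RBF(x,y) = exp(-||x-y||^2/2)` and constants alpha in [-1, 1] fixed
at creation. Invariants: depth <= 8, at least one kernel leaf.
Trees serialize to parenthesized prefix strings.

- **Fitness** = stratified 5-fold inner-CV accuracy of a soft-margin
  SVM (C = 1) trained on the tree's Gram matrix; the inner split is
  fixed per evolution run so all trees are scored on identical folds.
  When sample grouping is supplied (the cohort pipeline passes subject
  ids), the inner folds keep groups whole: otherwise sessions of one
  subject appear on both sides of the inner split and the fitness
  rewards kernels that memorize subjects rather than group structure.
- **Evolution**: population 100, 100 generations, ramped half-and-half
  initialization (depths 2-8), tournament selection of size 3, elitism
  1, per-offspring operator sampling with probabilities
  (0.1, 0.85, 0.1) renormalized to sum to one (they are specified
  summing to 1.05; renormalization is the closest faithful reading,
  and a sequential crossover-then-mutation variant is reachable via
  `sequential_variation`). The best tree of any generation is the
  result, with the generation of its first appearance.
- **Indefinite kernels**: evolved expressions with negative constants
  need not be PSD. Training Gram matrices are repaired by spectral
  clipping (negative eigenvalues to zero, plus a ridge of
  `1e-12 x largest eigenvalue` to absorb reconstruction rounding at
  extreme kernel magnitudes); prediction-time cross-kernels are
  evaluated raw. The pre-repair minimum eigenvalue is recorded.
- **Numerical guards**: exp arguments saturate at +-50 (with a
  warning); SVM solver iterations are capped and numerically exploding
  fits score the tree as unfit rather than aborting the run.

## Pipeline (`erpkit.pipeline`)

Per subject-session: ICA on all 18 channels, EOG-correlated source
removal, OEMD of each retained source, reduction to the IMF of
interest (scaled by its reconstruction coefficient), back-projection
to the 16 scalp channels, epoching. ICA is fit per subject-session
(stationarity within a session); the cohort pipeline caps ICA at 150
sweeps, which separates the dominant blink/response sources well
before full convergence of the weaker noise sources.

Classification uses subject-grouped stratified 5-fold CV: all sessions
of a subject stay in one fold (asserted per split), and samples are
subject-sessions (13+13 subjects x 3 sessions = 78 samples; a
subject-level aggregation policy is available). Feature vectors are
standardized on the training fold and scaled by `1/sqrt(d)`: the base
kernels have fixed width and offset, so pairwise squared distances
must be O(1) — without this, 16-dimensional standardized vectors give
`K_RBF ~ e^-16` and the Gram matrix degenerates to the identity. A
kernel is evolved independently within each training fold (evolving
once on all data would leak validation information into the kernel).
LDA and QDA run on the same folds; QDA falls back to a PCA-reduced
subspace when a class has fewer samples than features, since its
per-class covariance is otherwise singular.

Group statistics per feature type: channels are summarized by the
channel with the largest |t|; a variance-ratio F test and Welch t test
compare the groups, and when both tasks are present a one-way F across
the four task x group cells with Bonferroni-adjusted pairwise
comparisons is added.

`write_report` produces the accuracy matrix (4 features x 3
classifiers), per-fold accuracies, per-fold best kernel expressions
with generation numbers, the statistics table, and a JSON manifest
(package and library versions plus the full configuration) sufficient
to re-run bit-identically.

## Verification problem sizes

The test suite and `scripts/acceptance.py` run entirely on synthetic
data at these sizes, chosen to exercise every code path at full
fidelity where the check depends on it and at reduced scale where it
does not:

- OEMD: 100 random 1024-sample signals; ICA: ten 20 000-sample
  mixtures of 2-4 iid Laplacian/uniform sources (iid sources match the
  model; deterministic narrowband sources are excluded from mixture
  benchmarks because they violate the iid assumption and admit known
  spurious optima); kernels: 1000 random trees.
- Strong-effect cohort: the full 13+13 subjects x 3 sessions x 40
  trials with a reduced GP budget (population 30, 20 generations).
- Null cohorts: 10 seeds at 5+5 subjects x 2 sessions x 10 trials
  with population 8, 4 generations; the chance-level check constrains
  the mean accuracy per classifier/feature cell across seeds.
- Nonlinear (circle-in-ring) cohort: feature-space construction at
  78 samples; the two latent radial coordinates are mixed into all 16
  channels by a fixed orthonormal projection, mirroring how volume
  conduction spreads a source over electrodes.

## Known limitations

- Validation is synthetic-only; no claim about clinical recordings.
- The single-IMF reduction attenuates broadband components (above).
- db4's transition bands bound the theta-node selectivity (above).
- The GP search is stochastic; different seeds find different kernels
  of similar fitness. Reported kernels are per-fold winners, not a
  canonical expression.
- Extended Infomax assumes iid sources; strongly autocorrelated
  sources (pure sinusoids) can resist separation at realistic sample
  sizes.
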