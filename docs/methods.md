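# Methods

This note documents the models and procedures implemented in `dicmflex`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data generator does and does
not emulate.

## Signal model and preprocessing

A recording is a channels × samples matrix with a sampling rate; analyses
run in native sensor space per acquisition system (no cross-system channel
matching is attempted).  Downsampling uses polyphase resampling with the
exact rational rate ratio; a 3-min recording at 1017.25 Hz downsampled to
170 Hz gives 30,600 samples, and 2400 → 150 Hz gives 27,000.

The filterbank splits each channel into eight bands — δ 0.5–4, θ 4–8,
α₁ 8–10, α₂ 10–13, β₁ 13–15, β₂ 15–19, β₃ 20–29, γ 30–45 Hz (half-open
edges `[lo, hi)`) — with a 3rd-order Butterworth band-pass applied forward
and backward (zero phase; effective order 6), followed by the Hilbert
transform for envelope and instantaneous phase.

Windows are 2 s long (two δ cycles, so δ-paced cross-frequency modulation
is preserved inside every segment) and advance in 0.2-s steps.  The step
is a package choice: it reproduces T = 900 segments exactly for both
canonical recordings (30,600/34 = 27,000/30 = 900).  Windows that overrun
the end of the recording are truncated at the last sample rather than
wrapped; at full scale these are 9 of 900 segments (1 %), and estimator
bias on them is accepted.  At the short desk-scale durations used in
tests they are a visibly larger fraction, which is why planted-mode
recovery is also reported restricted to full windows.

## Frequency codes and estimators

Coupling candidates carry an integer frequency code: 1–8 for within-band
coupling in band order, 9–36 for the 28 ordered low<high band pairs in
lexicographic order, 0 for "no significant coupling".  The code table is
fixed and exported (`dicmflex.codes`).

* **AEC (id 1)** — Pearson correlation of Hilbert envelopes; strength
  |r|.  Cross-band AEC correlates the two bands' envelopes directly.
  Admissible codes 1–36.
* **iPLV (id 2)** — |Im mean exp(i(φ_a − φ_b))| on same-band phases;
  blind to zero-lag coupling by construction.  Codes 1–8.
* **PAC (id 3)** — the high-band envelope is re-filtered within the low
  band, Hilbert-phase extracted, and phase-locked (iPLV) against the
  other sensor's low-band phase; the pair-level value is the larger of
  the two directions.  Codes 9–36.
* **dSTE (id 4)** — transfer entropy between neural-gas symbol series,
  normalized by log k, scanned over a delay grid; direction is the larger
  best-delay TE and the net strength is |TE_ab − TE_ba| / max.
  Codes 1–36.
* **dPLI (id 5)** — mean Heaviside of the wrapped phase difference
  (H(0) = ½); 0.5 means no lead, and strength is 2|dPLI − ½|.  Cross-band
  dPLI uses the PAC-style envelope phase (an m:n phase mapping is not
  attempted).  Codes 1–36.

### dSTE parameters

Symbolization embeds each band-limited signal in 3 dimensions with a
band-adaptive lag of about a quarter period of the band's upper edge
(`max(1, round(fs/(4 f_hi)))`, at least one sample).  A fixed 1-sample
lag makes the embedded states of slow, heavily oversampled bands nearly
collinear and the transfer entropy vanishes even for a strongly planted
delayed copy; the adaptive lag is standard symbolization practice and is
config-exposed (`DsteConfig`).  One neural-gas codebook of k = 8
prototypes is trained per band, common across all channels and windows of
a recording, on a subsample of embedded state vectors; the neural gas
uses rank-based updates with exponentially annealed step size and
neighbourhood range, polished by a few batch (Lloyd) iterations, and
k = 1 returns the exact quantization-error minimizer (the mean).

In the windowed pipeline the delay per direction (grid 1–10 samples) and,
for cross-band codes, the channel-to-band assignment are selected **once
per pair** from the full-length symbol series and held fixed across
windows.  Selecting the delay per window by argmax makes the statistic
anti-conservative under surrogates that do not replicate the scan, and
replicating the scan for every surrogate is an order of magnitude more
expensive; fixing the parameters at the recording level removes the
per-window selection entirely, so the surrogate statistic is exactly the
observed statistic.  The standalone `dste()` estimator keeps the
per-call delay scan.

## Surrogate testing and mode selection

Surrogates circularly shift one channel of the pair over the **whole
recording** (random offset of at least one second, i.e. fs samples) and
re-window, so every surrogate window keeps its natural within-window
autocorrelation while cross-channel alignment is destroyed.  Shifting
within a 2-s window instead is degenerate (for a 2-s window the
admissible offset set collapses to a point) and introduces a wrap seam
that makes slow-drift statistics such as dPLI and δ-band AEC look
spuriously significant; this was verified empirically and motivated the
recording-level scheme.  The circular shift preserves each signal's
spectrum and envelope statistics, which makes it appropriate for all five
estimators.  Estimator-side selection steps (the PAC direction maximum,
the dSTE assignment) are replicated inside the surrogate statistic.

Two p-values are tracked per candidate.  The *raw surrogate proportion*
#{surr ≥ obs}/n_surr — which reaches 0 when the observation beats every
surrogate — drives both Benjamini–Hochberg FDR control (q = 0.01, applied
across the frequency candidates of each pair/window per estimator;
pooling across cells is config-switchable) and the stricter
multi-estimator threshold 0.01/4 = 0.0025.  The *add-one* estimator
(1 + #{surr ≥ obs})/(1 + n_surr), which can never be zero, is stored in
the result records and used for calibration checks.  The distinction
matters at practical surrogate counts: with n_surr in the hundreds the
add-one p-value is bounded below by ≈ 1/n_surr, above every BH step-up
threshold at q = 0.01 once a cell carries more than a handful of
candidates, and above 0.0025 always — the procedure would be
unconditionally empty.  The default n_surr is 200 for desk-scale work;
the config accepts up to 10,000.

Per cell (pair × window), each estimator contributes its max-strength
FDR-significant candidate.  A single significant estimator is kept
outright; with several, the bests are screened at 0.0025 and up to two
survivors are retained, smallest p first (ties broken by larger
strength).  Cells with nothing significant carry code 0.  Where two modes
coexist, the smaller-p record defines the cell's label for dominance
calls and the flexibility index, since those need a single label.
Degenerate windows (zero variance, or too short for the dSTE delay grid)
yield missing candidates and are excluded.

## Topological filtering (OMST)

The retained strengths of a window form a weighted graph (distance
d = 1/w).  Edge-disjoint minimum spanning trees are extracted iteratively;
after the m-th tree the objective J_m = GE_m − Cost_m is evaluated, where
GE is the mean inverse shortest-path distance over all node pairs of the
selected union (unreachable pairs contribute zero) and Cost is the
selected weight over the total weight.  The union maximizing J is kept
and pruned cells are reset to code 0.  Extraction is per connected
component of the original graph (spanning trees are undefined otherwise)
and stops when the remaining edges can no longer span a component.
Filtering runs per window, consistent with the dynamic character of the
analysis, and can be bypassed (`apply_omst=False`); it is skipped for
two-channel recordings where it cannot remove anything.

## Lobar aggregation

Sensors map to ten lobe-hemisphere groups (frontal, temporal, parietal,
parieto-occipital, occipital × L/R).  The packaged maps for the
248-sensor and 275-sensor arrays are deterministic block partitions with
plausible lobar proportions, shipped as editable YAML — explicitly
approximate, since no published per-sensor assignment exists.

A mode dominates a lobar block when more than 75 % of the block's sensor
pairs display it within a segment (strict inequality) and such segments
make up at least half of all segments.  MSS averages, over the dominant
segments, the block's retained strengths normalized by the block's pair
count; FO is N_Dom/N_TS.  Either retained record of a cell counts as
displaying a mode.  Within-hemisphere variants use the pairs internal to
a lobe's sensors (no self-pairs); "within and cross-hemispheric" rows use
all pairs between the two lobes.  The packaged 12-row subnetwork table
fixes band-label ambiguities by convention: γ sub-bands map to the single
30–45 Hz γ band and a bare "β" maps to β₂ (15–19 Hz).  Two rows carry no
FO (within-sensor associations), giving 12 MSS + 10 FO = 22 features.

The flexibility index counts label changes between consecutive segments
per pair, divided by T − 1, averaged over pairs.  Transitions into or out
of "no coupling" count as changes — the change rate is read literally.
FI depends only on label identity, so it is invariant to any relabeling.

## Synthetic data

The generator's purpose is statistical, not biophysical: recordings whose
coupling content is known exactly.  Each channel carries an independent
mixture of the eight band noises with 1/√f amplitude weights (a 1/f-like
spectrum).  Band noise is synthesized in the frequency domain (random
phases on in-band bins), so planted band power is exact.  Plan entries
superimpose:

* **iPLV** — a shared band-limited oscillation with a constant phase lag
  (default π/2);
* **dPLI** — a shared oscillation with a small sample delay;
* **AEC** — constant-envelope carriers multiplied by positive envelopes
  built from a shared slow modulator mixed at the planted correlation;
* **PAC** — a constant-envelope high-band carrier multiplied by
  1 − d + d(1 + cos(φ_low − ψ))/2 with depth d and a quadrature offset
  ψ = π/2 by default.  The offset represents a propagation lag and is a
  deliberate choice: strictly zero-lag modulation is invisible to an
  imaginary-part phase-locking detector, exactly as zero-lag phase
  coupling is invisible to iPLV;
* **dSTE** — a delayed noisy copy of the source's band component
  (within-band) or a delayed-phase modulation of a high-band carrier
  (cross-band).

Carriers for the multiplicative modes are constant-envelope (cosine of
the Hilbert phase of band noise, confined to the middle third of the
band) so that the planted envelope is imposed exactly and the modulation
sidebands stay inside the band filter.  The planted-to-background
amplitude ratio defaults to 8 (`CouplingEntry.snr`): a planted mode is
meant to *dominate* its band, and the graded dial is the `strength`
parameter, which scales the injection (additive modes), the envelope
correlation (AEC) or the modulation depth (PAC).  Estimated coupling
rises monotonically with planted strength.

Regime switching alternates whole coupling plans every `dwell_s` seconds
(which must cover at least one analysis window).  Cohorts follow
FI = a·age² + b·age + c with Gaussian noise clamped to [0, 1]; the
default curve (−0.0002, 0.016, 0.1) peaks at age 40, the default noise
is σ = 0.02, and ages are drawn from six bins (8–12, 13–17, 18–27,
28–37, 38–50, 51–60 years) with sizes proportional to a 178-participant
reference cohort (24/26/43/43/28/14).  Feature vectors for classifier
experiments are Gaussian with per-age-group mean shifts in sd units.
The fast path samples FI and features directly; recordings are generated
only where the pipeline itself is under test.

What the generator does **not** emulate: volume conduction and field
spread, sensor noise covariance of real arrays, non-stationary artifact
structure, 1/f exponents varying by region, or realistic source-level
geometry.  Passing tests therefore demonstrate the correctness and
calibration of the analysis chain on its own statistical assumptions,
not performance on real neuromagnetic data; the original cohort results
(classification accuracy near 89 %, FI–age r² ≈ 0.88) require the actual
178-participant dataset and are not reproducible here.

## Age and group modeling

Five FI–age families are fitted by least squares: linear, quadratic,
log (a·ln(age) + b), exponential (a·e^{b·age} + c) and Von Bertalanffy
(A(1 − e^{−k(age−t₀)})), compared by AIC = n·ln(RSS/n) + 2·#params;
non-converging families are excluded with a warning.  The winner's r² is
permutation-tested by age shuffles (add-one p; 500–1000 permutations
typical).  Classification uses z-scored features and a linear one-vs-one
SVM — chosen for a 22-feature, small-n setting where linear weights stay
interpretable — with stratified 5-fold splits repeated over reshuffles to
report mean ± sd, or leave-one-out; regression uses linear SVR with the
cost parameter selected per outer fold by an inner 3-fold grid search,
reporting out-of-fold R² (degenerate fits are reported as 0 with a
flag).  Group FI contrasts use the two-sided Wilcoxon rank-sum test.

## Baseline measures

Relative power uses Welch estimates (2-s segments, 50 % overlap) with
rectangular bin summation over each half-open band, normalized by total
0.5–45 Hz power — rectangular rather than trapezoid so adjacent bands
tile the axis without halving edge bins.  Imaginary coherence is the
cross-power-weighted band average of |Im coherency|, insensitive to
zero-lag mixing.  Multiscale entropy coarse-grains by non-overlapping
means and computes sample entropy with m = 2 and tolerance r = 0.2 × the
original signal's sd at every scale (the literature defaults,
config-exposed); a constant signal has entropy 0 by convention.

## Numerical and scale choices

Desk-scale defaults keep the full chain runnable on one CPU in minutes:
200 surrogates, recordings of 12–36 s with 2–4 channels for pipeline
tests, 100-replicate cohort simulations.  The evaluation module states
the problem size alongside every quantity it reports.  Determinism: all
randomness flows through numpy Generators seeded explicitly; fixed seeds
give bit-identical recordings, codebooks, surrogate draws and mode
tensors.

Known limitations: truncated tail windows bias estimators at short
durations (documented above); symbolic TE carries little information in
slow bands within 2-s windows even with the adaptive lag; the packaged
lobar maps are approximate; cross-band dPLI shares its carrier with PAC
and therefore flags the same planted phase relations — a genuine property
of the estimator pair, visible in the worked example.
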