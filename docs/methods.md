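# Methods

## Scope

The package quantifies, per trial and per behavioral session, (i) the
CS-evoked normalized LFP power in canonical bands and (ii) the strength and
lag of PL–IL coupling as the peak normalized cross-correlation coefficient,
for two-channel recordings organized into the 5-day discriminative auditory
fear conditioning (DAFC) protocol.  Group inference beyond a permutation
contrast (ANOVA-style models) is deliberately out of scope: the permutation
test on session blocks is the package's self-contained alternative and is
labeled as such in outputs.

## Synthetic data model

Each region's signal is a sum of independent stationary processes, in
microvolts at 1 kHz by default:

* **Background**: 1/f^β Gaussian noise (β = 1, RMS 15 µV), shaped in the
  frequency domain and rescaled to the requested RMS exactly.
* **Band components**: brick-wall band-filtered Gaussian noise in theta
  (4–10 Hz), slow gamma (30–55 Hz) and fast gamma (55–100 Hz), scaled so a
  component of "amplitude" A has RMS A/√2 (the RMS of a sinusoid of
  amplitude A).  Defaults: theta 60 µV, slow gamma 25 µV, fast gamma 15 µV.
  Band-filtered noise was chosen over a drifting sinusoid because it is
  stationary with analytically known power, so evoked-power and coupling
  recoveries have closed-form targets; a pure sinusoid can be injected
  through the public generator for exact closed-form tests.
* **CS-evoked gains**: during each 30-s CS window the designated region ×
  band component is multiplied by the configured gain, with 200 ms
  raised-cosine ramps at on/offset to avoid spectral splatter.  The gain is
  constant across the CS window (the protocol analyses found no
  early/middle/late differences within the CS, so no within-CS dynamics are
  modeled).
* **Coupling**: inside a CS window with coupling coefficient c the IL theta
  component is c · (lag-shifted, unit-variance PL theta) + √(1−c²) ·
  (independent theta), so the theoretical peak correlation of the noiseless
  components is c and total variance is preserved.  Outside CS windows the
  two theta components are independent (c = 0); the coefficient follows the
  same 200-ms ramps.  Gamma components are always independent between
  regions.  The configured lag is defined operationally: it is the lag at
  which the pipeline's PL→IL cross-correlation peaks (positive = PL must be
  advanced to align with IL).  Default lag 10 ms, a plausible mono-/
  di-synaptic cortico-cortical delay.

The default effect tables encode the qualitative state pattern the analysis
is meant to detect: PL theta amplitude gain 1.5 in acquisition and renewal
(one shared "high fear" level) and 0.8 in late extinction; IL theta 1.5 in
late extinction and 0.7 in renewal; CS+ coupling 0.52 in acquisition, both
extinction days and extinction recall, 0.25 in habituation, 0.32 in
renewal; CS− coupling 0.25 throughout; all other gains 1.  The high/low
coupling levels mirror the representative recorded peaks (≈ 0.52 extinction
recall vs ≈ 0.32 renewal).  Sessions between which no ordering is actually
reported share one injected value, so that recovery checks only constrain
genuinely ordered pairs; encoding unclaimed hair-thin differences (e.g.
acquisition 1.6 vs renewal 1.5) would turn the ordering check into a coin
flip at realistic trial counts without testing anything the experiment
established.

In the state-pattern recovery check, cells with no injected change (all
gamma cells, all CS− cells) must keep their session-mean ratio inside a
null window, by default (0.75, 1.35): the widest window that still excludes
every injected effect (nearest: 0.8² = 0.64, 1.5² = 2.25).  At 20 trials
the session-mean theta ratio has SD ≈ 0.05 and a small upward Jensen bias
(≈ +0.03, from the estimated pre-CS power in the denominator), so the
window leaves a ≥ 5σ margin for true nulls while any injected effect sits
far outside it.

Protocol structure: sessions Hab 5/5 (context A), ACQ 5/5 with the US
co-terminating each CS+ pip train, EXT1 and EXT2 12/12 (context B),
EXT_recall 2/2 (B), Renewal 2/2 (A); 30-s CS of twenty 500-ms pips at
1.5 Hz; inter-trial intervals uniform in 90–120 s; 180 s of free
exploration before the first trial; CS+/CS− order is a constrained shuffle
with at most three consecutive same-type trials.  Every draw comes from a
single seeded generator, so a fixed (config, plan, seed) triple produces a
byte-identical dataset.

**What the simulator does not emulate**: non-stationary background (drift,
movement artifacts except when injected explicitly), volume conduction,
cross-frequency coupling, within-CS power dynamics, per-animal
heterogeneity, and any spiking structure.  A green recovery test therefore
establishes that the pipeline measures what was injected under stationary
Gaussian assumptions — not that the biological effects exist.

The per-trial freezing generator is presentation plumbing only: a clipped
noisy linear function of the injected PL theta gain (baseline 10%, slope
55 %/gain-unit, SD 5%), standing in for human-scored behavior in demo
tables.

## Filtering

The bandpass filters are linear-phase FIRs specified by tolerances:
stopband attenuation ≥ 80 dB beyond 0.5 Hz transitions, passband ripple
≤ 1 dB.  The design is a Kaiser window sized from the attenuation and
transition width with a 5 dB over-design margin, then verified against the
spec on a 2^18-point frequency response; design fails loudly if either
constraint is missed.  An equiripple (Parks–McClellan) design was rejected:
at a 0.5 Hz transition and 1 kHz sampling the required order is ≈ 10⁴ taps,
beyond what the exchange algorithm handles reliably, while the Kaiser
design meets the contract with ~0.001 dB measured ripple.  Taps are odd in
number and exactly symmetric.

Application is a single forward convolution on the reflection-padded signal
with the integer group delay (taps−1)/2 removed, so in-band components come
out time-aligned with the input (verified to ±1 sample) and windows are
never time-shifted between regions.  Signals must be longer than 3× the
filter; at 1 kHz the filters are ≈ 10.7 s long, so filtering is done on
whole sessions, never on extracted 15-s windows, and analyzed windows start
≥ 15 s into the session so reflection edge effects never reach them.

Artifact handling makes the unstated manual criterion explicit: a trial is
excluded when the robust z-score (session median/MAD, Gaussian-consistent
scaling 1.4826) of the raw signal exceeds 6 continuously for ≥ 50 ms inside
the trial's pre-CS or CS span; both parameters are configurable and every
exclusion is logged with its trigger time.

## Welch PSD and the evoked-power ratio

A window of n samples is split into 16 equal non-overlapping segments
(n // 16 samples each; the ≤ 15 trailing samples are dropped and the count
is logged — at 15 s / 1 kHz: 937-sample segments, 8 samples dropped,
≈ 1.07 Hz resolution).  Each segment is mean-subtracted (DC leakage would
otherwise bias theta at this resolution), Hann-windowed, and the averaged
periodogram is scaled as power/Hz with window-power normalization so
Parseval holds for white noise.  The evoked ratio sums the PSD of the
band-filtered signal over all bins, CS window over pre-CS window; summing
the broadband PSD restricted to band bins is available as
`power_mode: broadband_bins` and agrees with the filtered route within a
few percent on band-limited content.  The ratio is exactly
scale-invariant, so calibration errors in µV cannot bias results.  SEM of a
single-trial block is reported as 0.

## Cross-correlation coupling

The coefficient follows the raw-moment definition (no mean subtraction, no
per-lag edge correction): bandpassed signals are near-zero-mean, so the
Pearson-style variant (available as an option) nearly coincides, and at
N = 15 000 samples with |lag| ≤ 500 the triangular edge bias is < 3.5%.
Computation uses FFT correlation and equals the direct sum to ≈ 1e−10
relative.  "Instantaneous amplitude" is taken to be the band-filtered
samples themselves (what one feeds to a stock correlation routine); a
Hilbert-envelope mode is provided behind `amplitude_mode: envelope`.
Cross-correlation is computed per trial on the 15-s CS window (mirroring
the power analysis) rather than on session-concatenated signals; the
pre-CS window is selectable.  The default peak is the signed maximum over
±500 ms (≥ 2 theta cycles); exact ties break to the smallest |lag|, then
the negative lag.  Peak-picking over ~10³ lags has a small positive bias at
low coupling (order +0.03 at c = 0.25 for 15-s theta windows); recovery
checks therefore compare the measured peak against the same estimator run
on the noiseless ground-truth components, which carries the same bias.

## Pipeline

Stages communicate through files (dataset directory in, CSVs out) so any
stage can be rerun in isolation; outputs are written to a temporary
directory and renamed atomically, so a failed run leaves nothing partial.
The run log records the config snapshot, achieved filter characteristics,
every excluded trial with its reason, Welch segmentation details and
timings.  The permutation contrast reports the two-sided
p = (1 + #{|perm| ≥ |obs|}) / (n_perm + 1) over seeded label shuffles, with
p = 1 by convention when all values are identical.

## Performance choices

Simulation synthesizes at the next FFT-friendly length and truncates
(stationarity makes this harmless), draws only in-band spectral
coefficients for band noise, and assembles sessions in float32 (µV-scale
signals; analysis precision is set by the float64 filtering/PSD path in
tests).  The analysis batches all trial windows of a session into single
Welch calls, numerically identical to the per-trial path.  Monte-Carlo
recovery checks run at 500 Hz with inter-trial intervals shortened to the
minimum preserving the 15-s baselines: ratios and normalized correlations
are invariant to sampling rate and dead time, so this reduces compute, not
difficulty; single-run recovery checks stay at the default 1 kHz.

## Known limitations

* The brick-wall band components concentrate all their power inside the
  analysis bands, so evoked-power recovery is easier than for real LFPs
  whose "theta" leaks beyond 4–10 Hz; the pink-noise floor only partially
  compensates.
* The coupling model is instantaneous mixing at a fixed lag; real coupling
  is frequency-dependent and time-varying.
* Artifact detection sees only sustained amplitude excursions; realistic
  chewing/grooming artifacts with band-limited structure may pass.
* Whether recorded "instantaneous amplitudes" means filtered samples or
  Hilbert envelopes is ambiguous; both are implemented, results can differ,
  and the default (filtered samples) is the documented choice.
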