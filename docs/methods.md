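# Methods

## Model

spectrank treats a digital signal s of even length 2N as a vector whose
unnormalized DFT, ŝ_k = Σ_i s_i e^(−2πi·ik/2N), is conjugate-symmetric.
The first N squared moduli form the power estimates Ps on the normalized
angular-frequency grid, the k-th (1-based) grid point at (k−1)π/N. With
this convention Parseval's identity reads Σ_{k=0}^{2N−1}|ŝ_k|² = 2N·Σ s_i²;
the half spectrum omits the conjugate half and the Nyquist bin, so the
often-quoted "half the energy" relation is exact only for signals with zero
DC and zero Nyquist energy — the test suite asserts the exact budget, and
the factor-1/2 form only in that special case. No taper is applied; the
descriptors depend only on the *ranks* of the power values, which any
monotone rescaling of the spectrum preserves, so calibration constants and
units are immaterial.

Ranking the N power values in descending order defines a permutation:
sigma maps grid location to intensity rank, its inverse maps rank r to the
grid location of the r-th strongest component. All structure extraction
operates on the inverse sequence:

- CiD = circular total variation of the inverse sequence, divided by its
  length. The wrap-around term closes the path, which makes CiD invariant
  under cyclic rotations of the rank sequence but not under arbitrary
  permutations.
- CoD = mean absolute displacement of the inverse sequence from the
  identity (the "perfectly ordered" spectrum).
- The rank-distance matrix M[r][s] = |inv(r) − inv(s)| is symmetric with
  zero diagonal; its eigenvalues (sorted by signed value, descending) sum
  to zero and their partial sums are exposed as a structural summary. The
  matrix is indexed by rank; under grid indexing the entry multiset, and
  hence the eigenvalue spectrum, is identical up to a symmetric
  permutation.

Spectral entropy (natural log; optional division by ln N) is computed
alongside as the permutation-invariant reference quantity the descriptors
are designed to complement: spectra sharing a rank vector have identical
CiD/CoD at any entropy between ~0 (line-like) and ~ln N (flat), while
rearranging a fixed value multiset moves CiD/CoD at exactly constant
entropy.

## Conventions and edge cases

- **Indexing.** Arrays are 0-based internally; rank and grid *values* are
  1-based, matching the k = 1..N grid. The boundary is the rank-vector
  construction.
- **Ties.** Exactly equal power values are ranked by lower grid index
  (stable sort) and the number of tie groups is propagated into results
  with a warning: heavily quantized or clipped inputs produce rank vectors
  that are artifacts of the tie-break, and callers should know.
- **DC.** The DC bin is part of the grid by default. `demean=True`
  subtracts the sample mean (and pins the DC power to exactly 0), which is
  the default in the windowed tracker because physiological offsets
  otherwise hand rank 1 to DC in every window.
- **Energy threshold.** L is the smallest number of top-ranked components
  whose powers sum to ≥ q·total (q ∈ (0,1], default 0.9 in the monitoring
  paths, 1.0 in one-shot analysis). Retained locations stay on the
  original grid 1..N and the descriptor normalization becomes 1/L; CoD
  still compares location inv(i) against rank index i. Components of
  exactly zero power are never retained — even at q = 1 they contribute
  nothing to any partial sum — so a demeaned spectrum keeps N−1 components.
  A relative tolerance of 1e−12 on the cumulative-energy comparison
  absorbs summation round-off. If L = 1, CiD is undefined and reported as
  NaN with a warning.

## Null models

Under no prior knowledge all N! rank arrangements are equally likely. For
N ≤ 8 the null is enumerated exactly (integer numerators, rational means:
E[CiD] = (N+1)/3 from E|X−Y| = (N+1)/3 for distinct uniform pairs;
E[CoD] = (N²−1)/(3N) from E Σ|π(i)−i| = (N²−1)/3). Larger N uses seeded
Monte Carlo with an unbiased shuffle; the default 64,000 replicates keep a
standard error of the mean near 0.007 at N = 64 while running in well
under a second. The near-normality of the bounded-support null is reported
(moment-matched fit, Q–Q correlation ≈ 0.9998 at N = 64) rather than
assumed; empirical tail probabilities use the samples or the exact table.
The minimum-sample guard for the normal fit applies to Monte Carlo nulls
only; exhaustive tables may be arbitrarily small, and a point-mass null
(e.g. N = 3 CiD, where the circular variation is constant) reports sd = 0
with an undefined Q–Q correlation.

## Monitoring

`windowed.track` slides a rectangular, right-aligned window (default
length 1024, step 128, matching common speech framing at these rates) and
reports, per window: CiD/CoD at threshold q, full-spectrum entropy, local
energy LE = population standard deviation of the window samples, and the
monitoring value log10(1+LE)/log10(Descriptor). The value is undefined for
descriptors ≤ 1 and emitted as NaN so downstream plots show gaps instead
of fabricated values. Times are window-end indices: the track is causal.
Decision rules (thresholds for endpoint or seizure calls) are deliberately
left to the caller; the package produces tracks.

`aeeg.to_aeeg` compresses a recording to two points per second: zero-phase
Butterworth band-pass (2–15 Hz, order 4 — the conventional aEEG band),
rectification, a 2 Hz zero-phase low-pass as envelope, then per-second max
(upper bound) and min (lower bound), dropping a trailing partial second.
This implements only the compression contract of clinical aEEG; asymmetric
filtering and semilogarithmic display compression are intentionally out of
scope, and all filter choices are keyword-exposed as non-canonical
defaults. `monitor_aeeg` then runs the windowed tracker on one bound
sequence (default upper) at 1 point/s, default window 128 and step 1, so
LE is the standard deviation of the last 128 trace points.

## Synthetic data

The generators define the conditions under which the package is validated:

- **flat/line spectrum families**: given any target rank arrangement and
  ε ∈ (0, 1/n²), the flat family places 1/n + (n−rank)·ε at each grid
  point (normalized), the line family places 1 − n(n−1)ε/2 at the rank-1
  location and (n+1−rank)·ε elsewhere. Both realize the target ranks
  exactly; their entropies approach ln n and 0 respectively as ε → 0.
- **multitone**: cosines at exact grid frequencies (bin g−1 for grid point
  g) with distinct amplitudes plus seeded white noise, so at zero noise
  each component occupies one bin and power ranks equal amplitude ranks.
  Grid point 1 is DC and carries double spectral weight.
- **burst_signal**: unit-variance Gaussian baseline with non-overlapping
  bursts. "Syllable" bursts are raised-cosine-enveloped harmonic stacks
  (fundamental rate/32, three harmonics, peak amplitude 6× the baseline
  SD) — a crude voiced-speech stand-in. "Seizure" bursts are 3 Hz
  rhythmic activity with a weak second harmonic at 3× the baseline SD,
  emulating high-amplitude ictal delta/theta. Ground-truth boundaries are
  returned with the signal.

These fixtures emulate controlled rank structure, stationary noise, and
abrupt regime changes. They do not emulate 1/f background spectra,
artifacts, electrode drift, or inter-subject variability, so passing tests
demonstrate correctness of the machinery and the qualitative
change-detection behaviour, not clinical performance on real EEG/EMG.

## Problem sizes and determinism

Exhaustive enumeration is capped at N = 8 (8! = 40,320 permutations);
brute-force cross-checks in the tests run N ≤ 7. Monte Carlo validation
uses N = 64 with 64,000 replicates. The monitoring acceptance checks use a
noise/tone recording of 2 × 4096 samples at 8 kHz and, for the aEEG path,
a seeded one-hour 256 Hz recording (tests use a 15-minute 64 Hz version)
with a 40 s seizure burst; onset is flagged when the monitoring value
departs from its pre-burst mean by more than three baseline standard
deviations, which the fixtures exceed by two orders of magnitude. All
randomness flows through explicit integer seeds (numpy `default_rng`);
identical seeds give byte-identical JSON outputs.

## Known limitations

- Descriptors are rank-based and therefore sensitive to noise in the weak
  tail of the spectrum; the q-threshold mitigates but does not remove
  this, and it sacrifices the strict full-spectrum invariants (e.g. the
  CiD lower bound tightens to the prefix form 2(L−1)/L).
- Tie handling makes results deterministic but arbitrary on heavily
  quantized data; monitor the tie counters.
- The aEEG stage is a simplified envelope compressor, not a clinically
  validated pipeline.
- No group-comparison statistics are bundled; descriptor outputs are plain
  arrays/DataFrames intended for downstream tests of the user's choice.
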