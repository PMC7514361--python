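# spectrank

Rank-order structure of signal power spectra for physiological time-series
analysis.

## The problem

Spectral entropy — the Shannon entropy of a power spectrum renormalized to a
probability vector — is a workhorse irregularity feature for EEG, EMG and
speech. But it is *permutation-invariant*: shuffle the power values across
the frequency grid and the entropy does not move, even though the signals
those spectra describe look completely different. The arrangement of power
over frequency ("which intensities live next to each other") carries
information that entropy erases.

spectrank extracts that arrangement. For a real signal of even length 2N it
takes the unnormalized DFT, keeps the first N squared moduli as the power
estimates Ps on the normalized grid [0, π), and ranks them in descending
order. Writing σ⁻¹(i) for the grid location of the i-th largest component,
two scalar descriptors summarize the permutation:

- **CiD** (circular difference descriptor) — the normalized circular total
  variation of the locations across adjacent intensity ranks:

      CiD_N = (1/N) · ( |σ⁻¹(N) − σ⁻¹(1)| + Σ_{i=1}^{N−1} |σ⁻¹(i) − σ⁻¹(i+1)| )

  Small when similar intensities cluster at nearby frequencies; invariant
  under cyclic rotation of the rank sequence; bounded by
  2(N−1)/N ≤ CiD ≤ ⌊N²/2⌋/N.

- **CoD** (correspondence difference descriptor) — the normalized 1-norm
  distance from the perfectly ordered spectrum:

      CoD_N = (1/N) · Σ_{i=1}^{N} |σ⁻¹(i) − i|

  Zero when the k-th largest component sits at the k-th grid point; maximal
  (⌊N²/2⌋/N) at the reversal.

Around the descriptors the package provides the rank-distance matrix
M_rs = |σ⁻¹(r) − σ⁻¹(s)| and its eigen-analysis, exact and Monte Carlo
permutation null models (E[CiD_N] = (N+1)/3, E[CoD_N] = (N²−1)/(3N)),
energy-thresholded variants that keep only the L top components carrying a
fraction q of total energy, sliding-window monitoring tracks with the value
log10(1+LE)/log10(Descriptor) (LE = window standard deviation), and an
amplitude-integrated EEG (aEEG)-style per-second envelope compression as a
substrate for long-term seizure monitoring.

## Worked example

```python
import numpy as np
from spectrank import (Signal, power_spectrum, describe,
                       monte_carlo_null, z_score)

# two tones close in frequency + weak noise, 2N = 128 samples
rng = np.random.default_rng(0)
i = np.arange(128)
x = (np.cos(2*np.pi*10*i/128) + 0.5*np.cos(2*np.pi*12*i/128)
     + 0.05*rng.normal(size=128))
ps = power_spectrum(Signal(x, rate=128.0), demean=True)

result = describe(ps, q=0.9)
print(result.cid, result.cod, result.n_used, result.n_total)
# 2.0 10.5 2 64

null = monte_carlo_null(64, "cid", reps=64_000, seed=1)
print(round(null.mean, 3), round(z_score(result.cid, null), 2))
# 21.654 -11.87
```

The energy threshold q = 0.9 keeps the L = 2 tone bins (grid points 11 and
13): CiD = (|13−11| + |11−13|)/2 = 2.0, far below the random-permutation
null mean ≈ 21.7 at N = 64 (z ≈ −11.9): the spectrum's order structure is
strongly non-random, while spectral entropy alone could not distinguish
this arrangement from the same two powers placed at opposite ends of the
grid.

The CLI wraps the same pipeline:

```sh
spectrank analyze recording.csv --q 0.9 -o result.json
spectrank track speech.wav --window 1024 --step 128 --q 0.9 -o track.csv
spectrank null --n 64 --reps 64000 --seed 1 -o null.json
spectrank synth burst --total-s 60 --burst 20:24:seizure -o fixture.csv
spectrank aeeg eeg.csv --window 128 --step 1 --trace-out trace.csv --track-out monitor.csv
```

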