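# Methods

`spikecodec` studies how much an implanted wireless neural interface can
compress extracellular spike waveforms before spike reconstruction and spike
sorting degrade. Everything runs on simulated recordings with known ground
truth, so both accuracies can be scored exactly.

## Ground-truth recording simulator

**Geometry.** A linear array of 19 electrode sites spaced 50 µm along the
z-axis (spacing configurable; single-site analyses use the central site).
Four *target* units sit near the array at (10,20,−2), (−2,18,20),
(−20,−5,−10) and (16,−13,15) µm; the medium- and low-SNR conditions multiply
these coordinates by 1.5 and 2.0, moving the units from ≈20 to ≈30 and ≈40 µm
planar distance. *Noise* units are placed uniformly at random inside a hollow
cylinder around the axis (inner radius 120 µm, outer 250 µm, half-height
450 µm; density 3×10⁵ /cm³ by default, giving ≈40 units).

**Waveforms.** Each unit's extracellular signature is a parametric template:
a difference of gamma-shaped lobes (sharp main deflection plus an
opposite-sign rebound), optionally preceded by a small leading lobe, sampled
over 64 points (2.56 ms at 25 kHz). The shape is distance-invariant and the
amplitude decays as 1/r from the soma (point-source approximation) from a
reference amplitude at 20 µm. The four target parameter sets are fixed and
chosen to behave like four distinct, sortable single units whose leading
lobes sit near the amplitude-detection threshold — this reproduces *detection
jitter*: with noise, individual spikes cross the threshold sometimes on the
leading lobe and sometimes on the main deflection. Dominant lobes are kept
unambiguous (≥2× any other lobe) so maximum-amplitude alignment has a stable
landmark.

**Firing and noise.** Inter-spike intervals are gamma distributed (shape 2 by
default) with a 1 ms refractory floor; target rates are uniform on
[1, 10] spikes/s, noise-unit rates on [1, 50] spikes/s. Channels are the
superposition of all unit templates at their spike times plus white Gaussian
thermal noise (SD 1.05 in raw units), then zero-phase 4th-order Butterworth
bandpass filtered to 300 Hz–5 kHz. Per-unit spike-train seeds derive from the
unit's identity, so synthesis is exactly additive over neuron sets.

**SNR.** For a unit at a site, SNR = peak-to-peak amplitude of its mean
measured waveform divided by the median-based noise SD estimate
σₙ = median(|x|)/0.6745; the reported figure is the mean over the four
target units. The defaults land at ≈10 / ≈7 / ≈5 for the three conditions.
Because the 1/r decay ties the low condition to exactly half the high
condition (20 vs 40 µm), the three regimes cannot be spread further apart
without changing the decay law; what matters for the studies is that they
are clearly separated and monotone.

## Detection and jitter emulation

Two detectors: **ABS** thresholds |x[n]| at k·σₙ (k = 4), and **NEO**
thresholds ψ[n] = x[n]² − x[n−1]·x[n+1] at C·mean(ψ) (C = 8). Both constants
are configurable. To keep sorting scores uncontaminated by false positives,
waveforms are extracted at the *true* spike times and detection jitter is
injected afterwards: each window's first threshold crossing is located on an
8× (200 kHz) upsampled grid; windows that never cross are dropped; crossing
times more than 1.5 SD from the modal time are dropped as outliers (these
are typically overlaps); survivors are shifted with band-limited
fractional-delay filters so every crossing lands on the modal time. The
outlier SD is computed over all crossing spikes.

## Alignment

Spikes are aligned on the maximum absolute amplitude inside a 13-sample
(≈0.5 ms) window after the detection time, the peak being moved to sample 16
of the 64-sample window. *External* alignment (architectures 0 and 2)
locates the peak at 200 kHz resolution and applies a fractional shift;
*implant* alignment (architecture 3) uses integer shifts only. Ties break
toward the earlier sample.

## Transform coding

With spikes as columns of X (64×N), the codec computes A = WᵀX and keeps
L coefficients through a row-selection matrix E: C = E·A; the receiver
reconstructs X̂ = W·Eᵀ·C. Bases:

- **optimal** — left singular vectors of X itself (recomputed per
  configuration; the reference case);
- **fixed1** — SVD of a library of model-unit waveforms evaluated at random
  points 15–60 µm around each target unit with small (±8%) jitter on the
  template time constants (10,000 points/unit by default; the bundled
  workbench helper uses 2,000/unit);
- **fixed2** — SVD of the *generic* surrogate library: 400 waveforms from an
  asymmetric-Gaussian-lobe family (main lobe with independent left/right
  widths, rebound, optional leading lobe, 20% positive polarity), generated
  deterministically from a frozen (version, seed) pair. The family is
  intentionally a different parametric class from the simulator's
  gamma-lobe templates, so this basis is unrelated to the data it
  compresses;
- **downsample** — identity basis keeping every D-th sample, D = round(64/L),
  no antialiasing before decimation; reconstruction is followed by ideal
  frequency-domain lowpass interpolation at fs/(2D) (bin at exactly the
  cutoff half-weighted). When D does not divide 64 the kept count can differ
  from L; the actual count is recorded;
- **haar** — orthonormal discrete Haar matrix, coarse scales first, keeping
  the first L coefficients without optimization.

SVD and PCA column signs follow a fixed convention (largest-magnitude element
positive) so bases and features are bit-reproducible. Optional uniform
mid-rise quantization (10 bits by default) exists for rate realism and is off
in the studies; at 10 bits it changes reconstruction accuracy by <0.005.

## Architectures

- **0** — extract → transmit raw → external alignment → sort (reference);
- **1** — extract → compress on the implant → reconstruct → sort;
- **2** — architecture 1 plus external alignment before sorting;
- **3** — extract → implant (integer) alignment → compress → reconstruct →
  sort.

## Scoring

Reconstruction accuracy A_rec is the lag-maximized normalized
cross-correlation between each (reconstructed) spike and its own unit's
noiseless bandpassed template, averaged over spikes. Sorting uses the first
three PCA weights of the reconstructed spikes and K-means (K = 4, 10
restarts, k-means++); A_sort is the fraction of spikes correct under the
best cluster→unit mapping (exhaustive over permutations for K ≤ 6, Hungarian
assignment otherwise). The combined score is (A_rec + A_sort)/2 — the
simplest symmetric combination mapping [0,1]² onto [0,1]; a product variant
can be swapped in. The *effective minimum number of coefficients* is the
smallest integer L whose cubic-spline-interpolated score is within 0.01 of
the maximum measured score (the reference maximum is taken from the measured
values because cubic splines can overshoot between knots). Group medians are
compared with bootstrap (2,000 resamples) 95% percentile intervals of the
median; disjoint intervals count as significant.

## Complexity and data-rate models

One operation = a one-bit addition; 10-bit words make an addition cost 10
operations and a multiplication 100. The detection statistic runs every
sample (ABS: one comparison; NEO: two multiplications, one subtraction, one
comparison) at 25 kHz; implant alignment (architecture 3) costs one
comparison per sample of the 13-sample search window per spike; compression
costs 64 multiplications and 63 additions per transmitted coefficient.
Per-spike stages are charged at 40 spikes/s (4 units × 10 spikes/s), and the
total is reported per spike per transmitted dimension. Under this accounting
NEO + architecture 1 costs ≈11× ABS + architecture 3 — the detector
dominates the budget. Data-rate accounting is closed-form: L coefficients ×
10 bits against 64 samples × 10 bits per spike, and 25 kHz × 10 bits for raw
streaming; the computed reduction at L = 4 is 99.36% (1.6 kbps vs 250 kbps
per channel).

## Problem sizes used in tests and the acceptance script

Studies run on 60 s single-site recordings (the package's default study
length), 9–12 recordings per comparison, with the fixed bases built from
2,000 model points per unit and the 400-waveform generic library. The
determinism check runs the full 456-configuration grid on 10 s recordings.

## What the simulator does and does not show

The generator reproduces the mechanisms that drive the architecture
comparison: amplitude-threshold detection jitter, alignment-landmark
stability, SVD coefficient-energy ordering, and the SNR dependence of
sorting. It does not model overlapping-spike resolution, bursting,
electrode drift, position-dependent waveform *shape* (only amplitude decays
with distance), LFPs beyond summed distant-unit activity, or electrode
impedance. Two consequences are worth knowing. First, passing tests show the
pipeline's relative orderings under these conditions, not absolute accuracy
on real tissue. Second, transform coding with a fixed basis itself absorbs
part of the detection jitter (a shifted minority mode reconstructs toward
the basis's registration), so the unaligned ABS architecture 1 performs as
well as the aligned ones here, whereas recordings with more similar units
would show a clearer benefit of alignment; the corresponding property tests
therefore assert non-inferiority rather than a strict ordering.

## Numerical choices

Fractional delays are exact index shifts for integer delays and
frequency-domain phase ramps on 4×-zero-padded copies otherwise; window
edges zero-pad. Threshold crossings are refined by Fourier resampling.
Alignment ties break earlier; degenerate inputs (empty spike sets,
zero-energy templates, zero noise SD) raise or warn explicitly rather than
propagating NaNs.
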