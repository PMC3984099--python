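"""Spike detection (absolute-value and nonlinear-energy-operator thresholds)
and ground-truth-anchored waveform extraction with detection jitter.

Two detectors are supported:

* ABS — threshold ``k * sigma_n`` on ``|x[n]|`` where ``sigma_n`` is the
  median-based noise SD estimate ``median(|x|)/0.6745``.
* NEO — threshold ``C * mean(psi)`` on the nonlinear energy operator
  ``psi[n] = x[n]^2 - x[n-1] x[n+1]``, which responds to simultaneous
  amplitude and frequency increases and therefore crosses closer to the spike
  peak, making detections largely self-aligning at high SNR.

To score sorting without contamination from false positives, waveforms are
extracted at the *true* spike times and detection jitter is injected
afterwards: each window's threshold-crossing time is measured on a 200 kHz
upsampled grid, windows that never cross are dropped, crossing-time outliers
(> 1.5 SD from the modal crossing) are dropped, and the survivors are shifted
with fractional-delay filters so that every crossing lands on the modal time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import signal

from .synthdata import Recording, SPIKE_LEN

UPSAMPLE_FACTOR = 8  # 25 kHz -> 200 kHz


@dataclass
class DetectorConfig:
    method: str = "abs"  # "abs" or "neo"
    abs_multiplier: float = 4.0
    neo_multiplier: float = 8.0
    spike_window: int = SPIKE_LEN
    pre_detection_samples: int = 16

    def __post_init__(self):
        self.method = self.method.lower()
        if self.method not in ("abs", "neo"):
            raise ValueError(f"unknown detector {self.method!r}")
        if self.abs_multiplier <= 0 or self.neo_multiplier <= 0:
            raise ValueError("threshold multipliers must be positive")


@dataclass
class SpikeMatrix:
    """Extracted spike waveforms, one column per spike."""

    waveforms: np.ndarray  # M x N
    detection_index: np.ndarray  # per-spike crossing sample within the window
    true_ids: np.ndarray  # per-spike neuron label (-1 if unknown)
    fs: float
    retained_mask: np.ndarray = field(default=None)  # over the pre-discard spikes

    def __post_init__(self):
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, float))
        if self.retained_mask is None:
            self.retained_mask = np.ones(self.waveforms.shape[1], dtype=bool)

    @property
    def n_spikes(self) -> int:
        return self.waveforms.shape[1]

    @property
    def window_len(self) -> int:
        return self.waveforms.shape[0]


def noise_sigma(x: np.ndarray) -> float:
    """Median-based noise SD estimate: ``median(|x|) / 0.6745``."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty signal")
    return float(np.median(np.abs(x)) / 0.6745)


def abs_threshold(sigma_n: float, k: float = 4.0) -> float:
    """ABS detection threshold ``k * sigma_n`` (applied to ``|x|``)."""
    if sigma_n < 0:
        raise ValueError("sigma_n must be non-negative")
    return k * sigma_n


def neo_transform(x: np.ndarray) -> np.ndarray:
    """Nonlinear energy operator ``psi[n] = x[n]^2 - x[n-1] x[n+1]``.

    Boundary samples (no two-sided neighbourhood) are set to zero.
    """
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("signal too short for the NEO (need >= 3 samples)")
    psi = np.zeros_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    return psi


def neo_threshold(psi: np.ndarray, C: float = 8.0) -> float:
    """NEO detection threshold ``C * mean(psi)``."""
    psi = np.asarray(psi)
    if psi.size == 0:
        raise ValueError("empty NEO sequence")
    return float(C * psi.mean())


def _detection_statistic(x: np.ndarray, config: DetectorConfig) -> tuple[np.ndarray, float]:
    """(statistic, threshold) pair for the configured detector."""
    if config.method == "abs":
        stat = np.abs(x)
        thr = abs_threshold(noise_sigma(x), config.abs_multiplier)
    else:
        stat = neo_transform(x)
        thr = neo_threshold(stat, config.neo_multiplier)
    return stat, thr


def detect_spikes(x: np.ndarray, config: DetectorConfig | None = None) -> np.ndarray:
    """Sample indices of rising-edge threshold crossings of the detection
    statistic, with a one-window lockout after each detection."""
    config = config or DetectorConfig()
    stat, thr = _detection_statistic(np.asarray(x, float), config)
    above = stat >= thr
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        rising = np.concatenate([[0], rising])
    detections = []
    last = -config.spike_window
    for idx in rising:
        if idx - last >= config.spike_window:
            detections.append(idx)
            last = idx
    return np.asarray(detections, dtype=int)


def _first_crossing_fine(stat_window: np.ndarray, thr: float, up: int = UPSAMPLE_FACTOR) -> int | None:
    """First index on the ``up``-times grid where the statistic crosses thr."""
    fine = signal.resample(stat_window, stat_window.size * up)
    hits = np.flatnonzero(fine >= thr)
    return int(hits[0]) if hits.size else None


def extract_true_windows(recording: Recording, channel: int) -> tuple[np.ndarray, np.ndarray]:
    """(M+2) x N windows at the true target spike times plus per-spike ids.

    One extra sample of context on each side supports the NEO at the window
    edges; callers trim to the central ``SPIKE_LEN`` samples.
    """
    x = recording.samples[channel]
    wins, ids = [], []
    for nid in recording.target_ids:
        starts = np.round(recording.true_spike_times[nid] * recording.fs).astype(int)
        for s in starts:
            if s - 1 < 0 or s + SPIKE_LEN + 1 > x.size:
                continue
            wins.append(x[s - 1 : s + SPIKE_LEN + 1])
            ids.append(nid)
    if not wins:
        return np.empty((SPIKE_LEN + 2, 0)), np.empty(0, int)
    return np.column_stack(wins), np.asarray(ids, int)


def extract_with_jitter(
    recording: Recording,
    channel: int,
    config: DetectorConfig | None = None,
    outlier_sd: float = 1.5,
) -> SpikeMatrix:
    """Extract ground-truth-anchored spikes and inject detection jitter.

    Windows that never cross the detector threshold are discarded; crossing
    times are measured at 200 kHz; spikes whose crossing deviates more than
    ``outlier_sd`` standard deviations from the modal crossing time are
    discarded as outliers (typically overlaps); the rest are fractionally
    shifted so all crossings coincide with the modal time, then returned at
    the native rate.
    """
    from .alignment import fractional_delay_shift

    config = config or DetectorConfig()
    x = recording.samples[channel]
    _, thr = _detection_statistic(x, config)

    wins_ctx, ids = extract_true_windows(recording, channel)
    n = wins_ctx.shape[1]
    if n == 0:
        warnings.warn("no spikes available for extraction")
        return SpikeMatrix(np.empty((SPIKE_LEN, 0)), np.empty(0, int), np.empty(0, int), recording.fs)

    crossings = np.full(n, -1)
    for j in range(n):
        w = wins_ctx[:, j]
        stat = np.abs(w[1:-1]) if config.method == "abs" else neo_transform(w)[1:-1]
        hit = _first_crossing_fine(stat, thr)
        if hit is not None:
            crossings[j] = hit

    crossed = crossings >= 0
    if not crossed.any():
        warnings.warn("no spikes crossed the detection threshold")
        return SpikeMatrix(
            np.empty((SPIKE_LEN, 0)), np.empty(0, int), np.empty(0, int), recording.fs,
            retained_mask=np.zeros(n, bool),
        )

    vals, counts = np.unique(crossings[crossed], return_counts=True)
    modal = int(vals[np.argmax(counts)])
    sd = float(crossings[crossed].std())
    keep = crossed & (np.abs(crossings - modal) <= outlier_sd * sd)

    kept_idx = np.flatnonzero(keep)
    waveforms = np.empty((SPIKE_LEN, kept_idx.size))
    for out_j, j in enumerate(kept_idx):
        delay = (modal - crossings[j]) / UPSAMPLE_FACTOR  # in native samples
        waveforms[:, out_j] = fractional_delay_shift(wins_ctx[1:-1, j], delay)

    det_idx = int(round(modal / UPSAMPLE_FACTOR))
    return SpikeMatrix(
        waveforms=waveforms,
        detection_index=np.full(kept_idx.size, det_idx),
        true_ids=ids[kept_idx],
        fs=recording.fs,
        retained_mask=keep,
    )
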