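"""Synthetic ground-truth extracellular recordings.

Emulates a 19-site linear microelectrode array recording from four nearby
"target" neurons embedded in a background of distant "noise" neurons placed
uniformly at random inside a hollow cylinder around the array axis.  Every
spike time and neuron identity is known, so downstream detection, compression
and sorting stages can be scored against ground truth.

The extracellular waveform of each neuron is a parametric biphasic template
(difference of two gamma-shaped lobes) whose amplitude falls off as 1/r from
the soma (point-source approximation); the template *shape* is distance
invariant.  Recordings are sampled at 25 kHz and zero-phase bandpass filtered
between 300 Hz and 5 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

FS_DEFAULT = 25_000.0
BAND_DEFAULT = (300.0, 5_000.0)
SPIKE_LEN = 64  # 2.56 ms at 25 kHz

#: Printed high-SNR target-neuron coordinates, micrometres.  The medium and
#: low SNR conditions scale these by 1.5 and 2.0.
TARGET_BASE_COORDS = np.array(
    [
        [10.0, 20.0, -2.0],
        [-2.0, 18.0, 20.0],
        [-20.0, -5.0, -10.0],
        [16.0, -13.0, 15.0],
    ]
)

#: SNR-condition labels mapped to coordinate multipliers.
SNR_SCALES = {"high": 1.0, "medium": 1.5, "low": 2.0}


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of the biphasic surrogate template.

    The template is ``polarity * amp_ref * (g1(t) - balance * g2(t))`` where
    ``g_i`` is a gamma-shaped lobe ``(t/t_peak)^(k-1) exp(...)`` normalised to
    unit peak.  ``amp_ref`` is the peak-to-peak amplitude (arbitrary units)
    observed at the reference distance ``r0_um``.
    """

    amp_ref: float = 8.0
    r0_um: float = 20.0
    k1: float = 3.0
    theta1_ms: float = 0.18
    k2: float = 4.0
    theta2_ms: float = 0.32
    balance: float = 0.65
    polarity: int = -1
    onset_ms: float = 0.3  # quiet lead-in before the first lobe
    lead: float = 0.0  # leading opposite-sign lobe, fraction of main lobe
    k0: float = 2.0
    theta0_ms: float = 0.05


@dataclass(frozen=True)
class NeuronSpec:
    position: np.ndarray  # 3-vector, micrometres
    waveform_params: WaveformParams
    mean_rate: float  # spikes / second
    gamma_shape: float = 2.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.mean_rate < 0:
            raise ValueError("mean_rate must be non-negative")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")


def default_electrode_positions(n_sites: int = 19, spacing_um: float = 50.0) -> np.ndarray:
    """Evenly spaced sites along the z axis, centred on the origin."""
    z = (np.arange(n_sites) - (n_sites - 1) / 2) * spacing_um
    pos = np.zeros((n_sites, 3))
    pos[:, 2] = z
    return pos


@dataclass
class GeometryConfig:
    """Array and noise-cylinder geometry.

    Noise neurons live in a hollow cylinder concentric with the array axis,
    with inner radius 120 um and outer radius 250 um.  ``snr_scale``
    multiplies the target-neuron coordinates (1.0 / 1.5 / 2.0 give the high /
    medium / low SNR conditions).
    """

    electrode_positions: np.ndarray = field(default_factory=default_electrode_positions)
    cylinder_inner_um: float = 120.0
    cylinder_outer_um: float = 250.0
    cylinder_halfheight_um: float = 450.0
    noise_density_per_cm3: float = 3.0e5
    snr_scale: float = 1.0

    def __post_init__(self):
        self.electrode_positions = np.atleast_2d(np.asarray(self.electrode_positions, float))
        if self.cylinder_inner_um >= self.cylinder_outer_um:
            raise ValueError("cylinder_inner_um must be < cylinder_outer_um")
        if self.cylinder_inner_um <= 0 or self.cylinder_halfheight_um <= 0:
            raise ValueError("cylinder bounds must be positive")
        if self.noise_density_per_cm3 < 0:
            raise ValueError("noise density must be non-negative")
        if self.snr_scale <= 0:
            raise ValueError("snr_scale must be positive")

    @property
    def cylinder_volume_cm3(self) -> float:
        um3_to_cm3 = 1e-12
        r_in, r_out = self.cylinder_inner_um, self.cylinder_outer_um
        h = 2 * self.cylinder_halfheight_um
        return float(np.pi * (r_out**2 - r_in**2) * h * um3_to_cm3)


@dataclass
class Recording:
    """Multi-channel synthetic recording plus its ground truth."""

    samples: np.ndarray  # channels x time
    fs: float
    true_spike_times: list[np.ndarray]  # seconds, one array per neuron
    neuron_ids: np.ndarray  # integer label per neuron (index into lists)
    templates: np.ndarray  # neurons x channels x SPIKE_LEN, bandpassed
    band: tuple[float, float]
    duration: float
    target_ids: np.ndarray  # which neuron ids are targets

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


# ---------------------------------------------------------------------------
# neuron placement


def place_noise_neurons(geometry: GeometryConfig, seed: int) -> list[NeuronSpec]:
    """Place noise neurons uniformly in the hollow cylindrical shell.

    The count is ``round(density * shell volume)``; positions are uniform in
    volume (radius sampled from the annular CDF); per-neuron mean rates are
    uniform on [1, 50] spikes/s.
    """
    if geometry.noise_density_per_cm3 <= 0:
        raise ValueError("noise density must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(geometry.noise_density_per_cm3 * geometry.cylinder_volume_cm3))
    r_in2 = geometry.cylinder_inner_um**2
    r_out2 = geometry.cylinder_outer_um**2
    # uniform in annular area: r = sqrt(U*(R^2-r^2)+r^2)
    r = np.sqrt(rng.uniform(r_in2, r_out2, size=n))
    phi = rng.uniform(0, 2 * np.pi, size=n)
    z = rng.uniform(-geometry.cylinder_halfheight_um, geometry.cylinder_halfheight_um, size=n)
    rates = rng.uniform(1.0, 50.0, size=n)
    neurons = []
    for i in range(n):
        params = WaveformParams(
            amp_ref=rng.uniform(4.0, 12.0),
            k1=rng.uniform(2.5, 3.5),
            theta1_ms=rng.uniform(0.12, 0.24),
            k2=rng.uniform(3.5, 4.5),
            theta2_ms=rng.uniform(0.26, 0.42),
            balance=rng.uniform(0.4, 0.9),
            polarity=-1 if rng.uniform() < 0.8 else 1,
        )
        pos = np.array([r[i] * np.cos(phi[i]), r[i] * np.sin(phi[i]), z[i]])
        neurons.append(NeuronSpec(pos, params, float(rates[i])))
    return neurons


#: Fixed per-neuron template parameters for the four target units.  Same
#: family (similar cell type), distinct time constants and balance so the
#: units are sortable but not trivially separable.
TARGET_WAVEFORM_PARAMS = (
    # narrow spike with a moderate rebound and a leading lobe
    WaveformParams(amp_ref=9.5, k1=2.4, theta1_ms=0.09, k2=3.2, theta2_ms=0.28, balance=0.35, polarity=-1, lead=0.55, theta0_ms=0.05),
    # broad spike, pronounced slow rebound, leading positive lobe
    WaveformParams(amp_ref=11.5, k1=3.0, theta1_ms=0.12, k2=4.5, theta2_ms=0.35, balance=0.70, polarity=-1, lead=0.20, theta0_ms=0.05),
    # positive-going spike with a leading negative lobe
    WaveformParams(amp_ref=8.5, k1=2.8, theta1_ms=0.11, k2=3.6, theta2_ms=0.20, balance=0.30, polarity=1, lead=0.58, theta0_ms=0.05),
    # medium-width, nearly monophasic spike with a leading lobe
    WaveformParams(amp_ref=9.0, k1=3.2, theta1_ms=0.105, k2=4.2, theta2_ms=0.18, balance=0.12, polarity=-1, lead=0.63, theta0_ms=0.05),
)


def place_target_neurons(
    base_coords: np.ndarray = TARGET_BASE_COORDS,
    snr_scale: float = 1.0,
    seed: int | None = None,
    waveform_params: tuple[WaveformParams, ...] = TARGET_WAVEFORM_PARAMS,
) -> list[NeuronSpec]:
    """Place the four target neurons at ``base_coords * snr_scale``.

    Mean firing rates are uniform on [1, 10] spikes/s (fixed ``seed`` for
    reproducibility).
    """
    base_coords = np.asarray(base_coords, float)
    if base_coords.shape != (len(waveform_params), 3):
        raise ValueError(
            f"expected {len(waveform_params)} coordinates, got shape {base_coords.shape}"
        )
    if snr_scale <= 0:
        raise ValueError("snr_scale must be positive")
    rng = np.random.default_rng(seed)
    rates = rng.uniform(1.0, 10.0, size=len(waveform_params))
    return [
        NeuronSpec(base_coords[i] * snr_scale, waveform_params[i], float(rates[i]))
        for i in range(len(waveform_params))
    ]


# ---------------------------------------------------------------------------
# spike trains and waveforms


def sample_spike_train(
    rate: float,
    gamma_shape: float = 2.0,
    duration: float = 60.0,
    refractory_floor: float = 1e-3,
    seed: int | None = None,
) -> np.ndarray:
    """Spike times with gamma-distributed inter-spike intervals.

    ISIs are gamma with shape ``gamma_shape`` and mean ``1/rate``, floored at
    ``refractory_floor``.  Returns strictly increasing times in [0, duration).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    scale = 1.0 / (rate * gamma_shape)
    # draw in blocks until past the end of the record
    times = []
    t = float(rng.uniform(0, 1.0 / rate))  # random phase for the first spike
    while t < duration:
        times.append(t)
        isi = max(rng.gamma(gamma_shape, scale), refractory_floor)
        t += isi
    return np.asarray(times)


def _gamma_lobe(t_ms: np.ndarray, k: float, theta_ms: float) -> np.ndarray:
    """Gamma-shaped lobe normalised to unit peak (peak at (k-1)*theta)."""
    x = np.maximum(t_ms, 0.0) / theta_ms
    lobe = x ** (k - 1) * np.exp(-x)
    peak = (k - 1) ** (k - 1) * np.exp(-(k - 1))
    return lobe / peak


def template_shape(params: WaveformParams, fs: float = FS_DEFAULT, window_len: int = SPIKE_LEN) -> np.ndarray:
    """Unit-scale biphasic template (peak-to-peak 1) for one neuron."""
    t_ms = np.arange(window_len) / fs * 1e3 - params.onset_ms
    w = _gamma_lobe(t_ms, params.k1, params.theta1_ms) - params.balance * _gamma_lobe(
        t_ms, params.k2, params.theta2_ms
    )
    if params.lead:
        w -= params.lead * _gamma_lobe(t_ms, params.k0, params.theta0_ms)
    w *= params.polarity
    ptp = w.max() - w.min()
    return w / ptp


def waveform_at_site(
    neuron: NeuronSpec,
    site: np.ndarray,
    fs: float = FS_DEFAULT,
    window_len: int = SPIKE_LEN,
) -> np.ndarray:
    """Noiseless template of ``neuron`` seen at electrode position ``site``.

    Point-source model: the shape is distance invariant and the peak-to-peak
    amplitude is ``amp_ref * (r0 / distance)``.
    """
    site = np.asarray(site, float)
    dist = float(np.linalg.norm(neuron.position - site))
    if dist == 0:
        raise ValueError("electrode site coincides with the neuron position")
    p = neuron.waveform_params
    amp = p.amp_ref * (p.r0_um / dist)
    return amp * template_shape(p, fs, window_len)


# ---------------------------------------------------------------------------
# recording synthesis


def _neuron_seed(base_seed: int, neuron: NeuronSpec) -> int:
    """Per-neuron spike-train seed derived from the neuron's identity, so
    synthesis is additive: simulating neuron sets separately and summing
    equals simulating their union (thermal noise aside)."""
    import zlib

    key = f"{np.round(neuron.position, 6).tolist()}|{neuron.mean_rate:.9f}|{neuron.waveform_params}"
    return int((base_seed + zlib.crc32(key.encode())) % (2**31))


def _bandpass_sos(fs: float, band: tuple[float, float], order: int = 4):
    return signal.butter(order, band, btype="bandpass", fs=fs, output="sos")


def bandpass_filter(x: np.ndarray, fs: float = FS_DEFAULT, band: tuple[float, float] = BAND_DEFAULT) -> np.ndarray:
    """Zero-phase 4th-order Butterworth bandpass along the last axis."""
    sos = _bandpass_sos(fs, band)
    return signal.sosfiltfilt(sos, x, axis=-1)


def _filtered_template(raw: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Bandpass a template embedded in a long zero record, re-windowed."""
    pad = 6 * SPIKE_LEN
    buf = np.zeros(raw.size + 2 * pad)
    buf[pad : pad + raw.size] = raw
    return bandpass_filter(buf, fs, band)[pad : pad + raw.size]


def synthesize_recording(
    geometry: GeometryConfig,
    targets: list[NeuronSpec],
    noise_neurons: list[NeuronSpec],
    duration: float = 60.0,
    thermal_sigma: float = 1.05,
    seed: int = 0,
    fs: float = FS_DEFAULT,
    band: tuple[float, float] = BAND_DEFAULT,
    gamma_shape: float = 2.0,
    refractory_floor: float = 1e-3,
) -> Recording:
    """Superpose all neurons' spike trains, add thermal noise, bandpass.

    Each channel is the sum over neurons of that neuron's site template placed
    at its spike sample indices, plus white Gaussian thermal noise of SD
    ``thermal_sigma``, zero-phase bandpass filtered to ``band``.  Ground-truth
    spike times, ids and (filtered) target templates ride along.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * fs))
    sites = geometry.electrode_positions
    n_ch = sites.shape[0]
    neurons = list(targets) + list(noise_neurons)
    n_targets = len(targets)

    raw = np.zeros((n_ch, n_samples))
    true_times: list[np.ndarray] = []
    win = np.arange(SPIKE_LEN)
    for idx, neuron in enumerate(neurons):
        train = sample_spike_train(
            neuron.mean_rate,
            gamma_shape=neuron.gamma_shape if neuron.gamma_shape else gamma_shape,
            duration=duration,
            refractory_floor=refractory_floor,
            seed=_neuron_seed(seed, neuron),
        )
        starts = np.round(train * fs).astype(int)
        starts = starts[starts + SPIKE_LEN < n_samples]
        true_times.append(starts / fs)
        if starts.size == 0:
            continue
        flat_idx = (starts[:, None] + win[None, :]).ravel()
        for ch in range(n_ch):
            tmpl = waveform_at_site(neuron, sites[ch], fs)
            raw[ch] += np.bincount(
                flat_idx, weights=np.tile(tmpl, starts.size), minlength=n_samples
            )

    if thermal_sigma > 0:
        raw += rng.normal(0.0, thermal_sigma, size=raw.shape)
    samples = bandpass_filter(raw, fs, band)

    templates = np.zeros((n_targets, n_ch, SPIKE_LEN))
    for i, neuron in enumerate(targets):
        for ch in range(n_ch):
            templates[i, ch] = _filtered_template(waveform_at_site(neuron, sites[ch], fs), fs, band)

    return Recording(
        samples=samples,
        fs=fs,
        true_spike_times=true_times[:n_targets],
        neuron_ids=np.arange(n_targets),
        templates=templates,
        band=band,
        duration=duration,
        target_ids=np.arange(n_targets),
    )


# ---------------------------------------------------------------------------
# SNR


def estimate_snr(recording: Recording, neuron_id: int, channel: int) -> float:
    """SNR = peak-to-peak of the neuron's mean measured waveform over the
    median-based noise SD estimate of the channel."""
    from .detection import noise_sigma  # local import to avoid a cycle

    times = recording.true_spike_times[neuron_id]
    if times.size == 0:
        raise ValueError("neuron has no spikes on record")
    x = recording.samples[channel]
    starts = np.round(times * recording.fs).astype(int)
    starts = starts[(starts >= 0) & (starts + SPIKE_LEN <= x.size)]
    wins = x[starts[:, None] + np.arange(SPIKE_LEN)[None, :]]
    mean_wf = wins.mean(axis=0)
    sigma = noise_sigma(x)
    if sigma == 0:
        raise ZeroDivisionError("noise SD estimate is zero; SNR undefined")
    return float((mean_wf.max() - mean_wf.min()) / sigma)


def mean_snr(recording: Recording, channel: int) -> float:
    """Mean SNR over the target neurons at one site (the reported summary)."""
    vals = [estimate_snr(recording, int(i), channel) for i in recording.target_ids]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# surrogate generic spike library (basis-building input)

#: Bump when the surrogate-library generator changes; the library is frozen
#: by (version, seed) rather than shipped as a data file.
LIBRARY_VERSION = 1
LIBRARY_SEED = 424242


def make_surrogate_library(
    n_waveforms: int = 400,
    fs: float = FS_DEFAULT,
    window_len: int = SPIKE_LEN,
    seed: int = LIBRARY_SEED,
) -> np.ndarray:
    """Generic spike-waveform library for the fixed *generic* basis.

    Asymmetric-Gaussian-lobe family: a sharp main deflection (independent
    left/right widths) with an opposite-sign rebound and an optional small
    leading lobe, drawn over wide parameter ranges.  The family is
    deliberately different from the recording simulator's gamma-difference
    templates, so the basis derived from it is unrelated to the test data
    while still spanning realistic spike-shape diversity.  Deterministic for
    a fixed seed; the default (version, seed) pair defines the frozen
    library.  Returns window_len x K.
    """
    if n_waveforms < window_len:
        raise ValueError("need at least window_len waveforms for a full-rank basis")
    rng = np.random.default_rng(seed)
    t = np.arange(window_len) / fs * 1e3  # ms
    lib = np.empty((window_len, n_waveforms))

    def asym_gauss(center, s_left, s_right):
        s = np.where(t < center, s_left, s_right)
        return np.exp(-0.5 * ((t - center) / s) ** 2)

    for j in range(n_waveforms):
        sign = -1.0 if rng.uniform() < 0.8 else 1.0
        t0 = rng.uniform(0.55, 0.80)  # ms, main deflection near the alignment point
        main = asym_gauss(t0, rng.uniform(0.05, 0.18), rng.uniform(0.07, 0.30))
        reb = rng.uniform(0.1, 0.8) * asym_gauss(
            t0 + rng.uniform(0.15, 0.55), rng.uniform(0.10, 0.25), rng.uniform(0.2, 0.6)
        )
        lead = rng.uniform(0.0, 0.5) * asym_gauss(
            t0 - rng.uniform(0.10, 0.25), rng.uniform(0.04, 0.10), rng.uniform(0.04, 0.10)
        )
        amp = rng.uniform(0.5, 1.5)
        lib[:, j] = amp * sign * (main - reb - lead)
    return lib


def make_model_library(
    targets: list[NeuronSpec] | None = None,
    n_points_per_neuron: int = 10_000,
    r_min_um: float = 15.0,
    r_max_um: float = 60.0,
    param_jitter: float = 0.08,
    fs: float = FS_DEFAULT,
    window_len: int = SPIKE_LEN,
    seed: int = 0,
) -> np.ndarray:
    """Library of model-neuron waveforms at random measurement points.

    For each target-neuron model, waveforms are evaluated at
    ``n_points_per_neuron`` random points in a spherical shell around the
    soma, with small multiplicative jitter on the template time constants (a
    stand-in for the position dependence of detailed neuron models).  This is
    the training set for the model-tuned fixed basis.
    """
    if targets is None:
        targets = place_target_neurons(seed=0)
    rng = np.random.default_rng(seed)
    cols = []
    for neuron in targets:
        p = neuron.waveform_params
        for _ in range(n_points_per_neuron):
            r = (rng.uniform(r_min_um**3, r_max_um**3)) ** (1 / 3)  # uniform in volume
            amp = p.amp_ref * (p.r0_um / r)
            jit = lambda v: v * rng.uniform(1 - param_jitter, 1 + param_jitter)
            pj = replace(
                p,
                theta1_ms=jit(p.theta1_ms),
                theta2_ms=jit(p.theta2_ms),
                balance=jit(p.balance),
            )
            cols.append(amp * template_shape(pj, fs, window_len))
    return np.column_stack(cols)
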