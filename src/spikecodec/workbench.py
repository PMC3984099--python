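"""End-to-end system architectures and parameter sweeps.

An architecture is a specific split of processing between the implanted and
external units:

* 0 — extract spikes, transmit uncompressed, align externally (reference);
* 1 — extract, compress on the implant, reconstruct externally;
* 2 — architecture 1 plus an external alignment step before sorting;
* 3 — extract, align on the implant (integer shifts), compress, reconstruct.

``run_architecture`` executes one configuration on one channel of a
ground-truth recording and returns the accuracies, score, complexity and
data-rate figures; ``sweep`` runs a configuration grid into a tidy table.
"""

from __future__ import annotations

from dataclasses import dataclass
import zlib

import numpy as np
import pandas as pd

from . import codec
from .alignment import AlignmentConfig, align_spikes
from .detection import DetectorConfig, SpikeMatrix, extract_with_jitter
from .evaluation import (
    CostModel,
    EvaluationResult,
    combined_score,
    data_rate,
    min_coefficients,
    op_count,
    reconstruction_accuracy,
)
from .sorting import sort_spikes
from .synthdata import (
    GeometryConfig,
    Recording,
    SNR_SCALES,
    mean_snr,
    place_noise_neurons,
    place_target_neurons,
    synthesize_recording,
)

DEFAULT_L_GRID = (2, 4, 8, 16, 32)


@dataclass
class ArchitectureConfig:
    architecture: int = 3
    detector: str = "abs"  # "abs" | "neo"
    basis_kind: str = "fixed2"  # ignored for architecture 0
    L: int = 8
    seed: int = 0
    snr_level: str = "high"

    def __post_init__(self):
        if self.architecture not in (0, 1, 2, 3):
            raise ValueError(f"architecture must be 0-3, got {self.architecture}")
        self.detector = self.detector.lower()
        if self.detector not in ("abs", "neo"):
            raise ValueError(f"unknown detector {self.detector!r}")
        if self.architecture != 0 and self.basis_kind not in codec.BASIS_KINDS:
            raise ValueError(f"unknown basis kind {self.basis_kind!r}")
        if self.snr_level not in SNR_SCALES:
            raise ValueError(f"snr_level must be one of {sorted(SNR_SCALES)}")

    def derived_seed(self, base_seed: int) -> int:
        """Stable per-configuration seed so sweep order cannot matter."""
        key = f"{self.architecture}|{self.detector}|{self.basis_kind}|{self.L}|{self.snr_level}"
        return int((base_seed + zlib.crc32(key.encode())) % (2**31))


def simulate_condition(
    snr_level: str = "high",
    duration: float = 60.0,
    seed: int = 0,
    n_sites: int = 1,
    **synth_kwargs,
) -> Recording:
    """Convenience constructor for one SNR condition's test recording.

    ``n_sites=1`` synthesizes only the central electrode site (the one used
    for single-channel analyses), which is much cheaper than the full array.
    """
    from .synthdata import default_electrode_positions

    scale = SNR_SCALES[snr_level]
    sites = default_electrode_positions()
    if n_sites < sites.shape[0]:
        mid = sites.shape[0] // 2
        half = n_sites // 2
        sites = sites[mid - half : mid - half + n_sites]
    geom = GeometryConfig(electrode_positions=sites, snr_scale=scale)
    targets = place_target_neurons(snr_scale=scale, seed=seed)
    noise = place_noise_neurons(geom, seed=seed + 1)
    return synthesize_recording(geom, targets, noise, duration=duration, seed=seed + 2, **synth_kwargs)


def _resolve_basis(
    config: ArchitectureConfig,
    spikes: SpikeMatrix,
    fixed_bases: dict[str, codec.CompressionBasis] | None,
) -> codec.CompressionBasis:
    kind = config.basis_kind
    M = spikes.window_len
    if kind == "optimal":
        return codec.build_optimal_basis(spikes)
    if kind == "downsample":
        return codec.build_downsampling_basis(M, config.L)
    if kind == "haar":
        return codec.build_haar_basis(M)
    if fixed_bases and kind in fixed_bases:
        return fixed_bases[kind]
    raise ValueError(f"no prebuilt basis supplied for kind {kind!r}")


def default_fixed_bases(library_seed: int = 0, n_model_points: int = 2000) -> dict[str, codec.CompressionBasis]:
    """Build the two fixed bases once (model-tuned and generic)."""
    from .synthdata import make_model_library, make_surrogate_library

    lib1 = make_model_library(n_points_per_neuron=n_model_points, seed=library_seed)
    lib2 = make_surrogate_library()
    return {
        "fixed1": codec.build_fixed_basis(lib1, "fixed1"),
        "fixed2": codec.build_fixed_basis(lib2, "fixed2"),
    }


def run_architecture(
    recording: Recording,
    channel: int,
    config: ArchitectureConfig,
    fixed_bases: dict[str, codec.CompressionBasis] | None = None,
    spikes: SpikeMatrix | None = None,
    cost_model: CostModel | None = None,
) -> EvaluationResult:
    """Run one configuration end to end and score it.

    ``spikes`` may carry a pre-extracted SpikeMatrix (matching the config's
    detector) to avoid repeating extraction across a sweep.
    """
    if spikes is None:
        det = DetectorConfig(method=config.detector)
        spikes = extract_with_jitter(recording, channel, det)
    if spikes.n_spikes == 0:
        raise ValueError("no spikes retained; cannot evaluate")

    arch = config.architecture
    if arch == 0:
        aligned = align_spikes(spikes, AlignmentConfig(mode="external"))
        Xhat = aligned.waveforms
        ids = aligned.true_ids
        L_eff = spikes.window_len
    elif arch in (1, 2):
        basis = _resolve_basis(config, spikes, fixed_bases)
        Xhat = codec.reconstruct(codec.compress(spikes, basis, config.L), basis)
        ids = spikes.true_ids
        if arch == 2:
            sm = SpikeMatrix(Xhat, spikes.detection_index.copy(), ids, spikes.fs)
            aligned = align_spikes(sm, AlignmentConfig(mode="external"))
            Xhat = aligned.waveforms
        L_eff = config.L
    else:  # arch 3
        aligned = align_spikes(spikes, AlignmentConfig(mode="implant"))
        basis = _resolve_basis(config, aligned, fixed_bases)
        Xhat = codec.reconstruct(codec.compress(aligned, basis, config.L), basis)
        ids = aligned.true_ids
        L_eff = config.L

    templates = recording.templates[:, channel, :]
    a_rec = reconstruction_accuracy(Xhat, templates, ids)
    sort = sort_spikes(Xhat, ids, K=len(recording.target_ids), seed=config.seed)
    score = combined_score(np.clip(a_rec, 0, 1), sort.accuracy)
    model = cost_model or CostModel()
    return EvaluationResult(
        A_rec=a_rec,
        A_sort=sort.accuracy,
        score=score,
        L=L_eff,
        snr=mean_snr(recording, channel),
        ops_per_spike_per_dim=op_count(arch, config.detector, L_eff, model),
        rate=data_rate(L_eff),
        extras={"n_spikes": spikes.n_spikes},
    )


def sweep(
    recordings: dict[str, Recording],
    configs: list[ArchitectureConfig],
    channel: int = 0,
    base_seed: int = 0,
    fixed_bases: dict[str, codec.CompressionBasis] | None = None,
) -> pd.DataFrame:
    """Evaluate a configuration grid; one tidy row per configuration.

    Spike extraction is cached per (snr_level, detector).  Adds the
    group-wise effective minimum coefficient count where a (detector,
    architecture, basis, snr) group covers at least three L values.
    """
    if not configs:
        raise ValueError("empty configuration grid")
    if fixed_bases is None:
        fixed_bases = default_fixed_bases()
    extraction_cache: dict[tuple[str, str], SpikeMatrix] = {}
    rows = []
    for cfg in configs:
        rec = recordings[cfg.snr_level]
        key = (cfg.snr_level, cfg.detector)
        if key not in extraction_cache:
            extraction_cache[key] = extract_with_jitter(
                rec, channel, DetectorConfig(method=cfg.detector)
            )
        cfg_seeded = ArchitectureConfig(
            architecture=cfg.architecture,
            detector=cfg.detector,
            basis_kind=cfg.basis_kind,
            L=cfg.L,
            seed=cfg.derived_seed(base_seed),
            snr_level=cfg.snr_level,
        )
        res = run_architecture(
            rec, channel, cfg_seeded, fixed_bases=fixed_bases, spikes=extraction_cache[key]
        )
        rows.append(
            {
                "snr_level": cfg.snr_level,
                "detector": cfg.detector,
                "architecture": cfg.architecture,
                "basis": cfg.basis_kind if cfg.architecture != 0 else "none",
                "L": res.L,
                "A_rec": res.A_rec,
                "A_sort": res.A_sort,
                "score": res.score,
                "ops_per_spike_per_dim": res.ops_per_spike_per_dim,
                "bits_per_spike": res.rate.bits_per_spike,
                "snr": res.snr,
                "n_spikes": res.extras["n_spikes"],
            }
        )
    df = pd.DataFrame(rows)
    df["L_min"] = np.nan
    for keys, grp in df.groupby(["snr_level", "detector", "architecture", "basis"]):
        if grp["L"].nunique() >= 3:
            lmin = min_coefficients(dict(zip(grp["L"], grp["score"])))
            df.loc[grp.index, "L_min"] = lmin
    return df


def compression_study(
    seeds,
    duration: float = 60.0,
    snr_level: str = "high",
    L_values=(2, 4, 8),
    channel: int = 0,
    fixed_bases: dict | None = None,
) -> pd.DataFrame:
    """Reference vs compression configurations across simulated recordings.

    For each seed, simulates one recording and evaluates the uncompressed
    reference (NEO detection, architecture 0) and the two headline
    compression configurations (ABS + architecture 3 and NEO + architecture
    1, both with the generic fixed basis) at each L.  Returns one tidy row
    per (seed, configuration, L).
    """
    if fixed_bases is None:
        fixed_bases = default_fixed_bases()
    rows = []
    for seed in seeds:
        rec = simulate_condition(snr_level, duration=duration, seed=int(seed))
        spikes = {
            d: extract_with_jitter(rec, channel, DetectorConfig(method=d))
            for d in ("abs", "neo")
        }
        def _run(arch, det, basis, L):
            cfg = ArchitectureConfig(arch, det, basis, L, seed=0, snr_level=snr_level)
            return run_architecture(rec, channel, cfg, fixed_bases=fixed_bases, spikes=spikes[det])
        r = _run(0, "neo", "optimal", L_values[0])
        rows.append({"seed": seed, "config": "reference", "L": None,
                     "A_rec": r.A_rec, "A_sort": r.A_sort, "score": r.score})
        for L in L_values:
            for name, arch, det in (("abs-arch3", 3, "abs"), ("neo-arch1", 1, "neo")):
                r = _run(arch, det, "fixed2", L)
                rows.append({"seed": seed, "config": name, "L": L,
                             "A_rec": r.A_rec, "A_sort": r.A_sort, "score": r.score})
    return pd.DataFrame(rows)


def basis_plateau_study(
    seeds,
    duration: float = 60.0,
    snr_level: str = "high",
    L_values=DEFAULT_L_GRID,
    architecture: int = 3,
    detector: str = "abs",
    channel: int = 0,
    fixed_bases: dict | None = None,
) -> dict[str, dict]:
    """Median score vs L per compression basis, plus the effective minimum
    coefficient count, for one detector/architecture combination."""
    if fixed_bases is None:
        fixed_bases = default_fixed_bases()
    scores: dict[str, dict[int, list[float]]] = {b: {} for b in codec.BASIS_KINDS}
    for seed in seeds:
        rec = simulate_condition(snr_level, duration=duration, seed=int(seed))
        spikes = extract_with_jitter(rec, channel, DetectorConfig(method=detector))
        for basis in codec.BASIS_KINDS:
            for L in L_values:
                cfg = ArchitectureConfig(architecture, detector, basis, L, seed=0, snr_level=snr_level)
                r = run_architecture(rec, channel, cfg, fixed_bases=fixed_bases, spikes=spikes)
                scores[basis].setdefault(L, []).append(r.score)
    out = {}
    for basis, by_L in scores.items():
        med = {int(L): float(np.median(v)) for L, v in by_L.items()}
        out[basis] = {"scores": med, "L_min": min_coefficients(med)}
    return out


def default_grid(
    snr_levels=("high", "medium", "low"),
    detectors=("abs", "neo"),
    architectures=(0, 1, 2, 3),
    bases=codec.BASIS_KINDS,
    L_values=DEFAULT_L_GRID,
) -> list[ArchitectureConfig]:
    """Full factorial grid; architecture 0 collapses its basis/L cells."""
    grid = []
    for snr in snr_levels:
        for det in detectors:
            for arch in architectures:
                if arch == 0:
                    grid.append(ArchitectureConfig(0, det, "optimal", L_values[0], 0, snr))
                    continue
                for basis in bases:
                    for L in L_values:
                        grid.append(ArchitectureConfig(arch, det, basis, L, 0, snr))
    return grid
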