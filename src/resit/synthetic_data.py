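"""Synthetic EEG: montage fixtures and dipole-simulated recordings.

Everything needed to exercise the toolkit offline: an idealized
extended 10-20 montage on the unit sphere, and recordings forward-
simulated through the same three-shell spherical physics as the inverse
model but from an *independent* random dipole set (no inverse crime
unless explicitly requested).

Signal models
-------------
``bandlimited_noise``
    Independent 1-30 Hz filtered Gaussian noise per source
    (resting-state-like broadband activity).
``alpha_oscillation``
    10 Hz sinusoids with random phase per source.
``erp_waveform``
    Epoched evoked response: a small negative deflection near 170 ms and
    a dominant positive deflection peaking in the 300-400 ms window
    (P300-like morphology), repeated over epochs spanning -200..800 ms
    with per-epoch amplitude jitter.

Scalp amplitudes are scaled so the clean signal has a target RMS in
microvolts; white sensor noise is added per channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .forward_model import (
    ConcentricSphereHeadModel,
    SourceGrid,
    _potential_series,
    build_source_grid,
)
from .montage import ElectrodeMontage, write_montage
from .recording import EEGRecording, write_recording

__all__ = [
    "SimulationConfig",
    "make_montage_fixture",
    "simulate_eeg",
    "write_fixture_bundle",
]

# Label subsets of the ideal spherical extended 10-20 layout, by cap size.
_LAYOUT_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]
_LAYOUT_32 = _LAYOUT_19 + [
    "Oz", "FC1", "FC2", "CP1", "CP2", "FC5", "FC6", "CP5", "CP6", "TP9",
    "TP10", "FT9", "FT10",
]
_LAYOUT_62 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "Oz",
]
_LAYOUTS = {19: _LAYOUT_19, 32: _LAYOUT_32, 62: _LAYOUT_62}


def make_montage_fixture(n_channels: int = 62) -> ElectrodeMontage:
    """Deterministic extended 10-20 montage on the unit sphere.

    Supported layouts: 19 (classic 10-20), 32 and 62 channels. Positions
    come from the ideal spherical extended 10-20 coordinates bundled with
    MNE (easycap-M1), rotated to the +x-nasion / +z-vertex convention and
    normalized to unit length; Cz sits exactly at the vertex.
    """
    if n_channels not in _LAYOUTS:
        raise ValueError(
            f"unsupported layout {n_channels}; supported sizes: {sorted(_LAYOUTS)}"
        )
    import mne

    labels = _LAYOUTS[n_channels]
    pos = mne.channels.make_standard_montage("easycap-M1").get_positions()["ch_pos"]
    raw = np.array([pos[l] for l in labels])
    # MNE head frame: +x right, +y nasion; ours: +x nasion, +y left.
    ours = np.column_stack([raw[:, 1], -raw[:, 0], raw[:, 2]])
    return ElectrodeMontage.from_positions(labels, ours)


@dataclass
class SimulationConfig:
    """Parameters of a dipole-simulated EEG recording.

    ``n_sources`` dipoles are drawn uniformly in a ball of radius
    ``source_radius_max`` (dimensionless, inside the brain compartment)
    with random orientations; ``sensor_noise_sd`` is the white sensor
    noise standard deviation in microvolts, and ``target_scalp_rms`` the
    RMS of the clean scalp signal (so SNR = target_scalp_rms /
    sensor_noise_sd; the defaults give SNR 5).
    """

    n_sources: int = 10
    source_radius_max: float = 0.8
    signal_model: str = "bandlimited_noise"
    sfreq: float = 500.0
    duration_s: float = 2.0
    n_epochs: int = 30
    epoch_tmin: float = -0.2
    epoch_tmax: float = 0.8
    erp_neg_peak_s: float = 0.17
    erp_pos_peak_s: float = 0.35
    erp_neg_amplitude: float = 0.4
    erp_pos_amplitude: float = 1.0
    sensor_noise_sd: float = 2.0
    target_scalp_rms: float = 10.0
    reference: str = "average"
    seed: int = 0
    inverse_crime: bool = False

    def __post_init__(self) -> None:
        if self.signal_model not in (
            "bandlimited_noise", "alpha_oscillation", "erp_waveform"
        ):
            raise ValueError(f"unknown signal_model {self.signal_model!r}")
        if self.n_sources < 0:
            raise ValueError("n_sources must be non-negative")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be non-negative")
        if self.n_sources == 0 and self.sensor_noise_sd == 0:
            raise ValueError("zero sources with zero noise is a degenerate all-zero recording")
        if self.sfreq <= 0 or self.duration_s <= 0:
            raise ValueError("sfreq and duration_s must be positive")
        if self.epoch_tmax <= self.epoch_tmin:
            raise ValueError("epoch window is empty")
        if not (self.reference == "average" or self.reference.startswith("point:")):
            raise ValueError("reference must be 'average' or 'point:<label>'")

    @property
    def n_times(self) -> int:
        if self.signal_model == "erp_waveform":
            return self.n_epochs * self.epoch_len
        return int(round(self.duration_s * self.sfreq))

    @property
    def epoch_len(self) -> int:
        return int(round((self.epoch_tmax - self.epoch_tmin) * self.sfreq))


def _draw_sources(
    config: SimulationConfig,
    model: ConcentricSphereHeadModel,
    grid: SourceGrid,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    if config.source_radius_max >= model.r_brain:
        raise ValueError("source_radius_max must be inside the brain compartment")
    if config.inverse_crime:
        idx = rng.choice(grid.n_sources, size=config.n_sources, replace=False)
        return grid.positions[idx], grid.orientations[idx]
    pos = np.empty((config.n_sources, 3))
    for i in range(config.n_sources):
        while True:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            p = u * config.source_radius_max * rng.uniform() ** (1.0 / 3.0)
            # generating sources must never coincide with inverse-grid nodes
            if np.min(np.linalg.norm(grid.positions - p, axis=1)) > 1e-6:
                pos[i] = p
                break
    ori = rng.normal(size=(config.n_sources, 3))
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    return pos, ori


def _source_timecourses(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n, T = config.n_sources, config.n_times
    t = np.arange(T) / config.sfreq
    if config.signal_model == "bandlimited_noise":
        sos = sps.butter(4, [1.0, 30.0], btype="bandpass", fs=config.sfreq, output="sos")
        return sps.sosfiltfilt(sos, rng.standard_normal((n, T)), axis=1)
    if config.signal_model == "alpha_oscillation":
        phase = rng.uniform(0, 2 * np.pi, size=n)
        amp = rng.uniform(0.5, 1.5, size=n)
        return amp[:, None] * np.sin(2 * np.pi * 10.0 * t[None, :] + phase[:, None])
    # erp_waveform: shared morphology, per-source and per-epoch amplitude jitter
    te = config.epoch_tmin + np.arange(config.epoch_len) / config.sfreq
    wave = (
        -config.erp_neg_amplitude * np.exp(-0.5 * ((te - config.erp_neg_peak_s) / 0.03) ** 2)
        + config.erp_pos_amplitude * np.exp(-0.5 * ((te - config.erp_pos_peak_s) / 0.05) ** 2)
    )
    src_amp = rng.uniform(0.5, 1.5, size=n)
    epoch_jit = 1.0 + 0.1 * rng.standard_normal((n, config.n_epochs))
    S = np.empty((n, T))
    for e in range(config.n_epochs):
        sl = slice(e * config.epoch_len, (e + 1) * config.epoch_len)
        S[:, sl] = (src_amp * epoch_jit[:, e])[:, None] * wave[None, :]
    return S


def simulate_eeg(
    model: ConcentricSphereHeadModel,
    montage: ElectrodeMontage,
    config: SimulationConfig,
    grid: SourceGrid | None = None,
    return_sources: bool = False,
):
    """Forward-simulate an EEG recording from random dipolar sources.

    Returns ``(recording, ground_truth)``: the referenced, noisy recording
    per ``config.reference``, and the noiseless infinity-reference ground
    truth. With ``return_sources=True`` a dict with the source positions,
    orientations and moment time courses is appended.

    ``grid`` is the equivalent-source grid used by the inverse model; by
    default the standard grid is built and used only to keep generating
    sources off its nodes (or, with ``config.inverse_crime``, to place
    them exactly on nodes for exact-recovery tests).
    """
    rng = np.random.default_rng(config.seed)
    if grid is None:
        grid = build_source_grid()
    T = config.n_times
    if config.n_sources:
        pos, ori = _draw_sources(config, model, grid, rng)
        S = _source_timecourses(config, rng)
        gains = _potential_series(model, montage.positions, pos, ori)
        clean = gains @ S
        rms = float(np.sqrt(np.mean(clean**2)))
        if rms > 0:
            scale = config.target_scalp_rms / rms
            clean *= scale
            S *= scale
    else:
        pos = np.empty((0, 3))
        ori = np.empty((0, 3))
        S = np.empty((0, T))
        clean = np.zeros((montage.n_channels, T))

    truth = EEGRecording(clean, list(montage.labels), config.sfreq, "infinity")
    data = clean + config.sensor_noise_sd * rng.standard_normal(clean.shape)
    if config.reference == "average":
        data = data - data.mean(axis=0, keepdims=True)
    else:
        lbl = config.reference.split(":", 1)[1]
        i = montage.index(lbl)
        data = data - data[i]
        data[i] = 0.0
    rec = EEGRecording(data, list(montage.labels), config.sfreq, config.reference)
    if return_sources:
        return rec, truth, {"positions": pos, "orientations": ori, "moments": S}
    return rec, truth


def write_fixture_bundle(
    outdir,
    model: ConcentricSphereHeadModel | None = None,
    n_channels: int = 62,
    seed: int = 0,
) -> dict[str, str]:
    """Write a self-contained simulation bundle: montage file, a 60 s
    resting-state recording, an epoched ERP recording, and a JSON manifest
    with the exact configurations and seed, so every run is reproducible
    offline. Returns the mapping of bundle item -> path."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    model = model or ConcentricSphereHeadModel()
    montage = make_montage_fixture(n_channels)

    rest_cfg = SimulationConfig(signal_model="bandlimited_noise", duration_s=60.0, seed=seed)
    erp_cfg = SimulationConfig(signal_model="erp_waveform", seed=seed + 1)
    paths = {
        "montage": str(out / "montage.sfp"),
        "resting": str(out / "resting.h5"),
        "erp": str(out / "erp_epochs.h5"),
        "manifest": str(out / "manifest.json"),
    }
    try:
        write_montage(montage, paths["montage"])
        rest, _ = simulate_eeg(model, montage, rest_cfg)
        write_recording(rest, paths["resting"])
        erp, _ = simulate_eeg(model, montage, erp_cfg)
        write_recording(erp, paths["erp"])
        manifest = {
            "seed": seed,
            "n_channels": n_channels,
            "head_model": {
                k: getattr(model, k)
                for k in (
                    "r_brain", "r_skull_outer", "r_scalp",
                    "sigma_brain", "sigma_skull", "sigma_scalp",
                )
            },
            "resting": rest_cfg.__dict__,
            "erp": erp_cfg.__dict__,
        }
        with open(paths["manifest"], "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except OSError as err:
        raise OSError(f"failed writing fixture bundle under {out}: {err}") from err
    return paths
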