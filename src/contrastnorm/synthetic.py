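"""Synthetic calcium-imaging recordings with known ground truth.

Trial-structured ROI fluorescence traces are generated by driving the
cascade model with the center-step stimulus and wrapping its response into
a realistic raw-fluorescence trace: a baseline fluorescence level
modulated by the response, slow baseline drift (sinusoid plus random walk,
to exercise the dynamic-baseline ΔF/F algorithm), additive Gaussian
recording noise, and — for a configurable fraction of recordings —
large-amplitude low-frequency movement artifacts that the SNR criterion
should reject.

Cell-type archetypes mirror the recorded neurons: ON cells (Mi1-like,
Tm3-like) and OFF cells (Tm1-like, Tm2-like) whose normalization strength
``k`` depends on the surround condition (weak for static surrounds, strong
for dynamic ones), plus an L1-like negative control whose ``k`` is the same
in every condition — a cell without contrast normalization.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, GeometryError
from .model import ModelParams, SignalTrace, low_pass, run_cascade
from .stimulus import (
    DYNAMIC_CONDITIONS,
    STATIC_CONDITIONS,
    ScreenGeometry,
    StimulusMovie,
    make_noise_stimulus,
)

__all__ = [
    "CellArchetype",
    "TrialRecording",
    "SimConfig",
    "default_archetypes",
    "simulate_center_drive",
    "model_response",
    "cell_model_params",
    "cell_response",
    "simulate_recording",
    "simulate_noise_mapping_session",
    "resample_trace",
    "save_recordings",
    "load_recordings",
]

ACQUISITION_RATE = 11.8  # Hz

# Normalization regimes: weak saturation under a static surround, strong
# saturation (shunting) under a dynamic surround.
K_STATIC = 0.2
K_DYNAMIC = 1.0


@dataclass
class CellArchetype:
    """Ground-truth description of a simulated cell type.

    ``params_by_condition`` maps each surround condition to the cascade
    parameters used when that condition is on screen — the surround acts
    only through the normalization parameter ``k``, never through the
    drive.  ``rf_sigma`` is the SD (degrees) of the spatial Gaussian
    receptive field; ``response_gain`` converts model output to ΔF/F units.
    """

    name: str
    polarity: str
    params_by_condition: dict[str, ModelParams]
    rf_center: tuple[float, float] = (0.0, 0.0)
    rf_sigma: float = 5.0
    response_gain: float = 2.0

    def __post_init__(self) -> None:
        if self.polarity not in ("ON", "OFF"):
            raise ValueError("polarity must be 'ON' or 'OFF'")
        if self.response_gain <= 0 or self.rf_sigma < 0:
            raise ValueError("response_gain must be positive, rf_sigma non-negative")

    def params_for(self, condition: str) -> ModelParams:
        try:
            return self.params_by_condition[condition]
        except KeyError:
            raise ConfigurationError(
                f"archetype {self.name!r} has no parameters for condition "
                f"{condition!r}"
            ) from None


def _condition_params(nl_mode: str = "dynamic", k_everywhere: float | None = None
                      ) -> dict[str, ModelParams]:
    params = {}
    for cond in STATIC_CONDITIONS:
        k = K_STATIC if k_everywhere is None else k_everywhere
        params[cond] = ModelParams(k=k, nl_mode=nl_mode)
    for cond in DYNAMIC_CONDITIONS:
        k = K_DYNAMIC if k_everywhere is None else k_everywhere
        params[cond] = ModelParams(k=k, nl_mode=nl_mode)
    return params


def default_archetypes(nl_mode: str = "dynamic") -> dict[str, CellArchetype]:
    """The five simulated cell types.

    RF widths follow the reported FWHM of the corresponding neurons
    (Mi1 29°, Tm3 12°, Tm1 27°, Tm2 31°; sigma = FWHM / 2.355).  The
    L1-like archetype uses the same ``k`` in every condition, emulating a
    cell without contrast normalization.
    """
    fwhm_to_sigma = 1.0 / 2.355
    return {
        "Mi1-like": CellArchetype(
            "Mi1-like", "ON", _condition_params(nl_mode), rf_sigma=29 * fwhm_to_sigma
        ),
        "Tm3-like": CellArchetype(
            "Tm3-like", "ON", _condition_params(nl_mode), rf_sigma=12 * fwhm_to_sigma
        ),
        "Tm1-like": CellArchetype(
            "Tm1-like", "OFF", _condition_params(nl_mode), rf_sigma=27 * fwhm_to_sigma
        ),
        "Tm2-like": CellArchetype(
            "Tm2-like", "OFF", _condition_params(nl_mode), rf_sigma=31 * fwhm_to_sigma
        ),
        "L1-like": CellArchetype(
            "L1-like",
            "OFF",
            _condition_params(nl_mode, k_everywhere=K_STATIC),
            rf_sigma=12 * fwhm_to_sigma,
        ),
    }


@dataclass
class TrialRecording:
    """One trial's raw ROI fluorescence trace with its labels."""

    trace: np.ndarray
    sample_rate: float = ACQUISITION_RATE
    cell_id: int = 0
    fly_id: int = 0
    trial_index: int = 0
    condition: str = "gray"
    cell_type: str = ""
    step_amplitude: float = 1.0
    ground_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if np.any(self.trace <= 0):
            raise ValueError("fluorescence trace must be strictly positive")


@dataclass
class SimConfig:
    """Simulation settings for a synthetic population.

    Noise defaults emulate a quiet two-photon recording: Gaussian noise of
    SD 5 on a baseline of 100 fluorescence units (~0.05 ΔF/F), plus slow
    drift of a few percent of baseline.  Cells are heterogeneous:
    per-cell lognormal variation of response gain (``gain_cv``), of the
    normalization strength ``k`` (``k_cv``, one factor per cell applied in
    every condition), and of the filter time constants (``tau_cv``).
    """

    seed: int = 0
    n_cells: int = 20
    n_flies: int = 5
    trials_per_condition: int = 3
    noise_sd: float = 5.0
    drift_amplitude: float = 2.0
    drift_timescale: float = 30.0
    corrupt_fraction: float = 0.0
    artifact_amplitude: float = 200.0
    baseline_f0: float = 100.0
    gain_cv: float = 0.1
    k_cv: float = 0.25
    tau_cv: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.corrupt_fraction <= 1:
            raise ValueError("corrupt_fraction must be in [0, 1]")
        if min(self.n_cells, self.n_flies, self.trials_per_condition) < 1:
            raise ValueError("counts must be >= 1")
        if self.baseline_f0 <= 0:
            raise ValueError("baseline_f0 must be positive")
        for name in ("noise_sd", "drift_amplitude", "artifact_amplitude",
                     "gain_cv", "k_cv", "tau_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg.get("sim", cfg))


def _rng_for(config: SimConfig, *labels) -> np.random.Generator:
    """Deterministic per-entity generator from (seed, labels)."""
    words = [config.seed & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, str):
            words.append(zlib.crc32(lab.encode()))
        else:
            words.append(int(lab) & 0xFFFFFFFF)
    return np.random.default_rng(words)


# --------------------------------------------------------------------------
# Step-protocol recordings
# --------------------------------------------------------------------------

def simulate_center_drive(
    movie: StimulusMovie, archetype: CellArchetype
) -> SignalTrace:
    """Scalar model drive from the luminance of the RF-center pixel.

    The drive is the polarity-signed deviation of the center-pixel
    luminance from its pre-step value, held at the model time step.  The
    surround condition selects the archetype's model parameters (``k``),
    never the drive: the surround acts only through normalization.
    """
    if "step_onset" not in movie.events:
        raise ValueError("movie lacks step timing events")
    params = archetype.params_for(movie.condition)
    pix = movie.pixel_trace(*archetype.rf_center)
    pre_mask = movie.times < movie.events["step_onset"]
    pre_value = pix[pre_mask].mean() if pre_mask.any() else pix[0]
    sign = 1.0 if archetype.polarity == "ON" else -1.0
    drive_frames = sign * (pix - pre_value)
    # Zero-order hold onto the model grid.
    n = round(movie.duration / params.dt)
    t = params.dt * np.arange(n)
    idx = np.minimum((t * movie.frame_rate).astype(int), pix.size - 1)
    return SignalTrace(values=drive_frames[idx], dt=params.dt)


def model_response(
    movie: StimulusMovie, archetype: CellArchetype
) -> SignalTrace:
    """Noiseless cascade response (model units) to the movie's center step."""
    drive = simulate_center_drive(movie, archetype)
    return run_cascade(drive, archetype.params_for(movie.condition))


def cell_model_params(
    archetype: CellArchetype, condition: str, config: SimConfig, cell_id: int
) -> ModelParams:
    """The archetype's parameters with this cell's individual variation.

    One set of lognormal factors is drawn per cell (from the simulation
    seed) and applied in every condition, so a cell that normalizes
    strongly does so under each surround.
    """
    base = archetype.params_for(condition)
    rng = _rng_for(config, archetype.name, "cellparams", cell_id)
    f_k = np.exp(config.k_cv * rng.standard_normal())
    f_lp, f_hp, f_ca = np.exp(config.tau_cv * rng.standard_normal(3))
    return replace(
        base,
        k=base.k * f_k,
        tau_lp=base.tau_lp * f_lp,
        tau_hp=base.tau_hp * f_hp,
        tau_ca=base.tau_ca * f_ca,
    )


def cell_response(
    movie: StimulusMovie,
    archetype: CellArchetype,
    config: SimConfig,
    cell_id: int,
) -> SignalTrace:
    """Noiseless cascade response of one individual (jittered) cell."""
    drive = simulate_center_drive(movie, archetype)
    return run_cascade(
        drive, cell_model_params(archetype, movie.condition, config, cell_id)
    )


def resample_trace(
    x: SignalTrace, sample_rate: float, duration: float | None = None
) -> np.ndarray:
    """Linear interpolation of a model-rate trace onto acquisition samples."""
    duration = x.duration if duration is None else duration
    t_out = np.arange(round(duration * sample_rate)) / sample_rate
    return np.interp(t_out, x.times, x.values)


def _slow_drift(
    n: int, sample_rate: float, amplitude: float, timescale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sinusoid of random phase plus a scaled random walk."""
    if amplitude == 0:
        return np.zeros(n)
    t = np.arange(n) / sample_rate
    phase = rng.uniform(0, 2 * np.pi)
    sin = amplitude * np.sin(2 * np.pi * t / timescale + phase)
    walk = np.cumsum(rng.standard_normal(n))
    scale = np.max(np.abs(walk))
    walk = amplitude * walk / scale if scale > 0 else walk
    return sin + walk


def _movement_artifact(
    n: int, sample_rate: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited (< 1 Hz) high-amplitude artifact noise."""
    from scipy.ndimage import gaussian_filter1d

    raw = rng.standard_normal(n)
    # sigma ~ 0.09 s per Hz of cutoff, matching the stimulus-noise convention
    smoothed = gaussian_filter1d(raw, 0.09 * sample_rate, mode="reflect")
    sd = smoothed.std()
    return amplitude * smoothed / sd if sd > 0 else smoothed


def simulate_recording(
    movie: StimulusMovie,
    archetype: CellArchetype,
    config: SimConfig,
    trial: int,
    cell_id: int = 0,
    response: SignalTrace | None = None,
) -> TrialRecording:
    """One trial's raw fluorescence trace for one cell.

    trace = F0 * (1 + gain * response) + drift + noise, resampled to the
    11.8 Hz acquisition rate.  Whether a cell is movement-corrupted is a
    per-cell draw; the artifact itself is redrawn per trial, producing the
    high inter-trial variance the SNR criterion targets.  Reproducible from
    (config.seed, cell type, condition, cell_id, trial).
    """
    if response is None:
        response = cell_response(movie, archetype, config, cell_id)
    resp = resample_trace(response, ACQUISITION_RATE, movie.duration)
    cell_rng = _rng_for(config, archetype.name, "cell", cell_id)
    gain = archetype.response_gain * np.exp(
        config.gain_cv * cell_rng.standard_normal()
    )
    corrupted = cell_rng.random() < config.corrupt_fraction
    rng = _rng_for(config, archetype.name, movie.condition, cell_id, trial)
    n = resp.size
    trace = config.baseline_f0 * (1.0 + gain * resp)
    trace = trace + _slow_drift(
        n, ACQUISITION_RATE, config.drift_amplitude, config.drift_timescale, rng
    )
    trace = trace + config.noise_sd * rng.standard_normal(n)
    if corrupted:
        trace = trace + _movement_artifact(
            n, ACQUISITION_RATE, config.artifact_amplitude, rng
        )
    trace = np.maximum(trace, 0.01 * config.baseline_f0)
    return TrialRecording(
        trace=trace,
        sample_rate=ACQUISITION_RATE,
        cell_id=cell_id,
        fly_id=cell_id % config.n_flies,
        trial_index=trial,
        condition=movie.condition,
        cell_type=archetype.name,
        step_amplitude=getattr(movie, "step_amplitude", 1.0),
        ground_truth=gain * resp,
    )


# --------------------------------------------------------------------------
# Noise-mapping session
# --------------------------------------------------------------------------

def rf_weights(
    geometry: ScreenGeometry, center: tuple[float, float], sigma: float
) -> np.ndarray:
    """Normalized spatial Gaussian receptive-field weights on the pixel grid.

    ``sigma -> 0`` degenerates to a delta on the nearest pixel.
    """
    if not geometry.contains(*center):
        raise GeometryError(f"RF center {center} is off screen")
    az = geometry.azimuths[np.newaxis, :]
    el = geometry.elevations[:, np.newaxis]
    if sigma < 1e-9:
        w = np.zeros((geometry.n_elevation, geometry.n_azimuth))
        w[geometry.nearest_pixel(*center)] = 1.0
        return w
    d2 = (az - center[0]) ** 2 + (el - center[1]) ** 2
    w = np.exp(-0.5 * d2 / sigma**2)
    return w / w.sum()


def simulate_noise_mapping_session(
    archetype: CellArchetype,
    geometry: ScreenGeometry,
    config: SimConfig,
    duration: float = 180.0,
    cell_id: int = 0,
) -> tuple[StimulusMovie, TrialRecording]:
    """A 3-minute RF-mapping session: noise movie plus the cell's response.

    The noiseless response is the calcium low-pass of the polarity-signed
    projection of the movie's luminance deviation onto the cell's spatial
    Gaussian RF; recording noise is then added as for step recordings.
    """
    rng = _rng_for(config, archetype.name, "mapping", cell_id)
    movie = make_noise_stimulus(
        geometry,
        duration=duration,
        frame_rate=ACQUISITION_RATE,
        seed=int(rng.integers(2**31)),
    )
    w = rf_weights(geometry, archetype.rf_center, archetype.rf_sigma)
    sign = 1.0 if archetype.polarity == "ON" else -1.0
    projection = sign * np.tensordot(movie.frames - 0.5, w, axes=([1, 2], [0, 1]))
    tau_ca = archetype.params_for("gray").tau_ca
    resp = low_pass(
        SignalTrace(values=projection, dt=1.0 / ACQUISITION_RATE), tau_ca
    ).values
    gain = archetype.response_gain
    trace = config.baseline_f0 * (1.0 + gain * resp)
    trace = trace + config.noise_sd * rng.standard_normal(trace.size)
    trace = np.maximum(trace, 0.01 * config.baseline_f0)
    rec = TrialRecording(
        trace=trace,
        sample_rate=ACQUISITION_RATE,
        cell_id=cell_id,
        fly_id=cell_id % config.n_flies,
        trial_index=0,
        condition="noise_mapping",
        cell_type=archetype.name,
        ground_truth=gain * resp,
    )
    return movie, rec


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

_ATTRS = ("sample_rate", "cell_id", "fly_id", "trial_index", "condition",
          "cell_type", "step_amplitude")


def save_recordings(path: str | Path, recordings: list[TrialRecording]) -> None:
    """Persist recordings in an HDF5 container (one group per trial)."""
    with h5py.File(path, "w") as fh:
        for i, rec in enumerate(recordings):
            grp = fh.create_group(f"recording_{i:05d}")
            grp.create_dataset("trace", data=rec.trace)
            if rec.ground_truth is not None:
                grp.create_dataset("ground_truth", data=rec.ground_truth)
            for key in _ATTRS:
                grp.attrs[key] = getattr(rec, key)


def load_recordings(path: str | Path) -> list[TrialRecording]:
    out = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            grp = fh[name]
            attrs = {}
            for key in _ATTRS:
                val = grp.attrs[key]
                if key in ("condition", "cell_type"):
                    attrs[key] = str(val)
                elif key in ("cell_id", "fly_id", "trial_index"):
                    attrs[key] = int(val)
                else:
                    attrs[key] = float(val)
            out.append(
                TrialRecording(
                    trace=grp["trace"][...],
                    ground_truth=(
                        grp["ground_truth"][...] if "ground_truth" in grp else None
                    ),
                    **attrs,
                )
            )
    return out


def manifest(recordings: list[TrialRecording]) -> pd.DataFrame:
    """Tidy manifest table (one row per trial recording)."""
    return pd.DataFrame(
        [
            {
                "cell_type": r.cell_type,
                "cell_id": r.cell_id,
                "fly_id": r.fly_id,
                "condition": r.condition,
                "trial_index": r.trial_index,
                "step_amplitude": r.step_amplitude,
                "n_samples": r.trace.size,
                "sample_rate": r.sample_rate,
            }
            for r in recordings
        ]
    )
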