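"""Visual stimulus generation.

Two stimulus families are produced as frame sequences with timing metadata:

* a spatiotemporal Gaussian noise movie used for receptive-field mapping
  (independent per-pixel Gaussian luminance, temporally smoothed), and
* a center-step protocol: a 1 s luminance step in a small circular window
  at the receptive-field center, isolated by a gray annulus, with one of
  four surround conditions (uniform gray, stationary square-wave grating,
  the same grating drifting at 1 Hz, or binary pixel noise) shown beyond
  the annulus.

The cylindrical projection arena is approximated by a flat rectangular
degree grid: only region membership and temporal structure matter to the
downstream model, not the exact projection geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import yaml
from scipy.ndimage import convolve1d

from .errors import GeometryError

__all__ = [
    "ScreenGeometry",
    "StimulusMovie",
    "StepProtocolSpec",
    "STATIC_CONDITIONS",
    "DYNAMIC_CONDITIONS",
    "SURROUND_CONDITIONS",
    "make_noise_stimulus",
    "make_step_protocol",
    "region_masks",
]

STATIC_CONDITIONS = ("gray", "stationary_grating")
DYNAMIC_CONDITIONS = ("moving_grating", "stochastic_noise")
SURROUND_CONDITIONS = STATIC_CONDITIONS + DYNAMIC_CONDITIONS

# Step-protocol timeline (seconds): surround appears 3 s before the step and
# stays 2 s after it; surround dynamics start 1 s before the step.
SURROUND_ONSET = 0.0
DYNAMICS_ONSET = 2.0
STEP_ONSET = 3.0
STEP_OFFSET = 4.0
SURROUND_OFFSET = 6.0


@dataclass(frozen=True)
class ScreenGeometry:
    """Rectangular degree grid covering the stimulation screen.

    Defaults: 180° azimuth x 105° elevation sampled on a 64 x 52 pixel
    grid, i.e. azimuth pixels of ~2.8°.  Azimuth spans [-90, 90]°,
    elevation [-52.5, 52.5]°; pixel coordinates refer to pixel centers.
    """

    azimuth_extent: float = 180.0
    elevation_extent: float = 105.0
    n_azimuth: int = 64
    n_elevation: int = 52

    def __post_init__(self) -> None:
        if self.n_azimuth < 1 or self.n_elevation < 1:
            raise ValueError("grid dimensions must be positive")
        if self.azimuth_extent <= 0 or self.elevation_extent <= 0:
            raise ValueError("screen extents must be positive")

    @property
    def pixel_size(self) -> float:
        """Azimuth pixel size in degrees (~2.8° at the default grid)."""
        return self.azimuth_extent / self.n_azimuth

    @property
    def elevation_pixel_size(self) -> float:
        return self.elevation_extent / self.n_elevation

    @property
    def azimuths(self) -> np.ndarray:
        """Azimuth of each pixel-column center, degrees."""
        return -self.azimuth_extent / 2 + self.pixel_size * (
            np.arange(self.n_azimuth) + 0.5
        )

    @property
    def elevations(self) -> np.ndarray:
        """Elevation of each pixel-row center, degrees."""
        return -self.elevation_extent / 2 + self.elevation_pixel_size * (
            np.arange(self.n_elevation) + 0.5
        )

    def contains(self, azimuth: float, elevation: float) -> bool:
        return (
            abs(azimuth) <= self.azimuth_extent / 2
            and abs(elevation) <= self.elevation_extent / 2
        )

    def nearest_pixel(self, azimuth: float, elevation: float) -> tuple[int, int]:
        """(row, col) of the pixel whose center is closest to the coordinate."""
        col = int(np.argmin(np.abs(self.azimuths - azimuth)))
        row = int(np.argmin(np.abs(self.elevations - elevation)))
        return row, col


@dataclass
class StimulusMovie:
    """Time-ordered luminance frames plus geometry and event timing.

    ``frames`` has shape (n_frames, n_elevation, n_azimuth) with luminance
    in [0, 1].  ``events`` maps event names (surround_onset, dynamics_onset,
    step_onset, step_offset, surround_offset, ...) to times in seconds.
    """

    frames: np.ndarray
    frame_rate: float
    geometry: ScreenGeometry
    events: dict[str, float] = field(default_factory=dict)
    condition: str = "noise_mapping"
    step_amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, elevation, azimuth)")
        lo, hi = self.frames.min(initial=0.5), self.frames.max(initial=0.5)
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"luminance out of [0, 1]: range [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def pixel_trace(self, azimuth: float, elevation: float) -> np.ndarray:
        row, col = self.geometry.nearest_pixel(azimuth, elevation)
        return self.frames[:, row, col]

    # ---- persistence -----------------------------------------------------

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("frames", data=self.frames, compression="gzip")
            ds.attrs["frame_rate"] = self.frame_rate
            ds.attrs["condition"] = self.condition
            ds.attrs["step_amplitude"] = self.step_amplitude
            for key in ("azimuth_extent", "elevation_extent", "n_azimuth", "n_elevation"):
                ds.attrs[key] = getattr(self.geometry, key)
            ev = fh.create_group("events")
            for name, t in self.events.items():
                ev.attrs[name] = t

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "StimulusMovie":
        with h5py.File(path, "r") as fh:
            ds = fh["frames"]
            geometry = ScreenGeometry(
                azimuth_extent=float(ds.attrs["azimuth_extent"]),
                elevation_extent=float(ds.attrs["elevation_extent"]),
                n_azimuth=int(ds.attrs["n_azimuth"]),
                n_elevation=int(ds.attrs["n_elevation"]),
            )
            return cls(
                frames=ds[...],
                frame_rate=float(ds.attrs["frame_rate"]),
                geometry=geometry,
                events={k: float(v) for k, v in fh["events"].attrs.items()},
                condition=str(ds.attrs["condition"]),
                step_amplitude=float(ds.attrs.get("step_amplitude", 1.0)),
            )


@dataclass
class StepProtocolSpec:
    """Parameters of the center-step protocol.

    The step is shown through a circular window (default 5° diameter) at the
    receptive-field center, surrounded by a gray annulus (default 30° outer
    diameter at luminance 0.5); one of four surround conditions covers the
    remaining screen.  ON polarity steps luminance 0 -> amplitude, OFF steps
    1 -> 1 - amplitude.
    """

    center: tuple[float, float] = (0.0, 0.0)
    center_diameter: float = 5.0
    annulus_diameter: float = 30.0
    annulus_luminance: float = 0.5
    surround_condition: str = "gray"
    step_amplitude: float = 1.0
    polarity: Literal["ON", "OFF"] = "ON"
    grating_wavelength: float = 20.0
    grating_temporal_frequency: float = 1.0
    noise_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.step_amplitude <= 1:
            raise ValueError("step_amplitude must be in (0, 1]")
        if self.center_diameter >= self.annulus_diameter:
            raise ValueError("center_diameter must be smaller than annulus_diameter")
        if self.surround_condition not in SURROUND_CONDITIONS:
            raise ValueError(
                f"surround_condition must be one of {SURROUND_CONDITIONS}"
            )
        if self.polarity not in ("ON", "OFF"):
            raise ValueError("polarity must be 'ON' or 'OFF'")

    @property
    def is_dynamic(self) -> bool:
        return self.surround_condition in DYNAMIC_CONDITIONS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StepProtocolSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        cfg = cfg.get("protocol", cfg)
        if "center" in cfg:
            cfg["center"] = tuple(cfg["center"])
        # YAML 1.1 reads bare ON/OFF as booleans
        if isinstance(cfg.get("polarity"), bool):
            cfg["polarity"] = "ON" if cfg["polarity"] else "OFF"
        return cls(**cfg)


# --------------------------------------------------------------------------
# Noise (receptive-field mapping) stimulus
# --------------------------------------------------------------------------

def _gaussian_kernel(sigma_samples: float) -> np.ndarray:
    """Normalized Gaussian kernel truncated at 4 sigma; delta for sigma ~ 0."""
    if sigma_samples < 1e-6:
        return np.array([1.0])
    radius = max(1, int(np.ceil(4 * sigma_samples)))
    t = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (t / sigma_samples) ** 2)
    return w / w.sum()


def _smoothed_unit_noise(
    shape: tuple[int, ...], sigma_samples: float, rng: np.random.Generator
) -> np.ndarray:
    """Temporally Gaussian-smoothed white noise, rescaled to unit variance
    (analytically, so pixels stay independent)."""
    white = rng.standard_normal(shape)
    kernel = _gaussian_kernel(sigma_samples)
    if kernel.size == 1:
        return white
    smoothed = convolve1d(white, kernel, axis=0, mode="reflect")
    return smoothed / np.sqrt(np.sum(kernel**2))


def make_noise_stimulus(
    geometry: ScreenGeometry,
    duration: float,
    frame_rate: float,
    temporal_sigma: float = 0.09,
    seed: int = 0,
    binarize: bool = False,
) -> StimulusMovie:
    """Full-field Gaussian pixel noise, temporally low-pass filtered.

    Each pixel's luminance is an independent Gaussian time series (mean 0.5,
    SD 0.25 — full-range "100% contrast" — clipped to [0, 1]) smoothed in
    time with a Gaussian window of standard deviation ``temporal_sigma``
    (default 90 ms).  With ``binarize=True`` the smoothed noise is instead
    thresholded at its mean to binary {0, 1} luminance.
    """
    if duration <= 0 or frame_rate <= 0:
        raise ValueError("duration and frame_rate must be positive")
    if temporal_sigma <= 0:
        raise ValueError("temporal_sigma must be positive")
    rng = np.random.default_rng(seed)
    n = round(duration * frame_rate)
    z = _smoothed_unit_noise(
        (n, geometry.n_elevation, geometry.n_azimuth),
        temporal_sigma * frame_rate,
        rng,
    )
    if binarize:
        frames = (z > 0).astype(float)
    else:
        frames = np.clip(0.5 + 0.25 * z, 0.0, 1.0)
    return StimulusMovie(
        frames=frames,
        frame_rate=frame_rate,
        geometry=geometry,
        events={"onset": 0.0},
        condition="noise_mapping",
    )


# --------------------------------------------------------------------------
# Center-step protocol
# --------------------------------------------------------------------------

def region_masks(
    spec: StepProtocolSpec, geometry: ScreenGeometry
) -> dict[str, np.ndarray]:
    """Boolean (elevation, azimuth) masks for center, annulus and surround.

    Membership uses the angular distance of each pixel center from the
    protocol center on the flat degree grid.
    """
    az0, el0 = spec.center
    az = geometry.azimuths[np.newaxis, :]
    el = geometry.elevations[:, np.newaxis]
    dist = np.hypot(az - az0, el - el0)
    center = dist <= spec.center_diameter / 2
    annulus = (dist > spec.center_diameter / 2) & (dist <= spec.annulus_diameter / 2)
    surround = dist > spec.annulus_diameter / 2
    return {"center": center, "annulus": annulus, "surround": surround}


def _check_fits(spec: StepProtocolSpec, geometry: ScreenGeometry) -> None:
    az0, el0 = spec.center
    r = spec.annulus_diameter / 2
    if (
        abs(az0) + r > geometry.azimuth_extent / 2
        or abs(el0) + r > geometry.elevation_extent / 2
    ):
        raise GeometryError(
            f"annulus of radius {r}° around {spec.center} exceeds the "
            f"{geometry.azimuth_extent}x{geometry.elevation_extent}° screen"
        )


def _square_grating(azimuths: np.ndarray, wavelength: float, phase: float) -> np.ndarray:
    """Full-contrast square-wave grating along azimuth: luminance in {0, 1}."""
    return (np.mod(azimuths - phase, wavelength) < wavelength / 2).astype(float)


def _center_luminance(spec: StepProtocolSpec, in_step: bool) -> float:
    if spec.polarity == "ON":
        return spec.step_amplitude if in_step else 0.0
    return 1.0 - spec.step_amplitude if in_step else 1.0


def make_step_protocol(
    spec: StepProtocolSpec,
    geometry: ScreenGeometry,
    frame_rate: float = 60.0,
    seed: int = 0,
) -> StimulusMovie:
    """Render the 6 s center-step protocol.

    Timeline: the surround condition appears at 0 s; for dynamic conditions
    its dynamics start at 2 s (1 s before the step); the 1 s luminance step
    runs from 3 s to 4 s; the surround stays until 6 s.  The center window
    and annulus are identical across all four surround conditions.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    _check_fits(spec, geometry)
    masks = region_masks(spec, geometry)
    n = round(SURROUND_OFFSET * frame_rate)
    times = np.arange(n) / frame_rate
    frames = np.empty((n, geometry.n_elevation, geometry.n_azimuth))

    # Surround pattern per frame
    az_row = geometry.azimuths
    cond = spec.surround_condition
    if cond == "stochastic_noise":
        # Binary pixel noise with the stated temporal cutoff: Gaussian noise
        # low-pass filtered (sigma ~ 0.09 s per 1 Hz of cutoff, matching the
        # 90 ms / 1 Hz correspondence of the mapping stimulus), thresholded
        # at its mean.  The pattern is frozen until dynamics onset.
        rng = np.random.default_rng(seed)
        sigma_s = 0.09 / spec.noise_cutoff
        z = _smoothed_unit_noise(
            (n, geometry.n_elevation, geometry.n_azimuth), sigma_s * frame_rate, rng
        )
        noise_frames = (z > 0).astype(float)

    for i, t in enumerate(times):
        if cond == "gray":
            surround_frame = 0.5
        elif cond == "stationary_grating":
            surround_frame = _square_grating(az_row, spec.grating_wavelength, 0.0)[
                np.newaxis, :
            ]
        elif cond == "moving_grating":
            # Drifts one wavelength per 1/f seconds once dynamics start.
            t_dyn = max(0.0, t - DYNAMICS_ONSET)
            phase = spec.grating_wavelength * spec.grating_temporal_frequency * t_dyn
            surround_frame = _square_grating(
                az_row, spec.grating_wavelength, phase
            )[np.newaxis, :]
        else:  # stochastic_noise
            idx = i if t >= DYNAMICS_ONSET else 0
            surround_frame = noise_frames[idx]

        frame = np.empty((geometry.n_elevation, geometry.n_azimuth))
        frame[masks["surround"]] = np.broadcast_to(
            surround_frame, frame.shape
        )[masks["surround"]]
        frame[masks["annulus"]] = spec.annulus_luminance
        in_step = STEP_ONSET <= t < STEP_OFFSET
        frame[masks["center"]] = _center_luminance(spec, in_step)
        frames[i] = frame

    events = {
        "surround_onset": SURROUND_ONSET,
        "step_onset": STEP_ONSET,
        "step_offset": STEP_OFFSET,
        "surround_offset": SURROUND_OFFSET,
    }
    if spec.is_dynamic:
        events["dynamics_onset"] = DYNAMICS_ONSET
    return StimulusMovie(
        frames=frames,
        frame_rate=frame_rate,
        geometry=geometry,
        events=events,
        condition=cond,
        step_amplitude=spec.step_amplitude,
    )


def save_region_traces(
    movie: StimulusMovie, spec: StepProtocolSpec, path: str | Path
) -> None:
    """Write per-region mean-luminance traces (time, center, annulus,
    surround) as CSV for inspection."""
    masks = region_masks(spec, movie.geometry)
    cols = [movie.times] + [
        movie.frames[:, masks[r]].mean(axis=1) for r in ("center", "annulus", "surround")
    ]
    np.savetxt(
        path,
        np.column_stack(cols),
        delimiter=",",
        header="time,center,annulus,surround",
        comments="",
    )
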