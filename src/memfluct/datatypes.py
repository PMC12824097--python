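"""Core data containers shared across the pipeline.

All containers are plain dataclasses that validate their invariants at
construction time.  Units are part of the contract and are documented on
every field: tension in pN/um, confinement in pN/um^3, lengths in nm for
heights and in um for lateral pixel sizes, wavevectors in 1/um.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

#: Boltzmann constant in pN*um/K (1.380649e-23 J/K).
KB_PN_UM_PER_K = 1.380649e-5


@dataclass(frozen=True)
class MechParams:
    """Physical parameter set of the membrane fluctuation model.

    Attributes
    ----------
    sigma : float
        Membrane tension, pN/um.
    gamma : float
        Confinement coefficient, pN/um^3.
    eta_eff : float
        Effective cytoplasmic viscosity, Pa*s (== pN*s/um^2).
    a_active : float
        Active temperature multiplier, dimensionless.
    kappa : float
        Bending rigidity in units of kB*T.
    temperature : float
        Absolute temperature, K.
    q_min, q_max : float
        Wavevector integration bounds, 1/um.
    """

    sigma: float
    gamma: float
    eta_eff: float
    a_active: float = 1.0
    kappa: float = 15.0
    temperature: float = 310.15
    q_min: float = 12.083
    q_max: float = 48.332

    def __post_init__(self) -> None:
        for name in ("sigma", "gamma", "eta_eff", "a_active", "kappa",
                     "temperature", "q_min", "q_max"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.q_min >= self.q_max:
            raise ValueError(
                f"q_min must be < q_max, got {self.q_min} >= {self.q_max}")

    @property
    def kbt(self) -> float:
        """Thermal energy kB*T in pN*um."""
        return KB_PN_UM_PER_K * self.temperature

    def replace(self, **changes) -> "MechParams":
        return replace(self, **changes)


@dataclass
class FluctuationMovie:
    """Time-resolved basal-membrane height or interference intensity field.

    ``values`` has shape (T, H, W); a 1x1 spatial field represents a single
    region time series.  ``units`` is ``"nm"`` for relative height and
    ``"au"`` for raw interference intensity.
    """

    values: np.ndarray
    units: str
    pixel_size: float          # nm per pixel
    frame_interval: float      # s
    seed: Optional[int] = None
    truth_tension: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a (T, H, W) array")
        if self.values.shape[0] < 2:
            raise ValueError("movie needs at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.units not in ("nm", "au"):
            raise ValueError("units must be 'nm' (height) or 'au' (intensity)")
        if self.truth_tension is not None:
            self.truth_tension = np.asarray(self.truth_tension, dtype=float)
            if self.truth_tension.shape != self.values.shape[1:]:
                raise ValueError("truth_tension must match the spatial shape")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape[1:]

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.frame_interval

    def series(self, row: int = 0, col: int = 0) -> np.ndarray:
        """Time series of a single pixel."""
        return self.values[:, row, col]


@dataclass
class FluorescenceStack:
    """Multi-channel fluorescence z-stack, shape (C, Z, H, W)."""

    values: np.ndarray
    channels: Tuple[str, ...]
    pixel_size_xy: float = 0.13   # um, default per confocal acquisition
    z_step: float = 1.0           # um
    truth_masks: Optional[np.ndarray] = None
    truth_overlap_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be a (C, Z, H, W) array")
        if np.any(self.values < 0):
            raise ValueError("intensities must be nonnegative")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.values.shape[0]:
            raise ValueError("channel names must match the first axis")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.truth_masks is not None:
            self.truth_masks = np.asarray(self.truth_masks, dtype=bool)
            if self.truth_masks.shape != self.values.shape:
                raise ValueError("truth_masks must match values shape")
        if self.truth_overlap_fraction is not None:
            if not 0.0 <= self.truth_overlap_fraction <= 1.0:
                raise ValueError("truth_overlap_fraction must lie in [0, 1]")

    @property
    def n_slices(self) -> int:
        return self.values.shape[1]

    def channel(self, name_or_index) -> np.ndarray:
        if isinstance(name_or_index, str):
            name_or_index = self.channels.index(name_or_index)
        return self.values[name_or_index]


@dataclass
class ScatteringProfile:
    """1-D small-angle scattering profile I(s), s in 1/nm."""

    s: np.ndarray
    intensity: np.ndarray
    sigma_i: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s.shape != self.intensity.shape or self.s.ndim != 1:
            raise ValueError("s and intensity must be 1-D arrays of equal length")
        if self.s.size < 8:
            raise ValueError("profile needs at least 8 points")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be strictly positive")
        if self.sigma_i is not None:
            self.sigma_i = np.asarray(self.sigma_i, dtype=float)
            if self.sigma_i.shape != self.s.shape:
                raise ValueError("sigma_i must match s")
            if np.any(self.sigma_i <= 0):
                raise ValueError("sigma_i must be strictly positive")


@dataclass
class CorrelationCurve:
    """1-D fluorescence correlation curve G(tau), tau in s."""

    tau: np.ndarray
    g: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.tau.shape != self.g.shape or self.tau.ndim != 1:
            raise ValueError("tau and g must be 1-D arrays of equal length")
        if self.tau.size < 10:
            raise ValueError("curve needs at least 10 lags")
        if np.any(self.tau <= 0) or np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing and positive")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("g must be finite")
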