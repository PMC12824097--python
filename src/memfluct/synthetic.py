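"""Synthetic ground-truth generators for every pipeline input.

All generators are pure functions of their arguments and an explicit seed;
no global random state is touched.  Height movies are produced by spectral
synthesis (random-phase inverse FFT) so the population spectrum of each
pixel series equals the fluctuation model exactly at the FFT bin
frequencies.  Neighbouring pixels are statistically independent — a stated
fidelity limitation that is sufficient for per-region and per-pixel fitting
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from skimage.morphology import diamond

from .datatypes import (CorrelationCurve, FluctuationMovie, FluorescenceStack,
                        MechParams, ScatteringProfile)
from .mechanics import helfrich_psd

__all__ = [
    "PRESETS",
    "preset_params",
    "simulate_height_series",
    "simulate_fluctuation_movie",
    "simulate_tirf_frame",
    "simulate_scattering_profile",
    "simulate_fcs_curve",
    "simulate_coloc_stack",
    "simulate_cell_image",
    "SyntheticCellImage",
    "fcs_model",
]


# Acquisition presets: the correlative TIRF-IRM sets use 2,048 frames at
# 20 Hz with ~65 nm pixels; stand-alone global measurements use 8,192 frames
# at 50 Hz with ~300 nm pixels.  q-bounds follow q_min = pi / (4 px) and
# q_max = pi / px.
PRESETS: Dict[str, Dict[str, float]] = {
    "tirf-irm": dict(n_frames=2048, sampling_rate=20.0, pixel_size=65.0),
    "irm-global": dict(n_frames=8192, sampling_rate=50.0, pixel_size=300.0),
}

_DEFAULT_MECH = dict(sigma=500.0, gamma=5.0e3, eta_eff=100.0, a_active=1.5,
                     kappa=15.0, temperature=310.15)


def preset_params(name: str, **overrides) -> Tuple[MechParams, Dict[str, float]]:
    """Mechanical parameters and acquisition settings for a named preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    acq = dict(PRESETS[name])
    px_um = acq["pixel_size"] / 1000.0
    mech = dict(_DEFAULT_MECH, q_min=np.pi / (4 * px_um), q_max=np.pi / px_um)
    mech.update(overrides)
    return MechParams(**mech), acq


# ---------------------------------------------------------------------------
# spectral synthesis
# ---------------------------------------------------------------------------

def _synthesize_series(psd_values: np.ndarray, n_frames: int,
                       sampling_rate: float, rng: np.random.Generator,
                       n_pixels: int = 1) -> np.ndarray:
    """Random-phase synthesis of stationary Gaussian series, shape (n_pixels, T).

    ``psd_values`` holds the one-sided model PSD (nm^2/Hz) at the positive
    rfft bin frequencies, shape (n_pixels, n_bins) or (n_bins,).
    """
    psd_values = np.atleast_2d(psd_values)
    n_bins = psd_values.shape[1]
    spectrum = np.zeros((n_pixels, n_bins + 1), dtype=complex)
    even = n_frames % 2 == 0
    n_complex = n_bins - 1 if even else n_bins
    scale = np.sqrt(psd_values[:, :n_complex] * sampling_rate * n_frames / 2.0)
    re = rng.standard_normal((n_pixels, n_complex))
    im = rng.standard_normal((n_pixels, n_complex))
    spectrum[:, 1:n_complex + 1] = scale * (re + 1j * im) / np.sqrt(2.0)
    if even:
        nyq_scale = np.sqrt(psd_values[:, -1] * sampling_rate * n_frames)
        spectrum[:, -1] = nyq_scale * rng.standard_normal(n_pixels)
    return np.fft.irfft(spectrum, n=n_frames, axis=1)


def simulate_height_series(params: MechParams, sampling_rate: float,
                           n_frames: int, seed: int) -> FluctuationMovie:
    """Single-region stationary Gaussian height series with the model PSD.

    Returns a 1x1-pixel movie in nm; the series is zero-mean by construction
    (DC bin fixed to zero) and bit-identical for identical arguments.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if n_frames < 256:
        raise ValueError("n_frames must be at least 256")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_frames, 1.0 / sampling_rate)[1:]
    psd = helfrich_psd(freqs, params)
    series = _synthesize_series(psd, n_frames, sampling_rate, rng)[0]
    pixel_size = 1000.0 * np.pi / params.q_max  # nm, consistent with q_max
    return FluctuationMovie(values=series[:, None, None], units="nm",
                            pixel_size=pixel_size,
                            frame_interval=1.0 / sampling_rate, seed=seed)


def simulate_fluctuation_movie(truth_tension, base_params: MechParams,
                               pixel_size: float, sampling_rate: float,
                               n_frames: int, seed: int) -> FluctuationMovie:
    """Pixel-wise independent height movie with per-pixel tension field.

    Each pixel's series is synthesized with sigma taken from
    ``truth_tension`` (pN/um) and the remaining parameters from
    ``base_params``; the truth field is stored in the output.
    """
    truth_tension = np.asarray(truth_tension, dtype=float)
    if truth_tension.ndim != 2:
        raise ValueError("truth_tension must be a 2-D field")
    if np.any(truth_tension <= 0) or not np.all(np.isfinite(truth_tension)):
        raise ValueError("truth_tension must be strictly positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if n_frames < 256:
        raise ValueError("n_frames must be at least 256")
    h, w = truth_tension.shape
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_frames, 1.0 / sampling_rate)[1:]
    flat = truth_tension.ravel()
    # model spectra are shared between pixels of equal tension
    unique, inverse = np.unique(flat, return_inverse=True)
    spectra = np.stack([helfrich_psd(freqs, base_params.replace(sigma=s))
                        for s in unique])
    psd_per_pixel = spectra[inverse]
    series = _synthesize_series(psd_per_pixel, n_frames, sampling_rate, rng,
                                n_pixels=flat.size)
    values = series.T.reshape(n_frames, h, w)
    return FluctuationMovie(values=values, units="nm", pixel_size=pixel_size,
                            frame_interval=1.0 / sampling_rate, seed=seed,
                            truth_tension=truth_tension)


# ---------------------------------------------------------------------------
# fluorescence fixtures
# ---------------------------------------------------------------------------

def simulate_tirf_frame(centers: Sequence[Tuple[float, float]],
                        amplitudes, psf_sigma: float, background: float,
                        noise_sd: float, shape: Tuple[int, int],
                        seed: int = 0) -> FluorescenceStack:
    """Sum of isotropic Gaussian spots + constant background + Gaussian noise."""
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    h, w = shape
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float),
                                 (len(centers),))
    rows, cols = np.mgrid[0:h, 0:w]
    image = np.full((h, w), float(background))
    for (cr, cc), amp in zip(centers, amplitudes):
        if not (0 <= cr < h and 0 <= cc < w):
            raise ValueError(f"center {(cr, cc)} outside image bounds")
        image += amp * np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2)
                              / (2.0 * psf_sigma ** 2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + noise_sd * rng.standard_normal((h, w))
    image = np.clip(image, 0.0, None)
    return FluorescenceStack(values=image[None, None], channels=("tirf",))


# ---------------------------------------------------------------------------
# scattering and correlation fixtures
# ---------------------------------------------------------------------------

def simulate_scattering_profile(rg: float, rc: Optional[float] = None,
                                i0: float = 1.0,
                                s_grid: Optional[np.ndarray] = None,
                                noise_cv: float = 0.0,
                                interparticle: bool = False,
                                seed: int = 0) -> ScatteringProfile:
    """Guinier-type scattering profile with optional rod factor and
    low-angle interparticle suppression.

    Without ``rc`` the profile is the globular form I = i0 exp(-s^2 rg^2 / 3).
    With ``rc`` the rod cross-section form (c/s) exp(-s^2 rc^2 / 2) is used,
    scaled so the first grid point is near ``i0``.  Interparticle repulsion
    is emulated as a linear deficit below s = 0.2/rg, mirroring the downward
    trend of the lowest-angle points seen for charged particles in
    low-ionic-strength solvent.
    """
    if rg <= 0:
        raise ValueError("rg must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if rc is not None and rc >= rg:
        raise ValueError("rc must be smaller than rg")
    if s_grid is None:
        s_grid = np.linspace(0.01, 2.0 / rg, 120)
    s = np.asarray(s_grid, dtype=float)
    if rc is None:
        intensity = i0 * np.exp(-(s ** 2) * rg ** 2 / 3.0)
    else:
        intensity = i0 * (s[0] / s) * np.exp(-(s ** 2) * rc ** 2 / 2.0)
    if interparticle:
        s_cut = 0.2 / rg
        deficit = 0.4 * np.clip(1.0 - s / s_cut, 0.0, 1.0)
        intensity = intensity * (1.0 - deficit)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + noise_cv * rng.standard_normal(s.size))
        intensity = np.maximum(intensity, 1e-12 * i0)
    return ScatteringProfile(s=s, intensity=intensity)


def fcs_model(tau, n_particles: float, tau_d: float, s_struct: float,
              k_triplet: float = 0.0, tau_triplet: float = 1e-6) -> np.ndarray:
    """3-D Gaussian one-component diffusion autocorrelation with triplet term.

    G(tau) = (1/N) (1 + tau/tauD)^-1 (1 + tau/(S^2 tauD))^-1/2
             * (1 + K exp(-tau/tauS))
    """
    tau = np.asarray(tau, dtype=float)
    g = (1.0 / n_particles
         * (1.0 + tau / tau_d) ** -1.0
         * (1.0 + tau / (s_struct ** 2 * tau_d)) ** -0.5)
    if k_triplet != 0.0:
        g = g * (1.0 + k_triplet * np.exp(-tau / tau_triplet))
    return g


def simulate_fcs_curve(n_particles: float, tau_d: float, s_struct: float = 5.0,
                       k_triplet: float = 0.0, tau_triplet: float = 2e-6,
                       tau_grid: Optional[np.ndarray] = None,
                       noise_cv: float = 0.0, seed: int = 0,
                       label: str = "") -> CorrelationCurve:
    """Model correlation curve with multiplicative Gaussian noise of CV noise_cv."""
    if n_particles <= 0:
        raise ValueError("n_particles must be positive")
    for name, value in (("tau_d", tau_d), ("tau_triplet", tau_triplet),
                        ("s_struct", s_struct)):
        if value <= 0:
            raise ValueError(f"{name} must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if tau_grid is None:
        tau_grid = np.logspace(-7, 0, 160)
    tau = np.asarray(tau_grid, dtype=float)
    g = fcs_model(tau, n_particles, tau_d, s_struct, k_triplet, tau_triplet)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        g = g * (1.0 + noise_cv * rng.standard_normal(tau.size))
    return CorrelationCurve(tau=tau, g=g, label=label)


# ---------------------------------------------------------------------------
# colocalization fixtures
# ---------------------------------------------------------------------------

_BLOB_RADIUS = 2          # diamond footprint radius, open under a 3x3 cross
_LATTICE_START = 10
_LATTICE_STEP = 9
# nonzero camera baseline keeps local-mean thresholding (threshold capped at
# twice the local mean) meaningful under additive noise
_BACKGROUND = 100.0
_ENDOSOME_AMP = 300.0
_ACTIN_AMP = 280.0


def _lattice_centers(shape: Tuple[int, int]) -> np.ndarray:
    h, w = shape
    rows = np.arange(_LATTICE_START, h - _LATTICE_START + 1, _LATTICE_STEP)
    cols = np.arange(_LATTICE_START, w - _LATTICE_START + 1, _LATTICE_STEP)
    return np.array([(r, c) for r in rows for c in cols])


def _stamp(mask: np.ndarray, center: Tuple[int, int]) -> None:
    foot = diamond(_BLOB_RADIUS).astype(bool)
    r, c = center
    mask[r - _BLOB_RADIUS: r + _BLOB_RADIUS + 1,
         c - _BLOB_RADIUS: c + _BLOB_RADIUS + 1] |= foot


def simulate_coloc_stack(n_endosomes: int, n_overlapping: int,
                         n_actin_extra: int = 0, cortical_ring: bool = False,
                         n_slices: int = 1, shape: Tuple[int, int] = (64, 64),
                         seed: int = 0) -> FluorescenceStack:
    """Dual-channel stack with controlled endosome/actin overlap.

    Channel 0 holds endosome blobs; channel 1 holds actin patches overlapping
    exactly ``n_overlapping`` endosomes plus ``n_actin_extra`` free patches
    and, optionally, a thick cortical ring along the boundary.  Blobs are
    diamond-shaped (open under the 3x3 cross used for despeckling) and are
    placed on a lattice guaranteeing at least 2 px separation between
    distinct objects.  The per-slice layout is re-randomized.
    """
    if n_overlapping > n_endosomes:
        raise ValueError("n_overlapping cannot exceed n_endosomes")
    if n_endosomes <= 0:
        raise ValueError("need at least one endosome")
    rng = np.random.default_rng(seed)
    centers = _lattice_centers(shape)
    needed = n_endosomes + n_actin_extra
    if len(centers) < needed:
        raise ValueError(
            f"geometry too crowded: {needed} objects requested but only "
            f"{len(centers)} lattice sites available in shape {shape}")
    h, w = shape
    endo = np.zeros((n_slices, h, w))
    actin = np.zeros((n_slices, h, w))
    endo_mask = np.zeros((n_slices, h, w), dtype=bool)
    actin_mask = np.zeros((n_slices, h, w), dtype=bool)
    for z in range(n_slices):
        order = rng.permutation(len(centers))
        picks = centers[order[:needed]]
        endo_centers = picks[:n_endosomes]
        extra_centers = picks[n_endosomes:]
        e_mask = np.zeros((h, w), dtype=bool)
        a_mask = np.zeros((h, w), dtype=bool)
        for center in endo_centers:
            _stamp(e_mask, tuple(center))
        for center in endo_centers[:n_overlapping]:
            _stamp(a_mask, (center[0] + 1, center[1] + 1))
        for center in extra_centers:
            _stamp(a_mask, tuple(center))
        if cortical_ring:
            ring = np.zeros((h, w), dtype=bool)
            ring[1:4, 1:w - 1] = True
            ring[h - 4:h - 1, 1:w - 1] = True
            ring[1:h - 1, 1:4] = True
            ring[1:h - 1, w - 4:w - 1] = True
            a_mask |= ring
        endo_mask[z] = e_mask
        actin_mask[z] = a_mask
        endo[z] = _BACKGROUND + (_ENDOSOME_AMP - _BACKGROUND) * e_mask
        actin[z] = _BACKGROUND + (_ACTIN_AMP - _BACKGROUND) * a_mask
    values = np.stack([endo, actin])
    masks = np.stack([endo_mask, actin_mask])
    return FluorescenceStack(
        values=values, channels=("endosome", "actin"),
        truth_masks=masks,
        truth_overlap_fraction=n_overlapping / n_endosomes)


# ---------------------------------------------------------------------------
# cell-image fixture
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCellImage:
    stack: FluorescenceStack
    nuclear_mask: np.ndarray
    cell_mask: np.ndarray


def simulate_cell_image(nuclear_mean: float, cyto_mean: float,
                        nuclear_mask, cell_mask, noise_sd: float = 0.0,
                        seed: int = 0) -> SyntheticCellImage:
    """Single-slice cell image with known region means and stored masks."""
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if nuclear_mask.shape != cell_mask.shape:
        raise ValueError("masks must share one shape")
    if np.any(nuclear_mask & ~cell_mask):
        raise ValueError("nuclear_mask must lie strictly inside cell_mask")
    if not np.any(cell_mask & ~nuclear_mask):
        raise ValueError("cytoplasmic region is empty")
    image = np.zeros(cell_mask.shape, dtype=float)
    image[cell_mask] = cyto_mean
    image[nuclear_mask] = nuclear_mean
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + noise_sd * rng.standard_normal(image.shape)
    image = np.clip(image, 0.0, None)
    stack = FluorescenceStack(values=image[None, None], channels=("signal",))
    return SyntheticCellImage(stack=stack, nuclear_mask=nuclear_mask,
                              cell_mask=cell_mask)
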