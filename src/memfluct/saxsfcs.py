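"""Ligand self-association analytics from SAXS profiles and FCS curves.

Guinier fits for globular (ln I vs s^2, Rg = sqrt(-3*slope)) and rod-like
(ln sI vs s^2, Rc = sqrt(-2*slope)) scatterers, the derived persistence
length L = sqrt(12 (Rg^2 - Rc^2)) and aspect ratio A = Rg/Rc, dimensionless
Kratky transform (peaking at s*Rg = sqrt(3) for an ideal Guinier scatterer),
low-angle interparticle-effect detection, autocorrelation fitting of the
3-D Gaussian one-component diffusion model, beam-waist calibration
(tauD = omega^2 / 4D) and cube-root oligomer counting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .datatypes import CorrelationCurve, ScatteringProfile

__all__ = [
    "GuinierResult",
    "RodGuinierResult",
    "ShapeParams",
    "KratkyCurve",
    "FCSFit",
    "FCSCalibration",
    "guinier_fit_globular",
    "guinier_fit_rod",
    "shape_parameters",
    "dimensionless_kratky",
    "detect_interparticle_effect",
    "fit_fcs_curve",
    "fcs_diffusion_calibration",
    "diffusion_coefficient",
    "diffusion_time",
    "oligomer_count",
    "particle_number_trend",
]


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------

@dataclass
class GuinierResult:
    rg: float                  # nm
    i0: float
    fit_range_max_srg: float
    r2: float
    n_points: int


@dataclass
class RodGuinierResult:
    rc: float                  # nm
    fit_range: Tuple[float, float]
    r2: float
    n_points: int


def _weighted_linfit(x, y, w=None) -> Tuple[float, float, float]:
    """Weighted least-squares line fit; returns slope, intercept, r^2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    wsum = w.sum()
    xm = (w * x).sum() / wsum
    ym = (w * y).sum() / wsum
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - slope * x - intercept
    ss_res = (w * resid ** 2).sum()
    ss_tot = (w * (y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def guinier_fit_globular(profile: ScatteringProfile,
                         srg_max: float = 1.3,
                         max_iter: int = 20) -> GuinierResult:
    """Iteratively windowed Guinier fit of ln I versus s^2.

    The admissible window s*rg <= srg_max is re-evaluated with the current
    rg estimate until it stabilizes (at most ``max_iter`` rounds).  Fits are
    weighted by the provided intensity uncertainties when present.
    """
    s = profile.s
    log_i = np.log(profile.intensity)
    weights = None
    if profile.sigma_i is not None:
        weights = (profile.intensity / profile.sigma_i) ** 2
    mask = np.ones(s.size, dtype=bool)
    rg = None
    for _ in range(max_iter):
        if mask.sum() < 3:
            raise ValueError("too few points in the Guinier window")
        w = weights[mask] if weights is not None else None
        slope, intercept, r2 = _weighted_linfit(s[mask] ** 2, log_i[mask], w)
        if slope >= 0:
            raise ValueError("nonnegative Guinier slope: no low-angle decay")
        new_rg = math.sqrt(-3.0 * slope)
        new_mask = s * new_rg <= srg_max
        if not new_mask.any():
            new_mask = np.zeros_like(mask)
            new_mask[:3] = True
        if rg is not None and np.array_equal(new_mask, mask):
            rg = new_rg
            break
        mask = new_mask
        rg = new_rg
    if mask.sum() < 3:
        raise ValueError("too few points in the Guinier window")
    w = weights[mask] if weights is not None else None
    slope, intercept, r2 = _weighted_linfit(s[mask] ** 2, log_i[mask], w)
    if slope >= 0:
        raise ValueError("nonnegative Guinier slope: no low-angle decay")
    rg = math.sqrt(-3.0 * slope)
    return GuinierResult(rg=rg, i0=float(np.exp(intercept)),
                         fit_range_max_srg=float(s[mask].max() * rg),
                         r2=r2, n_points=int(mask.sum()))


def guinier_fit_rod(profile: ScatteringProfile,
                    fit_range: Optional[Tuple[float, float]] = None
                    ) -> RodGuinierResult:
    """Rod-like Guinier fit of ln(s*I) versus s^2; rc = sqrt(-2*slope)."""
    s = profile.s
    log_si = np.log(s * profile.intensity)
    if fit_range is None:
        mask = np.ones(s.size, dtype=bool)
    else:
        lo, hi = fit_range
        mask = (s >= lo) & (s <= hi)
    if mask.sum() < 3:
        raise ValueError("too few points in the rod Guinier range")
    weights = None
    if profile.sigma_i is not None:
        weights = ((profile.intensity / profile.sigma_i) ** 2)[mask]
    slope, _, r2 = _weighted_linfit(s[mask] ** 2, log_si[mask], weights)
    if slope >= 0:
        raise ValueError("nonnegative rod-Guinier slope: no decay")
    rc = math.sqrt(-2.0 * slope)
    lo, hi = float(s[mask].min()), float(s[mask].max())
    return RodGuinierResult(rc=rc, fit_range=(lo, hi), r2=r2,
                            n_points=int(mask.sum()))


@dataclass
class ShapeParams:
    l_persist: float   # nm
    a_aspect: float


def shape_parameters(rg: float, rc: float) -> ShapeParams:
    """L = sqrt(12 (rg^2 - rc^2)), A = rg/rc."""
    if rc <= 0 or rg <= 0:
        raise ValueError("radii must be positive")
    if rc > rg:
        raise ValueError("rc must not exceed rg (negative radicand)")
    l_persist = math.sqrt(12.0 * (rg ** 2 - rc ** 2))
    return ShapeParams(l_persist=l_persist, a_aspect=rg / rc)


@dataclass
class KratkyCurve:
    x: np.ndarray          # s * rg
    y: np.ndarray          # (s rg)^2 I / I0
    peak_x: float


def dimensionless_kratky(profile: ScatteringProfile, rg: float,
                         i0: float) -> KratkyCurve:
    """Dimensionless Kratky transform y = (s rg)^2 I(s)/I0 on x = s rg."""
    if rg <= 0 or i0 <= 0:
        raise ValueError("rg and i0 must be positive")
    x = profile.s * rg
    y = x ** 2 * profile.intensity / i0
    peak_x = float(x[int(np.argmax(y))])
    return KratkyCurve(x=x, y=y, peak_x=peak_x)


def detect_interparticle_effect(profile: ScatteringProfile, rg: float,
                                n_low: int = 5, srg_max: float = 1.3,
                                deficit_tol: float = 0.05,
                                alpha: float = 0.05) -> Optional[bool]:
    """Flag low-angle intensity suppression (structure-factor effect).

    The ``n_low`` lowest-s points are set aside; a Guinier reference line is
    fitted on the upper half of the admissible window (s*rg in
    [srg_max/2, srg_max]) so a localized low-angle deficit cannot bias it.
    The flag is raised when the mean relative deficit of the excluded points
    versus the extrapolation exceeds ``deficit_tol`` and a one-sided sign
    test on their deficits is significant at ``alpha``.

    Returns None (insufficient data) when fewer than 3 low-s points or too
    few reference points are available.
    """
    if n_low < 3:
        raise ValueError("n_low must be at least 3")
    s = profile.s
    if s.size <= n_low + 3:
        return None
    ref = (s * rg >= srg_max / 2.0) & (s * rg <= srg_max)
    ref[:n_low] = False
    if ref.sum() < 3:
        return None
    slope, intercept, _ = _weighted_linfit(s[ref] ** 2,
                                           np.log(profile.intensity[ref]))
    expected = np.exp(intercept + slope * s[:n_low] ** 2)
    deficit = (expected - profile.intensity[:n_low]) / expected
    n_below = int(np.sum(deficit > 0))
    p_sign = stats.binomtest(n_below, n_low, 0.5, alternative="greater").pvalue
    return bool(deficit.mean() > deficit_tol and p_sign < alpha)


# ---------------------------------------------------------------------------
# FCS
# ---------------------------------------------------------------------------

@dataclass
class FCSFit:
    n_particles: float
    tau_d: float
    s_struct: float
    k_triplet: float
    tau_triplet: float
    r2: float
    converged: bool


def _fcs_g(tau, n, tau_d, s_struct, k, tau_s):
    g = (1.0 / n) * (1.0 + tau / tau_d) ** -1.0 \
        * (1.0 + tau / (s_struct ** 2 * tau_d)) ** -0.5
    if k != 0.0:
        g = g * (1.0 + k * np.exp(-tau / tau_s))
    return g


def fit_fcs_curve(curve: CorrelationCurve,
                  s_struct_fixed: Optional[float] = 5.0,
                  triplet: bool = False,
                  init: Optional[dict] = None) -> FCSFit:
    """Least-squares fit of the one-component diffusion model.

    The structural parameter S is fixed at the calibrated value by default
    (free when ``s_struct_fixed`` is None); with ``triplet=False`` the
    triplet amplitude K is fixed at 0.  Parameters are fitted in log space
    to enforce positivity.  A non-converging fit returns converged=False
    instead of raising.
    """
    tau = curve.tau
    g = curve.g
    init = dict(init or {})
    n0 = init.get("n_particles", 1.0 / max(g[0], 1e-12))
    # crude tau_d init: lag where g first drops below half its initial value
    half = g[0] / 2.0
    below = np.nonzero(g < half)[0]
    tau_d0 = init.get("tau_d", tau[below[0]] if below.size else tau[tau.size // 2])
    names = ["n_particles", "tau_d"]
    theta0 = [math.log(max(n0, 1e-9)), math.log(max(tau_d0, 1e-12))]
    if s_struct_fixed is None:
        names.append("s_struct")
        theta0.append(math.log(init.get("s_struct", 5.0)))
    if triplet:
        names += ["k_triplet", "tau_triplet"]
        theta0 += [math.log(init.get("k_triplet", 0.1)),
                   math.log(init.get("tau_triplet", tau_d0 / 50.0))]

    def unpack(theta):
        values = dict(zip(names, np.exp(theta)))
        n = values["n_particles"]
        tau_d = values["tau_d"]
        s_struct = values.get("s_struct", s_struct_fixed)
        k = values.get("k_triplet", 0.0)
        tau_s = values.get("tau_triplet", 1e-6)
        return n, tau_d, s_struct, k, tau_s

    def residuals(theta):
        return _fcs_g(tau, *unpack(theta)) - g

    result = optimize.least_squares(residuals, theta0, method="lm",
                                    xtol=1e-14, ftol=1e-14, max_nfev=2000)
    n, tau_d, s_struct, k, tau_s = unpack(result.x)
    ss_res = float(np.sum(result.fun ** 2))
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    converged = bool(result.success and np.all(np.isfinite(result.x)))
    return FCSFit(n_particles=n, tau_d=tau_d, s_struct=s_struct, k_triplet=k,
                  tau_triplet=tau_s, r2=r2, converged=converged)


@dataclass
class FCSCalibration:
    omega: float        # um, radial beam waist
    d_ref: float        # um^2/s
    tau_d_ref: float    # s


def fcs_diffusion_calibration(tau_d_ref: float, d_ref: float) -> FCSCalibration:
    """Beam waist from a reference dye: omega = sqrt(4 * D_ref * tauD_ref)."""
    if tau_d_ref <= 0 or d_ref <= 0:
        raise ValueError("calibration inputs must be positive")
    omega = math.sqrt(4.0 * d_ref * tau_d_ref)
    return FCSCalibration(omega=omega, d_ref=d_ref, tau_d_ref=tau_d_ref)


def diffusion_coefficient(tau_d: float, cal: FCSCalibration) -> float:
    """D = omega^2 / (4 tauD), um^2/s."""
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    return cal.omega ** 2 / (4.0 * tau_d)


def diffusion_time(d: float, cal: FCSCalibration) -> float:
    """tauD = omega^2 / (4 D), s (inverse of diffusion_coefficient)."""
    if d <= 0:
        raise ValueError("d must be positive")
    return cal.omega ** 2 / (4.0 * d)


def oligomer_count(fold_change_tau_d: float) -> float:
    """Monomer count from a diffusion-time fold change, cube-root rule.

    Diffusion time scales with the cube root of molecular weight, so the
    number of associated monomers is the cube of the tauD fold change.
    """
    if fold_change_tau_d < 1.0:
        raise ValueError("fold change must be >= 1")
    return fold_change_tau_d ** 3


# ---------------------------------------------------------------------------
# particle-number association trend
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided (negative-trend) exact Spearman p by full enumeration."""
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return 1.0
    observed = np.corrcoef(rx, ry)[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if rho <= observed + 1e-12:
            count += 1
        total += 1
    return count / total


def particle_number_trend(n_values, concentrations=None,
                          alpha: float = 0.05) -> Optional[str]:
    """Monotone-trend verdict on fitted particle numbers versus concentration.

    Uses Spearman rank correlation with a one-sided (decreasing) p-value:
    exact enumeration for up to 8 points, large-sample approximation
    otherwise.  Returns "association" when the decrease is significant,
    "none" otherwise, and None for fewer than 3 points.
    """
    n_values = np.asarray(n_values, dtype=float)
    if n_values.size < 3:
        return None
    if concentrations is None:
        concentrations = np.arange(n_values.size, dtype=float)
    concentrations = np.asarray(concentrations, dtype=float)
    if n_values.size <= 8:
        p = _spearman_exact_p(concentrations, n_values)
    else:
        rho, p_two = stats.spearmanr(concentrations, n_values)
        if not np.isfinite(rho):
            p = 1.0
        else:
            p = p_two / 2.0 if rho < 0 else 1.0 - p_two / 2.0
    return "association" if p < alpha else "none"
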