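"""Strain-dependent fiber-network constitutive model.

A planar fiber network under uniaxial stretch reorganizes: the fiber-angle
distribution R(theta, eps) is a Gaussian about a preferred angle theta0 whose
spread tightens exponentially with strain,

    sigma(eps) = sigma0 * exp(-alpha * eps) + sigma_inf,

and the axial second Piola-Kirchhoff stress accumulates fiber stresses over
angle and strain,

    S11(e11) = int_0^e11 int_{-pi/2}^{pi/2} R(theta, eps) cos^2(theta)
               * A * B * exp(B * eps) dtheta deps + k_matrix * e11,

with A (MPa) and B (dimensionless) governing fiber stiffness and
nonlinearity and k_matrix (MPa) the linear matrix contribution.  The Gaussian
is renormalized analytically over [-pi/2, pi/2) so that the angular density
integrates to one (a truncated normal); only its shape enters the fits.

Angles are degrees at every interface and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.stats import qmc


@dataclass(frozen=True)
class FiberModelParams:
    """Constitutive constants and organization parameters.

    A: fiber stiffness scale (MPa); B: nonlinearity exponent; k_matrix:
    matrix modulus (MPa); sigma0: initial angular spread (deg); sigma_inf:
    saturation spread (deg); alpha: organization rate; theta0: preferred
    fiber angle (deg).
    """

    A: float
    B: float
    k_matrix: float
    sigma0: float
    sigma_inf: float
    alpha: float
    theta0: float = 0.0

    def __post_init__(self) -> None:
        if self.A < 0 or self.B <= 0 or self.k_matrix < 0:
            raise ValueError("require A >= 0, B > 0, k_matrix >= 0")
        if self.sigma0 < 0 or self.sigma_inf <= 0 or self.alpha < 0:
            raise ValueError("require sigma0 >= 0, sigma_inf > 0, alpha >= 0")


@dataclass
class AngleHistogram:
    """Normalized fiber-angle histogram at one strain level."""

    theta_deg: np.ndarray
    frequency: np.ndarray
    strain: float = 0.0

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, float)
        self.frequency = np.asarray(self.frequency, float)
        if np.any(self.frequency < 0):
            raise ValueError("histogram frequencies must be >= 0")

    def normalize(self) -> "AngleHistogram":
        z = np.trapezoid(self.frequency, self.theta_deg)
        return AngleHistogram(self.theta_deg, self.frequency / z, self.strain)


@dataclass
class StressStrainCurve:
    strain: np.ndarray
    stress_mpa: np.ndarray


@dataclass
class OrganizationFit:
    sigma0: float
    sigma_inf: float
    alpha: float
    theta0: float
    strains: np.ndarray
    sigma_per_histogram: np.ndarray
    rmse_per_histogram: np.ndarray


@dataclass
class StressFit:
    A: float
    B: float
    k_matrix: float
    r_squared: float


def sigma_of_strain(eps, params: FiberModelParams):
    """Angular spread (degrees) at strain ``eps`` (Eq. sigma0*e^-alpha*eps + sigma_inf)."""
    eps = np.asarray(eps, float)
    if np.any(eps < 0):
        raise ValueError("strain must be >= 0")
    out = params.sigma0 * np.exp(-params.alpha * eps) + params.sigma_inf
    return float(out) if out.ndim == 0 else out


def _truncated_gaussian(theta_deg, theta0: float, sigma_deg: float):
    """Unit-integral Gaussian density (per degree) on [-90, 90)."""
    theta = np.asarray(theta_deg, float)
    z = (theta - theta0) / sigma_deg
    dens = np.exp(-0.5 * z**2)
    # Analytic normalization of the truncated normal.
    lo, hi = (-90.0 - theta0) / sigma_deg, (90.0 - theta0) / sigma_deg
    norm = sigma_deg * math.sqrt(math.pi / 2.0) * (
        special.erf(hi / math.sqrt(2)) - special.erf(lo / math.sqrt(2))
    )
    return dens / norm


def angle_distribution(theta_deg, eps: float, params: FiberModelParams):
    """Fiber-angle density (per degree) at strain ``eps`` on [-90, 90)."""
    theta = np.asarray(theta_deg, float)
    if np.any(theta < -90) or np.any(theta >= 90):
        raise ValueError("theta grid must lie in [-90, 90)")
    return _truncated_gaussian(theta, params.theta0, sigma_of_strain(eps, params))


def predict_stress(
    strain,
    params: FiberModelParams,
    theta_step: float = 3.0,
    eps_step: float = 1.6e-4,
) -> StressStrainCurve:
    """Axial stress via the double integral over fiber angle and strain.

    The theta integral uses the trapezoid rule on a ``theta_step`` grid; the
    strain integral is a cumulative trapezoid on an ``eps_step`` grid, then
    interpolated onto the requested strain points.  Defaults are 3 degrees
    and 0.016% strain.
    """
    strain = np.asarray(strain, float)
    if strain.ndim != 1 or len(strain) == 0:
        raise ValueError("strain grid must be a nonempty 1-D array")
    if np.any(np.diff(strain) <= 0) and len(strain) > 1:
        raise ValueError("strain grid must be strictly increasing")
    if np.any(strain < 0):
        raise ValueError("strain must be >= 0")
    if theta_step <= 0 or eps_step <= 0:
        raise ValueError("integration steps must be > 0")

    smax = float(strain.max())
    if smax == 0 or params.A == 0:
        return StressStrainCurve(strain, params.k_matrix * strain)

    n_eps = max(int(math.ceil(smax / eps_step)) + 1, 2)
    eps = np.linspace(0.0, smax, n_eps)
    theta = np.arange(-90.0, 90.0 + theta_step / 2, theta_step)
    sig = sigma_of_strain(eps, params)  # (n_eps,)
    z = (theta[None, :] - params.theta0) / sig[:, None]
    dens = np.exp(-0.5 * z**2)
    lo = (-90.0 - params.theta0) / sig
    hi = (90.0 - params.theta0) / sig
    norm = sig * math.sqrt(math.pi / 2.0) * (
        special.erf(hi / math.sqrt(2)) - special.erf(lo / math.sqrt(2))
    )
    dens /= norm[:, None]
    cos2 = np.cos(np.radians(theta)) ** 2
    inner = np.trapezoid(dens * cos2[None, :], theta, axis=1)
    integrand = inner * params.A * params.B * np.exp(params.B * eps)
    s_fiber = np.concatenate(
        ([0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(eps)))
    )
    stress = np.interp(strain, eps, s_fiber) + params.k_matrix * strain
    return StressStrainCurve(strain, stress)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_single_histogram(hist: AngleHistogram) -> tuple[float, float, float]:
    """Fit (theta0, sigma) of a truncated Gaussian to one histogram; RMSE."""
    theta, freq = hist.theta_deg, hist.frequency
    w = freq / freq.sum()
    mu0 = float(np.sum(w * theta))
    sd0 = float(np.sqrt(np.sum(w * (theta - mu0) ** 2)))
    sd0 = min(max(sd0, 1.0), 89.0)

    def resid(p):
        return _truncated_gaussian(theta, p[0], p[1]) - freq

    sol = optimize.least_squares(
        resid, x0=[mu0, sd0], bounds=([-90.0, 0.5], [90.0, 120.0])
    )
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return float(sol.x[0]), float(sol.x[1]), rmse


def fit_organization(histograms: list[AngleHistogram]) -> OrganizationFit:
    """Fit (sigma0, sigma_inf, alpha, theta0) from histograms at several strains.

    Each histogram is first fit to a Gaussian (RMSE minimization) yielding a
    per-strain spread sigma_i, then sigma(eps) = sigma0*exp(-alpha*eps) +
    sigma_inf is fit to the (eps_i, sigma_i) pairs by least squares with
    multi-start.  At least three distinct strains are required, otherwise
    (sigma0, sigma_inf, alpha) are not jointly identifiable.
    """
    strains = np.array([h.strain for h in histograms], float)
    if len(np.unique(strains)) < 3:
        raise ValueError(
            "need histograms at >= 3 distinct strains: (sigma0, sigma_inf, alpha) "
            "are not identifiable from fewer strain levels"
        )
    fits = [_fit_single_histogram(h) for h in histograms]
    theta0s = np.array([f[0] for f in fits])
    sigmas = np.array([f[1] for f in fits])
    rmses = np.array([f[2] for f in fits])

    def resid(p):
        s0, sinf, a = p
        return s0 * np.exp(-a * strains) + sinf - sigmas

    bounds = (np.array([0.0, 0.1, 0.0]), np.array([120.0, 120.0, 300.0]))
    sampler = qmc.LatinHypercube(d=3, seed=0)
    starts = qmc.scale(sampler.random(5), bounds[0], bounds[1])
    # Moment-based start: sigma at eps=0 minus the smallest sigma.
    starts[0] = [max(sigmas.max() - sigmas.min(), 1.0), sigmas.min(), 20.0]
    best = None
    for x0 in starts:
        sol = optimize.least_squares(resid, x0=x0, bounds=bounds)
        if best is None or sol.cost < best.cost:
            best = sol
    s0, sinf, a = best.x
    return OrganizationFit(
        float(s0), float(sinf), float(a), float(np.mean(theta0s)), strains, sigmas, rmses
    )


def fit_stress_params(
    curve: StressStrainCurve,
    org: OrganizationFit | FiberModelParams,
    toe_region_max_strain: float = 0.06,
) -> StressFit:
    """Fit (A, B, k_matrix) to a stress-strain curve in the toe region.

    The fiber-organization parameters come from ``org``; the curve is
    restricted to strains <= ``toe_region_max_strain`` and fit by bounded
    least squares with Latin-hypercube multi-start.
    """
    mask = np.asarray(curve.strain) <= toe_region_max_strain
    strain = np.asarray(curve.strain, float)[mask]
    stress = np.asarray(curve.stress_mpa, float)[mask]
    if len(strain) < 4 or np.allclose(stress, stress[0]):
        raise ValueError("degenerate curve: too few points or constant stress")

    def model(p):
        pars = FiberModelParams(
            A=p[0], B=p[1], k_matrix=p[2],
            sigma0=org.sigma0, sigma_inf=org.sigma_inf,
            alpha=org.alpha, theta0=org.theta0,
        )
        return predict_stress(strain, pars).stress_mpa

    def resid(p):
        return model(p) - stress

    lo = np.array([1e-8, 0.5, 0.0])
    hi = np.array([100.0, 200.0, 100.0])
    sampler = qmc.LatinHypercube(d=3, seed=0)
    starts = qmc.scale(sampler.random(5), lo, hi)
    starts[0] = [0.1, 30.0, max(stress[-1] / max(strain[-1], 1e-9) * 0.5, 0.1)]
    best = None
    for x0 in starts:
        sol = optimize.least_squares(resid, x0=x0, bounds=(lo, hi), x_scale=[0.1, 10.0, 1.0])
        if best is None or sol.cost < best.cost:
            best = sol
    pred = model(best.x)
    ss_res = float(np.sum((stress - pred) ** 2))
    ss_tot = float(np.sum((stress - stress.mean()) ** 2))
    return StressFit(
        float(best.x[0]), float(best.x[1]), float(best.x[2]), 1.0 - ss_res / ss_tot
    )


# ---------------------------------------------------------------------------
# Image-based orientation
# ---------------------------------------------------------------------------

def orientation_from_image(image: np.ndarray, n_bins: int = 45) -> AngleHistogram:
    """Fiber-orientation histogram from the angular power spectrum of an image.

    The image is Hann-windowed, the 2-D FFT power spectrum is computed, and
    power is binned by the orientation perpendicular to each spatial
    frequency (stripes at angle phi concentrate power along phi + 90 deg).
    The result is normalized to unit integral over [-90, 90).
    """
    img = np.asarray(image, float)
    if img.ndim != 2 or min(img.shape) < 64:
        raise ValueError("image must be 2-D and at least 64x64 pixels")
    if np.ptp(img) == 0:
        raise ValueError("constant image has no orientation content")
    h, w = img.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    F = np.fft.fftshift(np.fft.fft2((img - img.mean()) * win))
    power = np.abs(F) ** 2
    v, u = np.meshgrid(
        np.arange(h) - h // 2, np.arange(w) - w // 2, indexing="ij"
    )
    r = np.hypot(u, v)
    rmax = 0.45 * min(h, w)
    sel = (r >= 3) & (r <= rmax)
    # Spectral direction -> real-space stripe orientation (y up, CCW).
    ang = np.degrees(np.arctan2(-v, u))  # -v: row axis points down
    fiber = (ang + 90.0 + 90.0) % 180.0 - 90.0
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    idx = np.clip(np.digitize(fiber[sel], edges) - 1, 0, n_bins - 1)
    hist = np.bincount(idx, weights=power[sel], minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = hist / np.trapezoid(hist, centers)
    return AngleHistogram(centers, hist, 0.0)
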