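"""Optical-property-corrected absolute flow from speckle contrast.

Speckle contrast depends not only on scatterer motion but on the absorption
and reduced scattering of the medium: higher mu_a raises K at fixed flow,
higher mu_s' lowers it.  This module removes that confound by inverting the
correlation-diffusion forward model

    K^2 = (2 beta / T) * int_0^T g1^2(tau) (1 - tau/T) dtau

(with the spatial-frequency-domain ``g1`` of :mod:`qhi.optics`, evaluated at
fx = 0 for planar laser illumination) for the effective Brownian diffusion
coefficient ``Db`` (mm^2/s) — an absolute flow measure independent of the
optical properties.

The optical properties at the 633 nm speckle wavelength are obtained from
the SFDI measurements: mu_a from the unmixed hemoglobin concentrations, and
mu_s' by extrapolating a scattering power law fitted across the SFDI
wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from . import constants
from .constants import (DEFAULT_EXPOSURE_S, DEFAULT_REFRACTIVE_INDEX,
                        LSI_WAVELENGTH_NM, MUA_PER_EXTINCTION_UM, NM_PER_MM)
from .lsi import BetaFactor, ContrastMap, FlowMap
from .optics import OpticalProperties, boundary_terms
from .sfdi import ChromophoreMap

__all__ = [
    "PowerLawFit",
    "Lut3D",
    "k2_forward",
    "build_k2_lut",
    "invert_db",
    "fit_mus_powerlaw",
    "extrapolate_musp",
    "mua_at_lsi_wavelength",
    "percent_difference_map",
]

#: Upper edge of the default Db axis (mm^2/s); covers reported tissue
#: magnitudes (~1e-6 mm^2/s) with ample headroom.
DEFAULT_DB_MAX = 20e-6


@dataclass
class PowerLawFit:
    """Scattering power law ``mu_s'(lambda) = amp * (lambda/850)^slope``."""

    amp: np.ndarray | float
    slope: np.ndarray | float
    ref_wavelength_nm: float = 850.0


def _k0(wavelength_nm: float, n: float) -> float:
    return 2.0 * np.pi * n / (wavelength_nm / NM_PER_MM)


def k2_forward(db: float, op: OpticalProperties, beta: float = 1.0,
               exposure: float = DEFAULT_EXPOSURE_S,
               n: float = DEFAULT_REFRACTIVE_INDEX,
               fx: float = 0.0,
               wavelength_nm: float = LSI_WAVELENGTH_NM) -> float:
    """Exposure-integrated squared speckle contrast K^2.

    Computed by adaptive Gauss-Kronrod quadrature of
    ``(2 beta / T) g1^2(tau) (1 - tau/T)`` over ``[0, T]`` with relative
    tolerance 1e-9.  For ``db = 0`` the integrand is ``(1 - tau/T)`` and
    ``K^2 = beta`` (static limit).  ``beta`` enters only as a prefactor.
    """
    if isinstance(beta, BetaFactor):
        beta = beta.beta
    if not exposure > 0:
        raise ValueError(f"exposure must be > 0, got {exposure}")
    if db < 0:
        raise ValueError(f"db must be >= 0, got {db}")
    bt = boundary_terms(n)
    k0 = _k0(wavelength_nm, n)
    mua, musp = op.mua, op.musp
    mutr = mua + musp
    a = bt.a
    fx_term = (2.0 * np.pi * fx) ** 2

    def x_ratio(tau):
        dyn = 2.0 * musp * k0**2 * db * tau
        return np.sqrt(3.0 * (mua + dyn) * mutr + fx_term) / mutr

    x0 = x_ratio(0.0)
    d0 = (x0 + 1.0) * (x0 + 3.0 * a)

    def integrand(tau):
        x = x_ratio(tau)
        g1 = d0 / ((x + 1.0) * (x + 3.0 * a))
        return g1 * g1 * (1.0 - tau / exposure)

    val, abserr = quad(integrand, 0.0, exposure, epsabs=0.0, epsrel=1e-11,
                       limit=800)
    if not np.isfinite(val) or (val > 0 and abserr > 1e-6 * abs(val)):
        raise RuntimeError(
            f"quadrature failed to converge: value={val}, abserr={abserr}, "
            f"db={db}, mua={mua}, musp={musp}, T={exposure}")
    return 2.0 * beta / exposure * val


def _k2_panels(db, mua, musp, beta, exposure, a, k0, n_panels=10, gl_order=24):
    """Vectorized K^2 at fx = 0 via the x = mu_eff'/mu_tr substitution.

    With ``x(tau) = sqrt(3 (mu_a + c tau)/mu_tr)``, ``c = 2 mu_s' k0^2 Db``,
    the exposure integral becomes a smooth rational integral over
    ``[x0, xT]`` which panelled Gauss-Legendre resolves to ~1e-10 even in
    the fast-decay regime.  Broadcasts over ``db``, ``mua``, ``musp``.
    """
    db, mua, musp = np.broadcast_arrays(np.asarray(db, float),
                                        np.asarray(mua, float),
                                        np.asarray(musp, float))
    mutr = mua + musp
    x0 = np.sqrt(3.0 * mua / mutr)
    c = 2.0 * musp * k0**2 * db
    s = 3.0 * c * exposure / mutr          # xT^2 - x0^2
    xt = np.sqrt(x0**2 + s)
    d0 = (x0 + 1.0) * (x0 + 3.0 * a)

    out = np.full(db.shape, beta, dtype=float)   # static limit for db == 0
    dyn = s > 0
    if not np.any(dyn):
        return out

    x0d, sd, xtd, d0d = x0[dyn], s[dyn], xt[dyn], d0[dyn]
    nodes, weights = np.polynomial.legendre.leggauss(gl_order)
    ratio = (xtd / x0d) ** (1.0 / n_panels)
    integral = np.zeros(x0d.shape)
    lo = x0d.copy()
    for _ in range(n_panels):
        hi = lo * ratio
        half = 0.5 * (hi - lo)
        mid = 0.5 * (hi + lo)
        for w, t in zip(weights, nodes):
            x = mid + half * t
            f = x * (1.0 - (x**2 - x0d**2) / sd) / ((x + 1.0) * (x + 3.0 * a)) ** 2
            integral += w * half * f
        lo = hi
    out[dyn] = 4.0 * beta * d0d**2 / sd * integral
    return out


@dataclass
class Lut3D:
    """Forward K^2 grid over (Db, mu_a, mu_s') for one (beta, T, lambda, n).

    Default axes: Db linearly spaced over [0, 20e-6] mm^2/s with 256 values,
    mu_a over [0.0001, 0.3] and mu_s' over [0.001, 3] 1/mm with 128 values
    each.  ``k2_grid[i, j, k]`` is K^2 at ``db_axis[i], mua_axis[j],
    musp_axis[k]``; every Db column is strictly decreasing, which the
    inversion exploits.
    """

    db_axis: np.ndarray
    mua_axis: np.ndarray
    musp_axis: np.ndarray
    k2_grid: np.ndarray
    beta: float
    exposure: float
    lambda_lsi_nm: float
    n: float

    def save(self, path):
        np.savez_compressed(path, db_axis=self.db_axis, mua_axis=self.mua_axis,
                            musp_axis=self.musp_axis, k2_grid=self.k2_grid,
                            beta=self.beta, exposure=self.exposure,
                            lambda_lsi_nm=self.lambda_lsi_nm, n=self.n)

    @classmethod
    def load(cls, path):
        z = np.load(path)
        return cls(db_axis=z["db_axis"], mua_axis=z["mua_axis"],
                   musp_axis=z["musp_axis"], k2_grid=z["k2_grid"],
                   beta=float(z["beta"]), exposure=float(z["exposure"]),
                   lambda_lsi_nm=float(z["lambda_lsi_nm"]), n=float(z["n"]))


def build_k2_lut(beta: float = 1.0,
                 exposure: float = DEFAULT_EXPOSURE_S,
                 lambda_lsi_nm: float = LSI_WAVELENGTH_NM,
                 n: float = DEFAULT_REFRACTIVE_INDEX,
                 db_max: float = DEFAULT_DB_MAX,
                 n_db: int = 256,
                 n_mua: int = 128,
                 n_musp: int = 128,
                 mua_range: tuple[float, float] = (0.0001, 0.3),
                 musp_range: tuple[float, float] = (0.001, 3.0)) -> Lut3D:
    """Tabulate the K^2 forward model on the (Db, mu_a, mu_s') lattice.

    The beta used here is the same phantom-derived factor applied in the
    SFI normalization; ``Db = 0`` slices equal beta exactly.
    """
    if isinstance(beta, BetaFactor):
        beta = beta.beta
    db_axis = np.linspace(0.0, db_max, n_db)
    mua_axis = np.linspace(*mua_range, n_mua)
    musp_axis = np.linspace(*musp_range, n_musp)
    bt = boundary_terms(n)
    k0 = _k0(lambda_lsi_nm, n)
    mua_g, musp_g = np.meshgrid(mua_axis, musp_axis, indexing="ij")
    grid = np.empty((n_db, n_mua, n_musp))
    for i, db in enumerate(db_axis):          # chunk over Db to bound memory
        grid[i] = _k2_panels(db, mua_g, musp_g, beta, exposure, bt.a, k0)
    return Lut3D(db_axis=db_axis, mua_axis=mua_axis, musp_axis=musp_axis,
                 k2_grid=grid, beta=beta, exposure=exposure,
                 lambda_lsi_nm=lambda_lsi_nm, n=n)


def _bilinear_weights(axis, values):
    idx = np.clip(np.searchsorted(axis, values) - 1, 0, axis.size - 2)
    frac = (values - axis[idx]) / (axis[idx + 1] - axis[idx])
    return idx, frac


def invert_db(k, mua, musp, lut: Lut3D):
    """Invert measured speckle contrast into Db using the K^2 LUT.

    The (mu_a, mu_s') pair selects a strictly decreasing K^2-vs-Db profile
    by bilinear interpolation of the LUT; the measured K^2 is then located
    on that profile by monotone bracketing and linear inverse interpolation
    — more robust than 3-D scattered interpolation, with guaranteed
    uniqueness.

    Parameters
    ----------
    k : float, ndarray or ContrastMap
        Measured speckle contrast (not squared).
    mua, musp : float or ndarray
        Optical properties at the LSI wavelength, same shape as ``k``.
    lut : Lut3D

    Returns
    -------
    float or FlowMap
        Db (mm^2/s).  Scalar inputs return a float and raise when the
        contrast is unphysical (K^2 > beta) or beyond the LUT's dynamic
        range; map inputs flag such pixels invalid instead.

    Raises
    ------
    ValueError
        If optical properties lie outside the LUT axes (scalar input), or
        every pixel is uninvertible (map input).
    """
    scalar = np.isscalar(k) and np.isscalar(mua) and np.isscalar(musp)
    if isinstance(k, ContrastMap):
        k_arr = np.asarray(k.k, float)
        pre_invalid = k.invalid.copy()
    else:
        k_arr = np.asarray(k, dtype=float)
        pre_invalid = ~np.isfinite(k_arr)
    mua = np.broadcast_to(np.asarray(mua, float), k_arr.shape).ravel()
    musp = np.broadcast_to(np.asarray(musp, float), k_arr.shape).ravel()
    k2 = (k_arr.astype(float) ** 2).ravel()
    invalid = pre_invalid.ravel().copy()

    in_axis = ((mua >= lut.mua_axis[0]) & (mua <= lut.mua_axis[-1])
               & (musp >= lut.musp_axis[0]) & (musp <= lut.musp_axis[-1]))
    if scalar and not in_axis.item():
        raise ValueError(
            f"optical properties (mua={mua.item()}, musp={musp.item()}) "
            "outside the LUT axes")
    invalid |= ~in_axis

    db = np.full(k2.shape, np.nan)
    ok = ~invalid
    if not np.any(ok):
        raise ValueError("no invertible pixels: contrast or optical "
                         "properties out of range everywhere")

    ia, fa = _bilinear_weights(lut.mua_axis, mua[ok])
    im, fm = _bilinear_weights(lut.musp_axis, musp[ok])
    # profile over Db for each pixel: (n_ok, n_db)
    g = lut.k2_grid
    prof = ((1 - fa) * (1 - fm))[:, None] * g[:, ia, im].T \
        + (fa * (1 - fm))[:, None] * g[:, ia + 1, im].T \
        + ((1 - fa) * fm)[:, None] * g[:, ia, im + 1].T \
        + (fa * fm)[:, None] * g[:, ia + 1, im + 1].T

    t = k2[ok]
    top = prof[:, 0]                      # = beta (static limit)
    bottom = prof[:, -1]
    # tolerate float round-off when K equals sqrt(beta) exactly
    super_static = t > top * (1.0 + 1e-9)
    beyond_range = t < bottom
    static = t >= top * (1.0 - 1e-12)

    # first index where profile <= target (profiles strictly decreasing)
    j = np.argmax(prof <= t[:, None], axis=1)
    j = np.clip(j, 1, prof.shape[1] - 1)
    rows = np.arange(prof.shape[0])
    p_hi = prof[rows, j - 1]
    p_lo = prof[rows, j]
    frac = (p_hi - t) / (p_hi - p_lo)
    db_ok = lut.db_axis[j - 1] + frac * (lut.db_axis[j] - lut.db_axis[j - 1])
    db_ok[static] = 0.0
    db_ok[super_static | beyond_range] = np.nan

    db[ok] = db_ok
    invalid[np.flatnonzero(ok)[super_static | beyond_range]] = True

    if scalar:
        if invalid.item():
            raise ValueError(
                f"contrast K^2={k2.item():.6g} is outside the invertible "
                f"range (beta={lut.beta}, K^2 min={bottom.item():.6g})")
        return float(db.item())
    shape = k_arr.shape
    return FlowMap(values=db.reshape(shape), units="mm^2/s",
                   invalid=invalid.reshape(shape))


def fit_mus_powerlaw(musp_by_wavelength: dict,
                     ref_wavelength_nm: float = 850.0) -> PowerLawFit:
    """Fit the Mie scattering power law across wavelengths.

    ``log mu_s'(lambda) = log(amp) + slope * log(lambda/850)`` is solved by
    least squares; exact when the inputs lie on a power law.  Values may be
    scalars or per-pixel maps.
    """
    wavelengths = sorted(musp_by_wavelength)
    if len(wavelengths) < 2:
        raise ValueError("need mu_s' at >= 2 wavelengths")
    vals = np.stack([np.asarray(musp_by_wavelength[w], dtype=float)
                     for w in wavelengths])
    if np.any(vals <= 0):
        raise ValueError("mu_s' values must be > 0 for the log-space fit")
    lam = np.asarray(wavelengths, dtype=float)
    design = np.column_stack([np.ones(lam.size),
                              np.log(lam / ref_wavelength_nm)])
    shape = vals.shape[1:]
    coef = np.linalg.pinv(design) @ np.log(vals).reshape(lam.size, -1)
    amp = np.exp(coef[0]).reshape(shape)
    slope = coef[1].reshape(shape)
    if amp.ndim == 0:
        amp, slope = float(amp), float(slope)
    return PowerLawFit(amp=amp, slope=slope,
                       ref_wavelength_nm=ref_wavelength_nm)


def extrapolate_musp(fit: PowerLawFit, wavelength_nm: float):
    """Forward power-law evaluation: ``amp * (lambda/ref)^slope``."""
    if not wavelength_nm > 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength_nm}")
    return fit.amp * (wavelength_nm / fit.ref_wavelength_nm) ** fit.slope


def mua_at_lsi_wavelength(chrom: ChromophoreMap,
                          eps_pair: tuple[float, float] | None = None):
    """Absorption map at the speckle wavelength from hemoglobin maps.

    ``mu_a(633) = ln(10) (eps_HbO2 C_HbO2 + eps_HbR C_HbR) * 1e-7`` with
    extinction coefficients in 1/cm/M and concentrations in uM; the default
    pair comes from the same compiled tabulation used for the unmixing, so
    the round trip through :func:`qhi.sfdi.fit_chromophores` is consistent.
    """
    if eps_pair is None:
        eps_pair = constants.EXTINCTION_CM_PER_M[LSI_WAVELENGTH_NM]
    e1, e2 = eps_pair
    return MUA_PER_EXTINCTION_UM * (e1 * chrom.c_hbo2 + e2 * chrom.c_hbr)


def percent_difference_map(db_map, sfi_map):
    """Center-normalized percent difference between Db and SFI maps.

    Each map is normalized to its center pixel, then
    ``%diff = (Db_norm - SFI_norm) / SFI_norm * 100``.  Note the formula is
    asymmetric in its arguments.
    """
    db_arr = db_map.values if hasattr(db_map, "values") else np.asarray(db_map, float)
    sfi_arr = sfi_map.values if hasattr(sfi_map, "values") else np.asarray(sfi_map, float)
    if db_arr.shape != sfi_arr.shape:
        raise ValueError("maps must have matching shapes")
    cy, cx = db_arr.shape[0] // 2, db_arr.shape[1] // 2
    if db_arr[cy, cx] == 0 or sfi_arr[cy, cx] == 0 \
            or not np.isfinite(db_arr[cy, cx]) or not np.isfinite(sfi_arr[cy, cx]):
        raise ValueError("center pixel is zero or invalid; cannot normalize")
    db_norm = db_arr / db_arr[cy, cx]
    sfi_norm = sfi_arr / sfi_arr[cy, cx]
    return (db_norm - sfi_norm) / sfi_norm * 100.0
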