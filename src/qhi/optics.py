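"""Closed-form photon-transport quantities for the diffusion model.

This module is the pure numeric core shared by the SFDI inversion and the
speckle-contrast correction: partial-current boundary terms, the effective
attenuation coefficient with its dynamic (Brownian-motion) term, the
normalized field autocorrelation ``g1`` of the correlation-diffusion
equation in the spatial frequency domain, and the static diffuse reflectance
forward model ``Rd(fx)``.

The medium is assumed homogeneous and semi-infinite.  All lengths are in mm;
wavelengths are passed in nm and converted internally (see
:mod:`qhi.constants`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_REFRACTIVE_INDEX, LSI_WAVELENGTH_NM, NM_PER_MM

__all__ = [
    "OpticalProperties",
    "BoundaryTerms",
    "DynamicContext",
    "boundary_terms",
    "mueff_prime",
    "g1_normalized",
    "rd_forward",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering of a turbid medium at one wavelength.

    Attributes
    ----------
    mua : float
        Absorption coefficient (1/mm), > 0.
    musp : float
        Reduced scattering coefficient (1/mm), > 0.
    wavelength_nm : float
        Wavelength the coefficients refer to (nm).
    """

    mua: float
    musp: float
    wavelength_nm: float = LSI_WAVELENGTH_NM

    def __post_init__(self):
        if not (self.mua > 0):
            raise ValueError(f"mua must be > 0, got {self.mua}")
        if not (self.musp > 0):
            raise ValueError(f"musp must be > 0, got {self.musp}")
        if not (self.wavelength_nm > 0):
            raise ValueError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")

    @property
    def mutr(self) -> float:
        """Transport coefficient mu_tr = mu_a + mu_s' (1/mm)."""
        return self.mua + self.musp


@dataclass(frozen=True)
class BoundaryTerms:
    """Partial-current boundary quantities of the diffusion model.

    ``reff`` is the effective (internal) reflection coefficient of the
    tissue-air interface and ``a`` the boundary coefficient
    ``A = (1 - Reff) / (2 (1 + Reff))``.
    """

    n: float
    reff: float
    a: float


@dataclass(frozen=True)
class DynamicContext:
    """Dynamic and geometric context of a correlation measurement.

    Attributes
    ----------
    db : float
        Effective Brownian diffusion coefficient of the moving scatterers
        (mm^2/s), >= 0.
    tau : float
        Correlation lag (s), >= 0.  May be an array in the functional API.
    fx : float
        Spatial frequency of the illumination pattern (1/mm), >= 0.
    wavelength_nm : float
        Illumination wavelength (nm).
    n : float
        Refractive index of the medium.

    The illumination power ``P0`` of the reflectance forward model is
    deliberately absent: it cancels in the normalized ratio
    ``G1(tau)/G1(0)`` and never enters any computed quantity.
    """

    db: float = 0.0
    tau: float = 0.0
    fx: float = 0.0
    wavelength_nm: float = LSI_WAVELENGTH_NM
    n: float = DEFAULT_REFRACTIVE_INDEX

    def __post_init__(self):
        if self.db < 0:
            raise ValueError(f"db must be >= 0, got {self.db}")
        if np.any(np.asarray(self.tau) < 0):
            raise ValueError("tau must be >= 0")
        if self.fx < 0:
            raise ValueError(f"fx must be >= 0, got {self.fx}")

    @property
    def k0(self) -> float:
        """Optical wavenumber 2*pi*n/lambda in 1/mm (lambda converted nm->mm)."""
        return 2.0 * np.pi * self.n / (self.wavelength_nm / NM_PER_MM)


def boundary_terms(n: float) -> BoundaryTerms:
    """Effective reflection coefficient and boundary coefficient A.

    Uses the polynomial approximation
    ``Reff = 0.0636 n + 0.668 + 0.710/n - 1.440/n^2`` and
    ``A = (1 - Reff) / (2 (1 + Reff))``.
    """
    if not n > 0:
        raise ValueError(f"refractive index must be > 0, got {n}")
    reff = 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2
    a = (1.0 - reff) / (2.0 * (1.0 + reff))
    return BoundaryTerms(n=n, reff=reff, a=a)


def _mueff_prime(mua, musp, db, tau, fx, k0):
    """Vectorized mu_eff' (1/mm); any argument may be an ndarray."""
    mutr = mua + musp
    dynamic_absorption = (1.0 / 3.0) * musp * k0**2 * (6.0 * db * tau)
    mueff_sq = 3.0 * (mua + dynamic_absorption) * mutr
    return np.sqrt(mueff_sq + (2.0 * np.pi * fx) ** 2)


def mueff_prime(op: OpticalProperties, ctx: DynamicContext):
    """Effective attenuation coefficient mu_eff' (1/mm).

    ``mu_eff' = sqrt(mu_eff^2 + (2 pi fx)^2)`` with
    ``mu_eff = sqrt(3 (mu_a + (1/3) mu_s' k0^2 6 Db tau) mu_tr)``.
    The Brownian term acts as an extra, lag-dependent absorption; it is
    strictly increasing in each of ``mu_a``, ``Db``, ``tau`` and ``fx``.
    """
    return _mueff_prime(op.mua, op.musp, ctx.db, np.asarray(ctx.tau, dtype=float),
                        ctx.fx, ctx.k0)


def _g1_ratio(mua, musp, db, tau, fx, k0, a):
    """g1(tau) = G1(tau)/G1(0); static prefactor and P0 cancel."""
    mutr = mua + musp
    x0 = _mueff_prime(mua, musp, db, 0.0, fx, k0) / mutr
    x = _mueff_prime(mua, musp, db, tau, fx, k0) / mutr
    return ((x0 + 1.0) * (x0 + 3.0 * a)) / ((x + 1.0) * (x + 3.0 * a))


def g1_normalized(op: OpticalProperties, ctx: DynamicContext):
    """Normalized field autocorrelation g1(tau) in (0, 1].

    Evaluates the spatial-frequency-domain correlation-diffusion solution
    ``G1(tau) = 3 P0 A (mu_s'/mu_tr) / ((mu_eff'/mu_tr + 1)(mu_eff'/mu_tr + 3A))``
    and returns the normalized ratio ``G1(tau)/G1(0)``, so the illumination
    power and the static prefactor cancel.  ``g1(0) = 1`` exactly and g1 is
    non-increasing in ``tau`` (constant 1 when ``db = 0``).
    """
    bt = boundary_terms(ctx.n)
    tau = np.asarray(ctx.tau, dtype=float)
    out = _g1_ratio(op.mua, op.musp, ctx.db, tau, ctx.fx, ctx.k0, bt.a)
    return float(out) if np.isscalar(ctx.tau) or out.ndim == 0 else out


def rd_forward(op, fx: float = 0.0, n: float = DEFAULT_REFRACTIVE_INDEX):
    """Static diffuse reflectance Rd at spatial frequency ``fx``.

    Diffusion forward model (the tau = 0 limit of the correlation solution):

    ``Rd = 3 A (mu_s'/mu_tr) / ((mu_eff'/mu_tr + 1)(mu_eff'/mu_tr + 3A))``

    Parameters
    ----------
    op : OpticalProperties or tuple of array_like
        Either a single :class:`OpticalProperties` or a ``(mua, musp)`` pair
        of broadcastable arrays for grid evaluation.
    fx : float
        Spatial frequency (1/mm), >= 0.
    n : float
        Refractive index used for the boundary coefficient.

    Returns
    -------
    float or ndarray
        Dimensionless reflectance in (0, 1) for physical inputs.
    """
    if fx < 0:
        raise ValueError(f"fx must be >= 0, got {fx}")
    if isinstance(op, OpticalProperties):
        mua, musp = op.mua, op.musp
    else:
        mua, musp = (np.asarray(v, dtype=float) for v in op)
        if np.any(mua < 0) or np.any(musp < 0):
            raise ValueError("mua and musp must be non-negative")
    mutr = mua + musp
    if np.any(mutr <= 0):
        raise ValueError("mutr = mua + musp must be > 0")
    bt = boundary_terms(n)
    x = _mueff_prime(mua, musp, 0.0, 0.0, fx, 0.0) / mutr  # k0 irrelevant at tau=0
    rd = 3.0 * bt.a * (musp / mutr) / ((x + 1.0) * (x + 3.0 * bt.a))
    return float(rd) if np.ndim(rd) == 0 else rd
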