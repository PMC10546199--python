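"""SFDI processing: demodulation, calibration, LUT inversion, chromophores.

Raw three-phase spatial-frequency-domain frames are demodulated into an AC
amplitude image, calibrated against a phantom of known optical properties to
give diffuse reflectance ``Rd(fx)``, and the per-pixel ``(Rd(0), Rd(0.3))``
pair is inverted through a forward-model lookup table into absorption and
reduced scattering maps.  Multi-wavelength absorption maps are finally
unmixed into oxy-/deoxy-hemoglobin concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.ndimage import gaussian_filter

from . import constants
from .constants import DEFAULT_REFRACTIVE_INDEX, MUA_PER_EXTINCTION_UM
from .optics import OpticalProperties, rd_forward

__all__ = [
    "PhaseTriplet",
    "DemodulatedMap",
    "RdMap",
    "Lut2D",
    "OpticalPropertyMap",
    "ChromophoreMap",
    "demodulate",
    "demodulate_dc",
    "smooth",
    "calibrate",
    "build_rd_lut",
    "invert_optical_properties",
    "extinction_matrix",
    "fit_chromophores",
]

#: Unique constant for which a three-phase sinusoid of amplitude A
#: demodulates to exactly A (see docs/methods.md on the 2/3 vs sqrt(2)/3
#: typesetting ambiguity).
DEMOD_CONSTANT = np.sqrt(2.0) / 3.0


@dataclass
class PhaseTriplet:
    """Three reflectance images at phases 0, 120 and 240 degrees."""

    i1: np.ndarray
    i2: np.ndarray
    i3: np.ndarray
    fx: float
    wavelength_nm: float

    def __post_init__(self):
        if not (self.i1.shape == self.i2.shape == self.i3.shape):
            raise ValueError("phase images must share one shape, got "
                             f"{self.i1.shape}, {self.i2.shape}, {self.i3.shape}")


@dataclass
class DemodulatedMap:
    """AC (or DC) amplitude image M_AC(fx) in camera counts."""

    mac: np.ndarray
    fx: float
    wavelength_nm: float
    smoothed: bool = False


@dataclass
class RdMap:
    """Calibrated diffuse reflectance image at one spatial frequency."""

    rd: np.ndarray
    fx: float
    wavelength_nm: float


@dataclass
class OpticalPropertyMap:
    """Per-pixel (mu_a, mu_s') with an invalid-pixel mask."""

    mua: np.ndarray
    musp: np.ndarray
    wavelength_nm: float
    invalid: np.ndarray


@dataclass
class ChromophoreMap:
    """Hemoglobin concentration maps (uM) with derived HbT and StO2 (%)."""

    c_hbo2: np.ndarray
    c_hbr: np.ndarray
    hbt: np.ndarray
    sto2: np.ndarray


def demodulate(t: PhaseTriplet) -> DemodulatedMap:
    """Three-phase AC demodulation.

    ``M_AC = (sqrt(2)/3) sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2)`` pixelwise.
    For phase images ``DC + A cos(2 pi fx x + phi_k)`` this returns exactly
    the modulation amplitude ``A``, independent of the DC level.
    """
    i1 = np.asarray(t.i1, dtype=float)
    i2 = np.asarray(t.i2, dtype=float)
    i3 = np.asarray(t.i3, dtype=float)
    mac = DEMOD_CONSTANT * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )
    return DemodulatedMap(mac=mac, fx=t.fx, wavelength_nm=t.wavelength_nm)


def demodulate_dc(t: PhaseTriplet) -> DemodulatedMap:
    """Planar (fx = 0) demodulation: mean of the three frames.

    The fx = 0 slots are projected as uniform illumination, so the three
    "phase" frames are nominally identical and the AC formula would return
    zero; the DC amplitude is their pixelwise mean.
    """
    mac = (np.asarray(t.i1, float) + np.asarray(t.i2, float)
           + np.asarray(t.i3, float)) / 3.0
    return DemodulatedMap(mac=mac, fx=t.fx, wavelength_nm=t.wavelength_nm)


def smooth(m: DemodulatedMap, window: int = 15, sigma: float | None = None) -> DemodulatedMap:
    """Gaussian noise filter applied to a demodulated amplitude image.

    ``window`` is the truncation size in pixels (odd); ``sigma`` defaults to
    ``window / 6`` so the kernel is well contained in the window.  Borders
    use reflective padding.  ``window = 1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window == 1:
        return DemodulatedMap(m.mac.copy(), m.fx, m.wavelength_nm, smoothed=True)
    if sigma is None:
        sigma = window / 6.0
    radius = (window - 1) // 2
    out = gaussian_filter(np.asarray(m.mac, float), sigma=sigma,
                          mode="reflect", radius=radius)
    return DemodulatedMap(out, m.fx, m.wavelength_nm, smoothed=True)


def calibrate(m: DemodulatedMap, m_phantom: DemodulatedMap,
              phantom_op: OpticalProperties,
              n: float = DEFAULT_REFRACTIVE_INDEX) -> RdMap:
    """Phantom calibration: ``Rd(fx) = (M_AC / M_AC,phantom) Rd_phantom(fx)``.

    The model reflectance of the calibration phantom is computed with the
    diffusion forward model at the triplet's spatial frequency.
    """
    if m.fx != m_phantom.fx:
        raise ValueError(f"fx mismatch: {m.fx} vs {m_phantom.fx}")
    if m.wavelength_nm != m_phantom.wavelength_nm:
        raise ValueError("wavelength mismatch: "
                         f"{m.wavelength_nm} vs {m_phantom.wavelength_nm}")
    mac_p = np.asarray(m_phantom.mac, float)
    n_zero = int(np.count_nonzero(mac_p <= 0))
    if n_zero:
        raise ValueError(
            f"phantom amplitude is zero or negative at {n_zero} pixel(s); "
            "cannot form the calibration ratio")
    rd_p = rd_forward(phantom_op, fx=m.fx, n=n)
    return RdMap(rd=np.asarray(m.mac, float) / mac_p * rd_p,
                 fx=m.fx, wavelength_nm=m.wavelength_nm)


@dataclass
class Lut2D:
    """Forward Rd grids at fx = 0 and 0.3 1/mm over a (mu_a, mu_s') lattice.

    Default axes: 512 linearly spaced values over mu_a in [0.0001, 0.2] and
    mu_s' in [0.001, 3] 1/mm.  Inverse queries outside the attainable
    (Rd0, Rd03) region are flagged invalid, never extrapolated.
    """

    mua_axis: np.ndarray
    musp_axis: np.ndarray
    rd0: np.ndarray
    rd03: np.ndarray
    n: float = DEFAULT_REFRACTIVE_INDEX
    _interp: LinearNDInterpolator | None = field(default=None, repr=False)

    def _inverse_interpolator(self) -> LinearNDInterpolator:
        if self._interp is None:
            pts = np.column_stack([self.rd0.ravel(), self.rd03.ravel()])
            mua_g, musp_g = np.meshgrid(self.mua_axis, self.musp_axis,
                                        indexing="ij")
            vals = np.column_stack([mua_g.ravel(), musp_g.ravel()])
            self._interp = LinearNDInterpolator(pts, vals)
        return self._interp


def build_rd_lut(n: float = DEFAULT_REFRACTIVE_INDEX,
                 n_points: int = 512,
                 mua_range: tuple[float, float] = (0.0001, 0.2),
                 musp_range: tuple[float, float] = (0.001, 3.0),
                 fx_pair: tuple[float, float] = constants.SFDI_FX_PAIR) -> Lut2D:
    """Fill the forward reflectance LUT over the standard axis ranges."""
    mua_axis = np.linspace(*mua_range, n_points)
    musp_axis = np.linspace(*musp_range, n_points)
    mua_g, musp_g = np.meshgrid(mua_axis, musp_axis, indexing="ij")
    rd0 = rd_forward((mua_g, musp_g), fx=fx_pair[0], n=n)
    rd03 = rd_forward((mua_g, musp_g), fx=fx_pair[1], n=n)
    return Lut2D(mua_axis=mua_axis, musp_axis=musp_axis, rd0=rd0, rd03=rd03, n=n)


def invert_optical_properties(rd0: RdMap, rd03: RdMap, lut: Lut2D) -> OpticalPropertyMap:
    """Per-pixel (mu_a, mu_s') by scattered-data inverse interpolation.

    The measured ``(Rd(0), Rd(0.3))`` pair at each pixel is interpolated
    linearly over the forward grid's point cloud.  Pixels outside the convex
    hull of attainable reflectance pairs are flagged invalid (silent
    extrapolation would produce unphysical coefficients).  A fully
    out-of-range input raises.
    """
    if rd0.rd.shape != rd03.rd.shape:
        raise ValueError("rd0 and rd03 must have the same shape")
    if rd0.wavelength_nm != rd03.wavelength_nm:
        raise ValueError("rd0 and rd03 must share a wavelength")
    interp = lut._inverse_interpolator()
    q = np.column_stack([rd0.rd.ravel(), rd03.rd.ravel()])
    res = interp(q)
    mua = res[:, 0].reshape(rd0.rd.shape)
    musp = res[:, 1].reshape(rd0.rd.shape)
    invalid = ~np.isfinite(mua) | ~np.isfinite(musp)
    if invalid.all():
        raise ValueError("all pixels fall outside the attainable reflectance "
                         "region of the LUT")
    return OpticalPropertyMap(mua=mua, musp=musp,
                              wavelength_nm=rd0.wavelength_nm, invalid=invalid)


def extinction_matrix(wavelengths_nm) -> np.ndarray:
    """Rows of (eps_HbO2, eps_HbR) in 1/cm/M at the given wavelengths."""
    return np.array([constants.EXTINCTION_CM_PER_M[float(w)]
                     for w in wavelengths_nm], dtype=float)


def fit_chromophores(mua_maps: dict, eps: np.ndarray | None = None,
                     eps_units: str = "cm/M") -> ChromophoreMap:
    """Unmix multi-wavelength absorption into HbO2 / HbR concentrations (uM).

    Solves, per pixel, the least-squares system
    ``mu_a(lambda) = ln(10) * (eps_HbO2 C_HbO2 + eps_HbR C_HbR) * 1e-7``
    with extinction coefficients in 1/cm/M and concentrations in uM, then
    forms ``HbT = HbO2 + HbR`` and ``StO2 = 100 HbO2 / HbT``.

    Parameters
    ----------
    mua_maps : dict
        ``{wavelength_nm: 2-D mu_a map (1/mm)}`` for at least 2 wavelengths.
    eps : ndarray, optional
        Extinction matrix (n_wavelengths x 2, 1/cm/M); defaults to the
        compiled tabulation in :mod:`qhi.constants` at the map wavelengths.
    eps_units : str
        ``"cm/M"`` (default) applies the ln(10) and unit conversion above;
        ``"design"`` treats ``eps`` directly as the linear design matrix
        mapping concentrations to mu_a (useful for synthetic-unit tests).
    """
    wavelengths = sorted(mua_maps)
    if len(wavelengths) < 2:
        raise ValueError("need mu_a at >= 2 wavelengths to unmix 2 chromophores")
    if eps is None:
        eps = extinction_matrix(wavelengths)
    eps = np.asarray(eps, dtype=float)
    if np.linalg.matrix_rank(eps) < 2:
        raise ValueError("extinction matrix is rank deficient")
    if eps_units == "cm/M":
        design = MUA_PER_EXTINCTION_UM * eps
    elif eps_units == "design":
        design = eps
    else:
        raise ValueError(f"unknown eps_units {eps_units!r}")
    stack = np.stack([np.asarray(mua_maps[w], dtype=float) for w in wavelengths])
    shape = stack.shape[1:]
    # pseudo-inverse solve, identical to per-pixel least squares
    coeffs = np.linalg.pinv(design) @ stack.reshape(len(wavelengths), -1)
    c_hbo2 = coeffs[0].reshape(shape)
    c_hbr = coeffs[1].reshape(shape)
    hbt = c_hbo2 + c_hbr
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2 = np.where(hbt > 0, 100.0 * c_hbo2 / hbt, 0.0)
    return ChromophoreMap(c_hbo2=c_hbo2, c_hbr=c_hbr, hbt=hbt, sto2=sto2)
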