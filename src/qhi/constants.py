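"""Physical constants and instrument defaults.

Unit conventions (used everywhere in this package):

* lengths in mm (wavelengths are carried in nm and converted to mm only
  when forming the optical wavenumber ``k0 = 2*pi*n/lambda``),
* absorption and reduced scattering coefficients ``mu_a``, ``mu_s'`` in 1/mm,
* hemoglobin concentrations in micromolar (uM),
* times in seconds, Brownian diffusion coefficient ``Db`` in mm^2/s.

Mixing nm and mm when forming ``k0`` is the single likeliest unit bug in
this kind of code, hence the conversion is centralized here.
"""

import math

NM_PER_MM = 1.0e6

#: SFDI illumination wavelengths (nm).
SFDI_WAVELENGTHS_NM = (660.0, 780.0, 850.0)

#: Laser speckle imaging wavelength (nm).
LSI_WAVELENGTH_NM = 633.0

#: Camera exposure time (s).
DEFAULT_EXPOSURE_S = 0.010

#: Default tissue refractive index (typical soft tissue).
DEFAULT_REFRACTIVE_INDEX = 1.4

#: Spatial frequencies of the projected patterns (1/mm).
SFDI_FX_PAIR = (0.0, 0.3)

#: Raw (shared) acquisition rate of the instrument model (Hz).
DEFAULT_RAW_RATE_HZ = 50.0

#: Field of view and sensor geometry: 10 mm mapped onto 1200 px.
FOV_MM = 10.0
FOV_PX = 1200
PIXEL_PITCH_MM = FOV_MM / FOV_PX

#: Imaging-system magnification and speckle optics.
MAGNIFICATION = 0.42
F_NUMBER = 4.0
CAMERA_PIXEL_UM = 3.45

# ---------------------------------------------------------------------------
# Hemoglobin molar extinction coefficients, in 1/cm per mol/L.
#
# Values are taken (interpolated where needed) from the widely used compiled
# oxy-/deoxy-hemoglobin spectra distributed by S. Prahl (Oregon Medical Laser
# Center), themselves compiled from Gratzer and Kollias.  They are
# approximate to a few percent, which is the accuracy of any such
# tabulation; all round-trip consistency inside this package uses this one
# table so no test depends on the absolute scale.
# ---------------------------------------------------------------------------

#: wavelength (nm) -> (eps_HbO2, eps_HbR), 1/cm/M
EXTINCTION_CM_PER_M = {
    633.0: (350.0, 4930.0),
    660.0: (319.6, 3226.56),
    780.0: (740.0, 1160.0),
    850.0: (1058.0, 691.32),
}

#: mu_a [1/mm] = ln(10) * eps [1/cm/M] * 1e-7 * C [uM]
#: (1e-6 M per uM, and 1/cm -> 1/mm).
MUA_PER_EXTINCTION_UM = math.log(10.0) * 1.0e-7


def mua_from_concentrations(wavelength_nm, c_hbo2_um, c_hbr_um):
    """Absorption coefficient (1/mm) from hemoglobin concentrations (uM)."""
    eps_hbo2, eps_hbr = EXTINCTION_CM_PER_M[float(wavelength_nm)]
    return MUA_PER_EXTINCTION_UM * (eps_hbo2 * c_hbo2_um + eps_hbr * c_hbr_um)


# Calibration phantom optical properties (1/mm) at the SFDI wavelengths.
CALIBRATION_PHANTOM_MUA = {660.0: 0.019, 780.0: 0.019, 850.0: 0.019}
CALIBRATION_PHANTOM_MUSP = {660.0: 1.07, 780.0: 0.83, 850.0: 0.72}

# Static part of the flow-tube phantom (1/mm).
FLOW_PHANTOM_MUA = {660.0: 0.0049, 780.0: 0.0059, 850.0: 0.0062}
FLOW_PHANTOM_MUSP = {660.0: 0.87, 780.0: 0.67, 850.0: 0.60}
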