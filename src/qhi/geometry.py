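"""Field-of-view and speckle-optics arithmetic."""

from .constants import (CAMERA_PIXEL_UM, F_NUMBER, FOV_MM, FOV_PX,
                        LSI_WAVELENGTH_NM, MAGNIFICATION)

__all__ = ["px_to_mm", "mm_to_px", "speckle_size_um", "speckle_pixel_ratio"]


def px_to_mm(px: float, fov_mm: float = FOV_MM, fov_px: int = FOV_PX) -> float:
    """Convert a pixel distance to mm on the sample (10 mm over 1200 px)."""
    return px * fov_mm / fov_px


def mm_to_px(mm: float, fov_mm: float = FOV_MM, fov_px: int = FOV_PX) -> float:
    return mm * fov_px / fov_mm


def speckle_size_um(wavelength_nm: float = LSI_WAVELENGTH_NM,
                    magnification: float = MAGNIFICATION,
                    f_number: float = F_NUMBER) -> float:
    """Minimum speckle size on the sensor: ``2.44 lambda (1 + M) f/#``."""
    return 2.44 * (wavelength_nm * 1e-3) * (1.0 + magnification) * f_number


def speckle_pixel_ratio(pixel_um: float = CAMERA_PIXEL_UM, **kwargs) -> float:
    """Speckle-to-camera-pixel size ratio (~9 um over 3.45 um by default)."""
    return speckle_size_um(**kwargs) / pixel_um
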