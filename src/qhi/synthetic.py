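"""Synthetic raw-frame generation for instrument-free testing.

Two renderers make every pipeline stage testable without hardware:

* :func:`render_sfdi_frames` draws the 18-frame patterned-illumination cycle
  over a digital phantom scene, with the per-pixel reflectance given by the
  same diffusion forward model the inversion assumes, so noise-free
  renderings round-trip exactly.
* :func:`simulate_speckle_stack` draws fully developed speckle whose field
  decorrelates exponentially in time (correlation time ``tau_c``) and whose
  intensity is integrated over the camera exposure.  The speckle-to-pixel
  size ratio is controlled by rendering the field on an oversampled grid
  and letting each camera pixel integrate ``oversample^2`` independent
  speckle modes, which sets ``beta ~ 1/oversample^2`` — with the default
  oversample of 2 a static stack measures K around 0.5, in the range
  observed on real static phantoms.

To emulate a target Brownian diffusion coefficient, the generator solves
for the ``tau_c`` whose discretely integrated exponential-decay contrast
equals the correlation-diffusion model's K^2 at that ``Db``, so forward and
inverse models meet at the level of measured contrast (see
docs/methods.md for what this does and does not validate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import constants
from .constants import (DEFAULT_EXPOSURE_S, DEFAULT_REFRACTIVE_INDEX,
                        LSI_WAVELENGTH_NM, PIXEL_PITCH_MM,
                        SFDI_WAVELENGTHS_NM)
from .flow import fit_mus_powerlaw, k2_forward
from .optics import OpticalProperties, rd_forward

__all__ = [
    "PhantomScene",
    "SpeckleStackSpec",
    "render_sfdi_frames",
    "simulate_speckle_stack",
    "phantom_library",
    "flow_tube_scene",
    "scene_from_chromophores",
    "k2_integrated_discrete",
    "tau_c_for_k2",
    "tau_c_from_db",
    "tau_c_map_for_scene",
]


@dataclass
class PhantomScene:
    """Piecewise-constant digital phantom.

    ``mua`` / ``musp`` map wavelength (nm) -> 2-D array (1/mm); ``db`` is
    the per-pixel Brownian diffusion coefficient (mm^2/s, 0 = static).
    Optional chromophore ground truth (uM) is carried when the scene was
    built from hemoglobin concentrations.
    """

    name: str
    shape: tuple
    mua: dict
    musp: dict
    db: np.ndarray
    pixel_pitch_mm: float = PIXEL_PITCH_MM
    c_hbo2: np.ndarray | None = None
    c_hbr: np.ndarray | None = None
    tube: dict | None = None

    def mua_map(self, wavelength_nm: float) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.mua[wavelength_nm], float),
                               self.shape)

    def musp_map(self, wavelength_nm: float) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.musp[wavelength_nm], float),
                               self.shape)

    def db_map(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.db, float), self.shape)


@dataclass
class SpeckleStackSpec:
    """Parameters of a synthetic speckle acquisition.

    ``tau_c`` is the field correlation time in seconds (scalar or per-pixel
    map; ``np.inf`` means static).  ``oversample`` is the linear
    speckle-per-pixel factor controlling beta (see module docstring).
    """

    shape: tuple
    n_frames: int
    tau_c: float | np.ndarray
    exposure: float = DEFAULT_EXPOSURE_S
    frame_period: float = 0.020
    substeps: int = 64
    oversample: int = 2
    mean_counts: float = 60.0
    bit_depth: int | None = 8
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducible stacks")
        if np.any(np.asarray(self.tau_c, float) <= 0):
            raise ValueError("tau_c must be > 0 (use np.inf for static)")


# ---------------------------------------------------------------------------
# SFDI rendering
# ---------------------------------------------------------------------------

def render_sfdi_frames(scene: PhantomScene, schedule,
                       m0: float = 60000.0, noise_sd: float = 0.0,
                       seed: int | None = 0) -> list:
    """Render one 18-frame SFDI cycle over a scene.

    fx = 0 slots are uniform illumination: ``I = m0 * Rd(0)``, identical for
    the three nominal phases.  fx > 0 slots carry the projected sinusoid:
    ``I = (m0/2) Rd(0) + (m0/2) Rd(fx) cos(2 pi fx x + phase)`` — the DC
    pedestal reflects with ``Rd(0)``, the modulated part with ``Rd(fx)``.
    Additive Gaussian noise of ``noise_sd`` counts is drawn per frame;
    ``noise_sd = 0`` gives exact round-trip inputs.

    Returns a list of ``(SlotSpec, float ndarray)`` in slot order.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.shape
    x_mm = np.arange(w) * scene.pixel_pitch_mm
    frames = []
    rd_cache: dict = {}
    for slot in schedule.entries:
        key = (slot.wavelength_nm, slot.fx)
        if key not in rd_cache:
            pair = (scene.mua_map(slot.wavelength_nm),
                    scene.musp_map(slot.wavelength_nm))
            rd_cache[key] = rd_forward(pair, fx=slot.fx)
        rd0 = rd_cache.setdefault(
            (slot.wavelength_nm, 0.0),
            rd_forward((scene.mua_map(slot.wavelength_nm),
                        scene.musp_map(slot.wavelength_nm)), fx=0.0))
        if slot.fx == 0.0:
            frame = m0 * np.array(rd0, dtype=float, copy=True)
        else:
            phase = np.deg2rad(slot.phase_deg)
            pattern = np.cos(2.0 * np.pi * slot.fx * x_mm + phase)
            frame = 0.5 * m0 * rd0 + 0.5 * m0 * rd_cache[key] * pattern[None, :]
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames.append((slot, frame))
    return frames


# ---------------------------------------------------------------------------
# Speckle synthesis
# ---------------------------------------------------------------------------

def k2_integrated_discrete(x: float, substeps: int) -> float:
    """Integrated contrast of an AR(1)-sampled exponential field decay.

    ``x = T / tau_c``.  The exposure integral is realized as the mean of
    ``M`` field samples with intensity autocovariance ``q^|m-n|``,
    ``q = exp(-2 x / M)``, giving

    ``K^2 = (M + 2 sum_{k=1}^{M-1} (M - k) q^k) / M^2``

    which tends to the continuous ``(e^{-2x} - 1 + 2x) / (2 x^2)`` as
    ``M -> inf`` and to 1 as ``x -> 0``.
    """
    m = substeps
    q = np.exp(-2.0 * x / m)
    k = np.arange(1, m)
    return float((m + 2.0 * np.sum((m - k) * q**k)) / m**2)


def tau_c_for_k2(k2_target: float, exposure: float = DEFAULT_EXPOSURE_S,
                 substeps: int = 64) -> float:
    """Correlation time whose discrete integrated contrast equals the target.

    ``k2_target`` is the field-level (beta = 1) squared contrast in (0, 1).
    """
    if not 0.0 < k2_target < 1.0:
        raise ValueError(f"k2_target must be in (0, 1), got {k2_target}")
    floor = k2_integrated_discrete(1e9 * exposure, substeps)
    if k2_target <= floor * 1.001:
        raise ValueError("target contrast below the temporal sampling floor; "
                         "increase substeps")
    f = lambda logx: k2_integrated_discrete(np.exp(logx), substeps) - k2_target
    logx = brentq(f, np.log(1e-8), np.log(1e8), xtol=1e-13)
    return exposure / np.exp(logx)


def tau_c_from_db(db: float, op: OpticalProperties,
                  exposure: float = DEFAULT_EXPOSURE_S,
                  n: float = DEFAULT_REFRACTIVE_INDEX,
                  substeps: int = 64) -> float:
    """tau_c realizing the correlation-diffusion K^2 at a given Db."""
    if db == 0:
        return np.inf
    target = k2_forward(db, op, beta=1.0, exposure=exposure, n=n)
    return tau_c_for_k2(target, exposure=exposure, substeps=substeps)


def simulate_speckle_stack(spec: SpeckleStackSpec) -> np.ndarray:
    """Generate a temporally decorrelating, exposure-integrated speckle stack.

    Each speckle mode is a circular complex Gaussian evolved as an AR(1)
    process so the field autocorrelation is ``exp(-tau/tau_c)``; intensity
    is averaged over ``substeps`` samples spanning the exposure, then over
    ``oversample^2`` modes per camera pixel, scaled to ``mean_counts`` and
    (optionally) quantized.  Deterministic given the seed.

    Returns an ``(n_frames, H, W)`` array, dtype uint8/uint16 when
    ``bit_depth`` is set, float64 otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    s = int(spec.oversample)
    fh, fw = h * s, w * s
    tau_c = np.broadcast_to(np.asarray(spec.tau_c, float), spec.shape)
    tau_fine = np.repeat(np.repeat(tau_c, s, axis=0), s, axis=1)
    dt = spec.exposure / spec.substeps
    gap = max(spec.frame_period - spec.exposure, 0.0)
    with np.errstate(over="ignore"):
        rho_step = np.exp(-dt / tau_fine)
        rho_gap = np.exp(-gap / tau_fine)
    innov_step = np.sqrt(1.0 - rho_step**2)
    innov_gap = np.sqrt(1.0 - rho_gap**2)

    def fresh():
        return (rng.standard_normal((fh, fw))
                + 1j * rng.standard_normal((fh, fw))) / np.sqrt(2.0)

    def evolve(e, rho, innov):
        return rho * e + innov * fresh()

    e = fresh()
    out = np.empty((spec.n_frames, h, w))
    for f in range(spec.n_frames):
        acc = np.zeros((fh, fw))
        for _ in range(spec.substeps):
            acc += e.real**2 + e.imag**2
            e = evolve(e, rho_step, innov_step)
        intensity = acc / spec.substeps
        # camera pixel integrates oversample^2 independent speckle modes
        binned = intensity.reshape(h, s, w, s).mean(axis=(1, 3))
        out[f] = binned * spec.mean_counts
        e = evolve(e, rho_gap, innov_gap)
    if spec.bit_depth is None:
        return out
    full = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    return np.clip(np.rint(out), 0, full).astype(dtype)


# ---------------------------------------------------------------------------
# Scene library
# ---------------------------------------------------------------------------

def _homogeneous(name, mua_by_wl, musp_by_wl, shape=(64, 64), db=0.0):
    return PhantomScene(
        name=name, shape=shape,
        mua={w: np.full(shape, m) for w, m in mua_by_wl.items()},
        musp={w: np.full(shape, m) for w, m in musp_by_wl.items()},
        db=np.full(shape, float(db)))


def phantom_library(shape=(64, 64)) -> dict:
    """The four characterization phantoms, anchored at the calibration values.

    Phantom 1 carries the calibration-phantom optical properties; phantom 2
    doubles mu_a (higher contrast at fixed flow), phantom 3 doubles mu_s'
    (lower contrast), phantom 4 doubles both (contrast ~ phantom 1, since
    K^2 is invariant under joint scaling).
    """
    base_mua = constants.CALIBRATION_PHANTOM_MUA
    base_musp = constants.CALIBRATION_PHANTOM_MUSP
    scale = {
        "phantom1": (1.0, 1.0),
        "phantom2": (2.0, 1.0),
        "phantom3": (1.0, 2.0),
        "phantom4": (2.0, 2.0),
    }
    return {
        name: _homogeneous(
            name,
            {w: sa * m for w, m in base_mua.items()},
            {w: ss * m for w, m in base_musp.items()},
            shape=shape)
        for name, (sa, ss) in scale.items()
    }


def flow_tube_scene(shape=(128, 128), tube_radius_px: int = 20,
                    db_tube: float = 2e-6,
                    pixel_pitch_mm: float = PIXEL_PITCH_MM) -> PhantomScene:
    """Static scattering slab with an embedded flow channel.

    Mimics a capillary-tube flow phantom: the static part carries the
    measured tube-phantom optical properties, a horizontal band through the
    center carries Brownian motion at ``db_tube``.  The channel's optical
    properties are kept equal to the slab's, so the scene isolates the
    flow contrast.
    """
    h, w = shape
    rows = np.arange(h)[:, None]
    band = np.abs(rows - h // 2) <= tube_radius_px
    db = np.where(band & np.ones((1, w), bool), db_tube, 0.0)
    scene = _homogeneous("flow_tube", constants.FLOW_PHANTOM_MUA,
                         constants.FLOW_PHANTOM_MUSP, shape=shape, db=0.0)
    # properties at the 633 nm speckle wavelength: mu_s' from the scattering
    # power law fitted to the printed values, mu_a taken from the adjacent
    # 660 nm value (ink/silicone absorption varies slowly there)
    fit = fit_mus_powerlaw(constants.FLOW_PHANTOM_MUSP)
    scene.musp[LSI_WAVELENGTH_NM] = np.full(
        shape, fit.amp * (LSI_WAVELENGTH_NM / 850.0) ** fit.slope)
    scene.mua[LSI_WAVELENGTH_NM] = np.full(
        shape, constants.FLOW_PHANTOM_MUA[660.0])
    scene.db = db
    scene.pixel_pitch_mm = pixel_pitch_mm
    scene.tube = {"center_row": h // 2, "radius_px": tube_radius_px,
                  "db": db_tube}
    return scene


def tau_c_map_for_scene(scene: PhantomScene,
                        exposure: float = DEFAULT_EXPOSURE_S,
                        n: float = DEFAULT_REFRACTIVE_INDEX,
                        substeps: int = 64) -> np.ndarray:
    """Per-pixel tau_c realizing the scene's Db at its 633 nm properties.

    Piecewise-constant scenes are resolved per unique (db, mu_a, mu_s')
    triple; static pixels (db = 0) get ``np.inf``.
    """
    db = scene.db_map()
    mua = scene.mua_map(LSI_WAVELENGTH_NM)
    musp = scene.musp_map(LSI_WAVELENGTH_NM)
    out = np.full(scene.shape, np.inf)
    triples = np.unique(
        np.stack([db, mua, musp], axis=-1).reshape(-1, 3), axis=0)
    for d, ma, ms in triples:
        if d <= 0:
            continue
        tc = tau_c_from_db(float(d), OpticalProperties(float(ma), float(ms),
                                                       LSI_WAVELENGTH_NM),
                           exposure=exposure, n=n, substeps=substeps)
        out[(db == d) & (mua == ma) & (musp == ms)] = tc
    return out


def scene_from_chromophores(c_hbo2, c_hbr, musp_amp, musp_slope, db,
                            wavelengths_nm=SFDI_WAVELENGTHS_NM,
                            pixel_pitch_mm: float = PIXEL_PITCH_MM,
                            name: str = "chromophore-scene") -> PhantomScene:
    """Build a scene whose absorption derives from hemoglobin maps.

    mu_a at every wavelength (including 633 nm) follows the extinction
    table; mu_s' follows the scattering power law ``amp (lambda/850)^slope``
    — so the full SFDI -> chromophores -> 633 nm -> Db chain has an exact
    ground truth.
    """
    c_hbo2 = np.asarray(c_hbo2, float)
    c_hbr = np.asarray(c_hbr, float)
    shape = c_hbo2.shape
    all_wl = tuple(wavelengths_nm) + (LSI_WAVELENGTH_NM,)
    mua = {w: constants.mua_from_concentrations(w, c_hbo2, c_hbr)
           for w in all_wl}
    musp = {w: np.broadcast_to(
        np.asarray(musp_amp, float) * (w / 850.0) ** np.asarray(musp_slope, float),
        shape) for w in all_wl}
    return PhantomScene(name=name, shape=shape, mua=mua, musp=musp,
                        db=np.broadcast_to(np.asarray(db, float), shape),
                        pixel_pitch_mm=pixel_pitch_mm,
                        c_hbo2=c_hbo2, c_hbr=c_hbr)
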