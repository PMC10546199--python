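"""End-to-end runs: simulate a dataset, process it, report on the outputs.

The three entry points mirror the CLI subcommands and are plain functions
so tests can call each stage directly.  Every run echoes its configuration
hash into the outputs; reruns on identical inputs are bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants, io
from .acquisition import (FrameRecord, make_schedule, read_manifest,
                          validate_sets, write_manifest)
from .config import RunConfig, config_hash
from .flow import (build_k2_lut, extrapolate_musp, fit_mus_powerlaw,
                   invert_db, mua_at_lsi_wavelength, percent_difference_map)
from .lsi import (ContrastMap, beta_correct, estimate_beta, roi_timecourse,
                  sfi, speckle_contrast)
from .optics import OpticalProperties
from .sfdi import (PhaseTriplet, build_rd_lut, calibrate, demodulate,
                   demodulate_dc, fit_chromophores, invert_optical_properties,
                   smooth)
from .synthetic import (PhantomScene, SpeckleStackSpec, flow_tube_scene,
                        phantom_library, render_sfdi_frames,
                        scene_from_chromophores, simulate_speckle_stack,
                        tau_c_map_for_scene)

__all__ = ["build_scene", "cmd_simulate", "cmd_process", "cmd_report",
           "central_disc"]

log = logging.getLogger("qhi")


def central_disc(shape, radius: int | None = None) -> np.ndarray:
    """Central circular ROI mask (default radius: a quarter of the side)."""
    h, w = shape
    if radius is None:
        radius = min(h, w) // 4
    yy, xx = np.ogrid[:h, :w]
    return (yy - h // 2) ** 2 + (xx - w // 2) ** 2 <= radius**2


def build_scene(cfg: RunConfig) -> PhantomScene:
    """Construct the digital phantom named in the config."""
    sim = cfg.simulate
    shape = tuple(sim.shape)
    name = sim.scene
    if name == "brain":
        # cortex-like background with a focal high-perfusion patch
        c_hbo2 = np.full(shape, 70.0)
        c_hbr = np.full(shape, 30.0)
        db = np.full(shape, 1.0e-6)
        disc = central_disc(shape, radius=min(shape) // 6)
        c_hbo2[disc], c_hbr[disc] = 90.0, 40.0
        db[disc] = 2.0e-6
        scene = scene_from_chromophores(
            c_hbo2, c_hbr, musp_amp=1.0, musp_slope=-1.3, db=db,
            wavelengths_nm=cfg.physics.wavelengths_nm,
            pixel_pitch_mm=cfg.physics.pixel_pitch_mm, name="brain")
        return scene
    if name == "flow_tube":
        return flow_tube_scene(shape, pixel_pitch_mm=cfg.physics.pixel_pitch_mm)
    if name in ("phantom1", "phantom2", "phantom3", "phantom4"):
        return phantom_library(shape)[name]
    if name == "calibration":
        return _calibration_scene(shape)
    raise ValueError(f"unknown scene {name!r}")


def _calibration_scene(shape) -> PhantomScene:
    return PhantomScene(
        name="calibration", shape=shape,
        mua={w: np.full(shape, m)
             for w, m in constants.CALIBRATION_PHANTOM_MUA.items()},
        musp={w: np.full(shape, m)
              for w, m in constants.CALIBRATION_PHANTOM_MUSP.items()},
        db=np.zeros(shape))


def cmd_simulate(cfg: RunConfig) -> dict:
    """Render a paired LSI+SFDI dataset, calibration set and ground truth."""
    data_dir = Path(cfg.paths.data_dir)
    (data_dir / "calibration").mkdir(parents=True, exist_ok=True)
    (data_dir / "beta").mkdir(parents=True, exist_ok=True)
    sim, phys = cfg.simulate, cfg.physics
    scene = build_scene(cfg)
    schedule = make_schedule(phys.raw_rate_hz, phys.wavelengths_nm,
                             phys.fx_pair)
    rng = np.random.default_rng(cfg.seed)
    drops = {tuple(d) for d in sim.drop}
    period = 1.0 / phys.raw_rate_hz

    records = []
    # --- SFDI stream ------------------------------------------------------
    for cycle in range(sim.cycles):
        frames = render_sfdi_frames(scene, schedule, m0=sim.m0,
                                    noise_sd=sim.noise_sd,
                                    seed=int(rng.integers(2**31)))
        for slot, frame in frames:
            if ("SFDI", cycle, slot.index) in drops:
                continue
            name = io.frame_name("sfdi", cycle, slot.index)
            io.write_frame(data_dir / name, frame, bit_depth=16)
            records.append(FrameRecord(
                modality="SFDI", cycle=cycle, index=slot.index,
                timestamp_s=(cycle * 18 + slot.index) * period, path=name))

    # --- LSI stream -------------------------------------------------------
    tau_map = tau_c_map_for_scene(scene, exposure=phys.exposure_s,
                                  n=phys.n, substeps=sim.substeps)
    stack = simulate_speckle_stack(SpeckleStackSpec(
        shape=scene.shape, n_frames=18 * sim.cycles, tau_c=tau_map,
        exposure=phys.exposure_s, frame_period=period,
        substeps=sim.substeps, oversample=sim.oversample,
        mean_counts=sim.mean_counts, bit_depth=8,
        seed=int(rng.integers(2**31))))
    for f in range(stack.shape[0]):
        cycle, index = divmod(f, 18)
        if ("LSI", cycle, index) in drops:
            continue
        name = io.frame_name("lsi", cycle, index)
        io.write_frame(data_dir / name, stack[f], bit_depth=8)
        records.append(FrameRecord(modality="LSI", cycle=cycle, index=index,
                                   timestamp_s=f * period, path=name))
    write_manifest(records, data_dir / "manifest.csv")

    # --- calibration phantom (one SFDI cycle) -----------------------------
    cal_scene = _calibration_scene(scene.shape)
    cal_records = []
    for slot, frame in render_sfdi_frames(cal_scene, schedule, m0=sim.m0,
                                          noise_sd=sim.noise_sd,
                                          seed=int(rng.integers(2**31))):
        name = io.frame_name("sfdi", 0, slot.index)
        io.write_frame(data_dir / "calibration" / name, frame, bit_depth=16)
        cal_records.append(FrameRecord(
            modality="SFDI", cycle=0, index=slot.index,
            timestamp_s=slot.index * period, path=name))
    write_manifest(cal_records, data_dir / "calibration" / "manifest.csv")

    # --- static phantom stack for beta ------------------------------------
    beta_stack = simulate_speckle_stack(SpeckleStackSpec(
        shape=scene.shape, n_frames=sim.beta_frames, tau_c=np.inf,
        exposure=phys.exposure_s, frame_period=period,
        substeps=1, oversample=sim.oversample,
        mean_counts=sim.mean_counts, bit_depth=8,
        seed=int(rng.integers(2**31))))
    for f in range(beta_stack.shape[0]):
        io.write_frame(data_dir / "beta" / f"beta_{f:03d}.tiff",
                       beta_stack[f], bit_depth=8)

    truth = {
        "scene": scene.name,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "beta_nominal": 1.0 / sim.oversample**2,
        "median_db_dynamic": float(np.median(scene.db_map()[scene.db_map() > 0]))
        if np.any(scene.db_map() > 0) else 0.0,
        "mua_median": {str(w): float(np.median(scene.mua_map(w)))
                       for w in scene.mua},
        "musp_median": {str(w): float(np.median(scene.musp_map(w)))
                        for w in scene.musp},
    }
    truth["dataset_hash"] = io.dataset_hash(data_dir)
    (data_dir / "ground_truth.yaml").write_text(yaml.safe_dump(truth))
    log.info("simulated %s: %d cycles, %d frames, hash %s", scene.name,
             sim.cycles, len(records), truth["dataset_hash"][:12])
    return truth


def _sfdi_triplets(frames_by_index: dict, schedule):
    """Group one SFDI cycle's frames into (wavelength, fx) phase triplets."""
    by_key: dict = {}
    for slot in schedule.entries:
        by_key.setdefault((slot.wavelength_nm, slot.fx), []).append(slot)
    triplets = {}
    for (wl, fx), slots in by_key.items():
        slots = sorted(slots, key=lambda s: s.phase_deg)
        imgs = [np.asarray(frames_by_index[s.index], float) for s in slots]
        triplets[(wl, fx)] = PhaseTriplet(i1=imgs[0], i2=imgs[1], i3=imgs[2],
                                          fx=fx, wavelength_nm=wl)
    return triplets


def _demodulated_amplitudes(triplets, gaussian_window):
    """Demodulate and smooth every (wavelength, fx) triplet of one cycle."""
    out = {}
    for (wl, fx), trip in triplets.items():
        mac = demodulate_dc(trip) if fx == 0.0 else demodulate(trip)
        out[(wl, fx)] = smooth(mac, window=gaussian_window)
    return out


def cmd_process(cfg: RunConfig) -> dict:
    """Full processing chain from raw frames to optical property and Db maps.

    validate sets -> demodulate -> calibrate -> invert optical properties ->
    chromophores -> speckle contrast -> beta -> scattering power law ->
    Db inversion; writes maps, time courses and a JSON report.
    """
    phys, filters, luts = cfg.physics, cfg.filters, cfg.luts
    data_dir = Path(cfg.paths.data_dir)
    out_dir = Path(cfg.paths.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schedule = make_schedule(phys.raw_rate_hz, phys.wavelengths_nm,
                             phys.fx_pair)

    records = read_manifest(data_dir / "manifest.csv")
    accepted, report = validate_sets(records)
    if not accepted:
        raise RuntimeError(
            "no complete 18-frame set in both streams: every cycle has a "
            "dropped frame, and an incomplete cycle in either stream is "
            "disregarded for both")
    log.info("accepted %d cycles, rejected %d", len(report.accepted_cycles),
             len(report.rejected_cycles))

    # --- calibration phantom amplitudes -----------------------------------
    cal_records = read_manifest(data_dir / "calibration" / "manifest.csv")
    cal_frames = {r.index: io.read_frame(data_dir / "calibration" / r.path)
                  for r in cal_records}
    cal_mac = _demodulated_amplitudes(_sfdi_triplets(cal_frames, schedule),
                                      filters.gaussian_window)
    phantom_ops = {
        wl: OpticalProperties(constants.CALIBRATION_PHANTOM_MUA[wl],
                              constants.CALIBRATION_PHANTOM_MUSP[wl], wl)
        for wl in phys.wavelengths_nm}

    rd_lut = build_rd_lut(n=phys.n, n_points=luts.rd_points,
                          fx_pair=phys.fx_pair)

    # --- per-cycle SFDI maps ----------------------------------------------
    per_cycle: dict = {}
    invalid_fraction = {}
    for cycle, streams in accepted.items():
        frames = {i: io.read_frame(data_dir / rec.path)
                  for i, rec in streams["SFDI"].items()}
        mac = _demodulated_amplitudes(_sfdi_triplets(frames, schedule),
                                      filters.gaussian_window)
        mua_maps, musp_maps = {}, {}
        for wl in phys.wavelengths_nm:
            rd0 = calibrate(mac[(wl, phys.fx_pair[0])],
                            cal_mac[(wl, phys.fx_pair[0])],
                            phantom_ops[wl], n=phys.n)
            rd03 = calibrate(mac[(wl, phys.fx_pair[1])],
                             cal_mac[(wl, phys.fx_pair[1])],
                             phantom_ops[wl], n=phys.n)
            opmap = invert_optical_properties(rd0, rd03, rd_lut)
            mua = np.where(opmap.invalid, np.nan, opmap.mua)
            musp = np.where(opmap.invalid, np.nan, opmap.musp)
            mua_maps[wl], musp_maps[wl] = mua, musp
            invalid_fraction[f"cycle{cycle}_mua_{wl:.0f}nm"] = \
                float(opmap.invalid.mean())
            io.write_map(out_dir / f"mua_{wl:.0f}nm_cycle{cycle}.tiff", mua,
                         units="1/mm", wavelength_nm=wl, fx=list(phys.fx_pair))
            io.write_map(out_dir / f"musp_{wl:.0f}nm_cycle{cycle}.tiff", musp,
                         units="1/mm", wavelength_nm=wl, fx=list(phys.fx_pair))
        chrom = fit_chromophores(mua_maps)
        fit = fit_mus_powerlaw(musp_maps)
        mua_lsi = mua_at_lsi_wavelength(chrom)
        musp_lsi = extrapolate_musp(fit, phys.lambda_lsi_nm)
        per_cycle[cycle] = {"mua_maps": mua_maps, "musp_maps": musp_maps,
                            "chrom": chrom, "mua_lsi": mua_lsi,
                            "musp_lsi": musp_lsi}
        io.write_map(out_dir / f"hbt_cycle{cycle}.tiff", chrom.hbt, units="uM")
        io.write_map(out_dir / f"sto2_cycle{cycle}.tiff", chrom.sto2,
                     units="percent")
        io.write_map(out_dir / f"mua_{phys.lambda_lsi_nm:.0f}nm_cycle{cycle}.tiff",
                     mua_lsi, units="1/mm", wavelength_nm=phys.lambda_lsi_nm)
        io.write_map(out_dir / f"musp_{phys.lambda_lsi_nm:.0f}nm_cycle{cycle}.tiff",
                     musp_lsi, units="1/mm", wavelength_nm=phys.lambda_lsi_nm)

    # --- beta from the static phantom stack --------------------------------
    beta_paths = sorted((data_dir / "beta").glob("beta_*.tiff"))
    if not beta_paths:
        raise RuntimeError("no static-phantom frames found for beta estimation")
    beta_ks = [speckle_contrast(io.read_frame(p).astype(float),
                                window=filters.contrast_window,
                                exposure=phys.exposure_s)
               for p in beta_paths]
    beta = estimate_beta(ContrastMap(
        k=np.concatenate([c.k for c in beta_ks], axis=0),
        exposure=phys.exposure_s, window=filters.contrast_window,
        invalid=np.concatenate([c.invalid for c in beta_ks], axis=0)))
    log.info("beta = %.4f from %d static frames", beta.beta, len(beta_paths))

    # --- LSI contrast / SFI ------------------------------------------------
    lsi_records = sorted(
        (rec for streams in accepted.values() for rec in streams["LSI"].values()),
        key=lambda r: r.timestamp_s)
    contrasts, sfis = [], []
    for rec in lsi_records:
        c = speckle_contrast(io.read_frame(data_dir / rec.path).astype(float),
                             window=filters.contrast_window,
                             exposure=phys.exposure_s)
        contrasts.append(c)
        sfis.append(beta_correct(sfi(c), beta))

    # --- Db map: per-pixel median K + cycle-median optical properties ------
    import warnings
    with warnings.catch_warnings():
        # contrast maps are NaN on the 2-px window border by design
        warnings.simplefilter("ignore", RuntimeWarning)
        k_median = np.nanmedian(np.stack([c.k for c in contrasts]), axis=0)
        mua_lsi_med = np.nanmedian(
            np.stack([v["mua_lsi"] for v in per_cycle.values()]), axis=0)
        musp_lsi_med = np.nanmedian(
            np.stack([v["musp_lsi"] for v in per_cycle.values()]), axis=0)
    k2_lut = build_k2_lut(beta=beta.beta, exposure=phys.exposure_s,
                          lambda_lsi_nm=phys.lambda_lsi_nm, n=phys.n,
                          db_max=luts.db_max, n_db=luts.k2_n_db,
                          n_mua=luts.k2_n_mua, n_musp=luts.k2_n_musp)
    db_map = invert_db(k_median, mua_lsi_med, musp_lsi_med, k2_lut)
    io.write_map(out_dir / "k_median.tiff", k_median, units="dimensionless")
    io.write_map(out_dir / "db_map.tiff",
                 np.where(db_map.invalid, np.nan, db_map.values),
                 units="mm^2/s", beta=beta.beta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sfi_median = np.nanmedian(np.stack([s.values for s in sfis]), axis=0)
    io.write_map(out_dir / "sfi_beta_median.tiff", sfi_median, units="1/s",
                 beta=beta.beta)
    invalid_fraction["db_map"] = float(db_map.invalid.mean())

    # --- ROI time courses ---------------------------------------------------
    roi = central_disc(k_median.shape)
    sfi_series = roi_timecourse(sfis, roi, filter_len=1)
    k_series = roi_timecourse(contrasts, roi, filter_len=1)
    mua_roi = float(np.nanmedian(mua_lsi_med[roi]))
    musp_roi = float(np.nanmedian(musp_lsi_med[roi]))
    db_series = np.array([
        _safe_invert(k, mua_roi, musp_roi, k2_lut) for k in k_series])
    timestamps = np.array([r.timestamp_s for r in lsi_records])
    pd.DataFrame({
        "frame_index": np.arange(len(lsi_records)),
        "timestamp_s": timestamps,
        "k_roi_median": k_series,
        "sfi_beta": sfi_series,
        "db": db_series,
    }).to_csv(out_dir / "timecourse_raw.csv", index=False)
    flen = min(filters.moving_average, len(sfi_series))
    kernel = np.full(flen, 1.0 / flen)
    pd.DataFrame({
        "timestamp_s": timestamps[flen - 1:] - 0.5 * (flen - 1) / phys.raw_rate_hz,
        "sfi_beta": np.convolve(sfi_series, kernel, mode="valid"),
        "db": np.convolve(db_series, kernel, mode="valid"),
    }).to_csv(out_dir / "timecourse_filtered.csv", index=False)

    run_report = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "beta": beta.beta,
        "accepted_cycles": report.accepted_cycles,
        "rejected_cycles": report.rejected_cycles,
        "missing": {str(c): m for c, m in report.missing.items()},
        "frames_in": report.frames_in,
        "frames_accepted": report.frames_accepted,
        "invalid_fraction": invalid_fraction,
        "moving_average": filters.moving_average,
    }
    (out_dir / "report.json").write_text(json.dumps(run_report, indent=1,
                                                    sort_keys=True))
    return {"report": run_report, "per_cycle": per_cycle, "beta": beta,
            "db_map": db_map, "k_median": k_median,
            "sfi_median": sfi_median,
            "mua_lsi": mua_lsi_med, "musp_lsi": musp_lsi_med,
            "timecourse": {"t": timestamps, "sfi": sfi_series,
                           "db": db_series}}


def _safe_invert(k, mua, musp, lut):
    try:
        return invert_db(float(k), mua, musp, lut)
    except ValueError:
        return np.nan


def cmd_report(cfg: RunConfig) -> dict:
    """Human-readable summary: normalized time courses, % difference map."""
    out_dir = Path(cfg.paths.output_dir)
    if not (out_dir / "report.json").exists():
        raise FileNotFoundError(f"no processed outputs in {out_dir}; "
                                "run the process step first")
    run_report = json.loads((out_dir / "report.json").read_text())
    tc = pd.read_csv(out_dir / "timecourse_raw.csv")

    # normalized to t = 0; beta cancels in the normalized SFI curve
    norm = pd.DataFrame({
        "timestamp_s": tc["timestamp_s"],
        "sfi_norm": tc["sfi_beta"] / tc["sfi_beta"].iloc[0],
        "db_norm": tc["db"] / tc["db"].iloc[0],
    })
    norm.to_csv(out_dir / "timecourse_normalized.csv", index=False)

    db_arr, _ = io.read_map(out_dir / "db_map.tiff")
    sfi_arr, _ = io.read_map(out_dir / "sfi_beta_median.tiff")
    pdiff = percent_difference_map(db_arr.astype(float), sfi_arr.astype(float))
    io.write_map(out_dir / "percent_difference.tiff", pdiff, units="percent")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].plot(norm["timestamp_s"], norm["sfi_norm"], label="SFI (norm)")
    axes[0].plot(norm["timestamp_s"], norm["db_norm"], label="Db (norm)")
    axes[0].set_xlabel("time (s)")
    axes[0].set_ylabel("relative flow")
    axes[0].legend()
    im = axes[1].imshow(pdiff, cmap="RdBu_r", vmin=-25, vmax=25)
    axes[1].set_title("(Db_norm - SFI_norm)/SFI_norm x 100")
    fig.colorbar(im, ax=axes[1])
    fig.tight_layout()
    fig.savefig(out_dir / "summary.png", dpi=110)
    plt.close(fig)

    from .acquisition import effective_rates
    lsi_rate, sfdi_rate = effective_rates(cfg.physics.raw_rate_hz)
    summary = {
        "config_hash": run_report["config_hash"],
        "beta": run_report["beta"],
        "lsi_rate_hz": lsi_rate,
        "sfdi_rate_hz": round(sfdi_rate, 1),
        "moving_average": run_report["moving_average"],
        "accepted_cycles": run_report["accepted_cycles"],
        "rejected_cycles": run_report["rejected_cycles"],
        "percent_difference_median": float(np.nanmedian(pdiff)),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                     sort_keys=True))
    return {"summary": summary, "normalized": norm, "percent_difference": pdiff}
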