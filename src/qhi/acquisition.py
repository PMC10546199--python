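"""Acquisition cycle model: 18-frame schedule, rates, dropped-frame rejection.

The instrument interleaves three wavelengths, two spatial frequencies and
three phases into an 18-frame cycle shared by the paired LSI and SFDI
streams (wavelengths cycle fastest, to mitigate LED thermal drift).  Frames
carry an order index 0-17 and a timestamp; an incomplete cycle in *either*
stream invalidates that cycle for *both*, since the correction method needs
matched data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .constants import DEFAULT_RAW_RATE_HZ, SFDI_FX_PAIR, SFDI_WAVELENGTHS_NM

__all__ = [
    "SlotSpec",
    "CycleSchedule",
    "FrameRecord",
    "RejectionReport",
    "make_schedule",
    "effective_rates",
    "validate_sets",
    "write_manifest",
    "read_manifest",
]

FRAMES_PER_CYCLE = 18
MODALITIES = ("LSI", "SFDI")


@dataclass(frozen=True)
class SlotSpec:
    """One slot of the 18-frame cycle."""

    index: int
    wavelength_nm: float
    fx: float
    phase_deg: float


@dataclass(frozen=True)
class CycleSchedule:
    """Deterministic 18-slot schedule at a given raw frame rate."""

    raw_rate_hz: float
    entries: tuple

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.raw_rate_hz

    @property
    def cycle_duration_s(self) -> float:
        return FRAMES_PER_CYCLE / self.raw_rate_hz


@dataclass(frozen=True)
class FrameRecord:
    """One saved frame: stream, cycle, in-cycle index, timestamp, file."""

    modality: str
    cycle: int
    index: int
    timestamp_s: float
    path: str = ""


@dataclass
class RejectionReport:
    """Bookkeeping of the set-level dropped-frame rejection."""

    accepted_cycles: list = field(default_factory=list)
    rejected_cycles: list = field(default_factory=list)
    #: cycle -> {modality: sorted list of missing indices}
    missing: dict = field(default_factory=dict)
    frames_in: int = 0
    frames_accepted: int = 0
    frames_rejected: int = 0


def make_schedule(raw_rate_hz: float = DEFAULT_RAW_RATE_HZ,
                  wavelengths_nm=SFDI_WAVELENGTHS_NM,
                  fx_pair=SFDI_FX_PAIR,
                  phases_deg=(0.0, 120.0, 240.0)) -> CycleSchedule:
    """Build the 18-slot cycle: wavelengths innermost, then phase, then fx.

    Slots 0, 1, 2 carry the three wavelengths at the same (fx, phase); the
    projected pattern advances once every three frames.  Phase order within
    a (wavelength, fx) block is 0, 120, 240 degrees by convention; the
    schedule carries the explicit assignment so demodulation never guesses.
    """
    if not raw_rate_hz > 0:
        raise ValueError(f"raw_rate_hz must be > 0, got {raw_rate_hz}")
    entries = []
    for p, (fx, phase) in enumerate(product(fx_pair, phases_deg)):
        for w, wavelength in enumerate(wavelengths_nm):
            entries.append(SlotSpec(index=3 * p + w, wavelength_nm=wavelength,
                                    fx=fx, phase_deg=phase))
    assert len(entries) == FRAMES_PER_CYCLE
    return CycleSchedule(raw_rate_hz=raw_rate_hz, entries=tuple(entries))


def effective_rates(raw_rate_hz: float) -> tuple[float, float]:
    """(LSI rate, SFDI rate) in Hz: every frame is an LSI frame, one full
    SFDI acquisition needs the whole 18-frame cycle."""
    if not raw_rate_hz > 0:
        raise ValueError(f"raw_rate_hz must be > 0, got {raw_rate_hz}")
    return raw_rate_hz, raw_rate_hz / FRAMES_PER_CYCLE


def validate_sets(records) -> tuple[dict, RejectionReport]:
    """Group frames into 18-sets and apply the either-stream rejection rule.

    Frames are grouped by their cycle number; a cycle is accepted only if
    both modalities contain every index 0-17 exactly once.  A gap in either
    stream rejects the cycle for both.  Rejection is a reported outcome,
    not an error.

    Returns
    -------
    accepted : dict
        ``{cycle: {modality: {index: FrameRecord}}}`` for complete cycles.
    report : RejectionReport
    """
    by_cycle: dict = {}
    report = RejectionReport(frames_in=len(records))
    for rec in records:
        if rec.modality not in MODALITIES:
            raise ValueError(f"unknown modality {rec.modality!r}")
        if not 0 <= rec.index < FRAMES_PER_CYCLE:
            raise ValueError(f"index {rec.index} outside 0-17")
        by_cycle.setdefault(rec.cycle, {m: {} for m in MODALITIES})
        by_cycle[rec.cycle][rec.modality][rec.index] = rec

    accepted = {}
    for cycle in sorted(by_cycle):
        missing = {
            m: sorted(set(range(FRAMES_PER_CYCLE)) - set(by_cycle[cycle][m]))
            for m in MODALITIES
        }
        n_frames = sum(len(by_cycle[cycle][m]) for m in MODALITIES)
        if any(missing.values()):
            report.rejected_cycles.append(cycle)
            report.missing[cycle] = {m: v for m, v in missing.items() if v}
            report.frames_rejected += n_frames
        else:
            accepted[cycle] = by_cycle[cycle]
            report.accepted_cycles.append(cycle)
            report.frames_accepted += n_frames
    return accepted, report


def write_manifest(records, path) -> None:
    """Write the frame manifest CSV (path, modality, cycle, index, timestamp_s)."""
    df = pd.DataFrame([{
        "path": r.path, "modality": r.modality, "cycle": r.cycle,
        "index": r.index, "timestamp_s": r.timestamp_s,
    } for r in records])
    df.to_csv(path, index=False)


def read_manifest(path) -> list:
    """Read a frame manifest CSV back into FrameRecords, sorted by timestamp."""
    df = pd.read_csv(path)
    recs = [FrameRecord(modality=str(r.modality), cycle=int(r.cycle),
                        index=int(r.index), timestamp_s=float(r.timestamp_s),
                        path=str(r.path))
            for r in df.itertuples()]
    return sorted(recs, key=lambda r: (r.timestamp_s, r.modality))
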