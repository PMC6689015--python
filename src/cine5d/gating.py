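"""ECG synchronization: sort readout lines into heartbeats, reconstruct
low-resolution per-beat volumes for respiratory motion tracking, and derive
the 1D self-gating surrogate used as the comparison baseline.

Per-beat volumes deliberately pool *all* lines of a beat regardless of
cardiac phase: most of the cardiac cycle is diastole, so beat-to-beat
differences between these volumes are dominated by respiration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantom import KSpaceBundle
from .sampling import view_share_fill

__all__ = [
    "BeatIndex",
    "sort_beats",
    "lowres_beat_volume",
    "all_beat_volumes",
    "self_gating_1d",
    "cardiac_phase_assign",
]

log = logging.getLogger(__name__)

# triggers implying beats outside this range are treated as artifacts
MIN_BEAT_MS = 300.0
MAX_BEAT_MS = 2000.0


@dataclass
class BeatIndex:
    beat_id: int
    line_ids: np.ndarray
    trigger_time_ms: float
    next_trigger_ms: float

    @property
    def instantaneous_hr_bpm(self) -> float:
        return 60000.0 / (self.next_trigger_ms - self.trigger_time_ms)

    @property
    def center_ms(self) -> float:
        return 0.5 * (self.trigger_time_ms + self.next_trigger_ms)


def sort_beats(bundle: KSpaceBundle) -> list[BeatIndex]:
    """Partition lines into heartbeats bounded by consecutive ECG triggers.

    Lines before the first or after the last trigger are discarded (count
    logged); beats with implausible duration are rejected as trigger
    artifacts.
    """
    trig = np.asarray(bundle.ecg_triggers_ms, dtype=float)
    if len(trig) < 2:
        raise ValueError("need at least 2 ECG triggers to define a beat")
    if np.any(np.diff(trig) <= 0):
        raise ValueError("ECG triggers must be strictly increasing")
    t = bundle.t_ms
    beats: list[BeatIndex] = []
    n_assigned = 0
    for i in range(len(trig) - 1):
        dur = trig[i + 1] - trig[i]
        sel = np.where((t >= trig[i]) & (t < trig[i + 1]))[0]
        if not (MIN_BEAT_MS <= dur <= MAX_BEAT_MS):
            log.warning("beat %d duration %.0f ms outside [%.0f, %.0f]; rejected",
                        i, dur, MIN_BEAT_MS, MAX_BEAT_MS)
            continue
        beats.append(BeatIndex(
            beat_id=len(beats), line_ids=sel,
            trigger_time_ms=float(trig[i]), next_trigger_ms=float(trig[i + 1]),
        ))
        n_assigned += len(sel)
    n_discarded = bundle.n_lines - n_assigned
    if n_discarded:
        log.info("%d of %d lines outside usable beats", n_discarded, bundle.n_lines)
    return beats


def lowres_band(bundle: KSpaceBundle, target_resolution_mm: float = 4.0
                ) -> tuple[int, int, int]:
    """Central-band sample counts per axis matching the target resolution.

    band = FOV / resolution, rounded to the nearest even number and capped
    at the grid size.
    """
    band = []
    for fov, n in zip(bundle.fov_mm, bundle.matrix_size):
        b = int(round(fov / target_resolution_mm / 2.0)) * 2
        band.append(int(np.clip(b, 2, n)))
    if min(band) < 2:
        raise ValueError("empty central band at requested resolution")
    return tuple(band)


def _position_index(bundle: KSpaceBundle):
    """Per (ky, kz) position: sorted acquisition times and line indices."""
    index: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    order = np.lexsort((bundle.t_ms, bundle.kz_idx, bundle.ky_idx))
    ky, kz, t = bundle.ky_idx[order], bundle.kz_idx[order], bundle.t_ms[order]
    starts = np.where(np.diff(ky) | np.diff(kz))[0] + 1
    bounds = np.concatenate([[0], starts, [len(order)]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        index[(int(ky[a]), int(kz[a]))] = (t[a:b], order[a:b])
    return index


def lowres_beat_volume(
    beat: BeatIndex,
    bundle: KSpaceBundle,
    target_resolution_mm: float = 4.0,
    position_index=None,
    view_share: bool = True,
) -> np.ndarray:
    """Root-sum-of-squares magnitude volume of one heartbeat at ~4 mm.

    Only the central k-space band is retained; positions the beat missed are
    view-shared from the temporally nearest acquisition elsewhere in the
    scan; never-acquired positions stay zero.
    """
    if len(beat.line_ids) == 0:
        raise ValueError(f"beat {beat.beat_id} holds no lines")
    nx, ny, nz = bundle.matrix_size
    bx, by, bz = lowres_band(bundle, target_resolution_mm)
    if position_index is None:
        position_index = _position_index(bundle)

    beat_lines = {}
    for i in beat.line_ids:
        beat_lines[(int(bundle.ky_idx[i]), int(bundle.kz_idx[i]))] = int(i)
    if view_share:
        filled, _, _ = view_share_fill(beat_lines, position_index, beat.center_ms)
    else:
        filled = beat_lines

    ylo, yhi = ny // 2 - by // 2, ny // 2 + by // 2
    zlo, zhi = nz // 2 - bz // 2, nz // 2 + bz // 2
    k = np.zeros((bundle.n_coils, nx, by, bz), dtype=complex)
    for (ky, kz), line in filled.items():
        if ylo <= ky < yhi and zlo <= kz < zhi:
            k[:, :, ky - ylo, kz - zlo] = bundle.data[line]

    xlo, xhi = nx // 2 - bx // 2, nx // 2 + bx // 2
    k = k[:, xlo:xhi]
    imgs = np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(k, axes=(1, 2, 3)),
                     axes=(1, 2, 3), norm="ortho"),
        axes=(1, 2, 3),
    )
    return np.sqrt((np.abs(imgs) ** 2).sum(axis=0))


def all_beat_volumes(bundle: KSpaceBundle, beats: list[BeatIndex],
                     target_resolution_mm: float = 4.0,
                     view_share: bool = True) -> np.ndarray:
    """Stack of per-beat low-res volumes, shape (n_beats, bx, by, bz)."""
    idx = _position_index(bundle)
    return np.stack([
        lowres_beat_volume(b, bundle, target_resolution_mm, idx, view_share)
        for b in beats
    ])


def lowres_spacing(bundle: KSpaceBundle, target_resolution_mm: float = 4.0
                   ) -> tuple[float, float, float]:
    band = lowres_band(bundle, target_resolution_mm)
    return tuple(f / b for f, b in zip(bundle.fov_mm, band))


def self_gating_1d(bundle: KSpaceBundle, beats: list[BeatIndex] | None = None,
                   smooth: int = 1) -> np.ndarray:
    """1D respiratory surrogate from the repeated k-space centre line.

    Per beat, the DC phase-encode readouts are inverse-FFT'd into
    superior-inferior projection profiles (root-sum-of-squares over coils
    and averaged over repeats), and the sub-voxel 1D shift that best aligns
    each profile to the first beat's profile is the trace (in mm, same sign
    convention as the x displacement).  Beats without a DC line inherit a
    linear interpolation of their neighbours.
    """
    if beats is None:
        beats = sort_beats(bundle)
    nx = bundle.matrix_size[0]
    dcy, dcz = bundle.matrix_size[1] // 2, bundle.matrix_size[2] // 2
    dx = bundle.spacing_mm[0]

    profiles = np.full((len(beats), nx), np.nan)
    for b in beats:
        sel = [i for i in b.line_ids
               if bundle.ky_idx[i] == dcy and bundle.kz_idx[i] == dcz]
        if not sel:
            continue
        prof = np.zeros(nx)
        for i in sel:
            img = np.fft.fftshift(
                np.fft.ifft(np.fft.ifftshift(bundle.data[i], axes=-1),
                            axis=-1, norm="ortho"), axes=-1)
            prof += np.sqrt((np.abs(img) ** 2).sum(axis=0))
        profiles[b.beat_id] = prof / len(sel)

    have = ~np.isnan(profiles[:, 0])
    if not have.any():
        raise ValueError("no beat contains the DC phase-encode line")
    ref = profiles[np.argmax(have)]

    trace = np.full(len(beats), np.nan)
    for i in range(len(beats)):
        if not have[i]:
            continue
        trace[i] = _subpixel_shift_1d(profiles[i], ref) * dx
    missing = np.isnan(trace)
    if missing.any():
        log.warning("%d beats missing the DC line; trace interpolated",
                    int(missing.sum()))
        ids = np.arange(len(beats))
        trace[missing] = np.interp(ids[missing], ids[~missing], trace[~missing])
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        trace = np.convolve(trace, kernel, mode="same")
    return trace


def _subpixel_shift_1d(profile: np.ndarray, reference: np.ndarray) -> float:
    """Shift (in samples) of ``profile`` relative to ``reference`` by
    cross-correlation with parabolic sub-sample refinement.  Positive shift
    means the structure moved towards larger x index."""
    n = len(profile)
    p = profile - profile.mean()
    r = reference - reference.mean()
    xc = np.real(np.fft.ifft(np.fft.fft(p) * np.conj(np.fft.fft(r))))
    xc = np.fft.fftshift(xc)
    lags = np.arange(n) - n // 2
    j = int(np.argmax(xc))
    if 0 < j < n - 1:
        denom = xc[j - 1] - 2 * xc[j] + xc[j + 1]
        frac = 0.5 * (xc[j - 1] - xc[j + 1]) / denom if denom != 0 else 0.0
    else:
        frac = 0.0
    return float(lags[j] + frac)


def cardiac_phase_assign(t_ms: np.ndarray, triggers_ms: np.ndarray,
                         tr_ms: float, views_per_segment: int = 10
                         ) -> np.ndarray:
    """Cardiac-phase index of each line: consecutive ``views_per_segment``
    TRs after the beat's trigger share a phase.  Lines outside [first, last)
    trigger get phase -1.  Temporal resolution = views_per_segment x TR."""
    if views_per_segment < 1:
        raise ValueError("views_per_segment must be >= 1")
    t = np.asarray(t_ms, dtype=float)
    trig = np.asarray(triggers_ms, dtype=float)
    i = np.searchsorted(trig, t, side="right") - 1
    inside = (i >= 0) & (i < len(trig) - 1)
    phase = np.full(len(t), -1, dtype=int)
    seg = views_per_segment * tr_ms
    phase[inside] = ((t[inside] - trig[i[inside]]) / seg).astype(int)
    return phase


def temporal_resolution_ms(tr_ms: float, views_per_segment: int = 10) -> float:
    return views_per_segment * tr_ms
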