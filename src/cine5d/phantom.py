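"""Digital cardiorespiratory phantom and MR acquisition simulator.

The phantom is a torso with a beating two-ventricle heart.  The left
ventricle (LV) is an ellipsoidal shell (bright cavity, darker myocardium)
whose semi-axes interpolate cyclically between end-diastole (ED) and
end-systole (ES); the right ventricle (RV) is the crescent left over between
a larger ellipsoid and the LV epicardium.  The whole heart is rigidly
displaced by a quasi-periodic respiratory waveform, predominantly along the
vertical axis of the short-axis plane (array axis 0, called ``x``; positive
``x`` = heart moves up, i.e. towards end-expiration).  A chest-wall slab
moves with the same waveform, optionally phase-lagged with respect to the
heart (thoracoabdominal asynchrony); the bellows surrogate records the
chest-wall displacement, not the heart's.

Respiratory sinus arrhythmia is built in: the instantaneous heart rate is
minimal at end-expiration and maximal at end-inspiration, modulated within
``heart_rate_base ± rsa_amplitude``.

The simulator produces multi-coil Cartesian k-space readout lines (one kx
column per (ky, kz) phase encode) by evaluating the 3D orthonormal DFT of
the coil-weighted instantaneous volume at each line's timestamp.  k-space
indexing convention: DC sits at grid index ``floor(N/2)`` on every axis,
indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "KSpaceBundle",
    "Phantom",
    "make_phantom",
    "simulate_acquisition",
]


# tissue intensities (arbitrary proton-density-like units, peak = 1)
_I_BODY = 0.20
_I_CHEST_WALL = 0.55
_I_MYOCARDIUM = 0.35
_I_LV_BLOOD = 1.00
_I_RV_BLOOD = 0.90


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, physiology and acquisition parameters of the phantom.

    Lengths are mm, rates are per minute, times are ms unless noted.
    """

    matrix_size: tuple[int, int, int] = (64, 64, 24)
    fov_mm: tuple[float, float, float] = (256.0, 256.0, 96.0)
    n_coils: int = 8
    heart_rate_base: float = 60.0
    rsa_amplitude: float = 4.0          # HR swing (bpm) over the breathing cycle
    resp_rate: float = 14.0             # breaths per minute
    resp_depth_mm: float = 10.0         # peak-to-peak SI heart excursion
    resp_inplane_fraction: float = 0.3  # x-y components relative to SI
    asynchrony_phase_rad: float = 0.0   # chest wall lag behind the heart
    drift_mm_per_min: float = 0.0
    # waveform shape: insp level = |sin(theta/2)|**(2*exponent); exponents
    # above 1 dwell longer near end-expiration (asymmetric breathing)
    resp_waveform_exponent: float = 1.4
    resp_period_jitter: float = 0.04    # per-cycle fractional period scatter
    resp_amp_jitter: float = 0.08       # per-cycle fractional depth scatter
    # LV cavity semi-axes at ED / ES, and wall thickness at ED / ES
    lv_radii_ed: tuple[float, float, float] = (25.0, 25.0, 35.0)
    lv_radii_es: tuple[float, float, float] = (19.0, 19.0, 28.0)
    lv_wall_ed_mm: float = 8.0
    lv_wall_es_mm: float = 12.0
    lv_center_mm: tuple[float, float, float] = (0.0, -14.0, 0.0)
    # RV crescent: outer ellipsoid minus the (gap-padded) LV epicardium
    rv_radii_ed: tuple[float, float, float] = (38.0, 30.0, 30.0)
    rv_radii_es: tuple[float, float, float] = (31.0, 24.5, 24.5)
    rv_center_mm: tuple[float, float, float] = (0.0, 22.0, 0.0)
    rv_gap_mm: float = 4.0
    # torso & chest wall
    body_radii_mm: tuple[float, float] = (110.0, 120.0)
    chest_wall_x_mm: float = 84.0
    chest_wall_thickness_mm: float = 14.0
    chest_wall_depth_mm: float | None = None  # default: resp_depth_mm
    noise_sigma: float = 0.0            # complex noise std relative to peak signal
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.matrix_size):
            raise ValueError(f"matrix_size must be positive, got {self.matrix_size}")
        if any(f <= 0 for f in self.fov_mm):
            raise ValueError(f"fov_mm must be positive, got {self.fov_mm}")
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")
        if self.resp_depth_mm < 0:
            raise ValueError("resp_depth_mm must be >= 0")
        if not (0 <= self.rsa_amplitude < self.heart_rate_base):
            raise ValueError("need 0 <= rsa_amplitude < heart_rate_base")
        if _ellipsoid_volume(self.lv_radii_es) >= _ellipsoid_volume(self.lv_radii_ed):
            raise ValueError("ES cavity volume must be smaller than ED (contraction)")
        if _ellipsoid_volume(self.rv_radii_es) >= _ellipsoid_volume(self.rv_radii_ed):
            raise ValueError("RV ES geometry must be smaller than ED (contraction)")

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return tuple(f / n for f, n in zip(self.fov_mm, self.matrix_size))


def _ellipsoid_volume(semi_axes: Sequence[float]) -> float:
    """Closed-form ellipsoid volume in mL from semi-axes in mm."""
    a, b, c = semi_axes
    return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


@dataclass
class GroundTruth:
    """Everything downstream stages can be checked against."""

    beat_times_ms: np.ndarray
    true_displacement_mm: Callable[[np.ndarray], np.ndarray]  # t (ms) -> (..., 3)
    chest_displacement_mm: Callable[[np.ndarray], np.ndarray]
    true_volumes_ml: dict[str, np.ndarray]      # per cardiac phase, reference position
    cardiac_phase_grid: np.ndarray              # phase fractions of true_volumes rows
    coil_maps: np.ndarray                       # (n_coils, Nx, Ny, Nz) complex

    def instantaneous_hr_bpm(self) -> np.ndarray:
        """HR of each beat from consecutive trigger intervals (len = n_beats - 1)."""
        return 60000.0 / np.diff(self.beat_times_ms)

    def volumes_ed_es_ml(self, ventricle: str) -> tuple[float, float]:
        v = self.true_volumes_ml[ventricle]
        return float(v.max()), float(v.min())

    def ef_pct(self, ventricle: str) -> float:
        edv, esv = self.volumes_ed_es_ml(ventricle)
        return (edv - esv) / edv * 100.0


@dataclass
class KSpaceBundle:
    """Continuously acquired multi-coil readout lines plus physiology logs.

    ``data[i, c, :]`` is the kx column (readout) of coil ``c`` for the i-th
    line at phase encode ``(ky_idx[i], kz_idx[i])``, acquired at ``t_ms[i]``.
    """

    ky_idx: np.ndarray
    kz_idx: np.ndarray
    t_ms: np.ndarray
    data: np.ndarray                 # (n_lines, n_coils, Nx) complex
    ecg_triggers_ms: np.ndarray
    bellows_t_ms: np.ndarray
    bellows: np.ndarray
    matrix_size: tuple[int, int, int]
    fov_mm: tuple[float, float, float]
    tr_ms: float
    partial_fourier: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("line timestamps must be strictly increasing")

    @property
    def n_lines(self) -> int:
        return len(self.t_ms)

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return tuple(f / n for f, n in zip(self.fov_mm, self.matrix_size))


class _RespWaveform:
    """Quasi-periodic inspiration level in [0, 1]; 0 = end-expiration.

    Cycles have independently jittered period and amplitude, so repeated
    visits to the same respiratory phase scatter realistically.  Phase 0
    (t = 0) is end-expiration, making the first heartbeat the natural
    motion reference.
    """

    def __init__(self, cfg: PhantomConfig, rng: np.random.Generator,
                 max_duration_ms: float) -> None:
        period = 60000.0 / cfg.resp_rate
        n_cycles = int(np.ceil(max_duration_ms / period)) + 2
        pj = rng.normal(0.0, cfg.resp_period_jitter, n_cycles).clip(-0.3, 0.3)
        aj = rng.normal(0.0, cfg.resp_amp_jitter, n_cycles).clip(-0.4, 0.4)
        self.periods = period * (1.0 + pj)
        self.amps = 1.0 + aj
        self.starts = np.concatenate([[0.0], np.cumsum(self.periods)])
        self.exponent = float(cfg.resp_waveform_exponent)

    def _cycle_phase(self, t_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        idx = np.clip(np.searchsorted(self.starts, t, side="right") - 1,
                      0, len(self.periods) - 1)
        theta = 2.0 * np.pi * (t - self.starts[idx]) / self.periods[idx]
        return idx, theta

    def level(self, t_ms: np.ndarray, phase_lag_rad: float = 0.0) -> np.ndarray:
        idx, theta = self._cycle_phase(t_ms)
        s = np.abs(np.sin((theta - phase_lag_rad) / 2.0))
        return self.amps[idx] * s ** (2.0 * self.exponent)


class Phantom:
    """Dynamic phantom: ``render(t)`` gives the 3D intensity volume at time t."""

    def __init__(self, config: PhantomConfig, truth: GroundTruth,
                 waveform: _RespWaveform) -> None:
        self.config = config
        self.truth = truth
        self._waveform = waveform
        cfg = config
        # mm coordinates of voxel centres; origin at index floor(N/2)
        self._coords = [
            (np.arange(n) - n // 2) * s
            for n, s in zip(cfg.matrix_size, cfg.spacing_mm)
        ]

    # -- geometry ---------------------------------------------------------

    def _ellipsoid_mask(self, center, semi) -> np.ndarray:
        x, y, z = self._coords
        q = (
            ((x[:, None, None] - center[0]) / semi[0]) ** 2
            + ((y[None, :, None] - center[1]) / semi[1]) ** 2
            + ((z[None, None, :] - center[2]) / semi[2]) ** 2
        )
        return q <= 1.0

    def cardiac_weight(self, frac: np.ndarray) -> np.ndarray:
        """Contraction weight: 0 at ED (phase 0), 1 at ES (mid-cycle)."""
        return np.sin(np.pi * np.asarray(frac)) ** 2

    def render_volume(self, cardiac_frac: float, heart_disp_mm: Sequence[float],
                      chest_disp_mm: float = 0.0) -> np.ndarray:
        """Piecewise-constant intensity volume for an explicit state."""
        cfg = self.config
        w = float(self.cardiac_weight(cardiac_frac))
        d = np.asarray(heart_disp_mm, dtype=float)
        x, y, z = self._coords

        vol = np.zeros(cfg.matrix_size, dtype=float)
        bx, by = cfg.body_radii_mm
        body = ((x[:, None, None] / bx) ** 2 + (y[None, :, None] / by) ** 2) <= 1.0
        vol[np.broadcast_to(body, cfg.matrix_size)] = _I_BODY

        cw_lo = cfg.chest_wall_x_mm + chest_disp_mm
        cw = (x[:, None, None] >= cw_lo) & (
            x[:, None, None] <= cw_lo + cfg.chest_wall_thickness_mm
        )
        cw = np.broadcast_to(cw & body, cfg.matrix_size)
        vol[cw] = _I_CHEST_WALL

        lv_cav = _interp(cfg.lv_radii_ed, cfg.lv_radii_es, w)
        wall = (1 - w) * cfg.lv_wall_ed_mm + w * cfg.lv_wall_es_mm
        lv_out = lv_cav + wall
        rv_semi = _interp(cfg.rv_radii_ed, cfg.rv_radii_es, w)
        lv_c = np.asarray(cfg.lv_center_mm) + d
        rv_c = np.asarray(cfg.rv_center_mm) + d

        lv_epi = self._ellipsoid_mask(lv_c, lv_out)
        rv_cav = self._ellipsoid_mask(rv_c, rv_semi) & ~self._ellipsoid_mask(
            lv_c, lv_out + cfg.rv_gap_mm
        )
        vol[rv_cav] = _I_RV_BLOOD
        vol[lv_epi] = _I_MYOCARDIUM
        vol[self._ellipsoid_mask(lv_c, lv_cav)] = _I_LV_BLOOD
        return vol

    # -- time-resolved state ----------------------------------------------

    def cardiac_fraction(self, t_ms: np.ndarray) -> np.ndarray:
        bt = self.truth.beat_times_ms
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        i = np.clip(np.searchsorted(bt, t, side="right") - 1, 0, len(bt) - 2)
        return (t - bt[i]) / (bt[i + 1] - bt[i])

    def render(self, t_ms: float) -> np.ndarray:
        """Instantaneous volume: cardiac interpolation + rigid respiratory shift."""
        c = float(self.cardiac_fraction(t_ms)[0])
        d = self.truth.true_displacement_mm(np.asarray([t_ms]))[0]
        cw = float(self.truth.chest_displacement_mm(np.asarray([t_ms]))[0])
        return self.render_volume(c, d, cw)


def _interp(ed, es, w: float) -> np.ndarray:
    return (1 - w) * np.asarray(ed) + w * np.asarray(es)


def _make_coil_maps(cfg: PhantomConfig) -> np.ndarray:
    """Smooth Gaussian-magnitude maps with distinct linear phases per coil,
    normalised to unit root-sum-of-squares per voxel."""
    nx, ny, nz = cfg.matrix_size
    x = (np.arange(nx) - nx // 2) * cfg.spacing_mm[0]
    y = (np.arange(ny) - ny // 2) * cfg.spacing_mm[1]
    z = (np.arange(nz) - nz // 2) * cfg.spacing_mm[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    maps = np.empty((cfg.n_coils, nx, ny, nz), dtype=complex)
    r_ring = 0.55 * max(cfg.fov_mm[0], cfg.fov_mm[1])
    sigma = 0.65 * max(cfg.fov_mm)
    for c in range(cfg.n_coils):
        ang = 2.0 * np.pi * c / cfg.n_coils
        cx, cy = r_ring * np.cos(ang), r_ring * np.sin(ang)
        mag = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2 + Z**2) / (2 * sigma**2))
        ph = 2.0 * np.pi * (
            0.08 * np.cos(ang) * X / cfg.fov_mm[0]
            + 0.08 * np.sin(ang) * Y / cfg.fov_mm[1]
        ) + ang
        maps[c] = mag * np.exp(1j * ph)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    return maps / rss[None]


def _rv_volume_numeric(cfg: PhantomConfig, w: float, step_mm: float = 1.0) -> float:
    """RV crescent volume (mL) by voxel counting on a fine grid."""
    rv_semi = _interp(cfg.rv_radii_ed, cfg.rv_radii_es, w)
    lv_cav = _interp(cfg.lv_radii_ed, cfg.lv_radii_es, w)
    wall = (1 - w) * cfg.lv_wall_ed_mm + w * cfg.lv_wall_es_mm
    lv_excl = lv_cav + wall + cfg.rv_gap_mm
    rc = np.asarray(cfg.rv_center_mm)
    lc = np.asarray(cfg.lv_center_mm)
    axes = [
        np.arange(rc[i] - rv_semi[i], rc[i] + rv_semi[i] + step_mm, step_mm)
        for i in range(3)
    ]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    inside_rv = (
        ((X - rc[0]) / rv_semi[0]) ** 2
        + ((Y - rc[1]) / rv_semi[1]) ** 2
        + ((Z - rc[2]) / rv_semi[2]) ** 2
    ) <= 1.0
    inside_lv = (
        ((X - lc[0]) / lv_excl[0]) ** 2
        + ((Y - lc[1]) / lv_excl[1]) ** 2
        + ((Z - lc[2]) / lv_excl[2]) ** 2
    ) <= 1.0
    return float((inside_rv & ~inside_lv).sum()) * step_mm**3 / 1000.0


def make_phantom(config: PhantomConfig, duration_s: float = 300.0,
                 n_cardiac_phases: int = 25) -> Phantom:
    """Build the phantom: respiratory waveform, beat times (with RSA),
    analytic ground-truth volumes and coil maps.

    ``true_displacement_mm(0) == (0,0,0)``: the scan starts at
    end-expiration, which is the reference respiratory position.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    duration_ms = duration_s * 1000.0
    wave = _RespWaveform(cfg, rng, duration_ms)

    # beat times: next interval from the instantaneous (RSA-modulated) HR
    beats = [0.0]
    while beats[-1] < duration_ms:
        lvl = float(wave.level(np.asarray([beats[-1]]))[0])
        hr = cfg.heart_rate_base + cfg.rsa_amplitude * (2.0 * min(lvl, 1.0) - 1.0)
        beats.append(beats[-1] + 60000.0 / hr)
    beat_times = np.asarray(beats)

    f = cfg.resp_inplane_fraction
    depth = cfg.resp_depth_mm

    def displacement(t_ms: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        m = -depth * wave.level(t) + cfg.drift_mm_per_min * t / 60000.0
        return np.stack([m, f * m, 0.6 * f * m], axis=-1)

    cw_depth = cfg.chest_wall_depth_mm if cfg.chest_wall_depth_mm is not None \
        else cfg.resp_depth_mm

    def chest_displacement(t_ms: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        return -cw_depth * wave.level(t, phase_lag_rad=cfg.asynchrony_phase_rad)

    phase_grid = np.arange(n_cardiac_phases) / n_cardiac_phases
    w_grid = np.sin(np.pi * phase_grid) ** 2
    lv_vol = np.asarray([
        _ellipsoid_volume(_interp(cfg.lv_radii_ed, cfg.lv_radii_es, w))
        for w in w_grid
    ])
    rv_vol = np.asarray([_rv_volume_numeric(cfg, w) for w in w_grid])

    truth = GroundTruth(
        beat_times_ms=beat_times,
        true_displacement_mm=displacement,
        chest_displacement_mm=chest_displacement,
        true_volumes_ml={"LV": lv_vol, "RV": rv_vol},
        cardiac_phase_grid=phase_grid,
        coil_maps=_make_coil_maps(cfg),
    )
    return Phantom(cfg, truth, wave)


def kspace_3d(volume: np.ndarray, coil_map: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal 3D DFT of (coil map x volume) with DC at index floor(N/2)."""
    img = volume if coil_map is None else coil_map * volume
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(img), norm="ortho"))


def kx_partial_fourier_mask(nx: int, pf: float) -> np.ndarray:
    """Boolean readout mask keeping the trailing ``pf`` fraction of kx
    (asymmetric-echo truncation; the dropped samples are zero-filled)."""
    keep = int(round(pf * nx))
    mask = np.zeros(nx, dtype=bool)
    mask[nx - keep:] = True
    return mask


def simulate_acquisition(
    phantom: Phantom,
    schedule,
    duration_s: float,
    tr_ms: float = 4.0,
    noise_sigma: float | None = None,
    resp_quant_mm: float = 0.5,
    n_cardiac_bins: int = 25,
    freeze_cardiac_at: float | None = None,
) -> KSpaceBundle:
    """Continuous free-running acquisition over ``duration_s`` seconds.

    Lines follow the schedule order (repeating it if the scan outlasts one
    full cycle), one line per TR.  Each line is the kx column of the 3D DFT
    of the coil-weighted instantaneous volume, plus complex Gaussian noise.

    The phantom state is quantised — cardiac phase to ``n_cardiac_bins`` per
    beat and displacement to ``resp_quant_mm`` — so that lines sharing a
    state reuse one set of coil FFTs.  Set ``resp_quant_mm=0`` for exact
    (slow) per-line rendering.
    """
    cfg = phantom.config
    nx, ny, nz = cfg.matrix_size
    tr = float(tr_ms)
    n_lines = int(duration_s * 1000.0 / tr)
    if n_lines < 1:
        raise ValueError("duration too short for a single readout line")
    bt = phantom.truth.beat_times_ms
    if duration_s * 1000.0 > bt[-1]:
        raise ValueError("phantom beat schedule shorter than requested duration; "
                         "rebuild make_phantom with a larger duration_s")
    if duration_s * 1000.0 < 10 * 60000.0 / (cfg.heart_rate_base + cfg.rsa_amplitude):
        raise ValueError("duration must cover at least 10 heartbeats")

    entries = schedule.entries
    if len(entries) == 0:
        raise ValueError("empty sampling schedule")
    ky = np.asarray([e[0] for e in entries])
    kz = np.asarray([e[1] for e in entries])
    if ky.min() < 0 or ky.max() >= ny or kz.min() < 0 or kz.max() >= nz:
        bad = int(np.argmax((ky < 0) | (ky >= ny) | (kz < 0) | (kz >= nz)))
        raise ValueError(
            f"schedule line {bad} with (ky={ky[bad]}, kz={kz[bad]}) outside "
            f"grid ({ny}, {nz})"
        )
    reps = int(np.ceil(n_lines / len(entries)))
    ky = np.tile(ky, reps)[:n_lines]
    kz = np.tile(kz, reps)[:n_lines]
    t_ms = np.arange(n_lines) * tr

    if freeze_cardiac_at is None:
        cfrac = phantom.cardiac_fraction(t_ms)
        card_bin = np.minimum((cfrac * n_cardiac_bins).astype(int),
                              n_cardiac_bins - 1)
    else:
        # fully static heart (testing/calibration use)
        card_bin = np.full(n_lines, min(int(freeze_cardiac_at * n_cardiac_bins),
                                        n_cardiac_bins - 1))
    disp = phantom.truth.true_displacement_mm(t_ms)
    chest = phantom.truth.chest_displacement_mm(t_ms)
    q = resp_quant_mm
    if q > 0:
        disp_q = np.round(disp / q) * q
        chest_q = np.round(chest / q) * q
    else:
        disp_q, chest_q = disp, chest

    pf = getattr(schedule, "partial_fourier", 1.0)
    kx_mask = kx_partial_fourier_mask(nx, pf)

    data = np.empty((n_lines, cfg.n_coils, nx), dtype=np.complex64)
    keys = np.concatenate(
        [card_bin[:, None], disp_q, chest_q[:, None]], axis=1
    )
    _, group_ids = np.unique(keys, axis=0, return_inverse=True)
    maps = phantom.truth.coil_maps
    for g in np.unique(group_ids):
        sel = np.where(group_ids == g)[0]
        i0 = sel[0]
        vol = phantom.render_volume(
            (card_bin[i0] + 0.5) / n_cardiac_bins, disp_q[i0], float(chest_q[i0])
        )
        for c in range(cfg.n_coils):
            k3 = kspace_3d(vol, maps[c])
            data[sel, c, :] = k3[:, ky[sel], kz[sel]].T

    data[:, :, ~kx_mask] = 0.0
    sigma = cfg.noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        nrng = np.random.default_rng(cfg.seed + 1)
        noise = nrng.normal(0.0, sigma / np.sqrt(2.0), (n_lines, cfg.n_coils, nx, 2))
        data += (noise[..., 0] + 1j * noise[..., 1]).astype(np.complex64) \
            * kx_mask[None, None, :]

    triggers = bt[bt <= duration_s * 1000.0]
    bell_t = np.arange(0.0, duration_s * 1000.0, 25.0)
    bell = phantom.truth.chest_displacement_mm(bell_t)
    return KSpaceBundle(
        ky_idx=ky, kz_idx=kz, t_ms=t_ms, data=data,
        ecg_triggers_ms=triggers, bellows_t_ms=bell_t, bellows=bell,
        matrix_size=cfg.matrix_size, fov_mm=cfg.fov_mm, tr_ms=tr,
        partial_fourier=pf,
    )
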