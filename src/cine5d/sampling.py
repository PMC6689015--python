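"""CIRCUS-style Cartesian phase-encode scheduling and view sharing.

The (ky, kz) plane is partitioned into concentric square rings centred on
DC (index ``floor(N/2)``).  One *interleave* picks exactly one point from
every ring that intersects the partial-Fourier region, so the ring-0
neighbourhood of DC is revisited every interleave while outer rings are
sparsely covered: any contiguous run of interleaves is a variable-density,
pseudo-random Cartesian subset.  The position picked from ring ``r`` on
interleave ``t`` walks the ring perimeter by a golden-ratio increment with
a spiral twist proportional to ``c``:

    u(r, t) = frac(t * phi + c * r / R_max) * P_r

with ``phi`` the golden-ratio conjugate (~0.618) and ``P_r`` the ring's
perimeter length.  ``c = 0`` degenerates to radial-like spokes; the
published protocol uses ``c = 1.5``.  A selection falling outside the
partial-Fourier region, or colliding with a point already used by an
earlier interleave, advances deterministically to the next free in-region
perimeter position, so the union of interleaves covers every in-region
point at most once before the schedule repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingSchedule",
    "ring_partition",
    "circus_schedule",
    "view_share_fill",
    "undersampling_factor",
    "sampling_mask",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class SamplingSchedule:
    """Ordered CIRCUS phase-encode sequence (interleave-major)."""

    entries: list[tuple[int, int, int, int]]  # (ky, kz, interleave_id, ring_id)
    grid: tuple[int, int]
    circus_c: float = 1.5
    partial_fourier: float = 0.75

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_interleaves(self) -> int:
        return max(e[2] for e in self.entries) + 1

    def interleave(self, t: int) -> list[tuple[int, int, int, int]]:
        return [e for e in self.entries if e[2] == t]


def _ring_index_1d(offsets: np.ndarray) -> np.ndarray:
    # ring 0 is the 2x2 (even N) / 1x1-adjacent block around DC
    return np.maximum(offsets, -1 - offsets)


def ring_partition(grid: tuple[int, int]) -> np.ndarray:
    """Map each (ky, kz) point to its square-ring id (DC block = ring 0).

    Returns an (Ny, Nz) integer array.  Every point belongs to exactly one
    ring; for anisotropic grids the outer "rings" are the partial segments
    that remain inside the grid.
    """
    ny, nz = grid
    if ny < 2 or nz < 2:
        raise ValueError("grid must be at least 2x2")
    dy = _ring_index_1d(np.arange(ny) - ny // 2)
    dz = _ring_index_1d(np.arange(nz) - nz // 2)
    return np.maximum(dy[:, None], dz[None, :])


def partial_fourier_keep(n: int, pf: float) -> tuple[int, int]:
    """Index range [lo, hi) kept on an axis at partial-Fourier fraction pf.

    Asymmetric truncation: the most-negative frequencies are dropped, the
    DC index floor(n/2) is always retained.
    """
    keep = int(round(pf * n))
    return n - keep, n


def _ring_perimeter_points(ring_map: np.ndarray, ring_id: int) -> np.ndarray:
    """Points of one ring ordered by angle around DC -> (P, 2) index array."""
    ny, nz = ring_map.shape
    pts = np.argwhere(ring_map == ring_id)
    # order along the perimeter; +0.5 centres the even-N DC block
    ang = np.arctan2(pts[:, 1] - (nz // 2 - 0.5), pts[:, 0] - (ny // 2 - 0.5))
    return pts[np.argsort(ang)]


def circus_schedule(
    grid: tuple[int, int],
    circus_c: float = 1.5,
    partial_fourier: float = 0.75,
    n_interleaves: int = 32,
    seed: int = 0,
) -> SamplingSchedule:
    """Generate the interleaved pseudo-random variable-density schedule.

    ``seed`` rotates the golden-ratio phase origin (byte-identical schedules
    for identical arguments).  Interleaves are emitted in time order, rings
    centre-out within each interleave, so any contiguous window of the
    schedule is a valid interleaved subset.
    """
    if not (0.5 <= partial_fourier <= 1.0):
        raise ValueError("partial_fourier must be in [0.5, 1]")
    ny, nz = grid
    ring_map = ring_partition(grid)
    ylo, yhi = partial_fourier_keep(ny, partial_fourier)
    zlo, zhi = partial_fourier_keep(nz, partial_fourier)

    rings = []
    for r in range(int(ring_map.max()) + 1):
        pts = _ring_perimeter_points(ring_map, r)
        in_region = (
            (pts[:, 0] >= ylo) & (pts[:, 0] < yhi)
            & (pts[:, 1] >= zlo) & (pts[:, 1] < zhi)
        )
        if in_region.any():
            rings.append((r, pts, in_region))
    r_max = max(r for r, _, _ in rings)

    max_ring_points = max(int(m.sum()) for _, _, m in rings)
    if n_interleaves > max_ring_points:
        warnings.warn(
            f"n_interleaves={n_interleaves} exceeds the {max_ring_points} unique "
            "in-region points of the largest ring; truncating", stacklevel=2,
        )
        n_interleaves = max_ring_points

    phase0 = (seed * _GOLDEN) % 1.0
    used: dict[int, set[int]] = {r: set() for r, _, _ in rings}
    entries: list[tuple[int, int, int, int]] = []
    for t in range(n_interleaves):
        for r, pts, in_region in rings:
            perim = len(pts)
            u = ((t * _GOLDEN + phase0 + (circus_c * r / max(r_max, 1))) % 1.0)
            j = int(u * perim) % perim
            n_avail = int(in_region.sum())
            if len(used[r]) >= n_avail:
                used[r].clear()  # ring exhausted: schedule repeats coverage
            for step in range(perim):
                jj = (j + step) % perim
                if in_region[jj] and jj not in used[r]:
                    used[r].add(jj)
                    entries.append((int(pts[jj, 0]), int(pts[jj, 1]), t, r))
                    break
    return SamplingSchedule(
        entries=entries, grid=grid, circus_c=circus_c,
        partial_fourier=partial_fourier,
    )


def sampling_mask(schedule: SamplingSchedule,
                  interleaves: int | None = None) -> np.ndarray:
    """Binary (Ny, Nz) mask of the first ``interleaves`` interleaves."""
    mask = np.zeros(schedule.grid, dtype=bool)
    for ky, kz, t, _ in schedule.entries:
        if interleaves is None or t < interleaves:
            mask[ky, kz] = True
    return mask


def undersampling_factor(grid: tuple[int, int], lines_per_beat: int) -> float:
    """Acceleration R of a per-beat volume: full phase-encode count over
    the lines actually collected in that beat."""
    if lines_per_beat < 1:
        raise ValueError("lines_per_beat must be >= 1")
    ny, nz = grid
    return ny * nz / lines_per_beat


def view_share_fill(
    beat_lines: dict[tuple[int, int], int],
    all_lines: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]],
    beat_center_ms: float,
    lowfreq_band: tuple[tuple[int, int], tuple[int, int]] | None = None,
    policy: str = "nearest",
) -> tuple[dict[tuple[int, int], int], dict[tuple[int, int], int], int]:
    """Nearest-neighbour view sharing for one heartbeat.

    Parameters
    ----------
    beat_lines : mapping (ky, kz) -> line index acquired *within* the beat
        (the beat's own data always wins, so sharing happens mainly at the
        sparsely covered high frequencies).
    all_lines : mapping (ky, kz) -> (sorted timestamps, line indices) over
        the whole scan.
    beat_center_ms : temporal centre of the beat; "nearest" is measured
        against it.
    lowfreq_band : optional ((ky_lo, ky_hi), (kz_lo, kz_hi)) band used only
        for bookkeeping of how much sharing touched the low frequencies.

    Returns
    -------
    filled : mapping (ky, kz) -> line index for every position acquired
        anywhere in the scan; ``provenance`` maps shared positions to the
        donor line; ``n_unfilled`` counts positions never acquired at all
        (left to the caller to zero-fill).
    """
    if policy != "nearest":
        raise ValueError(f"unknown view-sharing policy {policy!r}")
    filled = dict(beat_lines)
    provenance: dict[tuple[int, int], int] = {}
    n_unfilled = 0
    for pos, (times, idx) in all_lines.items():
        if pos in filled:
            continue
        if len(times) == 0:
            n_unfilled += 1
            continue
        j = int(np.argmin(np.abs(times - beat_center_ms)))
        filled[pos] = int(idx[j])
        provenance[pos] = int(idx[j])
    return filled, provenance, n_unfilled


def psf_peak_sidelobe_ratio(mask: np.ndarray) -> float:
    """Point-spread-function peak over max sidelobe for a (Ny, Nz) mask;
    an incoherence proxy that grows as more interleaves accumulate."""
    psf = np.fft.ifftshift(np.fft.ifft2(np.fft.ifftshift(mask.astype(float))))
    mag = np.abs(psf)
    peak_pos = np.unravel_index(np.argmax(mag), mag.shape)
    peak = mag[peak_pos]
    mag[peak_pos] = 0.0
    return float(peak / mag.max())
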