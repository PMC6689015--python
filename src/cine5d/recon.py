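"""k-t SPARSE-SENSE reconstruction of respiratory-phase-resolved cardiac cine.

Each respiratory phase is reconstructed independently (no regularisation
across the respiratory dimension, which keeps respiratory states from
bleeding into each other).  The solver addresses

    argmin_x  1/2 || E x - y ||^2  +  lambda_t * TV_cardiac(x)

where E = (sampling mask) o (3D FFT) o (coil sensitivity multiply) and
TV_cardiac is the cyclic finite-difference total variation along the
cardiac-phase axis (the cine loops).  A monotone proximal-gradient (ISTA)
iteration is used: the encoding operator has unit norm for RSS-normalised
coil maps, so the gradient step size is 1; the TV proximal map is evaluated
per voxel time-series by Chambolle's dual projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft

from .phantom import KSpaceBundle, kx_partial_fourier_mask

__all__ = [
    "EncodingOperator",
    "estimate_coil_maps",
    "bin_kspace",
    "ktss_reconstruct",
    "tv_prox_cyclic",
    "ReconResult",
]

log = logging.getLogger(__name__)


def _fft3(img: np.ndarray, axes=(-3, -2, -1)) -> np.ndarray:
    # scipy.fft preserves single precision (numpy's upcasts to double)
    return np.fft.fftshift(
        spfft.fftn(np.fft.ifftshift(img, axes=axes), axes=axes, norm="ortho"),
        axes=axes)


def _ifft3(ksp: np.ndarray, axes=(-3, -2, -1)) -> np.ndarray:
    return np.fft.fftshift(
        spfft.ifftn(np.fft.ifftshift(ksp, axes=axes), axes=axes, norm="ortho"),
        axes=axes)


@dataclass
class EncodingOperator:
    """Multi-coil Cartesian SENSE encoding for a cardiac cine.

    ``maps``: (n_coils, Nx, Ny, Nz) unit-RSS coil sensitivities.
    ``mask``: (n_card, Nx, Ny, Nz) boolean sampling mask per cardiac phase.
    Image layout: (n_card, Nx, Ny, Nz) complex.  Applications loop over
    coils to bound the working set (single precision internally).
    """

    maps: np.ndarray
    mask: np.ndarray

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(n_card, ...) image -> (n_coils, n_card, ...) masked k-space."""
        x = np.ascontiguousarray(x, dtype=np.complex64)
        out = np.empty((len(self.maps),) + x.shape, dtype=np.complex64)
        for c, m in enumerate(self.maps.astype(np.complex64)):
            out[c] = self.mask * _fft3(m[None] * x)
        return out

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        acc = np.zeros(y.shape[1:], dtype=np.complex64)
        for c, m in enumerate(self.maps.astype(np.complex64)):
            acc += np.conj(m)[None] * _ifft3(
                self.mask * np.asarray(y[c], dtype=np.complex64))
        return acc


def estimate_coil_maps(bundle: KSpaceBundle, calib_resolution_mm: float = 8.0,
                       support_threshold: float = 0.05) -> np.ndarray:
    """Coil sensitivity maps from the time-averaged k-space centre.

    All acquisitions of each (ky, kz) position are averaged, the central
    calibration band is kept (Hamming-apodised), and the low-resolution
    coil images are normalised by their root sum of squares.  Voxels below
    ``support_threshold`` of the peak RSS are zeroed (no signal support).
    """
    nx, ny, nz = bundle.matrix_size
    acc = np.zeros((bundle.n_coils, nx, ny, nz), dtype=complex)
    cnt = np.zeros((ny, nz))
    np.add.at(cnt, (bundle.ky_idx, bundle.kz_idx), 1.0)
    for c in range(bundle.n_coils):
        np.add.at(acc[c].transpose(1, 2, 0),
                  (bundle.ky_idx, bundle.kz_idx), bundle.data[:, c, :])
    nonzero = cnt > 0
    acc[:, :, nonzero] /= cnt[nonzero]

    wins = []
    for fov, n in zip(bundle.fov_mm, bundle.matrix_size):
        b = min(n, max(4, int(round(fov / calib_resolution_mm / 2)) * 2))
        w = np.zeros(n)
        lo = n // 2 - b // 2
        w[lo:lo + b] = np.hamming(b)
        wins.append(w)
    apod = wins[0][:, None, None] * wins[1][None, :, None] * wins[2][None, None, :]
    if not np.any(np.abs(acc) * apod):
        raise ValueError("k-space centre is empty; cannot calibrate coil maps")

    imgs = _ifft3(acc * apod[None])
    rss = np.sqrt((np.abs(imgs) ** 2).sum(axis=0))
    support = rss > support_threshold * rss.max()
    maps = np.zeros_like(imgs)
    maps[:, support] = imgs[:, support] / rss[support]
    return maps


def bin_kspace(bundle: KSpaceBundle, beats, beat_labels: np.ndarray,
               line_cardiac_phase: np.ndarray, n_cardiac_phases: int,
               n_resp_phases: int = 4, resp_phases=None):
    """Sort lines into (respiratory phase, cardiac phase) cells.

    Duplicate (ky, kz) acquisitions within a cell are averaged.  Returns
    ``kspaces`` (dict respiratory phase -> (n_coils, n_card, Nx, Ny, Nz)
    array), ``masks`` (dict of (n_card, Ny, Nz) booleans) and the per-cell
    line counts (n_resp, n_card).  ``resp_phases`` restricts which
    respiratory phases are materialised (they are large arrays).
    """
    nx, ny, nz = bundle.matrix_size
    kspaces, masks = {}, {}
    occupancy = np.zeros((n_resp_phases, n_cardiac_phases), dtype=int)
    if resp_phases is None:
        resp_phases = range(n_resp_phases)
    for r in resp_phases:
        acc = np.zeros((bundle.n_coils, n_cardiac_phases, nx, ny, nz),
                       dtype=np.complex64)
        cnt = np.zeros((n_cardiac_phases, ny, nz), dtype=np.int32)
        for b in beats:
            if beat_labels[b.beat_id] != r:
                continue
            for i in b.line_ids:
                cp = line_cardiac_phase[i]
                if cp < 0 or cp >= n_cardiac_phases:
                    continue
                ky, kz = int(bundle.ky_idx[i]), int(bundle.kz_idx[i])
                acc[:, cp, :, ky, kz] += bundle.data[i]
                cnt[cp, ky, kz] += 1
                occupancy[r, cp] += 1
        dup = cnt > 1
        if dup.any():
            cp_i, ky_i, kz_i = np.where(dup)
            acc[:, cp_i, :, ky_i, kz_i] /= \
                cnt[cp_i, ky_i, kz_i][:, None, None].astype(np.float32)
        kspaces[r] = acc
        masks[r] = cnt > 0
        if not (cnt > 0).any():
            log.warning("respiratory phase %d received no data", r)
    return kspaces, masks, occupancy


def full_mask(mask_yz: np.ndarray, nx: int, partial_fourier: float = 1.0
              ) -> np.ndarray:
    """Expand a (n_card, Ny, Nz) mask to (n_card, Nx, Ny, Nz) including the
    readout partial-Fourier truncation."""
    kxm = kx_partial_fourier_mask(nx, partial_fourier)
    return kxm[None, :, None, None] & mask_yz[:, None, :, :]


def tv_prox_cyclic(v: np.ndarray, gamma: float, axis: int = 0,
                   n_iter: int = 30) -> np.ndarray:
    """Proximal map of gamma * cyclic 1D total variation along ``axis``,
    solved by Chambolle's dual projection (works for complex data)."""
    if gamma <= 0:
        return v
    v = np.moveaxis(v, axis, 0)
    p = np.zeros_like(v)
    tau = 0.25
    for _ in range(n_iter):
        div_p = p - np.roll(p, 1, axis=0)
        g = np.roll(div_p - v / gamma, -1, axis=0) - (div_p - v / gamma)
        p = (p + tau * g) / (1.0 + tau * np.abs(g))
    div_p = p - np.roll(p, 1, axis=0)
    return np.moveaxis(v - gamma * div_p, 0, axis)


def _tv_value(x: np.ndarray, axis: int = 0) -> float:
    return float(np.abs(np.roll(x, -1, axis=axis) - x).sum())


@dataclass
class ReconResult:
    cine: np.ndarray                  # (n_card, Nx, Ny, Nz) magnitude
    objective: np.ndarray             # per-iteration objective values
    residual: float                   # final data-fidelity residual
    lambda_t: float
    converged: bool = True


def ktss_reconstruct(cell_kspace: np.ndarray, mask_yz: np.ndarray,
                     maps: np.ndarray, lambda_frac: float = 0.02,
                     lambda_t: float | None = None, max_iter: int = 40,
                     tol: float = 1e-5, partial_fourier: float = 1.0,
                     prox_iter: int = 20) -> ReconResult:
    """Reconstruct one respiratory phase's cardiac cine.

    ``lambda_t`` defaults to ``lambda_frac`` times the maximum temporal
    finite-difference magnitude of the zero-filled reconstruction — a scale-
    free heuristic, since the acquisition normalisation is arbitrary.
    """
    n_card = cell_kspace.shape[1]
    if (mask_yz.reshape(n_card, -1).any(axis=1)).sum() < 2:
        raise ValueError("need data in at least 2 cardiac phases")
    nx = cell_kspace.shape[2]
    E = EncodingOperator(maps=maps,
                         mask=full_mask(mask_yz, nx, partial_fourier))
    y = np.asarray(cell_kspace, dtype=np.complex64)
    x = E.adjoint(y)                      # zero-filled SENSE initialisation
    if lambda_t is None:
        dx0 = np.abs(np.roll(x, -1, axis=0) - x)
        lambda_t = float(lambda_frac * dx0.max()) if dx0.max() > 0 else 0.0

    def objective(xx, rr):
        return 0.5 * float((np.abs(rr) ** 2).sum()) + lambda_t * _tv_value(xx)

    obj = []
    n_bad = 0
    converged = True
    for it in range(max_iter):
        r = E.forward(x) - y
        obj.append(objective(x, r))
        x_new = x - E.adjoint(r)          # step size 1: ||E|| <= 1
        if lambda_t > 0:
            x_new = tv_prox_cyclic(x_new, lambda_t, axis=0, n_iter=prox_iter)
        if it > 0:
            if obj[-1] > obj[-2] * (1 + tol):
                n_bad += 1
                if n_bad >= 5:
                    log.error("objective diverging; aborting at iter %d", it)
                    converged = False
                    break
            else:
                n_bad = 0
            if abs(obj[-2] - obj[-1]) <= tol * max(obj[-2], 1e-12):
                x = x_new
                break
        x = x_new
    r = E.forward(x) - y
    residual = float(np.sqrt((np.abs(r) ** 2).sum()))
    return ReconResult(cine=np.abs(x), objective=np.asarray(obj),
                       residual=residual, lambda_t=lambda_t,
                       converged=converged)


def zero_filled(cell_kspace: np.ndarray, mask_yz: np.ndarray,
                maps: np.ndarray, partial_fourier: float = 1.0) -> np.ndarray:
    """Magnitude of the adjoint (zero-filled SENSE) reconstruction."""
    nx = cell_kspace.shape[2]
    E = EncodingOperator(maps=maps,
                         mask=full_mask(mask_yz, nx, partial_fourier))
    return np.abs(E.adjoint(np.asarray(cell_kspace, dtype=np.complex64)))
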