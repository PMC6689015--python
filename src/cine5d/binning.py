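"""Respiratory phase binning by k-means and respiration-derived metrics.

Heartbeats are clustered on their (dx, dy, dz) displacement vectors into
four groups spanning the breathing cycle.  The cluster whose centroid has
the most positive x (heart highest) is end-expiration (EE); the most
negative is end-inspiration (EI); the two in-between are ordered by x.
Respiratory depth is the Euclidean distance between the EE and EI
centroids:

    delta_d = sqrt((c1x - c2x)^2 + (c1y - c2y)^2 + (c1z - c2z)^2)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .motion import MotionTrace

__all__ = [
    "RespBinning",
    "RespMetrics",
    "kmeans4",
    "assign_phases",
    "respiratory_depth",
    "resp_metrics",
    "PHASE_NAMES",
]

log = logging.getLogger(__name__)

PHASE_NAMES = ("EE", "mid-expiration", "mid-inspiration", "EI")


@dataclass
class RespBinning:
    labels: np.ndarray                  # per-beat cluster id in {0..k-1}
    centroids: np.ndarray               # (k, 3) mm
    inertia: float
    phase_names: dict[int, str] | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def cluster_of(self, phase: str) -> int:
        if self.phase_names is None:
            raise ValueError("phases not assigned yet; call assign_phases")
        for cid, name in self.phase_names.items():
            if name == phase:
                return cid
        raise KeyError(phase)

    def beats_in(self, phase: str) -> np.ndarray:
        return np.where(self.labels == self.cluster_of(phase))[0]


@dataclass
class RespMetrics:
    resp_rate_brpm: float
    resp_rate_bellows_brpm: float
    resp_depth_mm: float
    data_portion_pct: dict[str, float]
    average_motion_mm: dict[str, float]
    ee_ei_ratio: float
    hr_bpm: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "Respiratory Rate (brpm)": self.resp_rate_brpm,
            "Respiratory Rate, bellows (brpm)": self.resp_rate_bellows_brpm,
            "Respiratory Depth (mm)": self.resp_depth_mm,
            "Data Portion (%)": self.data_portion_pct,
            "Average Motion (mm)": self.average_motion_mm,
            "Data Ratio (EE to EI)": self.ee_ei_ratio,
            "Heart Rate (bpm)": self.hr_bpm,
        }


def kmeans4(trace: MotionTrace | np.ndarray, n_clusters: int = 4,
            restarts: int = 10, seed: int = 0) -> RespBinning:
    """Best-of-``restarts`` Lloyd's k-means on the per-beat 3D displacements.

    Each restart draws random initial seeds; the solution with the lowest
    total intra-cluster variance (inertia) wins.  Deterministic for a given
    ``seed``.
    """
    pts = trace.displacement_mm if isinstance(trace, MotionTrace) else np.asarray(trace)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected (n_beats, 3) displacements")
    if len(pts) < 2 * n_clusters:
        raise ValueError(f"need at least {2 * n_clusters} beats")
    if len(np.unique(pts, axis=0)) < n_clusters:
        raise ValueError("insufficient motion diversity: fewer than "
                         f"{n_clusters} distinct displacement points")
    km = KMeans(n_clusters=n_clusters, n_init=restarts, init="random",
                random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(pts)
    binning = RespBinning(labels=labels, centroids=km.cluster_centers_,
                          inertia=float(km.inertia_))
    return assign_phases(binning)


def assign_phases(binning: RespBinning) -> RespBinning:
    """Name clusters by the x (vertical/SI) component of their centroids:
    max -> EE, min -> EI, the rest in descending x between them."""
    cx = binning.centroids[:, 0]
    order = np.argsort(-cx, kind="stable")
    if len(np.unique(cx)) < len(cx):
        # tie on x: break by spread of the SI component, largest first
        log.warning("centroid x tie; breaking by SI second moment")
        spread = np.array([
            binning.centroids[c, 0] ** 2 for c in range(len(cx))
        ])
        order = np.lexsort((-spread, -cx))
    names = {}
    labels = (["EE"] + list(PHASE_NAMES[1:-1])[: len(cx) - 2] + ["EI"]) \
        if len(cx) >= 2 else ["EE"]
    for cid, name in zip(order, labels):
        names[int(cid)] = name
    binning.phase_names = names
    return binning


def respiratory_depth(binning: RespBinning) -> float:
    """Euclidean EE-EI centroid distance (mm)."""
    ee = binning.centroids[binning.cluster_of("EE")]
    ei = binning.centroids[binning.cluster_of("EI")]
    return float(np.linalg.norm(ee - ei))


def _dominant_frequency_brpm(t_ms: np.ndarray, signal: np.ndarray) -> float:
    """Spectral peak (excluding DC) of an evenly resampled trace, in 1/min."""
    t = np.asarray(t_ms, dtype=float)
    s = np.asarray(signal, dtype=float)
    if len(t) < 8 or np.ptp(s) == 0:
        return float("nan")
    dt = np.median(np.diff(t))
    tt = np.arange(t[0], t[-1], dt)
    ss = np.interp(tt, t, s)
    ss = ss - ss.mean()
    spec = np.abs(np.fft.rfft(ss * np.hanning(len(ss))))
    freqs = np.fft.rfftfreq(len(ss), d=dt / 1000.0)   # Hz
    spec[0] = 0.0
    return float(freqs[np.argmax(spec)] * 60.0)


def resp_metrics(binning: RespBinning, trace: MotionTrace,
                 hr_per_beat: np.ndarray,
                 beat_times_ms: np.ndarray | None = None,
                 bellows_t_ms: np.ndarray | None = None,
                 bellows: np.ndarray | None = None) -> RespMetrics:
    """Respiration-related measurements over the clustered heartbeats.

    Portions are by beat counts; average motion is the mean distance of a
    phase's beats from their own centroid; per-phase heart rate averages the
    instantaneous HR of member beats; the respiratory rate is the dominant
    spectral frequency of the SI motion trace (and of the bellows trace when
    provided).
    """
    pts = trace.displacement_mm
    n = len(pts)
    portions: dict[str, float] = {}
    avg_motion: dict[str, float] = {}
    hr: dict[str, float] = {}
    for cid, name in binning.phase_names.items():
        members = np.where(binning.labels == cid)[0]
        portions[name] = 100.0 * len(members) / n
        if len(members) == 0:
            log.warning("respiratory phase %s is empty", name)
            avg_motion[name] = float("nan")
            hr[name] = float("nan")
            continue
        d = np.linalg.norm(pts[members] - binning.centroids[cid], axis=1)
        avg_motion[name] = float(d.mean())
        hr[name] = float(np.asarray(hr_per_beat)[members].mean())

    if beat_times_ms is None:
        beat_times_ms = np.arange(n) * 1000.0
    rate = _dominant_frequency_brpm(np.asarray(beat_times_ms)[:n], pts[:, 0])
    rate_bellows = (
        _dominant_frequency_brpm(bellows_t_ms, bellows)
        if bellows is not None else float("nan")
    )
    ei = portions.get("EI", float("nan"))
    ratio = portions.get("EE", float("nan")) / ei if ei else float("nan")
    return RespMetrics(
        resp_rate_brpm=rate,
        resp_rate_bellows_brpm=rate_bellows,
        resp_depth_mm=respiratory_depth(binning),
        data_portion_pct=portions,
        average_motion_mm=avg_motion,
        ee_ei_ratio=ratio,
        hr_bpm=hr,
    )
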