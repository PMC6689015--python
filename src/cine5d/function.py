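"""Ventricular segmentation and function quantification.

Short-axis slices are segmented per cardiac phase: a Hough transform
proposes an initial circular LV contour, which a region-based (Chan-Vese
style) level set evolves to the actual cavity boundary while being softly
attracted toward its own best-fit ellipse (the cavity is roughly, but not
strictly, elliptical).  The RV uses the same evolution from a manually
provided covering circle.  Volumes follow by voxel counting over the
included slices; EF = (EDV - ESV) / EDV x 100 with ED/ES identified as the
phases of maximal/minimal cavity volume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.feature import canny
from skimage.segmentation import morphological_chan_vese
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "ChamberMasks",
    "FunctionReport",
    "hough_lv_init",
    "levelset_segment",
    "rv_segment",
    "chamber_volumes",
    "compare_phases",
]

log = logging.getLogger(__name__)


@dataclass
class ChamberMasks:
    """Binary cavity masks for one ventricle across cardiac phases."""

    masks: np.ndarray                # (n_phases, Nx, Ny, Nz) bool
    ventricle: str                   # "LV" or "RV"
    slice_range: tuple[int, int]     # [lo, hi) slices included in volumetry
    provenance: str = "auto"         # "auto" (Hough) or "manual" seed
    flags: list[str] = field(default_factory=list)


@dataclass
class SegmentationParams:
    n_outer: int = 6                 # ellipse-refinement rounds
    n_cv_iter: int = 8               # level-set iterations per round
    smoothing: int = 1
    shape_weight: float = 0.3        # pull toward the best-fit ellipse
    crop_factor: float = 2.2         # ROI half-width in units of init radius
    leakage_factor: float = 3.0      # abort if area grows beyond this x init
    # "center": keep the component containing the init centre (LV: the init
    # circle sits inside the cavity); "largest_in_seed": keep the largest
    # component overlapping the init circle (RV: the covering seed's centre
    # may fall outside the crescent-shaped cavity)
    component_rule: str = "center"
    confine_to_seed: bool = False    # clip the mask to the init circle
    confine_scale: float = 1.0       # confinement radius in units of init r


def hough_lv_init(short_axis_stack: np.ndarray, spacing_mm,
                  radius_range_mm: tuple[float, float] = (12.0, 35.0),
                  accumulator_threshold: float = 0.35
                  ) -> list[tuple[float, float, float] | None]:
    """Initial circular LV contour per slice via the circle Hough transform.

    Returns per-slice (cx, cy, r) in pixel units (None where no circle
    exceeded the accumulator threshold).  Detection starts from the slice
    with the strongest response and is propagated to neighbours by
    proximity, so the stack follows one coherent structure.
    """
    nz = short_axis_stack.shape[2]
    px = float(spacing_mm[0])
    radii = np.arange(max(2, int(radius_range_mm[0] / px)),
                      max(3, int(radius_range_mm[1] / px)) + 1)
    cands = []
    for z in range(nz):
        sl = short_axis_stack[:, :, z]
        if sl.max() <= 0:
            cands.append(None)
            continue
        edges = canny(sl / sl.max(), sigma=1.0)
        h = hough_circle(edges, radii)
        accums, cxs, cys, rs = hough_circle_peaks(h, radii, total_num_peaks=5)
        if len(accums) == 0 or accums[0] < accumulator_threshold:
            cands.append(None)
            continue
        # hough_circle_peaks returns (col, row) = (axis-1, axis-0) coords
        cands.append([(float(a), float(cy), float(cx), float(r))
                      for a, cx, cy, r in zip(accums, cxs, cys, rs)])

    best_z, best_a = None, -1.0
    for z, c in enumerate(cands):
        if c and c[0][0] > best_a:
            best_z, best_a = z, c[0][0]
    if best_z is None:
        log.warning("no circular structure found in any slice")
        return [None] * nz

    out: list[tuple[float, float, float] | None] = [None] * nz
    out[best_z] = cands[best_z][0][1:]

    def _propagate(order):
        prev = out[best_z]
        for z in order:
            if cands[z] is None:
                log.warning("slice %d flagged for manual seeding", z)
                prev = prev
                continue
            # nearest candidate to the neighbouring slice's circle
            best = min(cands[z],
                       key=lambda c: (c[1] - prev[0]) ** 2 + (c[2] - prev[1]) ** 2)
            if (best[1] - prev[0]) ** 2 + (best[2] - prev[1]) ** 2 < (4 * best[3]) ** 2:
                out[z] = best[1:]
                prev = best[1:]

    _propagate(range(best_z + 1, nz))
    _propagate(range(best_z - 1, -1, -1))
    return out


def _circle_mask(shape, cx: float, cy: float, r: float) -> np.ndarray:
    X, Y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (X - cx) ** 2 + (Y - cy) ** 2 <= r**2


def _best_fit_ellipse_mask(mask: np.ndarray) -> np.ndarray:
    """Same-area ellipse with the mask's centroid and second moments."""
    pts = np.argwhere(mask)
    if len(pts) < 8:
        return mask
    mu = pts.mean(axis=0)
    cov = np.cov((pts - mu).T)
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0):
        return mask
    # scale so the ellipse area matches the mask area
    area = len(pts)
    ab = 2.0 * np.sqrt(evals)          # ~semi-axes of a uniform ellipse
    scale = np.sqrt(area / (np.pi * ab[0] * ab[1]))
    a, b = ab * scale
    X, Y = np.meshgrid(np.arange(mask.shape[0]), np.arange(mask.shape[1]),
                       indexing="ij")
    rel = np.stack([X - mu[0], Y - mu[1]], axis=-1) @ evecs
    return (rel[..., 0] / a) ** 2 + (rel[..., 1] / b) ** 2 <= 1.0


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def _segment_slice(img: np.ndarray, init: tuple[float, float, float],
                   params: SegmentationParams,
                   exclude: np.ndarray | None = None,
                   intensity_range: float | None = None
                   ) -> tuple[np.ndarray, str | None]:
    """Elliptically refined level-set segmentation of one 2D slice.

    ``exclude`` marks pixels that can never belong to the target chamber
    (e.g. the already-segmented LV when evolving the RV contour).
    """
    cx, cy, r = init
    half = int(round(params.crop_factor * r))
    x0, x1 = int(max(0, cx - half)), int(min(img.shape[0], cx + half + 1))
    y0, y1 = int(max(0, cy - half)), int(min(img.shape[1], cy + half + 1))
    crop = img[x0:x1, y0:y1]
    excl = exclude[x0:x1, y0:y1] if exclude is not None else None
    ls = _circle_mask(crop.shape, cx - x0, cy - y0, r)
    init_area = max(1, int(ls.sum()))
    flag = None
    for _ in range(params.n_outer):
        ls = morphological_chan_vese(
            crop, num_iter=params.n_cv_iter, init_level_set=ls,
            smoothing=params.smoothing,
        ).astype(bool)
        if ls.sum() == 0:
            flag = "collapsed"
            ls = _circle_mask(crop.shape, cx - x0, cy - y0, r)
            break
        if ls.sum() < crop.size:
            # no bright-cavity/background contrast (e.g. a slice beyond the
            # chamber): nothing to segment
            scale = intensity_range if intensity_range is not None \
                else crop.max() - crop.min()
            contrast = crop[ls].mean() - crop[~ls].mean()
            if contrast < 0.15 * (scale + 1e-12) or scale < 1e-6:
                return np.zeros(img.shape, dtype=bool), "no contrast"
        if ls.sum() > params.leakage_factor * init_area:
            flag = "leakage"
            break
        seed_mask = _circle_mask(crop.shape, cx - x0, cy - y0,
                                 params.confine_scale * r)
        if excl is not None:
            ls = ls & ~excl
        if params.confine_to_seed:
            ls = ls & seed_mask
        lab, nlab = ndimage.label(ls)
        if nlab > 0:
            if params.component_rule == "center":
                keep = lab[int(round(cx - x0)), int(round(cy - y0))]
                if keep > 0:
                    ls = lab == keep
            else:  # largest component overlapping the seed circle
                overlaps = ndimage.sum_labels(seed_mask, lab,
                                              np.arange(1, nlab + 1))
                ls = lab == (int(np.argmax(overlaps)) + 1)
        ls = ndimage.binary_fill_holes(ls)
        if params.shape_weight > 0:
            phi = _signed_distance(ls)
            phi_e = _signed_distance(_best_fit_ellipse_mask(ls))
            ls = ((1 - params.shape_weight) * phi
                  + params.shape_weight * phi_e) > 0
            if excl is not None:
                ls = ls & ~excl
            if params.confine_to_seed:
                ls = ls & seed_mask
    ls = ndimage.binary_fill_holes(ls)
    if excl is not None:
        ls = ls & ~excl
    full = np.zeros(img.shape, dtype=bool)
    full[x0:x1, y0:y1] = ls
    return full, flag


def levelset_segment(volume: np.ndarray,
                     init_circles: list[tuple[float, float, float] | None],
                     params: SegmentationParams | None = None,
                     ventricle: str = "LV",
                     slice_range: tuple[int, int] | None = None,
                     provenance: str = "auto",
                     exclude_mask: np.ndarray | None = None) -> ChamberMasks:
    """Segment one cardiac phase of a short-axis volume, slice by slice.

    ``init_circles`` is the per-slice (cx, cy, r) initialisation; slices
    with None are skipped (empty mask, flagged).
    """
    params = params or SegmentationParams()
    nz = volume.shape[2]
    if slice_range is None:
        slice_range = (0, nz)
    mask = np.zeros(volume.shape, dtype=bool)
    flags: list[str] = []
    for z in range(*slice_range):
        init = init_circles[z] if z < len(init_circles) else None
        if init is None:
            flags.append(f"slice {z}: no initialisation")
            continue
        excl = exclude_mask[:, :, z] if exclude_mask is not None else None
        m, flag = _segment_slice(volume[:, :, z], init, params, excl,
                                 intensity_range=float(np.ptp(volume)))
        if flag:
            flags.append(f"slice {z}: {flag}")
            if flag == "leakage":
                continue
        mask[:, :, z] = m
    _drop_intensity_outlier_slices(volume, mask, slice_range, flags)
    return ChamberMasks(masks=mask[None], ventricle=ventricle,
                        slice_range=slice_range, provenance=provenance,
                        flags=flags)


def _drop_intensity_outlier_slices(volume, mask, slice_range, flags,
                                   rel_threshold: float = 0.6) -> None:
    """Zero out slices whose segmented region is much darker than the
    chamber's typical blood-pool intensity — such slices captured a
    neighbouring structure (e.g. myocardium beyond the cavity's extent)."""
    means = {}
    for z in range(*slice_range):
        if mask[:, :, z].any():
            means[z] = float(volume[:, :, z][mask[:, :, z]].mean())
    if len(means) < 3:
        return
    med = float(np.median(list(means.values())))
    for z, m in means.items():
        if m < rel_threshold * med:
            mask[:, :, z] = False
            flags.append(f"slice {z}: intensity outlier dropped")


def rv_segment(volume: np.ndarray, seed_circle: tuple[float, float, float],
               params: SegmentationParams | None = None,
               slice_range: tuple[int, int] | None = None,
               exclude_mask: np.ndarray | None = None) -> ChamberMasks:
    """RV segmentation from a manual covering circle, same level-set
    evolution as the LV path (the evolution shrinks the covering circle
    onto the crescent-shaped cavity).  Defaults differ from the LV in how
    the final component is chosen — the covering circle's centre may fall
    outside the crescent — and in a weaker elliptical attraction."""
    if params is None:
        params = SegmentationParams(component_rule="largest_in_seed",
                                    confine_to_seed=True, shape_weight=0.15)
    nz = volume.shape[2]
    circles = [seed_circle] * nz
    out = levelset_segment(volume, circles, params, ventricle="RV",
                           slice_range=slice_range, provenance="manual",
                           exclude_mask=exclude_mask)
    cx, cy, _ = seed_circle
    for z in range(*out.slice_range):
        m = out.masks[0][:, :, z]
        if m.any() and not m[int(round(cx)), int(round(cy))]:
            pts = np.argwhere(m)
            d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy).min()
            if d > 2 * np.sqrt(m.sum() / np.pi):
                out.flags.append(f"slice {z}: result far from seed")
    return out


def chamber_volumes(masks_per_phase: list[ChamberMasks] | np.ndarray,
                    spacing_mm, slice_range: tuple[int, int] | None = None,
                    smooth_window: int = 3) -> dict:
    """ESV/EDV/SV/EF from per-cardiac-phase cavity masks.

    Per-phase volume = voxel count x voxel volume over the included slices,
    in mL; EDV/ESV are the max/min over phases.  With ``smooth_window`` > 1
    the (cyclic) volume curve is median-filtered before the ED/ES pick, so
    a single-phase segmentation dropout cannot masquerade as end-systole;
    set 1 to disable.  The raw per-phase curve is always returned.
    """
    if isinstance(masks_per_phase, list):
        arr = np.concatenate([m.masks for m in masks_per_phase], axis=0)
        if slice_range is None:
            slice_range = masks_per_phase[0].slice_range
    else:
        arr = np.asarray(masks_per_phase)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 cardiac phases")
    if slice_range is None:
        slice_range = (0, arr.shape[3])
    vox_ml = float(np.prod(spacing_mm)) / 1000.0
    counts = arr[:, :, :, slice_range[0]:slice_range[1]].sum(axis=(1, 2, 3))
    vols = counts * vox_ml
    if smooth_window > 1 and len(vols) > smooth_window:
        half = smooth_window // 2
        padded = np.concatenate([vols[-half:], vols, vols[:half]])
        smoothed = np.array([
            np.median(padded[i:i + smooth_window]) for i in range(len(vols))])
    else:
        smoothed = vols
    edv, esv = float(smoothed.max()), float(smoothed.min())
    sv = edv - esv
    ef = (edv - esv) / edv * 100.0 if edv > 0 else float("nan")
    if edv == 0:
        log.warning("EDV is zero; EF undefined")
    return {
        "volumes_ml": vols, "ESV_mL": esv, "EDV_mL": edv, "SV_mL": sv,
        "EF_pct": ef, "ed_phase": int(np.argmax(smoothed)),
        "es_phase": int(np.argmin(smoothed)),
    }


@dataclass
class FunctionReport:
    """Per ventricle x respiratory phase function parameters plus
    respiration metrics and phase-comparison statistics."""

    measurements: dict                # {ventricle: {phase: {ESV_mL, ...}}}
    resp_metrics: dict | None = None
    statistics: dict | None = None
    qc_flags: list[str] = field(default_factory=list)

    def change_pct(self, ventricle: str, key: str) -> float:
        ee = self.measurements[ventricle]["EE"][key]
        ei = self.measurements[ventricle]["EI"][key]
        return (ei - ee) / ee * 100.0 if ee else float("nan")

    def to_json(self, path=None) -> str:
        def _clean(o):
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_clean(v) for v in o]
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o
        payload = json.dumps(_clean({
            "measurements": self.measurements,
            "resp_metrics": self.resp_metrics,
            "statistics": self.statistics,
            "qc_flags": self.qc_flags,
        }), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_table(self):
        """Long-format table of the volume-based measurements: one row per
        (ventricle, respiratory phase) with ESV_mL, EDV_mL, SV_mL, EF_pct
        and the EI-vs-EE change_pct."""
        import pandas as pd
        rows = []
        for vent, phases in self.measurements.items():
            for phase, m in phases.items():
                row = {"ventricle": vent, "phase": phase}
                for key in ("ESV_mL", "EDV_mL", "SV_mL", "EF_pct"):
                    row[key] = m.get(key)
                if "EE" in phases and "EI" in phases and phase == "EI":
                    row["change_pct"] = self.change_pct(vent, "EF_pct")
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_json(cls, text: str) -> "FunctionReport":
        d = json.loads(text)
        return cls(measurements=d["measurements"],
                   resp_metrics=d.get("resp_metrics"),
                   statistics=d.get("statistics"),
                   qc_flags=d.get("qc_flags", []))


def compare_phases(values_ee: np.ndarray, values_ei: np.ndarray,
                   group_labels: np.ndarray | None = None,
                   corr_pairs: list[tuple[np.ndarray, np.ndarray, str]] | None = None
                   ) -> dict:
    """Statistics block: paired two-tailed t-test EE vs EI, mean per-pair
    change (EI-EE)/EE x 100, optional Mann-Whitney between two groups and
    Pearson correlations for supplied parameter pairs.  Significance 0.05.
    """
    ee = np.asarray(values_ee, dtype=float)
    ei = np.asarray(values_ei, dtype=float)
    out: dict = {}
    if len(ee) < 3:
        out["paired_t"] = {"skipped": "n < 3"}
    elif np.allclose(ee, ei):
        # identical pairs: zero difference, no evidence of any effect
        out["paired_t"] = {"statistic": 0.0, "p": 1.0, "significant": False}
    else:
        t, p = stats.ttest_rel(ee, ei)
        out["paired_t"] = {"statistic": float(t), "p": float(p),
                           "significant": bool(p < 0.05)}
    with np.errstate(divide="ignore", invalid="ignore"):
        change = (ei - ee) / ee * 100.0
    out["change_pct_mean"] = float(np.nanmean(change))
    out["change_pct_sd"] = float(np.nanstd(change, ddof=1)) if len(ee) > 1 else float("nan")
    if group_labels is not None:
        g = np.asarray(group_labels)
        groups = np.unique(g)
        if len(groups) == 2 and min((g == x).sum() for x in groups) >= 3:
            u, p = stats.mannwhitneyu(ee[g == groups[0]], ee[g == groups[1]],
                                      alternative="two-sided")
            out["mann_whitney"] = {"statistic": float(u), "p": float(p),
                                   "significant": bool(p < 0.05)}
        else:
            out["mann_whitney"] = {"skipped": "need two groups with n >= 3"}
    if corr_pairs:
        out["correlations"] = {}
        for a, b, name in corr_pairs:
            a, b = np.asarray(a, float), np.asarray(b, float)
            if len(a) < 3:
                out["correlations"][name] = {"skipped": "n < 3"}
                continue
            r, p = stats.pearsonr(a, b)
            out["correlations"][name] = {"r": float(r), "p": float(p),
                                         "significant": bool(p < 0.05)}
    return out
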