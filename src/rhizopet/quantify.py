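"""Dynamic-PET quantification: decay correction, ROI masking, time-activity
curves, interleaved-position interpolation, tracer fractions and windowed
mean fractions.

The central quantity is the *tracer fraction*: ROI activity divided by the
total belowground activity at the same time point.  Because numerator and
denominator decay identically, fractions are dimensionless and independent
of decay correction.  With the alternating two-position acquisition each
position is imaged only every other frame, so the total from the position
not being imaged is filled in by local quadratic interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .acquisition import LOWER, UPPER, AcquisitionConfig, FrameSeries, window_bounds
from .phantom import NODULE, RootPhantom

WHOLE_ROOT = "whole_root"


class QuantifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# decay correction


def decay_correct(value, t_start: float, t_end: float | None = None, lam: float = None):
    """Correct a measurement for physical decay to reference time 0.

    Point form (``t_end`` equal to ``t_start`` or None): multiply by
    ``exp(lam * t)``.  Frame form (``t_end > t_start``): the value is a
    count integral over the frame, so the factor is
    ``lam * (t_end - t_start) / (exp(-lam t_start) - exp(-lam t_end))``,
    which restores the counts a non-decaying tracer would have produced.
    """
    if lam is None or lam <= 0:
        raise QuantifyError("lam must be > 0")
    if t_start < 0:
        raise QuantifyError("t_start must be >= 0")
    if t_end is None or t_end == t_start:
        return value * np.exp(lam * t_start)
    if t_end < t_start:
        raise QuantifyError("t_end must be >= t_start")
    factor = lam * (t_end - t_start) / (np.exp(-lam * t_start) - np.exp(-lam * t_end))
    return value * factor


# ---------------------------------------------------------------------------
# ROI definition


@dataclass
class ROI:
    """A region of interest in one acquisition position's window."""

    id: str
    seed: tuple  # window-local voxel index
    position: str  # lower | upper
    mask: np.ndarray  # boolean, (nx, ny, window_voxels)
    kind: str  # nodule | whole_root

    def __post_init__(self):
        if not self.mask.any():
            raise QuantifyError(f"ROI {self.id}: empty mask")
        if not self.mask[self.seed]:
            raise QuantifyError(f"ROI {self.id}: seed outside mask")


def region_grow(volume: np.ndarray, seed: tuple, rel_threshold: float) -> np.ndarray:
    """Standard region growing: the 26-connected component containing the
    seed, among voxels with intensity >= rel_threshold * (local seed
    neighborhood maximum, 3x3x3).

    The threshold is relative to the local neighborhood maximum rather than
    the seed voxel itself, making the mask robust to the seed landing one
    voxel off the intensity peak and to global intensity rescaling.
    A seed below its own threshold yields a single-voxel mask with a warning.
    """
    if not 0 < rel_threshold <= 1:
        raise QuantifyError("rel_threshold must be in (0, 1]")
    seed = tuple(int(i) for i in seed)
    if any(i < 0 or i >= n for i, n in zip(seed, volume.shape)):
        raise QuantifyError(f"seed {seed} outside volume of shape {volume.shape}")
    lo = tuple(max(i - 1, 0) for i in seed)
    hi = tuple(min(i + 2, n) for i, n in zip(seed, volume.shape))
    local_max = float(volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].max())
    threshold = rel_threshold * local_max
    above = volume >= threshold
    if not above[seed]:
        warnings.warn(f"seed {seed} below region-growing threshold; returning single voxel")
        mask = np.zeros(volume.shape, dtype=bool)
        mask[seed] = True
        return mask
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    return labels == labels[seed]


def whole_root_rois(phantom: RootPhantom, cfg: AcquisitionConfig) -> dict:
    """Whole-root total ROIs for both positions.

    The lower ROI covers its full window; the upper ROI excludes the axial
    slab that both positions see (assigned to the lower position), so that
    the two totals partition the belowground volume and their sum counts
    every voxel exactly once.
    """
    nx, ny = phantom.grid_shape[:2]
    overlap = cfg.window_voxels - cfg.offset_voxels  # voxels seen by both positions
    lower = np.ones((nx, ny, cfg.window_voxels), dtype=bool)
    upper = np.ones((nx, ny, cfg.window_voxels), dtype=bool)
    if overlap > 0:
        upper[:, :, :overlap] = False
    return {
        LOWER: ROI("whole_root_lower", (nx // 2, ny // 2, 0), LOWER, lower, WHOLE_ROOT),
        UPPER: ROI("whole_root_upper", (nx // 2, ny // 2, max(overlap, 0)), UPPER, upper, WHOLE_ROOT),
    }


def reference_image(frames: FrameSeries, position: str) -> np.ndarray:
    """Sum of all frames of one position — the ROI-drawing reference."""
    vols = [v for v, s in frames.frames_at(position)]
    if not vols:
        raise QuantifyError(f"no frames at position {position!r}")
    return np.sum(vols, axis=0).astype(float)


def nodule_position(phantom: RootPhantom, structure_id: int, cfg: AcquisitionConfig) -> str:
    """Acquisition position whose window fully contains the nodule."""
    vox = phantom.voxel_indices(structure_id)
    z_lo, z_hi = int(vox[:, 2].min()), int(vox[:, 2].max())
    if z_hi < cfg.window_voxels:
        return LOWER
    if z_lo >= cfg.offset_voxels:
        return UPPER
    raise QuantifyError(f"nodule {structure_id} spans both acquisition windows")


def nodule_rois_from_truth(
    phantom: RootPhantom,
    frames: FrameSeries,
    cfg: AcquisitionConfig,
    rel_threshold: float = 0.3,
    min_truth_overlap: float = 0.5,
    max_root_contamination: float = 0.2,
    dilate_voxels: int = 2,
    exclude_root_voxels: bool = True,
) -> list:
    """Auto-place nodule ROIs by region growing from ground-truth centers.

    The region-grown core is dilated by ``dilate_voxels`` so the mask also
    collects the PSF skirt of the nodule signal (the grown core alone stops
    at the intensity threshold and loses the blurred tail).  Mirrors the
    manual nodule-ROI criteria: the mask must recover at least
    ``min_truth_overlap`` of the true nodule voxels and contain at most a
    ``max_root_contamination`` fraction of root voxels (evaluated before
    any exclusion).  With ``exclude_root_voxels`` (default), voxels the
    ground-truth label map identifies as root are removed from the final
    mask — the phantom's label map plays the role of the co-registered MRI
    that guides manual ROI drawing towards "as few roots as possible".
    Ineligible nodules are dropped with a warning.
    """
    refs = {p: reference_image(frames, p) for p in (LOWER, UPPER)}
    root_label = np.isin(phantom.label_volume, [s.id for s in phantom.root_segments])
    out = []
    for s in phantom.nodules:
        position = nodule_position(phantom, s.id, cfg)
        z_lo, _ = window_bounds(cfg, position)
        cx, cy, cz = phantom.center_voxel(s.id)
        seed = (cx, cy, cz - z_lo)
        mask = region_grow(refs[position], seed, rel_threshold)
        if dilate_voxels > 0:
            mask = ndimage.binary_dilation(mask, iterations=dilate_voxels)
        truth = np.zeros(mask.shape, dtype=bool)
        vox = phantom.voxel_indices(s.id)
        sel = vox[(vox[:, 2] >= z_lo) & (vox[:, 2] < z_lo + cfg.window_voxels)]
        truth[sel[:, 0], sel[:, 1], sel[:, 2] - z_lo] = True
        root_win = root_label[:, :, z_lo:z_lo + cfg.window_voxels]
        overlap = (mask & truth).sum() / max(truth.sum(), 1)
        contamination = (mask & root_win).sum() / mask.sum()
        if overlap < min_truth_overlap or contamination > max_root_contamination:
            warnings.warn(
                f"nodule {s.id}: ROI ineligible (truth overlap {overlap:.2f}, "
                f"root contamination {contamination:.2f})"
            )
            continue
        if exclude_root_voxels:
            mask = mask & ~root_win
        out.append(ROI(f"nodule_{s.id}", seed, position, mask, NODULE))
    return out


# ---------------------------------------------------------------------------
# curves


@dataclass
class TimeActivityCurve:
    """Decay-corrected ROI counts versus frame midpoint time."""

    roi_id: str
    position: str
    t_start: np.ndarray  # frame start times, min
    t_mid: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_mid = np.asarray(self.t_mid, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if np.any(np.diff(self.t_mid) <= 0):
            raise QuantifyError("curve times must be strictly increasing")

    def __len__(self):
        return len(self.t_mid)


@dataclass
class FractionCurve:
    """Dimensionless per-ROI tracer fraction versus time."""

    roi_id: str
    position: str
    t_start: np.ndarray
    t_mid: np.ndarray
    fraction: np.ndarray

    def __post_init__(self):
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_mid = np.asarray(self.t_mid, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)

    def __len__(self):
        return len(self.t_mid)


def extract_tac(frames: FrameSeries, roi: ROI, lam: float) -> TimeActivityCurve:
    """Sum counts over the ROI mask per matching frame and decay-correct
    (frame form) to reference time 0; timestamps at frame midpoints."""
    matching = frames.frames_at(roi.position)
    if not matching:
        raise QuantifyError(f"no frames match ROI position {roi.position!r}")
    t_start, t_mid, values = [], [], []
    for vol, spec in matching:
        raw = float(vol[roi.mask].sum())
        values.append(decay_correct(raw, spec.t_start, spec.t_end, lam))
        t_start.append(spec.t_start)
        t_mid.append(spec.t_mid)
    return TimeActivityCurve(roi.id, roi.position, np.array(t_start), np.array(t_mid), np.array(values))


def interp_total(curve: TimeActivityCurve, query_times) -> np.ndarray:
    """Local 3-point Lagrange quadratic interpolation.

    Each query is evaluated on the quadratic through its three nearest
    sample points (the first/last three for endpoint queries); exact for
    any globally quadratic series.
    """
    t = curve.t_mid
    y = curve.value
    if len(t) < 3:
        raise QuantifyError("quadratic interpolation needs >= 3 points")
    q = np.atleast_1d(np.asarray(query_times, dtype=float))
    out = np.empty_like(q)
    for i, qi in enumerate(q):
        j = int(np.argmin(np.abs(t - qi)))
        j0 = min(max(j - 1, 0), len(t) - 3)
        ts, ys = t[j0:j0 + 3], y[j0:j0 + 3]
        # Lagrange basis on the three chosen nodes
        L0 = (qi - ts[1]) * (qi - ts[2]) / ((ts[0] - ts[1]) * (ts[0] - ts[2]))
        L1 = (qi - ts[0]) * (qi - ts[2]) / ((ts[1] - ts[0]) * (ts[1] - ts[2]))
        L2 = (qi - ts[0]) * (qi - ts[1]) / ((ts[2] - ts[0]) * (ts[2] - ts[1]))
        out[i] = ys[0] * L0 + ys[1] * L1 + ys[2] * L2
    return out if np.ndim(query_times) else float(out[0])


def fraction_curve(
    roi_tac: TimeActivityCurve,
    total_same: TimeActivityCurve,
    total_other: TimeActivityCurve | None,
) -> FractionCurve:
    """Tracer fraction: ROI counts over total belowground counts.

    ``total_same`` is the whole-root total of the ROI's own position
    (sampled at the same times); ``total_other`` is the other position's
    total, quadratically interpolated to the ROI's time points.  All three
    curves must be decay-corrected to the same reference (or all
    uncorrected — the fraction is invariant).
    """
    if not np.allclose(roi_tac.t_mid, total_same.t_mid):
        raise QuantifyError("roi and same-position total are on different time grids")
    denom = total_same.value.copy()
    if total_other is not None:
        denom = denom + interp_total(total_other, roi_tac.t_mid)
    if np.any(denom <= 0):
        raise QuantifyError("total belowground counts must be > 0 at every time point")
    return FractionCurve(roi_tac.roi_id, roi_tac.position, roi_tac.t_start, roi_tac.t_mid, roi_tac.value / denom)


# ---------------------------------------------------------------------------
# windowed means


def mean_fraction(curve: FractionCurve, window: tuple) -> tuple:
    """Mean and sample SD of the fraction points whose *frame start* lies
    inside ``window = (t_lo, t_hi)`` (inclusive)."""
    t_lo, t_hi = window
    sel = (curve.t_start >= t_lo) & (curve.t_start <= t_hi)
    if not sel.any():
        raise QuantifyError(f"window {window} contains no points")
    vals = curve.fraction[sel]
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


def default_window_index(n_points: int, width: int = 4) -> int:
    """Latest run of ``width`` consecutive same-position frames."""
    if n_points < width:
        raise QuantifyError("curve shorter than window width")
    return n_points - width


def run_window(curve: FractionCurve, start_index: int, width: int = 4) -> tuple:
    """(t_lo, t_hi) frame-start interval of a run of consecutive points."""
    return float(curve.t_start[start_index]), float(curve.t_start[start_index + width - 1])


def select_window(curves: list, width: int = 4) -> int:
    """Pick the run of ``width`` consecutive same-position frames with the
    least variation across all given curves.

    Runs are indexed by position-local frame index; the score of run i is
    the sum over curves of the within-run coefficient of variation.  Ties
    go to the latest run.  With the default schedule the quietest run is
    the late plateau (nominally 70/75-105 min after acquisition start).
    """
    if not curves:
        raise QuantifyError("no curves given")
    n = min(len(c) for c in curves)
    if n < width:
        raise QuantifyError("curves shorter than window width")
    best_idx, best_score = None, None
    for i in range(n - width + 1):
        score = 0.0
        for c in curves:
            vals = c.fraction[i:i + width]
            m = float(np.mean(vals))
            score += np.inf if m <= 0 else float(np.std(vals, ddof=1)) / m
        if best_score is None or score <= best_score:  # <= : ties go latest
            best_idx, best_score = i, score
    return best_idx
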