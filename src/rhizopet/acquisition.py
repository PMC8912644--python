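"""Forward model of two-position dynamic PET acquisition.

The scanner images an axial window of 95 voxels; a vertical moving table
alternates the plant between a lower and an upper position every frame
(5 min), extending the effective axial field of view.  Frames integrate the
true, physically decaying activity; decay correction is an analysis-side
step.  Image formation is emulated at the reconstructed-image level:
expected counts per structure are spread uniformly over the structure's
voxels inside the active window, blurred with a Gaussian PSF, and
Poisson-sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import _rng
from .kinetics import KineticModel
from .phantom import RootPhantom

log = logging.getLogger(__name__)

LOWER = "lower"
UPPER = "upper"

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class AcquisitionError(ValueError):
    pass


@dataclass(frozen=True)
class FrameSpec:
    t_start: float  # min
    t_end: float
    position: str  # LOWER | UPPER

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class AcquisitionConfig:
    frame_length: float = 5.0  # min
    total_duration: float = 110.0  # min
    window_voxels: int = 95  # axial extent of one reconstructed position
    offset_voxels: int = 70  # table shift between positions, voxels
    psf_fwhm_mm: float = 1.4  # intrinsic positron-range resolution limit
    count_scale: float = 10.0  # counts per Bq-equivalent * min
    noise: bool = True
    seed: int = 0

    def __post_init__(self):
        n = self.total_duration / self.frame_length
        if abs(n - round(n)) > 1e-9:
            raise AcquisitionError("total_duration must be divisible by frame_length")
        if self.psf_fwhm_mm < 0:
            raise AcquisitionError("psf_fwhm_mm must be >= 0")


@dataclass
class FrameSeries:
    """Time-ordered reconstructed frames of one measurement session.

    ``volumes[i]`` is the counts volume (x, y, z-window) of ``specs[i]``.
    """

    volumes: list
    specs: list

    def __post_init__(self):
        if len(self.volumes) != len(self.specs):
            raise AcquisitionError("volumes/specs length mismatch")
        for a, b in zip(self.specs[:-1], self.specs[1:]):
            if b.t_start < a.t_end:
                raise AcquisitionError("frames must be time-ordered and non-overlapping")

    def __len__(self):
        return len(self.specs)

    def frames_at(self, position: str):
        return [(v, s) for v, s in zip(self.volumes, self.specs) if s.position == position]


def make_schedule(cfg: AcquisitionConfig) -> list:
    """Alternating lower/upper frame schedule starting at the lower position.

    Defaults (110 min total, 5 min frames) give 11 lower + 11 upper frames.
    """
    n = int(round(cfg.total_duration / cfg.frame_length))
    return [
        FrameSpec(i * cfg.frame_length, (i + 1) * cfg.frame_length, LOWER if i % 2 == 0 else UPPER)
        for i in range(n)
    ]


def axial_coverage(single_fov_mm: float, shift_mm: float) -> float:
    """Length (mm) of the union of the two axial windows: [0, fov] and
    [shift, shift + fov].  Disjoint windows contribute both lengths."""
    if shift_mm < 0:
        raise AcquisitionError("shift must be >= 0")
    return float(single_fov_mm + min(shift_mm, single_fov_mm))


def window_bounds(cfg: AcquisitionConfig, position: str) -> tuple:
    """(z_lo, z_hi) voxel bounds of the active axial window, in grid coords."""
    if position == LOWER:
        return 0, cfg.window_voxels
    if position == UPPER:
        return cfg.offset_voxels, cfg.offset_voxels + cfg.window_voxels
    raise AcquisitionError(f"unknown position {position!r}")


def _structure_window_voxels(phantom: RootPhantom, cfg: AcquisitionConfig):
    """Per position: {structure_id: (n, 3) voxel indices inside the window,
    z shifted to window-local coordinates}.  Cached per phantom identity."""
    key = "_rhizopet_window_cache"
    cache = getattr(phantom, key, None)
    if cache is not None and cache[0] == (cfg.window_voxels, cfg.offset_voxels):
        return cache[1]
    out = {}
    for position in (LOWER, UPPER):
        z_lo, z_hi = window_bounds(cfg, position)
        table = {}
        for s in phantom.structures:
            vox = phantom.voxel_indices(s.id)
            sel = vox[(vox[:, 2] >= z_lo) & (vox[:, 2] < z_hi)]
            sel = sel.copy()
            sel[:, 2] -= z_lo
            table[s.id] = sel
        out[position] = table
    setattr(phantom, key, ((cfg.window_voxels, cfg.offset_voxels), out))
    return out


def render_frame(
    phantom: RootPhantom,
    model: KineticModel,
    session: int,
    frame: FrameSpec,
    cfg: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Expected (or Poisson-sampled) counts volume for one frame.

    Per structure, expected counts = count_scale * closed-form integral of
    the decaying activity over the frame, spread uniformly over the
    structure's voxels inside the active window, then blurred with the
    Gaussian PSF (reflective edges, applied per position window as
    reconstruction is per position).
    """
    if frame.t_end > cfg.total_duration + 1e-9:
        raise AcquisitionError("frame outside total_duration")
    nx, ny = phantom.grid_shape[:2]
    expected = np.zeros((nx, ny, cfg.window_voxels), dtype=float)
    tables = _structure_window_voxels(phantom, cfg)[frame.position]
    for s in phantom.structures:
        vox = tables[s.id]
        total_vox = len(phantom.voxel_indices(s.id))
        if total_vox == 0:
            continue
        if len(vox) == 0:
            other = UPPER if frame.position == LOWER else LOWER
            warned = getattr(phantom, "_warned_outside", set())
            if len(_structure_window_voxels(phantom, cfg)[other][s.id]) == 0 and s.id not in warned:
                warned.add(s.id)
                phantom._warned_outside = warned
                log.warning("structure %d lies outside both acquisition windows", s.id)
            continue
        counts = cfg.count_scale * model.activity_integral(s.id, frame.t_start, frame.t_end, session)
        # uniform specific activity: window voxels carry their share only
        expected[vox[:, 0], vox[:, 1], vox[:, 2]] += counts / total_vox
    if cfg.psf_fwhm_mm > 0:
        sigma = cfg.psf_fwhm_mm / _FWHM_TO_SIGMA / phantom.voxel_size
        expected = gaussian_filter(expected, sigma=sigma, mode="reflect")
    if cfg.noise:
        if rng is None:
            rng = _rng.stream(cfg.seed, _rng.ACQUISITION)
        return rng.poisson(expected).astype(np.int64)
    return expected


def simulate_session(
    phantom: RootPhantom,
    model: KineticModel,
    session: int,
    cfg: AcquisitionConfig,
    seed: int | None = None,
) -> FrameSeries:
    """Render the full alternating-position frame series of one session."""
    schedule = make_schedule(cfg)
    volumes = []
    for i, frame in enumerate(schedule):
        rng = _rng.stream(cfg.seed if seed is None else seed, _rng.ACQUISITION, session, i)
        volumes.append(render_frame(phantom, model, session, frame, cfg, rng=rng))
    return FrameSeries(volumes=volumes, specs=schedule)


def detector_trace(
    phantom: RootPhantom,
    model: KineticModel,
    schedule: list,
    compartment: str,
    session: int = 1,
) -> list:
    """Non-imaging scintillation-detector emulation.

    Returns per-frame records ``(t_mid, rate, usable)``: the decay-corrected
    mean count rate over the frame.  Because the moving table swaps what
    each detector sees, the root detector is usable only in lower-position
    frames and the shoot detector only in upper-position frames.
    """
    if not schedule:
        raise AcquisitionError("schedule is empty")
    if compartment not in ("root", "shoot_analog"):
        raise AcquisitionError(f"unknown compartment {compartment!r}")
    lam = model.lambda_decay
    out = []
    for frame in schedule:
        dt = frame.duration
        if compartment == "root":
            raw = sum(model.activity_integral(s.id, frame.t_start, frame.t_end, session) for s in phantom.structures)
            usable = frame.position == LOWER
        else:
            raw = model.shoot_activity_integral(frame.t_start, frame.t_end, session)
            usable = frame.position == UPPER
        # decay-correct the frame integral to reference time 0, then average
        denom = np.exp(-lam * frame.t_start) - np.exp(-lam * frame.t_end)
        rate = raw * lam / denom if denom > 0 else 0.0
        out.append((frame.t_mid, float(rate), usable))
    return out
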