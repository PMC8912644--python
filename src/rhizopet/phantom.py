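"""Voxelized nodulated-root phantom.

A stand-in for the MRI-derived structure of a pea root system grown in a
hydroponic pot: a primary root running down the axial (z) axis, lateral
roots branching from it, and a small number of spherical nodules attached
to the roots.  Each structure carries a dimensionless allocation weight —
its share of the total belowground carbon allocation — normalized so the
weights sum to exactly 1.

Geometry is in mm from the volume corner; the voxel grid is isotropic
(default 1.15 mm) and a voxel belongs to a structure when its *center*
falls inside the structure's geometry (sphere or capsule).  The default
grid is 61 x 61 x 166 voxels: tall enough that two 95-voxel acquisition
windows, offset by 70 voxels, tile the volume (the two-position moving
table geometry).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _rng

ROOT_SEGMENT = "root_segment"
NODULE = "nodule"


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class StructureSpec:
    """One labelled structure: a root segment (capsule) or a nodule (sphere).

    ``geometry`` is ``("segment", p0_mm, p1_mm, radius_mm)`` or
    ``("sphere", center_mm, radius_mm)``; all coordinates are mm from the
    volume corner.  ``allocation_weight`` is the structure's dimensionless
    share of total belowground tracer allocation.
    """

    id: int
    kind: str  # ROOT_SEGMENT or NODULE
    geometry: tuple
    allocation_weight: float

    def __post_init__(self):
        if self.kind not in (ROOT_SEGMENT, NODULE):
            raise PhantomError(f"unknown structure kind {self.kind!r}")
        if self.radius_mm <= 0:
            raise PhantomError(f"structure {self.id}: radius must be > 0")
        if self.allocation_weight < 0:
            raise PhantomError(f"structure {self.id}: allocation_weight must be >= 0")

    @property
    def radius_mm(self) -> float:
        return float(self.geometry[-1])


@dataclass
class RootPhantom:
    """Label volume plus structure table.

    ``label_volume[x, y, z]`` holds the integer structure id (0 = background).
    The axial axis is the third one and increases upward.
    """

    grid_shape: tuple
    voxel_size: float
    label_volume: np.ndarray
    structures: list = field(default_factory=list)

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if self.label_volume.shape != self.grid_shape:
            raise PhantomError("label_volume shape does not match grid_shape")
        ids = [s.id for s in self.structures]
        if len(ids) != len(set(ids)):
            raise PhantomError("structure labels must be unique")
        present = set(np.unique(self.label_volume)) - {0}
        if not present <= set(ids):
            raise PhantomError(f"labels without StructureSpec: {sorted(present - set(ids))}")
        total = sum(s.allocation_weight for s in self.structures)
        if self.structures and abs(total - 1.0) > 1e-9:
            raise PhantomError(f"allocation weights sum to {total}, expected 1")

    def structure(self, structure_id: int) -> StructureSpec:
        for s in self.structures:
            if s.id == structure_id:
                return s
        raise KeyError(f"unknown structure id {structure_id}")

    @property
    def nodules(self) -> list:
        return [s for s in self.structures if s.kind == NODULE]

    @property
    def root_segments(self) -> list:
        return [s for s in self.structures if s.kind == ROOT_SEGMENT]

    def voxel_indices(self, structure_id: int) -> np.ndarray:
        """(n, 3) voxel indices labelled with ``structure_id`` (cached)."""
        cache = self.__dict__.setdefault("_voxel_cache", {})
        if structure_id not in cache:
            cache[structure_id] = np.argwhere(self.label_volume == structure_id)
        return cache[structure_id]

    def center_voxel(self, structure_id: int) -> tuple:
        """Voxel index of a sphere center (nodules) or mask centroid."""
        s = self.structure(structure_id)
        if s.geometry[0] == "sphere":
            c = np.asarray(s.geometry[1], dtype=float)
            return tuple(int(v) for v in np.floor(c / self.voxel_size))
        vox = self.voxel_indices(structure_id)
        return tuple(int(v) for v in np.round(vox.mean(axis=0)))


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic root system.

    Defaults emulate the experimental geometry: a 61 x 61 x 166 grid of
    1.15 mm voxels (two 95-voxel windows with a 70-voxel shift), six
    PET-resolvable nodules, and 8% of total belowground allocation going
    to nodules in aggregate.
    """

    grid_shape: tuple = (61, 61, 166)
    voxel_size: float = 1.15
    n_nodules: int = 6
    n_laterals: int = 180
    primary_radius_mm: float = 1.5
    lateral_radius_range_mm: tuple = (0.9, 1.5)
    lateral_length_range_mm: tuple = (15.0, 40.0)
    pedicel_radius_mm: float = 0.6  # thin rootlet carrying each nodule
    pedicel_length_range_mm: tuple = (6.0, 10.0)
    nodule_radius_range_mm: tuple = (1.4, 2.2)
    nodule_allocation: float = 0.08  # summed nodule share of belowground allocation
    nodule_separation_voxels: float = 6.0  # min surface gap between nodules
    nodule_root_clearance_voxels: float = 3.0  # gap to non-pedicel roots (ROI separability)
    window_voxels: int = 95
    offset_voxels: int = 70
    edge_margin_voxels: int = 3  # keep nodules this far inside an acquisition window
    max_placement_tries: int = 200


def _voxel_centers_mm(grid_shape, voxel_size):
    axes = [(np.arange(n) + 0.5) * voxel_size for n in grid_shape]
    return axes


def _bbox_slices(grid_shape, voxel_size, lo_mm, hi_mm):
    idx = []
    for n, lo, hi in zip(grid_shape, lo_mm, hi_mm):
        i0 = max(int(np.floor(lo / voxel_size - 0.5)), 0)
        i1 = min(int(np.ceil(hi / voxel_size + 0.5)) + 1, n)
        idx.append(slice(i0, max(i1, i0)))
    return tuple(idx)


def rasterize_sphere(grid_shape, voxel_size, center_mm, radius_mm) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the sphere."""
    c = np.asarray(center_mm, dtype=float)
    mask = np.zeros(grid_shape, dtype=bool)
    sl = _bbox_slices(grid_shape, voxel_size, c - radius_mm, c + radius_mm)
    axes = [(np.arange(s.start, s.stop) + 0.5) * voxel_size for s in sl]
    d2 = (
        ((axes[0] - c[0]) ** 2)[:, None, None]
        + ((axes[1] - c[1]) ** 2)[None, :, None]
        + ((axes[2] - c[2]) ** 2)[None, None, :]
    )
    mask[sl] = d2 <= radius_mm ** 2
    return mask


def rasterize_segment(grid_shape, voxel_size, p0_mm, p1_mm, radius_mm) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within a capsule around p0-p1."""
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    lo = np.minimum(p0, p1) - radius_mm
    hi = np.maximum(p0, p1) + radius_mm
    mask = np.zeros(grid_shape, dtype=bool)
    sl = _bbox_slices(grid_shape, voxel_size, lo, hi)
    axes = [(np.arange(s.start, s.stop) + 0.5) * voxel_size for s in sl]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0.0:
        d2 = ((pts - p0) ** 2).sum(axis=-1)
    else:
        t = np.clip(((pts - p0) @ v) / vv, 0.0, 1.0)
        proj = p0[None, None, None, :] + t[..., None] * v[None, None, None, :]
        d2 = ((pts - proj) ** 2).sum(axis=-1)
    mask[sl] = d2 <= radius_mm ** 2
    return mask


def _point_segment_distance(p, a, b) -> float:
    p, a, b = (np.asarray(x, dtype=float) for x in (p, a, b))
    v = b - a
    vv = float(v @ v)
    t = 0.0 if vv == 0 else float(np.clip((p - a) @ v / vv, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * v)))


def _nodule_z_ok(z_mm, r_mm, cfg: PhantomConfig) -> bool:
    # nodule must sit entirely inside one acquisition window, a safety
    # margin away from the window edge (blur containment)
    vs = cfg.voxel_size
    lo, hi = (z_mm - r_mm) / vs, (z_mm + r_mm) / vs
    m = cfg.edge_margin_voxels
    in_lower = lo >= m and hi <= cfg.window_voxels - m
    in_upper = lo >= cfg.offset_voxels + m and hi <= cfg.offset_voxels + cfg.window_voxels - m
    return in_lower or in_upper


def build_phantom(config: PhantomConfig | None = None, seed: int = 0) -> RootPhantom:
    """Generate a nodulated-root phantom, deterministic for a fixed seed.

    The primary root is a connected chain of axial segments with small
    lateral jitter; laterals branch from it at random heights and grow
    outward/downward; nodules are spheres attached to the laterals (or the
    primary root when there are no laterals).  Allocation weights give
    ``config.nodule_allocation`` to the nodules in aggregate (equal split
    with mild jitter) and the remainder to root segments in proportion to
    their voxel volume; weights are normalized to sum to exactly 1.

    Raises ``PhantomError`` naming the structure if a nodule cannot be
    placed without overlapping another nodule after bounded retries.
    """
    cfg = config or PhantomConfig()
    if min(cfg.grid_shape) <= 0 or cfg.voxel_size <= 0:
        raise PhantomError("grid and voxel size must be positive")
    if cfg.n_nodules < 0:
        raise PhantomError("nodule count must be >= 0")
    rng = _rng.stream(seed, _rng.PHANTOM)
    vs = cfg.voxel_size
    nx, ny, nz = cfg.grid_shape
    ext = np.array([nx, ny, nz], dtype=float) * vs  # physical extents, mm

    structures: list[StructureSpec] = []
    masks: dict[int, np.ndarray] = {}
    next_id = 1

    # primary root: chain of axial segments from near the top to near the bottom
    z_top, z_bot = 0.94 * ext[2], 0.05 * ext[2]
    n_chain = 6
    zs = np.linspace(z_top, z_bot, n_chain + 1)
    xy = np.array([ext[0] / 2, ext[1] / 2])
    pts = []
    for i, z in enumerate(zs):
        jitter = rng.uniform(-1.5, 1.5, size=2) if 0 < i < n_chain else np.zeros(2)
        pts.append(np.array([xy[0] + jitter[0], xy[1] + jitter[1], z]))
    primary_ids = []
    for a, b in zip(pts[:-1], pts[1:]):
        m = rasterize_segment(cfg.grid_shape, vs, a, b, cfg.primary_radius_mm)
        structures.append(StructureSpec(next_id, ROOT_SEGMENT, ("segment", tuple(a), tuple(b), cfg.primary_radius_mm), 0.0))
        masks[next_id] = m
        primary_ids.append(next_id)
        next_id += 1

    # laterals: branch from random points on the primary chain and grow
    # outward/downward, giving a dense fibrous root background
    lateral_anchors = []
    for _ in range(cfg.n_laterals):
        u = rng.uniform(0.05, 0.95)
        zi = z_top + u * (z_bot - z_top)
        # interpolate the chain point at this height
        t = (zi - zs[0]) / (zs[-1] - zs[0]) * n_chain
        i0 = int(np.clip(np.floor(t), 0, n_chain - 1))
        frac = t - i0
        anchor = pts[i0] * (1 - frac) + pts[i0 + 1] * frac
        az = rng.uniform(0, 2 * np.pi)
        radius = rng.uniform(*cfg.lateral_radius_range_mm)
        length = rng.uniform(*cfg.lateral_length_range_mm)
        dip = rng.uniform(0.3, 0.8)  # downward component
        direction = np.array([np.cos(az), np.sin(az), -dip])
        direction /= np.linalg.norm(direction)
        end = anchor + direction * length
        margin = radius + vs
        end = np.clip(end, margin, ext - margin)
        m = rasterize_segment(cfg.grid_shape, vs, anchor, end, radius)
        structures.append(StructureSpec(next_id, ROOT_SEGMENT, ("segment", tuple(anchor), tuple(end), radius), 0.0))
        masks[next_id] = m
        lateral_anchors.append((anchor, end))
        next_id += 1

    # nodules: spheres at the tip of short thin pedicel rootlets branching
    # off a lateral (so a nodule ROI contains as few root voxels as possible)
    hosts = lateral_anchors or [(pts[i], pts[i + 1]) for i in range(n_chain)]
    nodule_centers: list[tuple[np.ndarray, float]] = []
    for j in range(cfg.n_nodules):
        placed = False
        for _ in range(cfg.max_placement_tries):
            a, b = hosts[rng.integers(len(hosts))]
            u = rng.uniform(0.2, 0.95)
            p = a + u * (b - a)
            r = rng.uniform(*cfg.nodule_radius_range_mm)
            az = rng.uniform(0, 2 * np.pi)
            dip = rng.uniform(-0.3, 0.3)
            direction = np.array([np.cos(az), np.sin(az), dip])
            direction /= np.linalg.norm(direction)
            ped_len = rng.uniform(*cfg.pedicel_length_range_mm)
            ped_end = p + direction * ped_len
            c = ped_end + direction * 0.8 * r  # nodule just touching the rootlet tip
            margin = r + vs
            if np.any(c < margin) or np.any(c > ext - margin):
                continue
            if np.any(ped_end < cfg.pedicel_radius_mm + vs) or np.any(ped_end > ext - cfg.pedicel_radius_mm - vs):
                continue
            if not _nodule_z_ok(c[2], r, cfg):
                continue
            # nodules must stay pairwise disjoint and PET-separable
            sep = cfg.nodule_separation_voxels * vs
            if any(np.linalg.norm(c - c2) < r + r2 + sep for c2, r2 in nodule_centers):
                continue
            # and clear of every root except their own pedicel, so the
            # (dilated) ROI picks up as little root signal as possible
            clearance = r + cfg.nodule_root_clearance_voxels * vs
            if any(
                _point_segment_distance(c, s.geometry[1], s.geometry[2]) < clearance + s.radius_mm
                for s in structures
                if s.kind == ROOT_SEGMENT
            ):
                continue
            structures.append(
                StructureSpec(next_id, ROOT_SEGMENT, ("segment", tuple(p), tuple(ped_end), cfg.pedicel_radius_mm), 0.0)
            )
            masks[next_id] = rasterize_segment(cfg.grid_shape, vs, p, ped_end, cfg.pedicel_radius_mm)
            next_id += 1
            m = rasterize_sphere(cfg.grid_shape, vs, c, r)
            structures.append(StructureSpec(next_id, NODULE, ("sphere", tuple(c), r), 0.0))
            masks[next_id] = m
            nodule_centers.append((c, r))
            next_id += 1
            placed = True
            break
        if not placed:
            raise PhantomError(f"could not place nodule {j + 1} without collision after {cfg.max_placement_tries} tries")

    # paint labels: roots first, nodules on top (a nodule overrides adjacent root voxels)
    label = np.zeros(cfg.grid_shape, dtype=np.int32)
    for s in structures:
        if s.kind == ROOT_SEGMENT:
            label[masks[s.id]] = s.id
    for s in structures:
        if s.kind == NODULE:
            label[masks[s.id]] = s.id

    # allocation weights: nodules share `nodule_allocation` (equal with mild
    # jitter), root segments share the rest in proportion to voxel volume
    nodule_ids = [s.id for s in structures if s.kind == NODULE]
    root_ids = [s.id for s in structures if s.kind == ROOT_SEGMENT]
    weights = {}
    if nodule_ids:
        w = rng.uniform(0.8, 1.2, size=len(nodule_ids))
        w *= cfg.nodule_allocation / w.sum()
        weights.update(dict(zip(nodule_ids, w)))
        root_total = 1.0 - cfg.nodule_allocation
    else:
        root_total = 1.0
    vols = np.array([max(int(np.count_nonzero(label == i)), 1) for i in root_ids], dtype=float)
    wr = root_total * vols / vols.sum()
    weights.update(dict(zip(root_ids, wr)))
    # exact renormalization against float drift
    total = sum(weights.values())
    weights = {i: w / total for i, w in weights.items()}

    structures = [dataclasses.replace(s, allocation_weight=weights[s.id]) for s in structures]
    return RootPhantom(cfg.grid_shape, vs, label, structures)
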