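"""File formats and run configuration.

Frames travel as 4D NIfTI (x, y, z-window, frame) with a JSON sidecar for
PET frame timing (NIfTI has no native frame-time field); masks as uint8
NIfTI; phantoms as int32 label NIfTI plus a JSON structure/kinetics table;
measurement records and report tables as CSV.  The run configuration is a
pydantic model whose JSON Schema is published via ``RunConfig.schema_json``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .acquisition import AcquisitionConfig, FrameSeries, FrameSpec
from .kinetics import KineticModel, KineticsConfig, StructureKinetics
from .phantom import PhantomConfig, RootPhantom, StructureSpec
from .quantify import ROI
from .stats import MeasurementRecord


class FormatError(ValueError):
    pass


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


# ---------------------------------------------------------------------------
# frames


def write_frames(frames: FrameSeries, path: str, voxel_size: float = 1.15) -> None:
    """4D NIfTI volume stack + ``<path>.json`` timing sidecar."""
    path = Path(path)
    data = np.stack([np.asarray(v) for v in frames.volumes], axis=-1)
    nib.save(nib.Nifti1Image(data.astype(np.int32), _affine(voxel_size)), str(path))
    sidecar = {
        "frames": [
            {"t_start": s.t_start, "t_end": s.t_end, "position": s.position} for s in frames.specs
        ]
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_frames(path: str) -> FrameSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D volume, got shape {data.shape}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "frames" not in sidecar:
        raise FormatError(f"{sidecar_path}: missing key 'frames'")
    specs = []
    for i, f in enumerate(sidecar["frames"]):
        for key in ("t_start", "t_end", "position"):
            if key not in f:
                raise FormatError(f"{sidecar_path}: frame {i} missing key {key!r}")
        specs.append(FrameSpec(f["t_start"], f["t_end"], f["position"]))
    if len(specs) != data.shape[3]:
        raise FormatError(
            f"{path}: {data.shape[3]} volumes but {len(specs)} sidecar frames"
        )
    return FrameSeries(volumes=[data[..., i] for i in range(data.shape[3])], specs=specs)


# ---------------------------------------------------------------------------
# masks


def write_mask(roi: ROI, path: str, voxel_size: float = 1.15) -> None:
    nib.save(nib.Nifti1Image(roi.mask.astype(np.uint8), _affine(voxel_size)), str(path))
    meta = {"id": roi.id, "seed": list(roi.seed), "position": roi.position, "kind": roi.kind}
    Path(path).with_suffix(Path(path).suffix + ".json").write_text(json.dumps(meta))


def read_mask(path: str) -> ROI:
    path = Path(path)
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj).astype(bool)
    meta_path = path.with_suffix(path.suffix + ".json")
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("id", "seed", "position", "kind"):
        if key not in meta:
            raise FormatError(f"{meta_path}: missing key {key!r}")
    return ROI(meta["id"], tuple(meta["seed"]), meta["position"], mask, meta["kind"])


# ---------------------------------------------------------------------------
# phantom + kinetics


def write_phantom(ph: RootPhantom, model: KineticModel | None, path_base: str) -> None:
    """Label volume as int32 NIfTI, structures (+ kinetics) as JSON."""
    base = Path(path_base)
    nib.save(nib.Nifti1Image(ph.label_volume.astype(np.int32), _affine(ph.voxel_size)), str(base) + "_labels.nii")
    doc = {
        "grid_shape": list(ph.grid_shape),
        "voxel_size_mm": ph.voxel_size,
        "structures": [
            {
                "id": s.id,
                "kind": s.kind,
                "geometry": _geometry_doc(s),
                "allocation_weight": s.allocation_weight,
            }
            for s in ph.structures
        ],
    }
    if model is not None:
        doc["kinetics"] = {
            "lambda_decay_per_min": model.lambda_decay,
            "session_scales": list(map(float, model.session_scales)),
            "treatment_factor": model.treatment_factor,
            "treatment_start_session": model.treatment_start_session,
            "per_structure": {
                str(i): {"k_per_min": k.k, "delay_min": k.d, "weight": k.weight, "kind": k.kind}
                for i, k in model.structures.items()
            },
        }
    Path(str(base) + "_structures.json").write_text(json.dumps(doc, indent=1))


def read_phantom(path_base: str):
    """Inverse of ``write_phantom``; returns ``(phantom, model_or_None)``."""
    base = Path(path_base)
    label_path = Path(str(base) + "_labels.nii")
    doc_path = Path(str(base) + "_structures.json")
    if not label_path.exists() or not doc_path.exists():
        raise FormatError(f"missing phantom files at {base}_labels.nii / _structures.json")
    label = np.asarray(nib.load(str(label_path)).dataobj).astype(np.int32)
    doc = json.loads(doc_path.read_text())
    structures = []
    for s in doc["structures"]:
        g = s["geometry"]
        if g["type"] == "sphere":
            geometry = ("sphere", tuple(g["center_mm"]), g["radius_mm"])
        else:
            geometry = ("segment", tuple(g["p0_mm"]), tuple(g["p1_mm"]), g["radius_mm"])
        structures.append(StructureSpec(s["id"], s["kind"], geometry, s["allocation_weight"]))
    ph = RootPhantom(tuple(doc["grid_shape"]), doc["voxel_size_mm"], label, structures)
    model = None
    if "kinetics" in doc:
        kd = doc["kinetics"]
        model = KineticModel(
            structures={
                int(i): StructureKinetics(weight=v["weight"], k=v["k_per_min"], d=v["delay_min"], kind=v["kind"])
                for i, v in kd["per_structure"].items()
            },
            session_scales=np.asarray(kd["session_scales"]),
            lambda_decay=kd["lambda_decay_per_min"],
            treatment_factor=kd["treatment_factor"],
            treatment_start_session=kd["treatment_start_session"],
        )
    return ph, model


def _geometry_doc(s: StructureSpec):
    if s.geometry[0] == "sphere":
        return {"type": "sphere", "center_mm": list(s.geometry[1]), "radius_mm": s.geometry[2]}
    return {
        "type": "segment",
        "p0_mm": list(s.geometry[1]),
        "p1_mm": list(s.geometry[2]),
        "radius_mm": s.geometry[3],
    }


# ---------------------------------------------------------------------------
# records / tables

RECORD_COLUMNS = ["plant", "group", "dat", "session", "time_days", "roi", "mean_fraction", "sd_fraction"]


def write_records(records: list, path: str) -> None:
    rows = []
    for r in records:
        for roi_id, (mean, sd) in sorted(r.fractions.items()):
            rows.append(
                {
                    "plant": r.plant_id,
                    "group": r.group,
                    "dat": r.dat,
                    "session": r.session_index,
                    "time_days": r.session_time_days,
                    "roi": roi_id,
                    "mean_fraction": mean,
                    "sd_fraction": sd,
                }
            )
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records(path: str) -> list:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for (plant, session), g in df.groupby(["plant", "session"], sort=True):
        first = g.iloc[0]
        records.append(
            MeasurementRecord(
                plant_id=str(plant),
                dat=int(first["dat"]),
                session_index=int(session),
                session_time_days=float(first["time_days"]),
                fractions={
                    str(row["roi"]): (float(row["mean_fraction"]), float(row["sd_fraction"]))
                    for _, row in g.iterrows()
                },
                group=str(first["group"]),
            )
        )
    records.sort(key=lambda r: (r.plant_id, r.session_index))
    return records


DETECTOR_COLUMNS = ["session", "compartment", "t_mid", "rate", "usable"]


def write_detector_traces(rows: list, path: str) -> None:
    """Detector traces as CSV rows ``(session, compartment, t_mid, rate,
    usable)`` — the non-imaging shoot/root monitor emulation."""
    pd.DataFrame(rows, columns=DETECTOR_COLUMNS).to_csv(path, index=False)


def read_detector_traces(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTOR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_curves(curves: dict, path: str) -> None:
    """Fraction curves of one plant: CSV (session, roi_id, t_mid, value)."""
    rows = []
    for session, by_roi in sorted(curves.items()):
        for roi_id, c in sorted(by_roi.items()):
            for ts, tm, v in zip(c.t_start, c.t_mid, c.fraction):
                rows.append({"session": session, "roi_id": roi_id, "position": c.position, "t_start": ts, "t_mid": tm, "value": v})
    pd.DataFrame(rows, columns=["session", "roi_id", "position", "t_start", "t_mid", "value"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration


class RosterEntry(BaseModel):
    plant_id: str
    group: str = "control"
    seed: int

    @field_validator("group")
    @classmethod
    def _group(cls, v):
        if v not in ("control", "treatment"):
            raise ValueError("group must be 'control' or 'treatment'")
        return v


class RunConfig(BaseModel):
    """Validated run configuration; defaults reproduce the standard
    scenario: 2 control + 5 treated plants, 8 sessions on DAT 13-16,
    nitrate treatment effective from session 5."""

    grid_shape: tuple = (61, 61, 166)
    voxel_size_mm: float = 1.15
    n_nodules: int = 6
    nodule_allocation: float = 0.08
    window_voxels: int = 95  # axial voxels per reconstructed position
    offset_voxels: int = 70  # table shift between the two positions
    phantom_overrides: dict = Field(default_factory=dict)  # extra PhantomConfig fields
    base_scale: float = 1.0e5
    growth: float = 0.5
    n_sessions: int = 8
    sessions_per_day: int = 2
    dats: tuple = (13, 14, 15, 16)
    clock_hours: tuple = (8.0, 11.0)
    frame_length_min: float = 5.0
    total_duration_min: float = 110.0
    psf_fwhm_mm: float = 1.4
    count_scale: float = 10.0
    noise: bool = True
    treatment_factor: float = Field(0.545, gt=0, le=1)
    treatment_start_session: int = 5
    region_grow_threshold: float = Field(0.3, gt=0, le=1)
    window_mode: str = "global"
    window_width: int = 4
    change_method: str = "day-mean"
    roster: list = Field(
        default_factory=lambda: [
            RosterEntry(plant_id=f"ctrl_P{i + 1}", group="control", seed=i + 1).model_dump() for i in range(2)
        ]
        + [
            RosterEntry(plant_id=f"treat_P{i + 1}", group="treatment", seed=11 + i).model_dump() for i in range(5)
        ]
    )

    @field_validator("roster")
    @classmethod
    def _roster(cls, v):
        return [RosterEntry.model_validate(e).model_dump() for e in v]

    @field_validator("window_mode")
    @classmethod
    def _window(cls, v):
        if v in ("global", "per-plant") or v.startswith("fixed:"):
            return v
        raise ValueError("window_mode must be 'global', 'per-plant', or 'fixed:LO-HI'")

    @field_validator("change_method")
    @classmethod
    def _change(cls, v):
        if v not in ("day-mean", "regression"):
            raise ValueError("change_method must be 'day-mean' or 'regression'")
        return v

    def phantom_config(self) -> PhantomConfig:
        overrides = {
            k: tuple(v) if isinstance(v, list) else v for k, v in self.phantom_overrides.items()
        }
        return PhantomConfig(
            grid_shape=tuple(self.grid_shape),
            voxel_size=self.voxel_size_mm,
            n_nodules=self.n_nodules,
            nodule_allocation=self.nodule_allocation,
            window_voxels=self.window_voxels,
            offset_voxels=self.offset_voxels,
            **overrides,
        )

    def kinetics_config(self) -> KineticsConfig:
        return KineticsConfig(
            base_scale=self.base_scale,
            growth=self.growth,
            n_sessions=self.n_sessions,
            sessions_per_day=self.sessions_per_day,
        )

    def acquisition_config(self, seed: int = 0) -> AcquisitionConfig:
        return AcquisitionConfig(
            frame_length=self.frame_length_min,
            total_duration=self.total_duration_min,
            window_voxels=self.window_voxels,
            offset_voxels=self.offset_voxels,
            psf_fwhm_mm=self.psf_fwhm_mm,
            count_scale=self.count_scale,
            noise=self.noise,
            seed=seed,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]


def load_config(path: str | None) -> RunConfig:
    if path is None:
        return RunConfig()
    return RunConfig.model_validate(json.loads(Path(path).read_text()))
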