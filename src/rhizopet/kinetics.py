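"""Tracer kinetics: terminal-sink accumulation with physical decay.

Each structure i receives a share w_i of the belowground allocation and
accumulates tracer as a delayed mono-exponential rise to a plateau, while
the tracer itself decays physically (11C, half-life 20.4 min):

    A_i(t | m) = S_m * w_i(m) * (1 - exp(-k_i (t - d_i))) * exp(-lambda t)

for t > d_i, else 0.  t is minutes after the start of PET acquisition.
S_m is the per-session amplitude (day-to-day growth of root uptake),
k_i the accumulation rate (plateau, by the 95% convention, at d_i + 3/k_i),
d_i the arrival delay, and w_i(m) the allocation weight after any nitrate
treatment adjustment.  Structures only accumulate (no washout), so the
decay-corrected curve is nondecreasing — the terminal-sink picture.

A nitrate treatment from session m* scales every nodule weight by a factor
r in (0, 1] and redistributes the removed share onto the root segments in
proportion to their weights, conserving total belowground allocation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import _rng
from .phantom import NODULE, ROOT_SEGMENT, RootPhantom

HALF_LIFE_MIN = 20.4
LAMBDA_C11 = np.log(2.0) / HALF_LIFE_MIN  # min^-1


class KineticsError(ValueError):
    pass


@dataclass(frozen=True)
class StructureKinetics:
    weight: float  # baseline allocation share w_i
    k: float  # accumulation rate, min^-1 (> 0; np.inf = instantaneous)
    d: float  # arrival delay, min (>= 0)
    kind: str  # root_segment | nodule


@dataclass(frozen=True)
class KineticModel:
    """Per-structure kinetic parameters plus session scaling and treatment.

    ``session_scales[m-1]`` is S_m (Bq-equivalent amplitude) for session m
    (1-based).  ``treatment_factor`` r and ``treatment_start_session`` m*
    encode the nodule-allocation step; r = 1 or m* = None means untreated.
    """

    structures: dict  # id -> StructureKinetics
    session_scales: np.ndarray
    lambda_decay: float = LAMBDA_C11
    treatment_factor: float = 1.0
    treatment_start_session: int | None = None
    shoot_scale: float = 10.0  # shoot-analog amplitude relative to S_m
    shoot_k: float = 0.3  # min^-1, fast arrival in the shoot
    shoot_d: float = 0.0

    def __post_init__(self):
        if self.lambda_decay <= 0:
            raise KineticsError("lambda_decay must be > 0")
        scales = np.asarray(self.session_scales, dtype=float)
        if np.any(scales <= 0):
            raise KineticsError("session scales S_m must be > 0")
        object.__setattr__(self, "session_scales", scales)
        for i, s in self.structures.items():
            if s.k <= 0:
                raise KineticsError(f"structure {i}: k must be > 0")
            if s.d < 0:
                raise KineticsError(f"structure {i}: d must be >= 0")

    @property
    def n_sessions(self) -> int:
        return len(self.session_scales)

    def _kin(self, structure_id: int) -> StructureKinetics:
        try:
            return self.structures[structure_id]
        except KeyError:
            raise KeyError(f"unknown structure id {structure_id}") from None

    def _treated(self, session: int) -> bool:
        return (
            self.treatment_start_session is not None
            and session >= self.treatment_start_session
            and self.treatment_factor != 1.0
        )

    def weight(self, structure_id: int, session: int) -> float:
        """Allocation share w_i(m), after treatment redistribution."""
        s = self._kin(structure_id)
        if not self._treated(session):
            return s.weight
        r = self.treatment_factor
        w_nod = sum(x.weight for x in self.structures.values() if x.kind == NODULE)
        w_root = sum(x.weight for x in self.structures.values() if x.kind == ROOT_SEGMENT)
        if s.kind == NODULE:
            return r * s.weight
        # removed nodule share goes to roots, proportional to root weights
        return s.weight * (1.0 + (1.0 - r) * w_nod / w_root)

    def scale(self, session: int) -> float:
        if not 1 <= session <= self.n_sessions:
            raise KineticsError(f"session {session} outside 1..{self.n_sessions}")
        return float(self.session_scales[session - 1])

    def activity(self, structure_id: int, t, session: int):
        """Measured (decaying) activity A_i(t), Bq-equivalent."""
        s = self._kin(structure_id)
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise KineticsError("t must be >= 0")
        S = self.scale(session)
        w = self.weight(structure_id, session)
        rise = -np.expm1(-s.k * np.maximum(t - s.d, 0.0)) if np.isfinite(s.k) else (t > s.d).astype(float)
        out = S * w * rise * np.exp(-self.lambda_decay * t)
        return out if out.shape else float(out)

    def decay_corrected_activity(self, structure_id: int, t, session: int):
        """A_i(t) * exp(lambda t): the accumulation curve with physical
        decay removed (computed directly, stable for large t)."""
        s = self._kin(structure_id)
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise KineticsError("t must be >= 0")
        rise = -np.expm1(-s.k * np.maximum(t - s.d, 0.0)) if np.isfinite(s.k) else (t > s.d).astype(float)
        out = self.scale(session) * self.weight(structure_id, session) * rise
        return out if out.shape else float(out)

    def activity_integral(self, structure_id: int, t_start: float, t_end: float, session: int) -> float:
        """Closed form of the frame integral of A_i(t) over [t_start, t_end]."""
        if t_end < t_start or t_start < 0:
            raise KineticsError("need 0 <= t_start <= t_end")
        s = self._kin(structure_id)
        lam = self.lambda_decay
        a = max(t_start, s.d)
        b = t_end
        if b <= a:
            return 0.0
        S = self.scale(session)
        w = self.weight(structure_id, session)
        term_decay = (np.exp(-lam * a) - np.exp(-lam * b)) / lam
        if np.isfinite(s.k):
            kl = s.k + lam
            term_rise = np.exp(s.k * s.d) * (np.exp(-kl * a) - np.exp(-kl * b)) / kl
        else:
            term_rise = 0.0
        return float(S * w * (term_decay - term_rise))

    def shoot_activity(self, t, session: int):
        """Aboveground (shoot) analog activity, for the shoot detector trace."""
        t = np.asarray(t, dtype=float)
        S = self.scale(session) * self.shoot_scale
        rise = -np.expm1(-self.shoot_k * np.maximum(t - self.shoot_d, 0.0))
        out = S * rise * np.exp(-self.lambda_decay * t)
        return out if out.shape else float(out)

    def shoot_activity_integral(self, t_start: float, t_end: float, session: int) -> float:
        lam = self.lambda_decay
        a, b = max(t_start, self.shoot_d), t_end
        if b <= a:
            return 0.0
        S = self.scale(session) * self.shoot_scale
        kl = self.shoot_k + lam
        term = (np.exp(-lam * a) - np.exp(-lam * b)) / lam - np.exp(self.shoot_k * self.shoot_d) * (
            np.exp(-kl * a) - np.exp(-kl * b)
        ) / kl
        return float(S * term)


def apply_treatment(model: KineticModel, r: float, start_session: int) -> KineticModel:
    """Return a model whose nodule allocation is scaled by ``r`` from
    ``start_session`` on, with the removed share redistributed to roots."""
    if not 0 < r <= 1:
        raise KineticsError(f"treatment factor r={r} outside (0, 1]")
    return dataclasses.replace(model, treatment_factor=float(r), treatment_start_session=int(start_session))


@dataclass(frozen=True)
class KineticsConfig:
    """Defaults: plateau (95% convention) near 50 min for nodules
    (k = 0.06 min^-1, 3/k = 50 min), a short transport delay, mild
    structure-to-structure rate jitter, and session amplitude growing
    linearly by +50% from the first to the last measurement day."""

    base_scale: float = 1.0e5  # S_1, Bq-equivalent
    growth: float = 0.5  # fractional S growth first -> last day
    n_sessions: int = 8
    sessions_per_day: int = 2
    nodule_k: float = 0.06  # min^-1
    root_k: float = 0.07  # min^-1
    delay_min: float = 2.0
    k_jitter: float = 0.1  # relative sd of per-structure rate jitter
    d_jitter: float = 0.5  # absolute jitter on delay, min


def session_scales(cfg: KineticsConfig) -> np.ndarray:
    """S_m growing linearly with day (both sessions of a day share S_m)."""
    days = (np.arange(cfg.n_sessions) // cfg.sessions_per_day).astype(float)
    n_days = max(int(np.ceil(cfg.n_sessions / cfg.sessions_per_day)), 1)
    frac = days / max(n_days - 1, 1)
    return cfg.base_scale * (1.0 + cfg.growth * frac)


def build_kinetics(phantom: RootPhantom, config: KineticsConfig | None = None, seed: int = 0) -> KineticModel:
    """Assign per-structure kinetics from the phantom's allocation weights."""
    cfg = config or KineticsConfig()
    rng = _rng.stream(seed, _rng.KINETICS)
    structures = {}
    for s in phantom.structures:
        base_k = cfg.nodule_k if s.kind == NODULE else cfg.root_k
        k = base_k * float(np.exp(rng.normal(0.0, cfg.k_jitter))) if cfg.k_jitter > 0 else base_k
        d = max(cfg.delay_min + float(rng.uniform(-cfg.d_jitter, cfg.d_jitter)), 0.0)
        structures[s.id] = StructureKinetics(weight=s.allocation_weight, k=k, d=d, kind=s.kind)
    return KineticModel(structures=structures, session_scales=session_scales(cfg))
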