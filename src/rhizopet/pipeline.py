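"""End-to-end orchestration: simulate -> quantify -> stats.

One plant = one phantom + kinetic model + eight labelling sessions (two per
day on four consecutive days, DAT 13-16).  Treatment plants get their
nodule allocation scaled by the treatment factor from session 5 onward
(the nitrate exchange happens after day 2).  All randomness derives from
the single per-plant seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field


from . import acquisition, kinetics, phantom, quantify, stats
from .acquisition import LOWER, UPPER, AcquisitionConfig
from .kinetics import KineticsConfig
from .phantom import PhantomConfig


@dataclass(frozen=True)
class PlantSpec:
    plant_id: str
    group: str  # control | treatment
    seed: int


@dataclass
class PlantRun:
    """Quantification products of one plant."""

    spec: PlantSpec
    records: list = field(default_factory=list)  # MeasurementRecord per session
    fraction_curves: dict = field(default_factory=dict)  # session -> {roi_id: FractionCurve}
    rois: list = field(default_factory=list)


DEFAULT_DATS = (13, 14, 15, 16)
DEFAULT_CLOCK_HOURS = (8.0, 11.0)  # session start times within a day
DEFAULT_TREATMENT_FACTOR = 0.545
DEFAULT_TREATMENT_START = 5  # first session of day 3 (15 DAT)


def session_times_days(dats=DEFAULT_DATS, clock_hours=DEFAULT_CLOCK_HOURS):
    """Fractional-day time of each session since the first one."""
    t0 = dats[0] + clock_hours[0] / 24.0
    return [d + h / 24.0 - t0 for d in dats for h in clock_hours]


def simulate_plant(
    spec: PlantSpec,
    phantom_cfg: PhantomConfig | None = None,
    kin_cfg: KineticsConfig | None = None,
    treatment_factor: float = DEFAULT_TREATMENT_FACTOR,
    treatment_start: int = DEFAULT_TREATMENT_START,
):
    """Build the plant's phantom and kinetic model (treatment applied for
    treatment-group plants)."""
    ph = phantom.build_phantom(phantom_cfg or PhantomConfig(), seed=spec.seed)
    model = kinetics.build_kinetics(ph, kin_cfg or KineticsConfig(), seed=spec.seed)
    if spec.group == "treatment":
        model = kinetics.apply_treatment(model, treatment_factor, treatment_start)
    return ph, model


def quantify_plant(
    spec: PlantSpec,
    ph,
    model,
    acq_cfg: AcquisitionConfig | None = None,
    rel_threshold: float = 0.3,
    dats=DEFAULT_DATS,
    clock_hours=DEFAULT_CLOCK_HOURS,
) -> PlantRun:
    """Simulate every session and extract per-ROI fraction curves.

    ROIs are drawn once, on the session-1 reference images (the phantom is
    rigid, as the analysis requires), and reused for all sessions.
    Windowed means are *not* taken here — window selection may be global
    across plants (see ``finalize_records``).
    """
    acq_cfg = acq_cfg or AcquisitionConfig()
    if acq_cfg.seed != spec.seed:
        import dataclasses

        acq_cfg = dataclasses.replace(acq_cfg, seed=spec.seed)
    run = PlantRun(spec=spec)
    n_sessions = model.n_sessions
    totals_rois = quantify.whole_root_rois(ph, acq_cfg)
    for m in range(1, n_sessions + 1):
        frames = acquisition.simulate_session(ph, model, m, acq_cfg)
        if m == 1:
            run.rois = quantify.nodule_rois_from_truth(ph, frames, acq_cfg, rel_threshold=rel_threshold)
        totals = {
            p: quantify.extract_tac(frames, totals_rois[p], model.lambda_decay) for p in (LOWER, UPPER)
        }
        curves = {}
        for roi in run.rois:
            tac = quantify.extract_tac(frames, roi, model.lambda_decay)
            other = UPPER if roi.position == LOWER else LOWER
            curves[roi.id] = quantify.fraction_curve(tac, totals[roi.position], totals[other])
        run.fraction_curves[m] = curves
    times = session_times_days(dats, clock_hours)
    sessions_per_day = len(clock_hours)
    for m in range(1, n_sessions + 1):
        run.records.append(
            stats.MeasurementRecord(
                plant_id=spec.plant_id,
                dat=dats[(m - 1) // sessions_per_day],
                session_index=m,
                session_time_days=times[m - 1],
                fractions={},
                group=spec.group,
            )
        )
    return run


def finalize_records(runs: list, window_mode: str = "global", window_width: int = 4) -> None:
    """Fill per-ROI windowed mean fractions into every record, selecting the
    least-variation window globally across plants (default), per plant, or
    from a fixed ``"fixed:LO-HI"`` frame-start interval in minutes."""
    if window_mode == "global":
        pool = [c for run in runs for curves in run.fraction_curves.values() for c in curves.values()]
        idx = quantify.select_window(pool, window_width) if pool else 0
        modes = {id(run): idx for run in runs}
    elif window_mode == "per-plant":
        modes = {}
        for run in runs:
            pool = [c for curves in run.fraction_curves.values() for c in curves.values()]
            modes[id(run)] = quantify.select_window(pool, window_width) if pool else 0
    elif window_mode.startswith("fixed:"):
        lo, hi = (float(x) for x in window_mode[len("fixed:"):].split("-"))
        modes = None
    else:
        raise ValueError(f"unknown window mode {window_mode!r}")
    for run in runs:
        for rec in run.records:
            curves = run.fraction_curves[rec.session_index]
            fractions = {}
            for roi_id, curve in curves.items():
                if modes is None:
                    window = (lo, hi)
                else:
                    window = quantify.run_window(curve, modes[id(run)], window_width)
                fractions[roi_id] = quantify.mean_fraction(curve, window)
            rec.fractions = fractions


def run_plants(
    specs: list,
    phantom_cfg: PhantomConfig | None = None,
    kin_cfg: KineticsConfig | None = None,
    acq_cfg: AcquisitionConfig | None = None,
    treatment_factor: float = DEFAULT_TREATMENT_FACTOR,
    treatment_start: int = DEFAULT_TREATMENT_START,
    window_mode: str = "global",
    change_method: str = "day-mean",
    rel_threshold: float = 0.3,
):
    """Full pipeline for a plant roster; returns (runs, reports, table)."""
    runs = []
    for spec in specs:
        ph, model = simulate_plant(spec, phantom_cfg, kin_cfg, treatment_factor, treatment_start)
        runs.append(quantify_plant(spec, ph, model, acq_cfg, rel_threshold=rel_threshold))
    finalize_records(runs, window_mode=window_mode)
    reports = [stats.plant_report(run.records, change_method=change_method) for run in runs]
    return runs, reports, stats.build_table(reports)


def default_roster(n_control: int = 2, n_treatment: int = 5, control_seeds=None, treatment_seeds=None) -> list:
    """Paper-mimicking roster: 2 control + 5 treated plants."""
    control_seeds = control_seeds or list(range(1, n_control + 1))
    treatment_seeds = treatment_seeds or list(range(11, 11 + n_treatment))
    specs = [PlantSpec(f"ctrl_P{i + 1}", "control", s) for i, s in enumerate(control_seeds)]
    specs += [PlantSpec(f"treat_P{i + 1}", "treatment", s) for i, s in enumerate(treatment_seeds)]
    return specs
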