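"""Clinical-goal-driven iterative plan optimization.

Emulates how a dosimetrist steers an inverse plan: after every round of
fluence optimization and a full dose calculation, DVH statistics are
compared against the clinical goals; each failing goal escalates the
weight of its linked objective function by a factor between 1.2 and 3
that grows with the relative size of the violation, while organ-at-risk
objectives that are trivially satisfied (objective value exactly zero)
have their dose level tightened to 90% of the achieved statistic so
favourable geometries are not under-planned.  The loop repeats, 100
optimizer iterations per round, until every goal passes and nothing was
tightened, or a 600-iteration budget (6 rounds) is exhausted.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evalx
from .dose import (
    BeamletMatrix,
    DoseEngine,
    DoseGrid,
    OpenWeightPolicy,
    weight_open_beams,
)
from .geometry import (
    EnergyPolicy,
    TangentGeometry,
    build_tangent_geometry,
    make_imrt_beams,
)
from .objectives import FluenceMap, ObjectiveFunction, load_objectives_csv, optimize_fluence
from .phantom import PatientModel, downsample

__all__ = [
    "ClinicalGoal",
    "GoalLink",
    "EscalationPolicy",
    "LoopConfig",
    "LoopTrace",
    "RoundRecord",
    "Plan",
    "PlanReport",
    "link_goals_to_objectives",
    "evaluate_goals",
    "escalation_factor",
    "escalate_weights",
    "tighten_slack_objectives",
    "run_autoplan",
    "load_goals_csv",
]

GOAL_KINDS = ("min_dvh_dose", "max_dvh_volume", "max_mean", "max_dose", "min_dose")
MIN_KINDS = ("min_dvh_dose", "min_dose")

GOALS_HEADER = ["structure", "kind", "dose_cGy", "volume_pct", "strict"]


@dataclass(frozen=True)
class ClinicalGoal:
    """A DVH pass/fail criterion, e.g. lung V20Gy < 10% or PTV D95 > 4750."""

    structure: str
    kind: str
    dose_level: float  # cGy
    volume_level: float | None = None  # %
    strict: bool = True

    def __post_init__(self) -> None:
        if self.kind not in GOAL_KINDS:
            raise ValueError(f"unknown goal kind {self.kind!r}")
        if self.dose_level <= 0:
            raise ValueError("goal dose level must be positive")
        if self.kind in ("min_dvh_dose", "max_dvh_volume"):
            if self.volume_level is None or not (0.0 < self.volume_level <= 100.0):
                raise ValueError("dvh goals need volume_level in (0, 100]")

    @property
    def is_min_goal(self) -> bool:
        return self.kind in MIN_KINDS

    def describe(self) -> str:
        if self.kind == "min_dvh_dose":
            return f"{self.structure} D{self.volume_level:g}>{self.dose_level:g}cGy"
        if self.kind == "max_dvh_volume":
            return f"{self.structure} V{self.dose_level:g}cGy<{self.volume_level:g}%"
        op = ">" if self.is_min_goal else "<"
        stat = {"max_mean": "Mean", "max_dose": "Max", "min_dose": "Min"}[self.kind]
        return f"{self.structure} {stat}{op}{self.dose_level:g}cGy"


@dataclass(frozen=True)
class GoalLink:
    goal: ClinicalGoal
    objective_index: int  # index into the plan's objective list


@dataclass(frozen=True)
class EscalationPolicy:
    factor_min: float = 1.2
    factor_max: float = 3.0
    tighten_fraction: float = 0.9
    tighten_floor: float = 10.0  # cGy: don't tighten below negligible dose

    def __post_init__(self) -> None:
        if not 1.0 < self.factor_min <= self.factor_max:
            raise ValueError("need 1 < factor_min <= factor_max")
        if not 0.0 < self.tighten_fraction < 1.0:
            raise ValueError("tighten_fraction must be in (0, 1)")


@dataclass(frozen=True)
class LoopConfig:
    iterations_per_round: int = 100
    max_total_iterations: int = 600

    def __post_init__(self) -> None:
        if self.iterations_per_round <= 0 or self.max_total_iterations <= 0:
            raise ValueError("iteration counts must be positive")

    @property
    def max_rounds(self) -> int:
        return max(1, self.max_total_iterations // self.iterations_per_round)


@dataclass
class RoundRecord:
    round_index: int
    weights: dict[int, float]  # objective index -> weight used this round
    objective_trace: list[float]
    goal_results: list[dict]
    tightened: list[dict]
    escalated: list[dict]
    ptv_d95: float
    all_goals_met: bool


@dataclass
class LoopTrace:
    rounds: list[RoundRecord] = field(default_factory=list)
    status: str = ""
    total_iterations: int = 0


@dataclass
class Plan:
    geometry: TangentGeometry
    open_weights: dict[str, float]
    fluence: FluenceMap
    final_dose: DoseGrid
    open_dose: DoseGrid
    prescription: float
    fractions: int
    objectives: list[ObjectiveFunction]


@dataclass
class PlanReport:
    status: str
    prescription: float
    fractions: int
    goal_results: list[dict]
    metrics_raw: dict
    metrics_scaled: dict
    compliance: dict
    geometry: dict
    trace_summary: list[dict]

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "status": self.status,
            "prescription_cGy": self.prescription,
            "fractions": self.fractions,
            "goals": self.goal_results,
            "metrics_raw_cGy": self.metrics_raw,
            "metrics_scaled_to_5000": self.metrics_scaled,
            "protocol_compliance": self.compliance,
            "geometry": self.geometry,
            "rounds": self.trace_summary,
        }


# ---------------------------------------------------------------------------
# linking


def _metric_family(goal_kind: str) -> tuple[str, ...]:
    """Objective kinds compatible with a goal kind."""
    return {
        "min_dvh_dose": ("min_dvh", "min_dose"),
        "min_dose": ("min_dose", "min_dvh"),
        "max_dvh_volume": ("max_dvh", "max_dose"),
        "max_dose": ("max_dose", "max_dvh"),
        "max_mean": ("max_mean",),
    }[goal_kind]


def link_goals_to_objectives(
    goals: list[ClinicalGoal], objectives: list[ObjectiveFunction]
) -> tuple[list[GoalLink], list[ClinicalGoal]]:
    """Link each goal to its driving objective function.

    Candidates share the goal's structure and a compatible metric family;
    max-type goals only consider objectives at or below the goal's dose
    level (pushing harder than the goal requires), min-type goals only
    objectives at or above it.  Among candidates the closest dose level
    wins (ties to the lower objective index).  Returns the links and the
    goals that found no candidate.
    """
    links: list[GoalLink] = []
    unlinked: list[ClinicalGoal] = []
    for goal in goals:
        fams = _metric_family(goal.kind)
        best = None
        best_key = None
        for i, obj in enumerate(objectives):
            if obj.structure != goal.structure or obj.kind not in fams:
                continue
            if goal.is_min_goal:
                if obj.dose_level < goal.dose_level:
                    continue
            else:
                if obj.dose_level > goal.dose_level:
                    continue
            key = (abs(obj.dose_level - goal.dose_level), fams.index(obj.kind), i)
            if best_key is None or key < best_key:
                best, best_key = i, key
        if best is None:
            unlinked.append(goal)
        else:
            links.append(GoalLink(goal=goal, objective_index=best))
    return links, unlinked


# ---------------------------------------------------------------------------
# goal evaluation


def _achieved(goal: ClinicalGoal, dvh: evalx.DVHCurve) -> float:
    if goal.kind == "min_dvh_dose":
        return evalx.metric(dvh, f"d{goal.volume_level:g}")
    if goal.kind == "max_dvh_volume":
        return evalx.metric(dvh, f"V{goal.dose_level:g}")
    if goal.kind == "max_mean":
        return dvh.mean
    if goal.kind == "max_dose":
        return dvh.max
    return evalx.metric(dvh, "d100")  # min_dose


def evaluate_goals(
    dose: DoseGrid, patient: PatientModel, goals: list[ClinicalGoal]
) -> list[dict]:
    """Per-goal pass/fail, achieved value and relative proximity.

    Proximity is |achieved - limit| / limit with the limit on the scale
    of the compared statistic (dose for dose goals, % volume for
    V-goals).  With strict inequalities, achieved == limit fails.
    """
    results = []
    dvh_cache: dict[str, evalx.DVHCurve] = {}
    for goal in goals:
        if goal.structure not in dvh_cache:
            mask = patient.mask(goal.structure)  # raises naming the structure
            dvh_cache[goal.structure] = evalx.compute_dvh(
                dose, mask, structure=goal.structure
            )
        dvh = dvh_cache[goal.structure]
        achieved = _achieved(goal, dvh)
        if goal.kind == "max_dvh_volume":
            limit = goal.volume_level
        else:
            limit = goal.dose_level
        if goal.is_min_goal:
            ok = achieved > limit if goal.strict else achieved >= limit
        else:
            ok = achieved < limit if goal.strict else achieved <= limit
        proximity = abs(achieved - limit) / limit if limit > 0 else float(achieved > 0)
        results.append(
            {
                "goal": goal.describe(),
                "structure": goal.structure,
                "kind": goal.kind,
                "limit": float(limit),
                "achieved": float(achieved),
                "passed": bool(ok),
                "proximity": float(proximity),
            }
        )
    return results


# ---------------------------------------------------------------------------
# escalation & tightening


def escalation_factor(proximity: float, policy: EscalationPolicy | None = None) -> float:
    """Weight multiplier for a failing goal: linear in the relative
    violation, clamped to [factor_min, factor_max]."""
    policy = policy or EscalationPolicy()
    if proximity < 0:
        raise ValueError("proximity must be >= 0")
    span = policy.factor_max - policy.factor_min
    return float(np.clip(policy.factor_min + span * proximity, policy.factor_min, policy.factor_max))


def escalate_weights(
    links: list[GoalLink],
    goal_results: list[dict],
    objectives: list[ObjectiveFunction],
    policy: EscalationPolicy | None = None,
) -> tuple[list[ObjectiveFunction], list[dict]]:
    """Escalate every objective linked to a failing goal.

    When several failing goals share one objective it escalates once per
    round, by the largest applicable factor.  Returns the new objective
    list and a record of the escalations applied.
    """
    policy = policy or EscalationPolicy()
    by_desc = {r["goal"]: r for r in goal_results}
    factor_per_obj: dict[int, float] = {}
    for link in links:
        res = by_desc.get(link.goal.describe())
        if res is None or res["passed"]:
            continue
        f = escalation_factor(res["proximity"], policy)
        factor_per_obj[link.objective_index] = max(
            factor_per_obj.get(link.objective_index, 0.0), f
        )
    out = list(objectives)
    applied = []
    for i, f in sorted(factor_per_obj.items()):
        out[i] = replace(out[i], weight=out[i].weight * f)
        applied.append(
            {
                "objective_index": i,
                "structure": out[i].structure,
                "kind": out[i].kind,
                "factor": round(f, 6),
                "new_weight": out[i].weight,
            }
        )
    return out, applied


def _objective_statistic(obj: ObjectiveFunction, d: np.ndarray) -> float:
    """The dose statistic an objective constrains, on its structure dose."""
    if obj.kind == "max_dose":
        return float(d.max())
    if obj.kind == "max_mean":
        return float(d.mean())
    if obj.kind == "max_dvh":
        # dose received by volume_param % of the structure
        k = max(1, int(np.ceil(obj.volume_param / 100.0 * len(d))))
        return float(np.sort(d)[::-1][k - 1])
    raise ValueError(f"no tightening statistic for kind {obj.kind!r}")


def tighten_slack_objectives(
    objectives: list[ObjectiveFunction],
    objective_values: list[float],
    dose: DoseGrid,
    patient: PatientModel,
    policy: EscalationPolicy | None = None,
    *,
    value_tol: float = 1e-12,
) -> tuple[list[ObjectiveFunction], bool, list[dict]]:
    """Tighten trivially-met OAR objectives to 90% of the achieved dose.

    Only organ-at-risk objectives of max type with an objective value of
    exactly zero (within ``value_tol``) are tightened; targets are never
    touched, and achieved statistics below the policy's dose floor are
    left alone (there is nothing meaningful left to spare).
    """
    policy = policy or EscalationPolicy()
    out = list(objectives)
    changed = []
    for i, (obj, val) in enumerate(zip(objectives, objective_values)):
        if not obj.is_oar or val > value_tol:
            continue
        if not obj.kind.startswith("max"):
            continue
        d = dose.values[patient.mask(obj.structure)]
        achieved = _objective_statistic(obj, d)
        if achieved <= policy.tighten_floor:
            continue
        new_level = policy.tighten_fraction * achieved
        if new_level >= obj.dose_level:
            continue
        out[i] = replace(obj, dose_level=new_level)
        changed.append(
            {
                "objective_index": i,
                "structure": obj.structure,
                "kind": obj.kind,
                "old_dose_cGy": obj.dose_level,
                "achieved_cGy": achieved,
                "new_dose_cGy": new_level,
            }
        )
    return out, bool(changed), changed


# ---------------------------------------------------------------------------
# the loop


def _structure_indices(patient: PatientModel, names: set[str]) -> dict[str, np.ndarray]:
    return {n: np.flatnonzero(patient.mask(n).ravel()) for n in names}


def run_autoplan(
    patient: PatientModel,
    goals: list[ClinicalGoal] | str,
    objectives: list[ObjectiveFunction] | str,
    *,
    prescription: float = 5000.0,
    fractions: int = 25,
    open_policy: OpenWeightPolicy | None = None,
    escalation: EscalationPolicy | None = None,
    loop: LoopConfig | None = None,
    energy_policy: EnergyPolicy | None = None,
    optimization_downsample: int | None = None,
) -> tuple[Plan, PlanReport, LoopTrace]:
    """Run the full automated planning pipeline on one patient.

    Stages: tangent setup -> conformal open apertures and 85%/95%
    weighting -> beamlet matrices on the coarse optimization grid ->
    [100 optimizer iterations -> full fine-grid dose -> goal evaluation
    -> weight escalation / slack tightening] repeated until all goals
    pass with nothing tightened, or the iteration budget is exhausted.
    Deterministic for fixed inputs.
    """
    if isinstance(goals, str):
        goals = load_goals_csv(goals)
    if isinstance(objectives, str):
        objectives = load_objectives_csv(objectives)
    open_policy = open_policy or OpenWeightPolicy()
    escalation = escalation or EscalationPolicy()
    loop = loop or LoopConfig()

    geom = build_tangent_geometry(patient, energy_policy=energy_policy)
    engine_fine = DoseEngine(patient)
    open_weights, open_dose_fine = weight_open_beams(
        patient, geom.beams, prescription, open_policy, engine=engine_fine
    )

    if optimization_downsample is None:
        # optimize on ~5 mm voxels: halve fine grids, keep coarse ones
        optimization_downsample = 2 if patient.spacing < 0.4 else 1
    coarse = (
        downsample(patient, optimization_downsample)
        if optimization_downsample > 1
        else patient
    )
    engine_coarse = DoseEngine(coarse)
    imrt_beams = make_imrt_beams(geom)
    matrices = [engine_coarse.beamlet_matrix(b) for b in imrt_beams]
    open_dose_coarse = np.zeros(coarse.shape)
    per_angle: dict[float, list] = {}
    for b in geom.beams:
        per_angle.setdefault(round(b.gantry_angle, 6), []).append(b)
    for beams in per_angle.values():
        for b in beams:
            open_dose_coarse += engine_coarse.beam_dose(b).values * b.weight
    bg_coarse = open_dose_coarse.ravel()

    links, unlinked = link_goals_to_objectives(goals, objectives)
    struct_names = {o.structure for o in objectives}
    sidx = _structure_indices(coarse, struct_names)

    trace = LoopTrace()
    fluence = None
    w0 = None
    final_dose = open_dose_fine
    goal_results: list[dict] = []
    objs = [copy.copy(o) for o in objectives]

    for rnd in range(1, loop.max_rounds + 1):
        fluence, obj_trace = optimize_fluence(
            matrices,
            objs,
            bg_coarse,
            iterations=loop.iterations_per_round,
            structure_indices=sidx,
            initial=w0,
        )
        w0 = fluence.weights
        trace.total_iterations += len(obj_trace) - 1

        imrt_fine = np.zeros(patient.shape)
        for beam, (bid, sl) in zip(imrt_beams, fluence.blocks):
            fl = _fluence_to_lattice(engine_coarse, beam, fluence.weights[sl])
            imrt_fine += engine_fine.beam_dose(beam, fl).values
        final_dose = DoseGrid(
            open_dose_fine.values + imrt_fine, patient.spacing, patient.origin.copy()
        )

        goal_results = evaluate_goals(final_dose, patient, goals)
        obj_values = [
            _objective_value_fine(o, final_dose, patient) for o in objs
        ]
        objs_t, any_tightened, tightened = tighten_slack_objectives(
            objs, obj_values, final_dose, patient, escalation
        )
        all_met = all(r["passed"] for r in goal_results)

        ptv_dvh = evalx.compute_dvh(final_dose, patient.mask("PTV_planning"))
        record = RoundRecord(
            round_index=rnd,
            weights={i: o.weight for i, o in enumerate(objs)},
            objective_trace=[float(v) for v in obj_trace],
            goal_results=goal_results,
            tightened=tightened,
            escalated=[],
            ptv_d95=float(evalx.metric(ptv_dvh, "d95")),
            all_goals_met=all_met,
        )

        if all_met and not any_tightened:
            trace.rounds.append(record)
            break
        budget_left = trace.total_iterations + loop.iterations_per_round <= loop.max_total_iterations
        if not budget_left or rnd == loop.max_rounds:
            trace.rounds.append(record)
            break
        objs_e, escalated = escalate_weights(links, goal_results, objs_t, escalation)
        record.escalated = escalated
        trace.rounds.append(record)
        objs = objs_e

    trace.status = (
        "all-goals-met"
        if goal_results and all(r["passed"] for r in goal_results)
        else "max-iterations-reached"
    )

    plan = Plan(
        geometry=geom,
        open_weights=open_weights,
        fluence=fluence,
        final_dose=final_dose,
        open_dose=open_dose_fine,
        prescription=prescription,
        fractions=fractions,
        objectives=objs,
    )
    report = build_report(plan, patient, trace, goal_results, unlinked)
    return plan, report, trace


def _fluence_to_lattice(engine: DoseEngine, beam, w: np.ndarray) -> np.ndarray:
    """Reshape a flat beamlet weight vector onto the beam's pixel lattice."""
    u_edges, v_edges = DoseEngine.fluence_lattice(beam)
    open_px = DoseEngine.open_fluence(beam, u_edges, v_edges) > 0
    fl = np.zeros_like(open_px, dtype=float)
    fl[open_px] = w
    return fl


def _objective_value_fine(obj: ObjectiveFunction, dose: DoseGrid, patient: PatientModel) -> float:
    from .objectives import objective_value

    return objective_value(obj, dose, patient.mask(obj.structure))


def build_report(
    plan: Plan,
    patient: PatientModel,
    trace: LoopTrace,
    goal_results: list[dict],
    unlinked: list[ClinicalGoal],
) -> PlanReport:
    dvhs = evalx.structure_dvhs(plan.final_dose, patient)
    raw = {}
    scaled = {}
    metric_specs = {
        "PTV_planning": ("d98", "d95", "mean", "d2"),
        "PTV_Breast": ("d98", "d95", "mean", "d2"),
        "Ipsilateral Lung": ("V500", "V2000", "V3000", "mean", "d2"),
        "Contralateral Lung": ("mean", "d5"),
        "Heart": ("V2500", "V2000", "V1000", "mean", "d2"),
        "Contralateral Breast": ("mean", "d5", "d2"),
        "Body": ("max",),
    }
    for s, specs in metric_specs.items():
        if s not in dvhs:
            continue
        raw[s] = {m: round(float(evalx.metric(dvhs[s], m)), 2) for m in specs}
        sc = {}
        for m in specs:
            if m.startswith("V"):
                # on the 5000-scale the V-level maps back to level*Rx/5000
                level = float(m[1:]) * plan.prescription / evalx.REFERENCE_DOSE
                sc[m] = round(float(evalx.metric(dvhs[s], f"V{level:g}")), 2)
            else:
                sc[m] = round(
                    float(
                        evalx.scale_to_reference(
                            evalx.metric(dvhs[s], m), plan.prescription
                        )
                    ),
                    2,
                )
        scaled[s] = sc
    compliance = {}
    for name in evalx.PROTOCOL_NAMES:
        res = evalx.evaluate_protocol(dvhs, name, plan.prescription)
        compliance[name] = {
            "verdict": res.verdict,
            "regime": res.regime,
            "mode": "alternate",
            "constraints": res.constraints,
        }
    return PlanReport(
        status=trace.status,
        prescription=plan.prescription,
        fractions=plan.fractions,
        goal_results=goal_results
        + [{"goal": g.describe(), "unlinked": True} for g in unlinked],
        metrics_raw=raw,
        metrics_scaled=scaled,
        compliance=compliance,
        geometry=plan.geometry.to_dict(),
        trace_summary=[
            {
                "round": r.round_index,
                "objective_start": r.objective_trace[0],
                "objective_end": r.objective_trace[-1],
                "iterations": len(r.objective_trace) - 1,
                "ptv_d95_cGy": r.ptv_d95,
                "all_goals_met": r.all_goals_met,
                "escalations": r.escalated,
                "tightenings": r.tightened,
                "weights": {str(k): v for k, v in r.weights.items()},
            }
            for r in trace.rounds
        ],
    )


# ---------------------------------------------------------------------------
# CSV


def load_goals_csv(path) -> list[ClinicalGoal]:
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != GOALS_HEADER:
        raise ValueError(f"goals CSV must have header {','.join(GOALS_HEADER)}")
    out = []
    for row in df.itertuples(index=False):
        vol = None if pd.isna(row.volume_pct) else float(row.volume_pct)
        out.append(
            ClinicalGoal(
                structure=str(row.structure),
                kind=str(row.kind),
                dose_level=float(row.dose_cGy),
                volume_level=vol,
                strict=str(row.strict).strip().lower() in ("true", "1", "yes"),
            )
        )
    return out
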