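"""Goal linking, evaluation, escalation, tightening, and the planning loop."""

import numpy as np
import pytest

from tangentplan import default_goals_path, default_objectives_path
from tangentplan.autoloop import (
    ClinicalGoal,
    EscalationPolicy,
    LoopConfig,
    escalate_weights,
    escalation_factor,
    evaluate_goals,
    link_goals_to_objectives,
    load_goals_csv,
    run_autoplan,
    tighten_slack_objectives,
)
from tangentplan.dose import DoseGrid
from tangentplan.objectives import ObjectiveFunction
from tangentplan.phantom import PatientModel, PhantomConfig, generate_phantom


# ---------------------------------------------------------------------------
# linking


def test_linking_picks_closest_lower_dose_for_max_goals():
    goal = ClinicalGoal("Ipsilateral Lung", "max_dvh_volume", 3000, 10)
    objs = [
        ObjectiveFunction("Ipsilateral Lung", "max_dvh", 2000, 10, is_oar=True),
        ObjectiveFunction("Ipsilateral Lung", "max_dvh", 2800, 10, is_oar=True),
        ObjectiveFunction("Ipsilateral Lung", "max_dvh", 3200, 10, is_oar=True),
    ]
    links, unlinked = link_goals_to_objectives([goal], objs)
    assert not unlinked
    assert links[0].objective_index == 1  # 2800: closest not above 3000


def test_linking_min_goal_restricted_to_higher_doses():
    goal = ClinicalGoal("PTV_planning", "min_dvh_dose", 4750, 95)
    objs = [
        ObjectiveFunction("PTV_planning", "min_dose", 4500),
        ObjectiveFunction("PTV_planning", "min_dvh", 4750, 95),
    ]
    links, unlinked = link_goals_to_objectives([goal], objs)
    assert links[0].objective_index == 1


def test_linking_reports_unlinked_goals():
    goal = ClinicalGoal("Heart", "max_mean", 400)
    links, unlinked = link_goals_to_objectives([goal], [])
    assert links == [] and unlinked == [goal]


@pytest.mark.parametrize("seed", range(10))
def test_linking_matches_exhaustive_search(seed):
    """Randomized goal/objective sets: linking must equal an independent
    exhaustive closest-candidate search, and be a function (one link per
    goal, stable under re-run)."""
    rng = np.random.default_rng(seed)
    structures = ["A", "B", "C"]
    kinds = ["max_dvh", "max_dose", "max_mean", "min_dvh", "min_dose"]
    objs = [
        ObjectiveFunction(
            structure=rng.choice(structures),
            kind=str(rng.choice(kinds)),
            dose_level=float(rng.integers(5, 55) * 100),
            volume_param=float(rng.integers(1, 99)),
            weight=1.0,
        )
        for _ in range(8)
    ]
    goal_kinds = ["max_dvh_volume", "max_dose", "max_mean", "min_dvh_dose", "min_dose"]
    goals = [
        ClinicalGoal(
            structure=rng.choice(structures),
            kind=str(rng.choice(goal_kinds)),
            dose_level=float(rng.integers(5, 55) * 100),
            volume_level=float(rng.integers(1, 99)),
        )
        for _ in range(6)
    ]
    fam = {
        "min_dvh_dose": ("min_dvh", "min_dose"),
        "min_dose": ("min_dose", "min_dvh"),
        "max_dvh_volume": ("max_dvh", "max_dose"),
        "max_dose": ("max_dose", "max_dvh"),
        "max_mean": ("max_mean",),
    }
    links, unlinked = link_goals_to_objectives(goals, objs)
    links2, _ = link_goals_to_objectives(goals, objs)
    assert [l.objective_index for l in links] == [l.objective_index for l in links2]
    linked_goals = {id(l.goal) for l in links}
    for g in goals:
        cands = [
            (abs(o.dose_level - g.dose_level), fam[g.kind].index(o.kind), i)
            for i, o in enumerate(objs)
            if o.structure == g.structure
            and o.kind in fam[g.kind]
            and (o.dose_level >= g.dose_level if g.kind in ("min_dvh_dose", "min_dose")
                 else o.dose_level <= g.dose_level)
        ]
        got = [l.objective_index for l in links if l.goal is g]
        assert len(got) <= 1
        if not cands:
            assert g in unlinked
        else:
            assert got[0] == min(cands)[2]


# ---------------------------------------------------------------------------
# goal evaluation


def ten_voxel_patient(doses):
    shape = (10, 1, 1)
    ones = np.ones(shape, bool)
    structures = {
        "External": ones,
        "PTV_Breast": ones.copy(),
        "PTV_planning": ones.copy(),
        "Ipsilateral Lung": ones.copy(),
        "Contralateral Lung": np.zeros(shape, bool),
        "Heart": np.zeros(shape, bool),
        "Contralateral Breast": np.zeros(shape, bool),
    }
    p = PatientModel(
        density=np.ones(shape), structures=structures,
        tattoo=np.zeros(3), laterality="left", spacing=1.0, origin=np.zeros(3),
    )
    return p, DoseGrid(np.asarray(doses, float).reshape(shape), 1.0, np.zeros(3))


def test_goal_evaluation_v30_proximity():
    """8 of 10 voxels below 30 Gy: V30 = 20 fails a <10% goal with
    proximity |20-10|/10 = 1; V30 = 8%-equivalent passes at 0.2."""
    p, dose = ten_voxel_patient([1000] * 8 + [3200, 3300])
    goal = ClinicalGoal("Ipsilateral Lung", "max_dvh_volume", 3000, 10)
    (res,) = evaluate_goals(dose, p, [goal])
    assert not res["passed"]
    assert res["achieved"] == pytest.approx(20.0)
    assert res["proximity"] == pytest.approx(1.0)

    p, dose = ten_voxel_patient([1000] * 9 + [3200])
    goal = ClinicalGoal("Ipsilateral Lung", "max_dvh_volume", 3000, 12.5)
    (res,) = evaluate_goals(dose, p, [goal])
    assert res["passed"]
    assert res["proximity"] == pytest.approx(abs(10 - 12.5) / 12.5)


def test_goal_strict_equality_fails():
    p, dose = ten_voxel_patient([5000] * 10)
    goal = ClinicalGoal("PTV_planning", "max_dose", 5000, strict=True)
    (res,) = evaluate_goals(dose, p, [goal])
    assert not res["passed"]


def test_goal_max_dose_passes_under_limit():
    p, dose = ten_voxel_patient([5000] * 10)
    goal = ClinicalGoal("PTV_planning", "max_dose", 5500)
    (res,) = evaluate_goals(dose, p, [goal])
    assert res["passed"]


def test_goal_missing_structure_names_it():
    p, dose = ten_voxel_patient([100] * 10)
    goal = ClinicalGoal("Spinal Cord", "max_dose", 4500)
    with pytest.raises(KeyError, match="Spinal Cord"):
        evaluate_goals(dose, p, [goal])


# ---------------------------------------------------------------------------
# escalation


@pytest.mark.parametrize(
    "proximity, expected",
    [(0.0, 1.2), (0.5, 2.1), (1.0, 3.0), (5.0, 3.0)],
)
def test_escalation_factor_linear_clamped(proximity, expected):
    assert escalation_factor(proximity) == pytest.approx(expected)


def test_escalation_factor_rejects_negative():
    with pytest.raises(ValueError):
        escalation_factor(-0.1)


def test_escalation_weight_100_factor_2_gives_200():
    goal = ClinicalGoal("PTV_planning", "min_dvh_dose", 4750, 95)
    obj = ObjectiveFunction("PTV_planning", "min_dvh", 4750, 95, weight=100)
    links, _ = link_goals_to_objectives([goal], [obj])
    results = [
        {"goal": goal.describe(), "passed": False,
         "proximity": (2.0 - 1.2) / 1.8}  # proximity chosen so factor == 2
    ]
    out, applied = escalate_weights(links, results, [obj])
    assert out[0].weight == pytest.approx(200.0)
    assert applied[0]["factor"] == pytest.approx(2.0)


def test_escalation_leaves_passing_and_unlinked_untouched():
    g1 = ClinicalGoal("A", "max_mean", 400)
    g2 = ClinicalGoal("B", "max_mean", 300)
    objs = [
        ObjectiveFunction("A", "max_mean", 350, weight=10, is_oar=True),
        ObjectiveFunction("B", "max_mean", 250, weight=10, is_oar=True),
        ObjectiveFunction("C", "max_mean", 100, weight=10, is_oar=True),
    ]
    links, _ = link_goals_to_objectives([g1, g2], objs)
    results = [
        {"goal": g1.describe(), "passed": True, "proximity": 0.3},
        {"goal": g2.describe(), "passed": False, "proximity": 0.25},
    ]
    out, applied = escalate_weights(links, results, objs)
    assert out[0].weight == 10  # passing goal untouched
    assert out[1].weight == pytest.approx(10 * (1.2 + 1.8 * 0.25))
    assert out[2].weight == 10  # unlinked objective never changes
    # brute-force recomputation of the bookkeeping
    assert {a["objective_index"] for a in applied} == {1}


# ---------------------------------------------------------------------------
# tightening


def test_tighten_slack_oar_objective():
    p, dose = ten_voxel_patient([1500] * 10)
    obj = ObjectiveFunction("Ipsilateral Lung", "max_dose", 2000, is_oar=True)
    out, flag, changed = tighten_slack_objectives([obj], [0.0], dose, p)
    assert flag
    assert out[0].dose_level == pytest.approx(0.9 * 1500)
    assert changed[0]["achieved_cGy"] == pytest.approx(1500)


def test_tighten_skips_violated_and_target_objectives():
    p, dose = ten_voxel_patient([1500] * 10)
    oar = ObjectiveFunction("Ipsilateral Lung", "max_dose", 2000, is_oar=True)
    tgt = ObjectiveFunction("PTV_planning", "max_dose", 2000, is_oar=False)
    out, flag, _ = tighten_slack_objectives([oar, tgt], [0.1, 0.0], dose, p)
    assert not flag
    assert out[0].dose_level == 2000 and out[1].dose_level == 2000


def test_tighten_respects_dose_floor():
    p, dose = ten_voxel_patient([5.0] * 10)
    obj = ObjectiveFunction("Ipsilateral Lung", "max_dose", 2000, is_oar=True)
    out, flag, _ = tighten_slack_objectives([obj], [0.0], dose, p)
    assert not flag


def test_tighten_max_dvh_uses_dose_at_volume():
    p, dose = ten_voxel_patient([100, 200, 300, 400, 500, 600, 700, 800, 900, 1000])
    obj = ObjectiveFunction("Ipsilateral Lung", "max_dvh", 2000, volume_param=20, is_oar=True)
    out, flag, changed = tighten_slack_objectives([obj], [0.0], dose, p)
    # dose to the hottest 20% (2 voxels) is 900 cGy
    assert flag
    assert changed[0]["achieved_cGy"] == pytest.approx(900)
    assert out[0].dose_level == pytest.approx(810)


# ---------------------------------------------------------------------------
# policies


def test_policy_validation():
    with pytest.raises(ValueError):
        EscalationPolicy(factor_min=0.9)
    with pytest.raises(ValueError):
        EscalationPolicy(tighten_fraction=1.0)
    with pytest.raises(ValueError):
        LoopConfig(iterations_per_round=0)
    with pytest.raises(ValueError):
        ClinicalGoal("s", "max_dvh_volume", 2000, volume_level=None)


# ---------------------------------------------------------------------------
# the loop (on the small coarse phantom for speed)


def test_unsatisfiable_goal_runs_six_rounds_with_monotone_weights(coarse_patient, tmp_path):
    # a coverage goal far beyond what any fluence can deliver under the
    # competing max-dose objective: the loop must exhaust its budget
    goals = [ClinicalGoal("PTV_planning", "min_dvh_dose", 20000, 95)]
    objs = [
        ObjectiveFunction("PTV_planning", "min_dvh", 20000, 95, weight=100),
        ObjectiveFunction("PTV_planning", "max_dose", 5350, weight=20),
    ]
    plan, report, trace = run_autoplan(
        coarse_patient, goals, objs, prescription=5000.0
    )
    assert trace.status == "max-iterations-reached"
    assert len(trace.rounds) == 6
    assert trace.total_iterations <= 600
    weights = [r.weights[0] for r in trace.rounds]
    assert all(b > a for a, b in zip(weights, weights[1:]))
    # factors implied by consecutive weights stay within [1.2, 3]
    for a, b in zip(weights, weights[1:]):
        assert 1.2 - 1e-9 <= b / a <= 3.0 + 1e-9


def test_autoplan_is_deterministic(coarse_patient):
    args = (coarse_patient, default_goals_path(), default_objectives_path())
    p1, r1, t1 = run_autoplan(*args)
    p2, r2, t2 = run_autoplan(*args)
    assert np.array_equal(p1.final_dose.values, p2.final_dose.values)
    assert t1.status == t2.status
    assert [r.weights for r in t1.rounds] == [r.weights for r in t2.rounds]
    assert [r.objective_trace for r in t1.rounds] == [
        r.objective_trace for r in t2.rounds
    ]


def test_goals_csv_round_trip(tmp_path):
    goals = load_goals_csv(default_goals_path())
    assert any(g.kind == "min_dvh_dose" and g.structure == "PTV_planning" for g in goals)
    bad = tmp_path / "bad.csv"
    bad.write_text("x,y\n1,2\n")
    with pytest.raises(ValueError):
        load_goals_csv(bad)
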