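"""tangentplan: automated hybrid-IMRT tangential breast planning.

Single-click planning on synthetic voxel phantoms: tangent beam
construction from border points, open conformal segments weighted to
85% of prescription, fluence optimization on top of the open-field
background, and a clinical-goal-driven loop that escalates objective
weights and tightens slack organ-at-risk objectives until the plan
meets its goals.
"""

from .phantom import (
    PatientModel,
    PhantomConfig,
    erode_to_planning_ptv,
    generate_phantom,
    load_phantom,
    save_phantom,
)
from .geometry import (
    Beam,
    BorderPoints,
    EnergyPolicy,
    TangentGeometry,
    build_tangent_geometry,
    compute_borders,
    fit_conformal_apertures,
    isocenter_position,
    lateral_gantry_angle,
    medial_gantry_angle,
    optimize_tangent,
    select_energies,
)
from .dose import (
    BeamletMatrix,
    DoseEngine,
    DoseGrid,
    DosePhysics,
    OpenWeightPolicy,
    compute_beam_dose,
    compute_beamlet_matrix,
    weight_open_beams,
)
from .objectives import (
    FluenceMap,
    ObjectiveFunction,
    load_objectives_csv,
    objective_value,
    optimize_fluence,
)
from .autoloop import (
    ClinicalGoal,
    EscalationPolicy,
    GoalLink,
    LoopConfig,
    LoopTrace,
    Plan,
    PlanReport,
    escalate_weights,
    escalation_factor,
    evaluate_goals,
    link_goals_to_objectives,
    load_goals_csv,
    run_autoplan,
    tighten_slack_objectives,
)
from .evalx import (
    ComplianceResult,
    DVHCurve,
    ProtocolTable,
    cohort_dvh_band,
    compute_dvh,
    evaluate_protocol,
    load_protocol,
    metric,
    scale_to_reference,
    structure_dvhs,
)

__version__ = "0.1.0"


def default_goals_path() -> str:
    """Path of the shipped default clinical-goals CSV (5000 cGy regime)."""
    from importlib import resources

    return str(resources.files("tangentplan.resources") / "goals_breast_5000.csv")


def default_objectives_path() -> str:
    """Path of the shipped default objective-template CSV."""
    from importlib import resources

    return str(resources.files("tangentplan.resources") / "objectives_breast_5000.csv")
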