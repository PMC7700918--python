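"""DVH metrics, dose-regime scaling and protocol compliance.

Metric conventions: ``V(d)`` is the percentage of a structure's volume
receiving at least ``d`` (closed threshold); ``dXX`` is the minimum dose
received by the hottest XX% of the volume, read off the cumulative DVH
with linear interpolation between bins (on plateaus the highest dose
still covering XX% is returned).  Plans prescribed under the
hypofractionated 4240 cGy regime are compared either against the
parenthesized alternate constraint levels of the protocol tables
(default) or after linear scaling of all metrics to the 5000 cGy
reference regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as importlib_resources

import numpy as np
import pandas as pd

from .dose import DoseGrid
from .phantom import PatientModel

__all__ = [
    "DVHCurve",
    "ProtocolTable",
    "ComplianceResult",
    "compute_dvh",
    "metric",
    "scale_to_reference",
    "evaluate_protocol",
    "cohort_dvh_band",
    "load_protocol",
    "PROTOCOL_NAMES",
    "structure_dvhs",
]

PROTOCOL_NAMES = ("EviQ", "RTOG1005", "LondonCancer")
REFERENCE_DOSE = 5000.0


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    dose: np.ndarray  # bin left edges, cGy, uniform
    volume: np.ndarray  # % of structure receiving >= dose
    structure: str
    voxel_count: int
    mean: float
    max: float

    def __post_init__(self) -> None:
        if self.volume[0] != 100.0:
            raise ValueError("cumulative DVH must start at 100%")
        if (np.diff(self.volume) > 1e-9).any():
            raise ValueError("cumulative DVH must be non-increasing")


def compute_dvh(
    dose: DoseGrid | np.ndarray,
    mask: np.ndarray,
    bin_width: float = 1.0,
    structure: str = "",
) -> DVHCurve:
    """Cumulative DVH by voxel counting (default 1 cGy bins)."""
    values = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose)
    d = values[mask]
    if d.size == 0:
        raise ValueError(f"empty structure mask {structure!r} in DVH computation")
    top = float(d.max())
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    # volume fraction receiving >= edge: reverse-cumulative histogram
    # (bins are left-closed, so the tail sum counts d >= edges[k] exactly)
    hist, _ = np.histogram(d, bins=np.append(edges, np.inf))
    counts = np.cumsum(hist[::-1])[::-1].astype(float)
    vol = 100.0 * counts / d.size
    return DVHCurve(
        dose=edges,
        volume=vol,
        structure=structure,
        voxel_count=int(d.size),
        mean=float(d.mean()),
        max=top,
    )


def metric(dvh: DVHCurve, spec: str) -> float:
    """Evaluate a metric specification on a DVH.

    ``spec`` is ``"d95"`` / ``"d50"`` (dose in cGy to the hottest XX% of
    volume), ``"V2000"`` (% volume receiving >= 2000 cGy), ``"mean"`` or
    ``"max"``.
    """
    s = spec.strip()
    low = s.lower()
    if low == "mean":
        return dvh.mean
    if low == "max":
        return dvh.max
    if low.startswith("d"):
        xx = float(s[1:])
        if not 0.0 < xx <= 100.0:
            raise ValueError("dXX requires XX in (0, 100]")
        return _dose_at_volume(dvh, xx)
    if s.startswith("V"):
        level = float(s[1:])
        return _volume_at_dose(dvh, level)
    raise ValueError(f"unknown metric spec {spec!r}")


def _volume_at_dose(dvh: DVHCurve, dose_cgy: float) -> float:
    if dose_cgy <= dvh.dose[0]:
        return 100.0
    if dose_cgy > dvh.dose[-1]:
        return 0.0
    return float(np.interp(dose_cgy, dvh.dose, dvh.volume))


def _dose_at_volume(dvh: DVHCurve, volume_pct: float) -> float:
    """Largest dose still covering at least volume_pct of the structure,
    with linear interpolation where the curve crosses the level."""
    vol = dvh.volume
    dose = dvh.dose
    covered = vol >= volume_pct - 1e-12
    if not covered.any():
        return 0.0
    i = int(np.max(np.flatnonzero(covered)))
    if i == len(dose) - 1 or vol[i] == volume_pct:
        return float(dose[i])
    # interpolate on the falling segment [i, i+1]
    v0, v1 = vol[i], vol[i + 1]
    if v0 == v1:
        return float(dose[i])
    frac = (v0 - volume_pct) / (v0 - v1)
    return float(dose[i] + frac * (dose[i + 1] - dose[i]))


def scale_to_reference(
    value: float, prescribed: float, reference: float = REFERENCE_DOSE
) -> float:
    """Scale a dose metric to the reference-regime analysis scale
    (value * reference / prescribed); e.g. 424 cGy under a 4240 cGy
    prescription maps to 500 cGy on the 5000 cGy scale."""
    if prescribed <= 0:
        raise ValueError("prescription must be positive")
    return value * reference / prescribed


# ---------------------------------------------------------------------------
# protocol tables


@dataclass
class ProtocolTable:
    """Target/ideal/acceptable constraint rows for one protocol."""

    name: str
    rows: pd.DataFrame  # tier, structure, metric, level, alt_level, limit, limit_kind


@dataclass
class ComplianceResult:
    verdict: str  # ideal | acceptable | fail
    protocol: str
    regime: str
    constraints: list[dict]  # per-constraint detail

    def passed(self, tier: str) -> bool:
        return all(c["passed"] for c in self.constraints if c["tier"] == tier)


def load_protocol(name: str) -> ProtocolTable:
    if name not in PROTOCOL_NAMES:
        raise ValueError(f"unknown protocol {name!r}; expected one of {PROTOCOL_NAMES}")
    ref = importlib_resources.files("tangentplan.resources") / "protocols.csv"
    with importlib_resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    rows = df[df["protocol"] == name].reset_index(drop=True)
    return ProtocolTable(name=name, rows=rows)


def _constraint_metric_spec(row, regime: str, mode: str) -> str:
    level = row.level
    if mode == "alternate" and regime == "4240" and not pd.isna(row.alt_level):
        level = row.alt_level
    m = row.metric
    if m == "V":
        return f"V{level:g}"  # level in cGy
    if m == "d":
        return f"d{level:g}"  # level in % volume
    return m  # mean / max


def evaluate_protocol(
    dvhs: dict[str, DVHCurve],
    protocol: ProtocolTable | str,
    prescription: float,
    *,
    regime: str | None = None,
    mode: str = "alternate",
) -> ComplianceResult:
    """Check a plan's DVHs against one protocol's constraint table.

    ``mode="alternate"`` (default) evaluates hypofractionated plans at
    the parenthesized alternate dose levels printed in the guidelines;
    ``mode="scaled"`` first scales every metric to the 5000 cGy analysis
    scale and applies the primary levels.  Verdict: *ideal* if every
    target and ideal constraint passes; otherwise *acceptable* if every
    target constraint and every acceptable constraint (falling back to
    the ideal bound where no acceptable bound is printed) passes;
    otherwise *fail*.
    """
    if isinstance(protocol, str):
        protocol = load_protocol(protocol)
    regime = regime or ("4240" if abs(prescription - 4240.0) < 1.0 else "5000")
    if mode not in ("alternate", "scaled"):
        raise ValueError("mode must be 'alternate' or 'scaled'")

    scale = 1.0
    eval_rx = prescription
    if mode == "scaled":
        scale = REFERENCE_DOSE / prescription
        eval_rx = REFERENCE_DOSE

    detail = []
    for row in protocol.rows.itertuples(index=False):
        if row.structure not in dvhs:
            raise KeyError(f"structure {row.structure!r} missing from plan DVHs")
        dvh = dvhs[row.structure]
        spec = _constraint_metric_spec(row, regime, mode)
        if spec.startswith("V"):
            # volume constraint: the dose level itself is regime-dependent
            level = float(spec[1:]) / (scale if mode == "scaled" else 1.0)
            achieved = _volume_at_dose(dvh, level)
            limit = float(row.limit)
        else:
            achieved = metric(dvh, spec) * scale
            if row.limit_kind == "pct_of_rx":
                limit = float(row.limit) / 100.0 * eval_rx
            else:
                limit = float(row.limit)
        passed = achieved < limit if row.cmp == "lt" else achieved > limit
        detail.append(
            {
                "tier": row.tier,
                "pair": row.pair,
                "structure": row.structure,
                "metric": spec,
                "achieved": float(achieved),
                "limit": float(limit),
                "cmp": row.cmp,
                "passed": bool(passed),
            }
        )

    def tier_ok(tier: str) -> bool:
        return all(c["passed"] for c in detail if c["tier"] == tier)

    target_ok = tier_ok("target")
    ideal_ok = tier_ok("ideal")
    # acceptable tier: each ideal constraint falls back to its paired
    # acceptable bound where one is printed, else must hold as-is
    pairs_with_acc = {c["pair"] for c in detail if c["tier"] == "acceptable"}
    acc_ok = all(
        c["passed"]
        for c in detail
        if c["tier"] == "acceptable"
        or (c["tier"] == "ideal" and c["pair"] not in pairs_with_acc)
    )

    if target_ok and ideal_ok:
        verdict = "ideal"
    elif target_ok and acc_ok:
        verdict = "acceptable"
    else:
        verdict = "fail"
    return ComplianceResult(
        verdict=verdict, protocol=protocol.name, regime=regime, constraints=detail
    )


def cohort_dvh_band(dvhs: list[DVHCurve]) -> dict[str, np.ndarray]:
    """Pointwise median and quartile curves across a cohort of DVHs.

    All curves must share their binning (dose axes are aligned by
    zero-padding the shorter volume arrays).  Quartiles use linear
    interpolation (type-7).
    """
    if not dvhs:
        raise ValueError("need at least one DVH")
    widths = {round(float(np.diff(c.dose).mean()), 9) for c in dvhs if len(c.dose) > 1}
    if len(widths) > 1:
        raise ValueError("DVHs have mismatched bin widths")
    n = max(len(c.dose) for c in dvhs)
    w = float(np.diff(dvhs[0].dose).mean()) if len(dvhs[0].dose) > 1 else 1.0
    dose = np.arange(n) * w
    stack = np.zeros((len(dvhs), n))
    for i, c in enumerate(dvhs):
        stack[i, : len(c.volume)] = c.volume
    return {
        "dose": dose,
        "median": np.percentile(stack, 50, axis=0),
        "q1": np.percentile(stack, 25, axis=0),
        "q3": np.percentile(stack, 75, axis=0),
    }


# ---------------------------------------------------------------------------
# convenience


ANALYSIS_STRUCTURES = (
    "PTV_Breast",
    "PTV_planning",
    "Ipsilateral Lung",
    "Contralateral Lung",
    "Heart",
    "Contralateral Breast",
)


def structure_dvhs(
    dose: DoseGrid, patient: PatientModel, bin_width: float = 1.0
) -> dict[str, DVHCurve]:
    """DVHs of all analysis structures, keyed by protocol structure names
    (the protocol tables' plain ``PTV`` maps to the planning PTV)."""
    out = {}
    for name in ANALYSIS_STRUCTURES:
        mask = patient.mask(name)
        if mask.any():
            out[name] = compute_dvh(dose, mask, bin_width, structure=name)
    if "PTV_planning" in out:
        out["PTV"] = out["PTV_planning"]
    out["Body"] = compute_dvh(dose, patient.mask("External"), bin_width, structure="Body")
    return out
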