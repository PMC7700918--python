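"""Inverse-planning objective functions and the fluence optimizer.

The hybrid technique optimizes a small modulated fluence on top of the
fixed open-field dose ("background").  Objectives are normalized
one-sided quadratic penalties, the standard differentiable form in
inverse planning:

* ``max_dose``:   (1/N) sum_i (max(0, d_i - D) / D)^2
* ``min_dose``:   (1/N) sum_i (max(0, D - d_i) / D)^2
* ``uniform_dose``: (1/N) sum_i ((d_i - D) / D)^2
* ``max_mean``:   (max(0, mean(d) - D) / D)^2
* ``max_dvh`` / ``min_dvh``: the one-sided penalty restricted to the
  DVH-violating voxel subset, re-identified from the current dose each
  iteration (for a V_D < v% objective the allowed hottest v% of voxels
  are exempt and the remaining, lowest-dose violators above D are pushed
  down; symmetrically for coverage objectives).

The optimizer is deterministic projected gradient descent with Armijo
backtracking, starting from zero fluence so all modulation grows out of
the open-field background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .dose import BeamletMatrix, DoseGrid

__all__ = [
    "ObjectiveFunction",
    "FluenceMap",
    "objective_value",
    "objective_value_and_gradient",
    "optimize_fluence",
    "load_objectives_csv",
    "save_objectives_csv",
]

KINDS = ("min_dose", "max_dose", "min_dvh", "max_dvh", "uniform_dose", "max_mean")


@dataclass(frozen=True)
class ObjectiveFunction:
    """One weighted penalty term tied to a structure."""

    structure: str
    kind: str
    dose_level: float  # cGy
    volume_param: float | None = None  # %, for dvh kinds
    weight: float = 1.0
    is_oar: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("objective weight must be positive")
        if self.kind.endswith("_dvh"):
            if self.volume_param is None or not (0.0 < self.volume_param < 100.0):
                raise ValueError("dvh objectives need volume_param in (0, 100)")
        if self.dose_level <= 0:
            raise ValueError("objective dose level must be positive")


@dataclass
class FluenceMap:
    """Non-negative beamlet weights, one block per modulated beam."""

    weights: np.ndarray  # concatenated over beams
    blocks: list[tuple[str, slice]]  # (beam_id, slice into weights)

    def per_beam(self) -> dict[str, np.ndarray]:
        return {bid: self.weights[sl] for bid, sl in self.blocks}


def _dvh_violators(d: np.ndarray, obj: ObjectiveFunction) -> np.ndarray:
    """Indices of voxels penalized by a DVH objective at dose vector d."""
    n = len(d)
    if obj.kind == "max_dvh":
        above = np.flatnonzero(d > obj.dose_level)
        allowed = int(math.floor(obj.volume_param / 100.0 * n))
        if len(above) <= allowed:
            return np.empty(0, dtype=int)
        # exempt the hottest `allowed` voxels; push down the coolest violators
        order = np.argsort(d[above])
        return above[order[: len(above) - allowed]]
    # min_dvh: the hottest `required` voxels must all reach dose_level
    required = int(math.ceil(obj.volume_param / 100.0 * n))
    order = np.argsort(d)[::-1]
    hottest = order[:required]
    return hottest[d[hottest] < obj.dose_level]


def _penalty(d: np.ndarray, obj: ObjectiveFunction) -> tuple[float, np.ndarray]:
    """Unweighted objective value and its gradient w.r.t. the structure's
    dose vector ``d`` (same length)."""
    D = obj.dose_level
    n = len(d)
    g = np.zeros_like(d)
    if obj.kind == "max_dose":
        r = np.maximum(0.0, d - D) / D
        val = float(r @ r) / n
        g = 2.0 * r / (D * n)
    elif obj.kind == "min_dose":
        r = np.maximum(0.0, D - d) / D
        val = float(r @ r) / n
        g = -2.0 * r / (D * n)
    elif obj.kind == "uniform_dose":
        r = (d - D) / D
        val = float(r @ r) / n
        g = 2.0 * r / (D * n)
    elif obj.kind == "max_mean":
        r = max(0.0, float(d.mean()) - D) / D
        val = r * r
        g[:] = 2.0 * r / (D * n)
    else:  # dvh kinds
        idx = _dvh_violators(d, obj)
        if len(idx) == 0:
            return 0.0, g
        if obj.kind == "max_dvh":
            r = (d[idx] - D) / D
            val = float(r @ r) / n
            g[idx] = 2.0 * r / (D * n)
        else:
            r = (D - d[idx]) / D
            val = float(r @ r) / n
            g[idx] = -2.0 * r / (D * n)
    return val, g


def objective_value(obj: ObjectiveFunction, dose: DoseGrid | np.ndarray, mask: np.ndarray) -> float:
    """Weighted-free objective value on a structure (zero iff satisfied)."""
    values = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose)
    d = values[mask] if mask.dtype == bool else values.ravel()[mask]
    if d.size == 0:
        raise ValueError(f"objective on empty structure {obj.structure!r}")
    return _penalty(np.asarray(d, dtype=float), obj)[0]


def objective_value_and_gradient(
    obj: ObjectiveFunction, dose_flat: np.ndarray, idx: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Value and sparse gradient (indices, values) on the flat dose vector."""
    val, g = _penalty(dose_flat[idx], obj)
    return val, idx, g


def optimize_fluence(
    matrices: list[BeamletMatrix],
    objectives: list[ObjectiveFunction],
    background: DoseGrid | np.ndarray,
    iterations: int = 100,
    *,
    structure_indices: dict[str, np.ndarray],
    initial: np.ndarray | None = None,
    grad_tol: float = 1e-10,
    rel_tol: float = 1e-8,
) -> tuple[FluenceMap, list[float]]:
    """Minimize the weighted objective sum over non-negative fluence.

    ``structure_indices`` maps structure names to flat voxel indices in
    the dose grid.  Runs projected gradient descent with Armijo
    backtracking for ``iterations`` accepted steps (or until the
    projected gradient / relative decrease drops below tolerance); the
    objective trace is non-increasing by construction.

    Returns the fluence map and the objective value trace (including the
    starting value).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    A = sparse.hstack([m.matrix for m in matrices], format="csr")
    blocks = []
    at = 0
    for m in matrices:
        blocks.append((m.beam_id, slice(at, at + m.n_beamlets)))
        at += m.n_beamlets

    bg = background.values.ravel() if isinstance(background, DoseGrid) else np.asarray(background).ravel()
    terms = []
    for obj in objectives:
        idx = structure_indices.get(obj.structure)
        if idx is None or len(idx) == 0:
            raise KeyError(f"no voxels for structure {obj.structure!r}")
        terms.append((obj, np.asarray(idx)))

    w = np.zeros(A.shape[1]) if initial is None else np.asarray(initial, dtype=float).copy()
    if (w < 0).any():
        raise ValueError("initial fluence must be non-negative")

    def evaluate(dose_flat: np.ndarray, with_grad: bool) -> tuple[float, np.ndarray | None]:
        total = 0.0
        gflat = np.zeros_like(dose_flat) if with_grad else None
        for obj, idx in terms:
            val, g = _penalty(dose_flat[idx], obj)
            total += obj.weight * val
            if with_grad:
                np.add.at(gflat, idx, obj.weight * g)
        if not np.isfinite(total):
            raise FloatingPointError("non-finite objective value during optimization")
        return total, gflat

    dose = bg + A @ w
    f, gd = evaluate(dose, True)
    trace = [f]
    step = 1.0
    for _ in range(iterations):
        grad_w = A.T @ gd
        # projected gradient: ignore descent directions blocked by w >= 0
        pg = grad_w.copy()
        pg[(w <= 0) & (pg > 0)] = 0.0
        pg_norm = float(np.linalg.norm(pg))
        if pg_norm < grad_tol:
            break
        accepted = False
        for _ls in range(60):
            w_new = np.maximum(0.0, w - step * grad_w)
            dw = w_new - w
            if not dw.any():
                break
            dose_new = bg + A @ w_new
            f_new, _ = evaluate(dose_new, False)
            if f_new <= f + 1e-4 * float(grad_w @ dw):
                accepted = True
                break
            step *= 0.5
        if not accepted or not f_new < f:
            break
        w, dose = w_new, dose_new
        f_prev = f
        f, gd = evaluate(dose, True)
        trace.append(f)
        step *= 2.0
        if f_prev - f <= rel_tol * max(f_prev, 1e-30):
            break
    return FluenceMap(weights=w, blocks=blocks), trace


# ---------------------------------------------------------------------------
# CSV interface: structure,kind,dose_cGy,volume_pct,weight,is_oar

OBJECTIVES_HEADER = ["structure", "kind", "dose_cGy", "volume_pct", "weight", "is_oar"]


def load_objectives_csv(path) -> list[ObjectiveFunction]:
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != OBJECTIVES_HEADER:
        raise ValueError(
            f"objectives CSV must have header {','.join(OBJECTIVES_HEADER)}"
        )
    out = []
    for row in df.itertuples(index=False):
        vol = None if pd.isna(row.volume_pct) else float(row.volume_pct)
        out.append(
            ObjectiveFunction(
                structure=str(row.structure),
                kind=str(row.kind),
                dose_level=float(row.dose_cGy),
                volume_param=vol,
                weight=float(row.weight),
                is_oar=str(row.is_oar).strip().lower() in ("true", "1", "yes"),
            )
        )
    return out


def save_objectives_csv(objectives: list[ObjectiveFunction], path) -> None:
    rows = [
        {
            "structure": o.structure,
            "kind": o.kind,
            "dose_cGy": o.dose_level,
            "volume_pct": "" if o.volume_param is None else o.volume_param,
            "weight": o.weight,
            "is_oar": o.is_oar,
        }
        for o in objectives
    ]
    pd.DataFrame(rows, columns=OBJECTIVES_HEADER).to_csv(path, index=False)
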