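"""Dose computation, generalized EUD, and the composite objective.

Each objective term produces a dimensionless, weighted penalty — the
objective function value (OFV) — which the outer-loop controller reads as
its feedback signal.  All penalties are normalized by the prescription dose
D_p so that, with the standard weights (3000 for the target, 10 per organ
at risk), OFV magnitudes land in the clinically reported regimes: the PTV
OFV sits near or above 1 while organ OFVs range roughly 0.1–2.5.

Functional forms (d_i = voxel doses on the term's structure, N voxels):

* ``uniform_dose``: w * (1/N) sum ((d_i - D_p) / D_p)^2
* ``max_eud``:      w * (max(0, gEUD_a(d) - EUD0) / EUD0)^2
* ``min_dose``:     w * (1/N) sum (max(0, L - d_i) / D_p)^2

The MaxEUD excess is normalized by the limit EUD0 itself (relative excess)
rather than by D_p.  This keeps the penalty scale-free as the controller
drives the limit down: the OFV grows without bound as EUD0 shrinks below
the achievable gEUD, so the linear feedback law s = m * OFV + n always has
a reachable fixed point, which is what makes saturation at the class
tuning OFVs possible at all.  At EUD0 = D_p (the Phase-1 setting) the two
normalizations coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import InfluenceMatrix

KINDS = ("uniform_dose", "max_eud", "min_dose")


@dataclass(frozen=True)
class ObjectiveSpec:
    """One objective term.

    ``level`` is the prescription D_p for ``uniform_dose``, the MaxEUD limit
    EUD0 for ``max_eud``, and the minimum-dose threshold for ``min_dose``.
    ``a`` is the gEUD exponent (only used by ``max_eud``; a = 1 gives mean
    dose, large a approaches max dose).
    """

    structure: str
    kind: str
    level: float
    a: float = 1.0
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.level <= 0:
            raise ValueError("level must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.kind == "max_eud" and self.a < 1:
            raise ValueError("gEUD exponent a must be >= 1")


@dataclass(frozen=True)
class ObjectiveReport:
    """Per-term OFVs plus per-structure dose summaries for one dose grid."""

    term_values: dict[tuple[str, str], float]
    total: float
    mean_dose: dict[str, float]
    max_dose: dict[str, float]

    def ofv(self, structure: str, kind: str = "max_eud") -> float:
        return self.term_values[(structure, kind)]


def compute_dose(influence: InfluenceMatrix, fluence: np.ndarray) -> np.ndarray:
    """Dose grid (Gy) from per-beamlet fluence; linear in the fluence."""
    fluence = np.asarray(fluence, dtype=float)
    if fluence.shape != (influence.n_beamlets,):
        raise ValueError(
            f"fluence has shape {fluence.shape}, expected ({influence.n_beamlets},)")
    if np.any(fluence < 0):
        raise ValueError("fluence must be nonnegative")
    dose = influence.matrix.T @ fluence
    return dose.reshape(influence.grid_shape)


def geud(dose: np.ndarray, mask: np.ndarray, a: float) -> float:
    """Generalized equivalent uniform dose ((1/N) sum d_i^a)^(1/a), in Gy.

    Computed with max-normalization for numerical stability at large a.
    """
    if a < 1:
        raise ValueError("gEUD exponent a must be >= 1")
    d = np.asarray(dose, dtype=float).ravel()[np.asarray(mask, dtype=bool).ravel()]
    if d.size == 0:
        raise ValueError("empty structure mask")
    if a == 1:
        return float(d.mean())
    m = float(d.max())
    if m == 0.0:
        return 0.0
    return m * float(np.mean((d / m) ** a) ** (1.0 / a))


def _geud_gradient(d: np.ndarray, a: float) -> np.ndarray:
    """d gEUD / d d_i on the masked voxel doses (same shape as d)."""
    n = d.size
    if a == 1:
        return np.full(n, 1.0 / n)
    m = float(d.max())
    if m == 0.0:
        return np.zeros(n)
    g = m * float(np.mean((d / m) ** a) ** (1.0 / a))
    if g == 0.0:
        return np.zeros(n)
    return (d ** (a - 1.0)) * g ** (1.0 - a) / n


def objective_value(spec: ObjectiveSpec, dose: np.ndarray,
                    masks: dict[str, np.ndarray], prescription: float) -> float:
    """Weighted OFV of a single term on the given dose grid."""
    if spec.structure not in masks:
        raise KeyError(f"unknown structure {spec.structure!r}")
    mask = np.asarray(masks[spec.structure], dtype=bool).ravel()
    d = np.asarray(dose, dtype=float).ravel()[mask]
    if d.size == 0:
        raise ValueError(f"structure {spec.structure!r} mask is empty")
    dp = prescription
    if spec.kind == "uniform_dose":
        return spec.weight * float(np.mean(((d - spec.level) / dp) ** 2))
    if spec.kind == "max_eud":
        excess = max(0.0, geud(d, np.ones(d.size, bool), spec.a) - spec.level)
        return spec.weight * (excess / spec.level) ** 2
    # min_dose
    short = np.maximum(0.0, spec.level - d)
    return spec.weight * float(np.mean((short / dp) ** 2))


def objective_gradient(spec: ObjectiveSpec, dose: np.ndarray,
                       masks: dict[str, np.ndarray],
                       prescription: float) -> np.ndarray:
    """Gradient of a term with respect to the flattened dose grid."""
    mask = np.asarray(masks[spec.structure], dtype=bool).ravel()
    d_all = np.asarray(dose, dtype=float).ravel()
    d = d_all[mask]
    n = d.size
    dp = prescription
    grad = np.zeros(d_all.size)
    if spec.kind == "uniform_dose":
        grad[mask] = spec.weight * 2.0 * (d - spec.level) / (n * dp ** 2)
    elif spec.kind == "max_eud":
        g = geud(d, np.ones(n, bool), spec.a)
        excess = g - spec.level
        if excess > 0:
            grad[mask] = (spec.weight * 2.0 * excess / spec.level ** 2
                          * _geud_gradient(d, spec.a))
    else:  # min_dose
        short = np.maximum(0.0, spec.level - d)
        grad[mask] = -spec.weight * 2.0 * short / (n * dp ** 2)
    return grad


def evaluate_objectives(objectives: list[ObjectiveSpec], dose: np.ndarray,
                        masks: dict[str, np.ndarray],
                        prescription: float) -> ObjectiveReport:
    """Evaluate every term and summarize per-structure mean/max dose."""
    values: dict[tuple[str, str], float] = {}
    for spec in objectives:
        values[(spec.structure, spec.kind)] = objective_value(
            spec, dose, masks, prescription)
    d = np.asarray(dose, dtype=float).ravel()
    mean_dose, max_dose = {}, {}
    for name, mask in masks.items():
        sel = d[np.asarray(mask, dtype=bool).ravel()]
        if sel.size:
            mean_dose[name] = float(sel.mean())
            max_dose[name] = float(sel.max())
    return ObjectiveReport(values, float(sum(values.values())), mean_dose, max_dose)


def total_objective_and_gradient(objectives: list[ObjectiveSpec],
                                 influence: InfluenceMatrix,
                                 fluence: np.ndarray,
                                 masks: dict[str, np.ndarray],
                                 prescription: float) -> tuple[float, np.ndarray]:
    """Composite objective and its gradient with respect to the fluence."""
    dose = influence.matrix.T @ np.asarray(fluence, dtype=float)
    total = 0.0
    grad_d = np.zeros(dose.size)
    for spec in objectives:
        total += objective_value(spec, dose, masks, prescription)
        grad_d += objective_gradient(spec, dose, masks, prescription)
    grad_x = influence.matrix @ grad_d
    return float(total), grad_x
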