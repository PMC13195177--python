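"""Plan-quality evaluation: DVH, V/D queries, Paddick CI, HI, clinical goals.

Conventions
-----------
* The cumulative DVH samples V(e) = % of structure voxels with dose >= e at
  bin edges spaced ``bin_width`` apart (default 0.1 Gy); V/D queries
  interpolate linearly between edges, so they are accurate to one bin width.
* Isodose membership for conformity uses the closed comparison
  dose >= 0.95 * D_p.
* Pseudo-volume = voxel count x in-plane voxel area x nominal slice
  thickness, so V_xGy can be reported both in % and in cm^3 analogs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume histogram for one structure."""

    structure: str
    edges_gy: np.ndarray        # dose bin edges (Gy), increasing
    cum_volume_pct: np.ndarray  # % of voxels with dose >= edge
    volume_cm3: float           # absolute structure pseudo-volume


def compute_dvh(dose: np.ndarray, mask: np.ndarray, bin_width: float = 0.1,
                structure: str = "", voxel_volume_cm3: float = 0.0) -> DVH:
    """Cumulative DVH with half-open bins [edge, edge + width)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    m = np.asarray(mask, bool).ravel()
    d = np.asarray(dose, float).ravel()[m]
    if d.size == 0:
        raise ValueError("empty structure mask")
    n_bins = int(np.floor(d.max() / bin_width)) + 2
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    # V(edge_k) = fraction of voxels with dose >= edge_k
    ge = np.concatenate([[d.size], d.size - np.cumsum(counts)])
    cum = 100.0 * ge / d.size
    return DVH(structure, edges, cum, float(d.size * voxel_volume_cm3))


def v_at_dose(dvh: DVH, dose_gy: float, absolute: bool = False) -> float:
    """V_D: volume receiving >= ``dose_gy``, in % (or cm^3 if ``absolute``)."""
    if dose_gy < 0:
        raise ValueError("dose must be nonnegative")
    pct = float(np.interp(dose_gy, dvh.edges_gy, dvh.cum_volume_pct,
                          right=0.0))
    return pct / 100.0 * dvh.volume_cm3 if absolute else pct


def d_at_volume(dvh: DVH, volume_pct: float) -> float:
    """D_v: the dose received by the hottest ``volume_pct`` % of the structure."""
    if not 0 < volume_pct <= 100:
        raise ValueError("volume percentage must lie in (0, 100]")
    # cum_volume_pct is nonincreasing in dose; invert by linear interpolation
    v = dvh.cum_volume_pct[::-1]
    e = dvh.edges_gy[::-1]
    return float(np.interp(volume_pct, v, e))


def paddick_ci(dose: np.ndarray, ptv_mask: np.ndarray, external_mask: np.ndarray,
               prescription: float) -> float:
    """Paddick conformity index (PIV_PTV/PTV_VOL) * (PIV_PTV/PIV_EXT).

    PIV_PTV = PTV volume at >= 95 % of prescription, PIV_EXT = external
    volume at >= 95 % of prescription.  1 = perfect conformity.
    """
    d = np.asarray(dose, float).ravel()
    ptv = np.asarray(ptv_mask, bool).ravel()
    ext = np.asarray(external_mask, bool).ravel()
    if not ptv.any() or not ext.any():
        raise ValueError("PTV and external masks must be non-empty")
    iso = d >= 0.95 * prescription
    piv_ptv = int((iso & ptv).sum())
    piv_ext = int((iso & ext).sum())
    if piv_ext == 0:
        warnings.warn("no tissue reaches the 95% isodose; CI defined as 0")
        return 0.0
    return (piv_ptv / int(ptv.sum())) * (piv_ptv / piv_ext)


def homogeneity_index(ptv_dvh: DVH) -> float:
    """HI = D_5 / D_95 of the PTV; 1 = perfectly uniform target dose."""
    d95 = d_at_volume(ptv_dvh, 95.0)
    if d95 == 0:
        raise ZeroDivisionError("D_95 is zero; homogeneity index undefined")
    return d_at_volume(ptv_dvh, 5.0) / d95


# ---------------------------------------------------------------------------
# Clinical goals


@dataclass(frozen=True)
class ClinicalGoal:
    structure: str
    metric: str        # "mean", "V_xGy" (%), or "D_x%" (Gy)
    comparator: str    # "<", "<=", ">", ">="
    limit: float

    def __post_init__(self):
        if self.limit <= 0:
            raise ValueError("goal limit must be positive")
        if self.comparator not in ("<", "<=", ">", ">="):
            raise ValueError(f"unknown comparator {self.comparator!r}")


#: Institutional defaults for whole-breast planning.
DEFAULT_GOALS = (
    ClinicalGoal("lung_ipsi", "mean", "<", 10.0),
    ClinicalGoal("lung_ipsi", "V_10Gy", "<", 35.0),
    ClinicalGoal("lung_ipsi", "V_20Gy", "<", 20.0),
    ClinicalGoal("lung_contra", "mean", "<", 2.0),
    ClinicalGoal("heart", "mean", "<=", 2.5),
    ClinicalGoal("breast_contra", "mean", "<=", 2.0),
)

_V_RE = re.compile(r"^V_([0-9.]+)Gy$")
_D_RE = re.compile(r"^D_([0-9.]+)%$")
_CMP = {"<": np.less, "<=": np.less_equal, ">": np.greater, ">=": np.greater_equal}


def _goal_value(goal: ClinicalGoal, dose: np.ndarray, mask: np.ndarray,
                voxel_volume_cm3: float) -> float:
    if goal.metric == "mean":
        d = np.asarray(dose, float).ravel()[np.asarray(mask, bool).ravel()]
        return float(d.mean())
    dvh = compute_dvh(dose, mask, structure=goal.structure,
                      voxel_volume_cm3=voxel_volume_cm3)
    if m := _V_RE.match(goal.metric):
        return v_at_dose(dvh, float(m.group(1)))
    if m := _D_RE.match(goal.metric):
        return d_at_volume(dvh, float(m.group(1)))
    raise ValueError(f"unknown metric {goal.metric!r}")


def evaluate_goals(dose: np.ndarray, masks: dict[str, np.ndarray],
                   goals: tuple[ClinicalGoal, ...] = DEFAULT_GOALS,
                   voxel_volume_cm3: float = 0.0) -> pd.DataFrame:
    """Evaluate each clinical goal; returns value, limit, and verdict per row."""
    rows = []
    for goal in goals:
        if goal.structure not in masks:
            raise KeyError(f"unknown structure {goal.structure!r}")
        value = _goal_value(goal, dose, masks[goal.structure], voxel_volume_cm3)
        rows.append({"structure": goal.structure, "metric": goal.metric,
                     "value": value, "comparator": goal.comparator,
                     "limit": goal.limit,
                     "passed": bool(_CMP[goal.comparator](value, goal.limit))})
    return pd.DataFrame(rows)
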