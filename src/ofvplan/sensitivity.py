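"""Sensitivity-analysis calibration of the controller's tuning-point OFVs.

The tuning points (the OFVs at which each organ class should saturate) are
derived empirically: one organ's MaxEUD limit follows an aggressive
geometric dose-reduction schedule while the other organs are held at fixed
limits, six plan metrics are traced across the schedule, smoothed with a
three-point moving average, differentiated between consecutive steps, and
gated by clinical "criticality" masks.  Summing the absolute gated
derivatives gives an aggregate sensitivity score S(j); the schedule step
that maximizes S(j) marks where further dose reduction starts to trade
against target coverage, and the organ OFV recorded there is the tuning
point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dose import ObjectiveSpec
from .metrics import compute_dvh, d_at_volume
from .optimizer import OptimizerConfig, initial_fluence, optimize_fluence
from .phantom import BeamSet, InfluenceMatrix, Phantom, compute_influence

#: Metric columns recorded at every schedule step.
METRIC_COLUMNS = ("ptv95vol_gy", "ptv_ofv", "external_max_gy",
                  "external_v105_cm3", "oar_ofv", "oar_mean_gy")

#: (rate column, mask column) pairs whose gated |derivatives| sum into S(j).
SCORED_METRICS = ("ptv95vol_gy", "oar_mean_gy", "external_max_gy",
                  "external_v105_cm3")


@dataclass(frozen=True)
class MetricTrace:
    """Per-step metric table for one dose-reduction schedule.

    ``data`` has one row per optimization step (column ``step`` from 1) and
    the six metric columns; ``limits_gy`` is the scheduled MaxEUD limit of
    the target organ per step (NaN at step 1, which runs without any
    organ-at-risk objective).
    """

    data: pd.DataFrame
    target_organ: str
    limits_gy: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class SensitivityConfig:
    """Schedule, companion limits, and criticality thresholds."""

    n_steps: int = 10
    halving_factor: float = 0.5     # steps 2 and 3
    taper_factor: float = 0.8       # steps >= 4
    target_organ: str = "lung_ipsi"
    # fixed MaxEUD (Gy) for the non-scheduled organs; ``None`` means
    # "half of that organ's step-1 mean dose"
    companion_limits: dict[str, float | None] = field(default_factory=lambda: {
        "lung_contra": 1.0, "breast_contra": 4.0, "heart": 2.5})
    smoothing_window: int = 3
    ptv95vol_floor_gy: float = 47.5   # PTV D95 below this is critical
    external_max_gy: float = 52.5     # external max above this is critical
    score_on_smoothed: bool = True    # difference the smoothed (vs raw) trace
    prescription: float = 50.0
    ptv_weight: float = 3000.0
    oar_weight: float = 10.0
    optimizer: OptimizerConfig = OptimizerConfig()

    def __post_init__(self):
        if self.n_steps < 4:
            raise ValueError("the schedule needs at least 4 steps")
        if self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be odd")


def _step_metrics(dose: np.ndarray, report, phantom: Phantom, config: SensitivityConfig,
                  oar_ofv: float, oar_mean: float) -> dict[str, float]:
    dp = config.prescription
    ptv_dvh = compute_dvh(dose, phantom.masks["PTV"], structure="PTV")
    d = np.asarray(dose, float).ravel()
    ext = phantom.masks["external"].ravel()
    v105 = int((ext & (d > 1.05 * dp)).sum()) * phantom.voxel_volume_cm3
    return {
        "ptv95vol_gy": d_at_volume(ptv_dvh, 95.0),
        "ptv_ofv": report.ofv("PTV", "uniform_dose"),
        "external_max_gy": report.max_dose["external"],
        "external_v105_cm3": v105,
        "oar_ofv": oar_ofv,
        "oar_mean_gy": oar_mean,
    }


def run_schedule(phantom: Phantom, beamset: BeamSet,
                 config: SensitivityConfig = SensitivityConfig(),
                 influence: InfluenceMatrix | None = None) -> MetricTrace:
    """Run the geometric dose-reduction schedule and trace the six metrics.

    Step 1 optimizes the PTV objective alone.  From step 2 on, the target
    organ's MaxEUD limit is 50 % of its step-1 mean dose, halved once more
    at step 3, then multiplied by 0.8 per step; companion organs keep fixed
    limits throughout.  Each step runs one inner-optimizer budget,
    warm-started from the previous fluence.
    """
    if influence is None:
        influence = compute_influence(phantom, beamset)
    dp = config.prescription
    masks = dict(phantom.masks)
    target = config.target_organ

    ptv_obj = ObjectiveSpec("PTV", "uniform_dose", dp, weight=config.ptv_weight)
    x = initial_fluence(influence, phantom.masks["PTV"], dp)
    result = optimize_fluence(influence, [ptv_obj], masks, dp, x, config.optimizer)
    dose = influence.matrix.T @ result.fluence
    mean1 = {organ: float(dose[masks[organ].ravel()].mean())
             for organ in list(config.companion_limits) + [target]}

    rows = [dict(step=1, **_step_metrics(dose, result.report, phantom, config,
                                         oar_ofv=0.0, oar_mean=mean1[target]))]
    limits = [float("nan")]

    companions = [
        ObjectiveSpec(organ, "max_eud",
                      0.5 * mean1[organ] if lim is None else lim,
                      a=1.0, weight=config.oar_weight)
        for organ, lim in config.companion_limits.items()]

    limit = config.halving_factor * mean1[target]
    for step in range(2, config.n_steps + 1):
        objectives = [ptv_obj,
                      ObjectiveSpec(target, "max_eud", limit, a=1.0,
                                    weight=config.oar_weight)] + companions
        result = optimize_fluence(influence, objectives, masks, dp,
                                  result.fluence, config.optimizer)
        dose = influence.matrix.T @ result.fluence
        rows.append(dict(step=step, **_step_metrics(
            dose, result.report, phantom, config,
            oar_ofv=result.report.ofv(target),
            oar_mean=float(dose[masks[target].ravel()].mean()))))
        limits.append(limit)
        factor = config.halving_factor if step == 2 else config.taper_factor
        limit = factor * limit
    return MetricTrace(pd.DataFrame(rows), target, tuple(limits))


def smooth_trace(trace: MetricTrace, window: int = 3) -> MetricTrace:
    """Centered moving average per metric; edges use the truncated window."""
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window > len(trace):
        raise ValueError("smoothing window exceeds trace length")
    data = trace.data.copy()
    cols = list(METRIC_COLUMNS)
    data[cols] = data[cols].rolling(window, center=True, min_periods=1).mean()
    return MetricTrace(data, trace.target_organ, trace.limits_gy)


def change_rates(trace: MetricTrace) -> pd.DataFrame:
    """Forward differences Delta m(j) = m(j+1) - m(j), one row per step j."""
    if len(trace) < 2:
        raise ValueError("need at least 2 steps to difference")
    cols = list(METRIC_COLUMNS)
    rates = trace.data[cols].diff().shift(-1).iloc[:-1].copy()
    rates.insert(0, "step", trace.data["step"].iloc[:-1].to_numpy())
    return rates.reset_index(drop=True)


def criticality_masks(trace: MetricTrace, rates: pd.DataFrame,
                      config: SensitivityConfig = SensitivityConfig()) -> pd.DataFrame:
    """Boolean gates, one row per rate step j, one column per scored metric.

    * PTV D95 (at step j) below the coverage floor;
    * |Delta mean organ dose| strictly below its own median (sparing stalls);
    * external max dose (at step j) above the hot-spot threshold;
    * Delta(external volume > 105 %) strictly above its own median.

    Median comparisons are strict, so ties are excluded from criticality.
    """
    head = trace.data.iloc[:len(rates)]
    abs_oar = rates["oar_mean_gy"].abs()
    d_v105 = rates["external_v105_cm3"]
    masks = pd.DataFrame({
        "step": rates["step"].to_numpy(),
        "ptv95vol_gy": (head["ptv95vol_gy"] < config.ptv95vol_floor_gy).to_numpy(),
        "oar_mean_gy": (abs_oar < abs_oar.median()).to_numpy(),
        "external_max_gy": (head["external_max_gy"] > config.external_max_gy).to_numpy(),
        "external_v105_cm3": (d_v105 > d_v105.median()).to_numpy(),
    })
    return masks


@dataclass(frozen=True)
class SensitivityResult:
    """Aggregate score S(j) per step, its argmax, and the tuning-point OFV."""

    scores: pd.Series        # indexed by step j
    jstar: int
    ofv_at_jstar: float


def sensitivity_score(rates: pd.DataFrame, masks: pd.DataFrame,
                      trace: MetricTrace) -> SensitivityResult:
    """S(j) = sum over gated metrics of |Delta metric(j)|.

    The argmax j* breaks ties toward the earliest step (the most
    conservative sparing level); the tuning point is the organ OFV of
    ``trace`` at j*.
    """
    s = np.zeros(len(rates))
    for col in SCORED_METRICS:
        s += np.abs(rates[col].to_numpy()) * masks[col].to_numpy()
    steps = rates["step"].to_numpy()
    scores = pd.Series(s, index=pd.Index(steps, name="step"), name="S")
    if not masks[list(SCORED_METRICS)].to_numpy().any():
        warnings.warn("no metric met a criticality criterion; S(j) is "
                      "identically zero and j* falls back to the first step")
    jstar = int(steps[int(np.argmax(s))])  # np.argmax returns the first maximum
    ofv = float(trace.data.loc[trace.data["step"] == jstar, "oar_ofv"].iloc[0])
    return SensitivityResult(scores, jstar, ofv)


def analyze_trace(trace: MetricTrace,
                  config: SensitivityConfig = SensitivityConfig()) -> SensitivityResult:
    """Smooth, differentiate, gate, and score one metric trace."""
    smoothed = smooth_trace(trace, config.smoothing_window)
    rates = change_rates(smoothed if config.score_on_smoothed else trace)
    masks = criticality_masks(smoothed, rates, config)
    return sensitivity_score(rates, masks, smoothed)


def derive_tuning_points(phantoms: list[Phantom], beamsets: list[BeamSet],
                         config: SensitivityConfig = SensitivityConfig()
                         ) -> dict[str, object]:
    """Average tuning-point OFVs across phantoms for both organ classes.

    The class-2 point reduces the ipsilateral lung with the standard
    companions; the class-1 point reduces the contralateral breast with the
    ipsilateral lung held at half of its unconstrained mean dose.  Returns
    the per-phantom table plus the mean OFV per class.
    """
    if not phantoms:
        raise ValueError("need at least one phantom")
    if len(beamsets) != len(phantoms):
        raise ValueError("phantoms and beamsets must align")
    class1_cfg = replace(config, target_organ="breast_contra",
                         companion_limits={"lung_contra": 1.0, "heart": 2.5,
                                           "lung_ipsi": None})
    rows = []
    for phantom, beamset in zip(phantoms, beamsets):
        influence = compute_influence(phantom, beamset)
        for label, cfg in (("class2", config), ("class1", class1_cfg)):
            trace = run_schedule(phantom, beamset, cfg, influence=influence)
            res = analyze_trace(trace, cfg)
            rows.append({"seed": phantom.seed, "class": label,
                         "target_organ": cfg.target_organ, "jstar": res.jstar,
                         "tuning_ofv": res.ofv_at_jstar})
    table = pd.DataFrame(rows)
    means = table.groupby("class")["tuning_ofv"].mean()
    return {"per_phantom": table,
            "class2_mean_ofv": float(means["class2"]),
            "class1_mean_ofv": float(means["class1"])}
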