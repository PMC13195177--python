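"""End-to-end run: phantom -> influence -> controller -> metrics -> artifacts.

``run_pipeline`` writes five artifacts to the output directory:

* ``phantom.ctr``     phantom container (see :mod:`ofvplan.io`)
* ``trajectory.csv``  per-loop, per-organ OFV / MaxEUD / mean-dose log
* ``dvh.csv``         cumulative DVHs (structure, dose_Gy, volume_pct)
* ``report.json``     plan-quality metrics and clinical-goal verdicts
* ``summary.txt``     human-readable run summary
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as qm
from .config import RunConfig
from .controller import run_controller
from .io import save_phantom
from .phantom import REQUIRED_ROLES, build_beamset, compute_influence, generate_phantom

logger = logging.getLogger("ofvplan.pipeline")

ARTIFACTS = ("phantom.ctr", "trajectory.csv", "dvh.csv", "report.json",
             "summary.txt")


def dvh_table(dose: np.ndarray, phantom, bin_width: float = 0.1) -> pd.DataFrame:
    rows = []
    for name in REQUIRED_ROLES:
        dvh = qm.compute_dvh(dose, phantom.masks[name], bin_width, name,
                             phantom.voxel_volume_cm3)
        rows.append(pd.DataFrame({"structure": name, "dose_Gy": dvh.edges_gy,
                                  "volume_pct": dvh.cum_volume_pct}))
    return pd.concat(rows, ignore_index=True)


def plan_report(plan, config: RunConfig) -> dict:
    phantom = plan.phantom
    dp = plan.prescription
    ptv_dvh = qm.compute_dvh(plan.dose, phantom.masks["PTV"], structure="PTV",
                             voxel_volume_cm3=phantom.voxel_volume_cm3)
    goals = qm.evaluate_goals(plan.dose, phantom.masks,
                              voxel_volume_cm3=phantom.voxel_volume_cm3)
    report = {
        "prescription_Gy": dp,
        "laterality": phantom.laterality,
        "seed": phantom.seed,
        "ptv_v95_pct": plan.ptv_v95_pct(),
        "ci_paddick": qm.paddick_ci(plan.dose, phantom.masks["PTV"],
                                    phantom.masks["external"], dp),
        "homogeneity_index": qm.homogeneity_index(ptv_dvh),
        "mean_dose_Gy": {k: round(v, 4) for k, v in plan.report.mean_dose.items()},
        "max_dose_Gy": {k: round(v, 4) for k, v in plan.report.max_dose.items()},
        "ofv": {f"{s}:{k}": round(v, 6)
                for (s, k), v in plan.report.term_values.items()},
        "clinical_goals": goals.to_dict(orient="records"),
    }
    return report


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full automated planning pipeline; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage phantom: seed=%d laterality=%s", config.seed,
                config.laterality)
    phantom = generate_phantom(config.phantom_config(), config.seed,
                               config.laterality)
    save_phantom(phantom, out / "phantom.ctr")

    logger.info("stage beamset/influence")
    beamset = build_beamset(
        phantom, config.arc.start, config.arc.stop, config.arc.n_angles,
        config.arc.beamlets_per_angle, config.arc.margin_mm,
        config.arc.source_distance_mm)
    influence = compute_influence(phantom, beamset,
                                  config.kernel.attenuation_per_mm,
                                  config.kernel.lateral_sigma_mm,
                                  halo_amplitude=config.kernel.halo_amplitude,
                                  halo_sigma_mm=config.kernel.halo_sigma_mm)

    logger.info("stage controller")
    plan, log = run_controller(phantom, beamset, config.controller_config(),
                               influence=influence)

    logger.info("stage report")
    log.organs.to_csv(out / "trajectory.csv", index=False)
    dvh_table(plan.dose, phantom).to_csv(out / "dvh.csv", index=False)
    report = plan_report(plan, config)
    report["saturated"] = log.saturated
    report["saturation_loop"] = log.saturation_loop
    report["n_loops"] = log.n_loops
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    lines = [
        f"ofvplan run (seed {config.seed}, {config.laterality}-sided, "
        f"D_p = {config.prescription_gy} Gy)",
        f"outer loops: {log.n_loops} (saturated: {log.saturated}, "
        f"loop {log.saturation_loop})",
        f"PTV V95%: {report['ptv_v95_pct']:.2f} %   "
        f"CI: {report['ci_paddick']:.3f}   HI: {report['homogeneity_index']:.3f}",
    ]
    for organ in ("heart", "lung_ipsi", "lung_contra", "breast_contra"):
        lines.append(f"{organ:>14}: mean {report['mean_dose_Gy'][organ]:6.2f} Gy")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return out
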