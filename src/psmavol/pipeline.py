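"""End-to-end pipeline: simulate-or-load -> segment -> metrics -> analysis.

A single config (YAML/JSON) drives every stage; all randomness flows from
one root seed, so a manifest (config + seed + version) reproduces every
output byte-identically.

Two input modes, mutually exclusive:

* ``simulation`` — either a pure cohort simulation (``n_patients`` etc.,
  survival analysis only) or, with ``imaging: true``, per-patient synthetic
  PET phantoms for baseline and interim scans that are actually segmented,
  aggregated and classified before the survival stage.
* ``data`` — paths to real NIfTI PET volumes + organ-label volumes per scan
  and a clinical CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InputError
from .io import (
    lesion_label_volume,
    load_adjustments,
    load_organ_masks,
    load_pet,
    save_labels,
    save_pet,
)
from .metrics import aggregate_scan, build_response_record, lesions_to_frame
from .phantom import (
    CohortSimSpec,
    LesionSpec,
    default_body_phantom,
    generate_phantom,
    simulate_cohort,
)
from .segmentation import segment_scan
from .survival import km_median, run_paper_analysis

log = logging.getLogger("psmavol")

#: fields of CohortSimSpec a config may override
_COHORT_FIELDS = {f.name for f in dataclasses.fields(CohortSimSpec)}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        if str(path).endswith((".yaml", ".yml")):
            return yaml.safe_load(fh)
        return json.load(fh)


def _validate_config(config: dict) -> None:
    has_sim = "simulation" in config
    has_data = "data" in config
    if has_sim == has_data:
        raise ConfigurationError(
            "config must provide exactly one of 'simulation' or 'data'"
        )
    thresholds = config.get("response_thresholds", {})
    for key, val in thresholds.items():
        if not val > 0:
            raise ConfigurationError(f"response threshold {key} must be positive, got {val}")


def _simulate_imaging_patient(
    patient_seed: int, decline_factor: float, rng: np.random.Generator
):
    """Baseline + interim phantom pair for one simulated patient.

    Interim lesions shrink isotropically by decline_factor**(1/3) in radius,
    so their volume scales by the decline factor; lesions shrinking below
    3 mm radius vanish.
    """
    n_lesions = int(rng.integers(1, 4))
    sites = [
        (32.0, 90.0, 30.0),
        (90.0, 30.0, 40.0),
        (64.0, 64.0, 170.0),
    ]
    base_lesions = []
    for k in range(n_lesions):
        radius = float(rng.uniform(7.0, 12.0))
        peak = float(rng.uniform(10.0, 25.0))
        base_lesions.append(LesionSpec(sites[k], radius, peak))
    shrink = decline_factor ** (1.0 / 3.0)
    interim_lesions = [
        LesionSpec(l.center_mm, l.radius_mm * shrink, l.peak_suv)
        for l in base_lesions
        if l.radius_mm * shrink >= 3.0
    ]
    base = generate_phantom(
        default_body_phantom(seed=patient_seed, lesions=base_lesions, psf_fwhm_mm=4.0, noise_sd=0.05)
    )
    interim = generate_phantom(
        dataclasses.replace(
            default_body_phantom(
                seed=patient_seed + 1, lesions=interim_lesions, psf_fwhm_mm=4.0, noise_sd=0.05
            ),
            timepoint="interim",
        )
    )
    return base, interim


def _run_imaging_simulation(sim_cfg: dict, seed: int, out_dir: Path, seg_opts: dict) -> pd.DataFrame:
    """Render, segment and aggregate per-patient phantom scan pairs."""
    n = int(sim_cfg.get("n_patients", 3))
    rng = np.random.default_rng(seed)
    spec = _cohort_spec(sim_cfg, seed + 1)
    clinical = simulate_cohort(dataclasses.replace(spec, n_patients=n))
    rows = []
    lesion_frames = []
    for i in range(n):
        pid = f"P{i:04d}"
        decline = float(clinical.loc[i, "tv_interim_ml"] / clinical.loc[i, "tv_baseline_ml"])
        base, interim = _simulate_imaging_patient(
            int(rng.integers(0, 2**31 - 1)), decline, rng
        )
        metrics = {}
        for tag, out in (("baseline", base), ("interim", interim)):
            lesions = segment_scan(out.volume, out.organ_masks, **seg_opts)
            metrics[tag] = aggregate_scan(lesions, scan_id=f"{pid}_{tag}", timepoint=tag)
            lesion_frames.append(lesions_to_frame(lesions, scan_id=f"{pid}_{tag}", timepoint=tag))
            save_labels(
                lesion_label_volume(lesions, out.volume.values.shape),
                out.volume.spacing,
                out_dir / f"{pid}_{tag}_lesions.nii.gz",
            )
        rec = build_response_record(
            pid, metrics["baseline"], metrics["interim"],
            psa_baseline=float(clinical.loc[i, "psa_baseline"]),
            psa_best=float(clinical.loc[i, "psa_best"]),
        )
        rows.append(
            {
                "patient_id": pid,
                "tv_baseline_ml": metrics["baseline"].psma_tv_ml,
                "tv_interim_ml": metrics["interim"].psma_tv_ml,
                "tlq_baseline": metrics["baseline"].tlq_sum,
                "tlq_interim": metrics["interim"].tlq_sum,
                "mean_suv_max_baseline": metrics["baseline"].mean_suv_max,
                "tv_ratio": rec.tv_ratio,
                "tv_decline_pct": rec.tv_decline_pct,
                "tv_responder": rec.tv_responder,
                "low_expression": rec.low_expression,
                "psa_baseline": float(clinical.loc[i, "psa_baseline"]),
                "psa_best": float(clinical.loc[i, "psa_best"]),
                "psa_decline_pct": rec.psa_decline_pct,
                "psa_responder": rec.psa_responder,
                "ldh": float(clinical.loc[i, "ldh"]),
                "os_months": float(clinical.loc[i, "os_months"]),
                "event": bool(clinical.loc[i, "event"]),
            }
        )
    pd.concat(lesion_frames, ignore_index=True).to_csv(out_dir / "lesions.csv", index=False)
    return pd.DataFrame(rows)


def _cohort_spec(sim_cfg: dict, seed: int) -> CohortSimSpec:
    kwargs = {k: v for k, v in sim_cfg.items() if k in _COHORT_FIELDS}
    kwargs["seed"] = seed
    return CohortSimSpec(**kwargs)


def _run_data_mode(data_cfg: dict, out_dir: Path, seg_opts: dict) -> pd.DataFrame:
    label_map = data_cfg.get("label_map", {"liver": 1, "spleen": 2, "kidney_left": 3, "kidney_right": 4})
    clinical = pd.read_csv(data_cfg["clinical_csv"])
    scans: dict[tuple[str, str], Any] = {}
    lesion_frames = []
    for scan in data_cfg["scans"]:
        pid, tp = scan["patient_id"], scan["timepoint"]
        volume = load_pet(scan["pet"], scan_id=f"{pid}_{tp}", timepoint=tp)
        masks = load_organ_masks(scan["organs"], label_map)
        adjustments = load_adjustments(scan["adjust"]) if scan.get("adjust") else None
        lesions = segment_scan(volume, masks, adjustments=adjustments, **seg_opts)
        scans[(pid, tp)] = aggregate_scan(lesions, scan_id=f"{pid}_{tp}", timepoint=tp)
        lesion_frames.append(lesions_to_frame(lesions, scan_id=f"{pid}_{tp}", timepoint=tp))
    if lesion_frames:
        pd.concat(lesion_frames, ignore_index=True).to_csv(out_dir / "lesions.csv", index=False)
    rows = []
    for _, cl in clinical.iterrows():
        pid = str(cl["patient_id"])
        base = scans.get((pid, "baseline"))
        interim = scans.get((pid, "interim"))
        if base is None or interim is None:
            log.warning("patient %s missing a scan; excluded", pid)
            continue
        rec = build_response_record(
            pid, base, interim,
            psa_baseline=cl.get("psa_baseline"), psa_best=cl.get("psa_best"),
        )
        rows.append(
            {
                "patient_id": pid,
                "tv_baseline_ml": base.psma_tv_ml,
                "tv_interim_ml": interim.psma_tv_ml,
                "tlq_baseline": base.tlq_sum,
                "tlq_interim": interim.tlq_sum,
                "mean_suv_max_baseline": base.mean_suv_max,
                "tv_ratio": rec.tv_ratio,
                "tv_decline_pct": rec.tv_decline_pct,
                "tv_responder": rec.tv_responder,
                "low_expression": rec.low_expression,
                "psa_baseline": cl.get("psa_baseline"),
                "psa_best": cl.get("psa_best"),
                "psa_decline_pct": rec.psa_decline_pct,
                "psa_responder": rec.psa_responder,
                "ldh": cl.get("ldh"),
                "os_months": float(cl["os_months"]),
                "event": bool(cl["event"]),
            }
        )
    return pd.DataFrame(rows)


def write_report(report: dict, cohort: pd.DataFrame, out_dir: Path) -> None:
    """Write the structured analysis report: CSV tables, JSON, KM plots."""
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out_dir / "cohort.csv", index=False)

    cox_rows = []
    for key, model in report.get("models", {}).items():
        if isinstance(model, dict) and "covariates" in model:
            for cov, eff in model["covariates"].items():
                cox_rows.append(
                    {
                        "model": key, "covariate": cov, "hr": eff["hr"],
                        "ci_lower": eff["ci_lower"], "ci_upper": eff["ci_upper"],
                        "p": eff["p"], "n_used": model["n_used"],
                    }
                )
    pd.DataFrame(cox_rows).to_csv(out_dir / "cox_results.csv", index=False)

    cut_rows = [
        {"model": key, **model}
        for key, model in report.get("models", {}).items()
        if key.startswith("maxstat_") and "cutoff" in model
    ]
    pd.DataFrame(cut_rows).to_csv(out_dir / "cutoffs.csv", index=False)

    pd.DataFrame(
        {"martingale_residual": report.get("martingale_residuals", [])}
    ).to_csv(out_dir / "martingale.csv", index=False)

    _write_km_outputs(cohort, out_dir)

    serializable = {k: v for k, v in report.items() if k != "martingale_residuals"}
    with open(out_dir / "report.json", "w") as fh:
        json.dump(serializable, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return str(obj)


def _write_km_outputs(cohort: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    from .survival import median_binarize

    curves = []
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    specs = [("tv_baseline_ml", "baseline PSMA-TV"), ("tlq_baseline", "baseline TLQ")]
    for ax, (col, title) in zip(axes, specs):
        if col not in cohort:
            continue
        try:
            flag = median_binarize(cohort[col])
        except Exception:
            continue
        for high, label in ((False, "low"), (True, "high")):
            m = flag == high
            if m.sum() == 0:
                continue
            kmf = KaplanMeierFitter()
            kmf.fit(cohort.loc[m, "os_months"], cohort.loc[m, "event"], label=label)
            kmf.plot_survival_function(ax=ax)
            sf = kmf.survival_function_
            curves.append(
                pd.DataFrame(
                    {
                        "covariate": col, "group": label,
                        "time_months": sf.index, "survival": sf[label],
                    }
                )
            )
        ax.set_title(f"OS by median {title}")
        ax.set_xlabel("months")
    fig.tight_layout()
    fig.savefig(out_dir / "km_plots.png", dpi=100)
    plt.close(fig)
    if curves:
        pd.concat(curves, ignore_index=True).to_csv(out_dir / "km_curves.csv", index=False)
    else:
        pd.DataFrame(columns=["covariate", "group", "time_months", "survival"]).to_csv(
            out_dir / "km_curves.csv", index=False
        )


def run_pipeline(config: dict, seed: int = 0, out_dir: str | Path = "psmavol_out") -> dict:
    """Run the configured pipeline end to end; returns the analysis report.

    The output directory receives cohort.csv, lesions.csv (imaging modes),
    cox_results.csv, cutoffs.csv, martingale.csv, km_curves.csv, km_plots.png,
    report.json and manifest.json.
    """
    _validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seg_opts = {
        k: config[src]
        for k, src in (("min_voxels", "min_voxels"), ("overlap_frac", "overlap_frac"), ("sd_ddof", "sd_ddof"))
        if src in config
    }

    stage = "input"
    try:
        if "simulation" in config:
            sim_cfg = config["simulation"] or {}
            if sim_cfg.get("imaging", False):
                stage = "imaging-simulation"
                cohort = _run_imaging_simulation(sim_cfg, seed, out_dir, seg_opts)
            else:
                stage = "cohort-simulation"
                cohort = simulate_cohort(_cohort_spec(sim_cfg, seed))
        else:
            stage = "data-loading"
            cohort = _run_data_mode(config["data"], out_dir, seg_opts)
        if cohort.empty:
            raise InputError("no patients survived the input stage")
        stage = "analysis"
        report = run_paper_analysis(
            cohort, alpha=float(config.get("alpha", 0.05)), seed=seed
        )
        stage = "reporting"
        write_report(report, cohort, out_dir)
    except Exception as exc:
        log.error("pipeline aborted in stage %r: %s", stage, exc)
        raise

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "stage_counts": {
            "patients_in": int(len(cohort)),
            "patients_analyzed": report["n_patients"],
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return report
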