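"""Simulate -> fit -> analyze -> report orchestration.

Library entry points (used by the CLI, the test-suite and the acceptance
script):

``refraction_mean_iod``
    group mean interocular refractive error difference per arm;
``mechanics_percent_iod``
    end-to-end recovery of the percent interocular differences in tensile
    modulus and hydraulic conductivity: oracle-simulated traces, series-model
    refits, paired log-link model with strain-deviation correction, EMM
    contrasts;
``run``
    staged file-based pipeline with a reproducible run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biometry, stats, uct_fitting
from .exceptions import DependencyError, InvalidInputError
from .synthetic import (
    CohortConfig,
    generate_assay_data,
    generate_cohort,
    generate_refraction_biometry,
    generate_uct_traces,
    fd_study_config,
)

__all__ = [
    "RunManifest",
    "refraction_mean_iod",
    "mechanics_percent_iod",
    "mechanics_outcome_table",
    "run",
]


# ---------------------------------------------------------------------------
# estimand recovery (in-memory)

def refraction_mean_iod(config: CohortConfig, seed: int) -> dict:
    """Per-arm paired Gaussian analysis of the refractive shift (D)."""
    manifest = generate_cohort(config, seed)
    re_table, _ = generate_refraction_biometry(manifest, config, seed)
    wide = re_table.pivot_table(index=["animal_id", "arm"], columns="eye_role",
                                values="refraction_d").reset_index()
    wide["iod"] = wide["treated"] - wide["contralateral"]
    out = {}
    for arm, grp in wide.groupby("arm"):
        out[arm] = stats.paired_gaussian_iod(grp["iod"].to_numpy())
    return out


def fit_records(records) -> pd.DataFrame:
    """Fit every raw compression record; returns the tidy step-fit table."""
    fits = [uct_fitting.fit_step(rec) for rec in records]
    return uct_fitting.fits_to_frame(fits)


def mechanics_outcome_table(step_fits: pd.DataFrame,
                            manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-eye, per-step outcome table for the paired log-link model."""
    per_eye = uct_fitting.aggregate_eye(step_fits)
    meta = manifest[["eye_id", "animal_id", "arm", "eye_role"]].drop_duplicates()
    table = per_eye.merge(meta, on="eye_id", how="left")
    if table["animal_id"].isna().any():
        raise InvalidInputError("step fits reference eyes absent from the manifest")
    return table.rename(columns={"eye_role": "eye"})


_MECH_FORMULA = ("_log_y ~ C(eye, Treatment(reference='contralateral')) "
                 "+ C(step) + strain_deviation")


def mechanics_percent_iod(
    config: CohortConfig, seed: int, arms=None, records=None, manifest=None
) -> dict:
    """End-to-end percent IOD recovery for H_A_plus and k, per arm.

    Returns ``{arm: {outcome: EffectEstimate}}``.  ``records``/``manifest``
    may be supplied to reuse a previous simulation.
    """
    if manifest is None:
        manifest = generate_cohort(config, seed)
    if arms is not None:
        manifest = manifest[manifest["arm"].isin(arms)]
    if records is None:
        records, _ = generate_uct_traces(manifest, config, seed)
    step_fits = fit_records(records)
    table = mechanics_outcome_table(step_fits, manifest)
    out: dict = {}
    for arm, grp in table.groupby("arm"):
        formula = _MECH_FORMULA if grp["step"].nunique() > 1 else (
            "_log_y ~ C(eye, Treatment(reference='contralateral')) + strain_deviation")
        out[arm] = {}
        for outcome in ("H_A_plus", "k"):
            fit = stats.fit_paired_log_model(grp, formula=formula, outcome=outcome)
            out[arm][outcome] = stats.emm_percent_iod(fit, contrast="eye")
    return out


# ---------------------------------------------------------------------------
# staged, file-based pipeline

@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    out_dir: str
    stages: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def record(self, stage: str, status: str, duration_s: float, outputs) -> None:
        self.stages[stage] = {"status": status, "duration_s": round(duration_s, 3)}
        for p in outputs:
            rel = str(p)
            if rel not in self.outputs:
                self.outputs.append(rel)

    def save(self, path: Path) -> None:
        from . import __version__

        path.write_text(json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "out_dir": self.out_dir, "scleramech_version": __version__,
             "stages": self.stages, "outputs": sorted(self.outputs)},
            indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(path.read_text())
        return cls(config_hash=d["config_hash"], seed=d["seed"],
                   out_dir=d["out_dir"], stages=d["stages"],
                   outputs=d["outputs"])


def config_hash(config: CohortConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{needed_by}' requires {path.name} produced by stage "
            f"'{stage}'; run that stage first"
        )
    return path


def _records_to_frames(records):
    trace_rows, meta_rows = [], []
    for rec in records:
        meta_rows.append({
            "sample_id": rec.sample_id, "eye_id": rec.eye_id,
            "step": rec.step_index, "diameter_m": rec.diameter_m,
            "thickness_ref_m": rec.thickness_ref_m,
            "target_strain": rec.target_strain,
            "applied_strain": rec.applied_strain,
            "ramp_duration": rec.ramp_duration,
        })
        trace_rows.append(pd.DataFrame({
            "sample_id": rec.sample_id, "step": rec.step_index,
            "time_s": rec.times, "load_uN": rec.load_uN,
        }))
    return pd.concat(trace_rows, ignore_index=True), pd.DataFrame(meta_rows)


def _frames_to_records(traces: pd.DataFrame, meta: pd.DataFrame):
    from .uct_fitting import RawCompressionRecord

    records = []
    for _, m in meta.iterrows():
        grp = traces[(traces["sample_id"] == m.sample_id) & (traces["step"] == m.step)]
        records.append(RawCompressionRecord(
            sample_id=m.sample_id, eye_id=m.eye_id, step_index=int(m.step),
            times=grp["time_s"].to_numpy(), load_uN=grp["load_uN"].to_numpy(),
            diameter_m=m.diameter_m, thickness_ref_m=m.thickness_ref_m,
            target_strain=m.target_strain, applied_strain=m.applied_strain,
            ramp_duration=m.ramp_duration,
        ))
    return records


def _stage_simulate(config, seed, out: Path) -> list:
    import tifffile

    manifest = generate_cohort(config, seed)
    manifest.to_csv(out / "manifest.csv", index=False)
    records, truth = generate_uct_traces(manifest, config, seed)
    traces, meta = _records_to_frames(records)
    traces.to_csv(out / "traces.csv", index=False)
    meta.to_csv(out / "trace_meta.csv", index=False)
    truth.to_csv(out / "uct_truth.csv", index=False)
    re_table, ifaces = generate_refraction_biometry(manifest, config, seed)
    re_table.to_csv(out / "refraction.csv", index=False)
    ifaces.to_csv(out / "interfaces.csv", index=False)
    assay = generate_assay_data(manifest, config, seed)
    _plate_to_csv(assay["dmmb_plate"], out / "dmmb_plate.csv")
    _plate_to_csv(assay["picogreen_plate"], out / "picogreen_plate.csv")
    pd.Series(assay["dry_mass_mg"], name="dry_mass_mg").rename_axis("eye_id") \
        .reset_index().to_csv(out / "dry_mass.csv", index=False)
    assay["truth"].to_csv(out / "assay_truth.csv", index=False)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    written = []
    for eye_id, slide in assay["slides"].items():
        for kind in ("chac", "chb", "buffer_only"):
            tifffile.imwrite(img_dir / f"{eye_id}_{kind}.tiff",
                             getattr(slide, kind))
        tifffile.imwrite(img_dir / f"{eye_id}_mask.tiff",
                         slide.mask_chac.astype(np.uint8) * 255)
    return ["manifest.csv", "traces.csv", "trace_meta.csv", "uct_truth.csv",
            "refraction.csv", "interfaces.csv", "dmmb_plate.csv",
            "picogreen_plate.csv", "dry_mass.csv", "assay_truth.csv", "images/"]


def _plate_to_csv(plate, path: Path) -> None:
    rows = [{"kind": "standard", "id": f"std{i}", "concentration": c,
             "a1": a, "a2": a, "a3": a}
            for i, (c, a) in enumerate(plate.standards)]
    rows += [{"kind": "sample", "id": sid, "concentration": np.nan,
              "a1": t[0], "a2": t[1], "a3": t[2]}
             for sid, t in plate.samples.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def _plate_from_csv(path: Path, assay: str):
    from .assays import PlateData

    df = pd.read_csv(path)
    standards = tuple(
        (row.concentration, row.a1)
        for row in df[df["kind"] == "standard"].itertuples()
    )
    samples = {row.id: (row.a1, row.a2, row.a3)
               for row in df[df["kind"] == "sample"].itertuples()}
    return PlateData(standards=standards, samples=samples, assay=assay)


def _stage_fit(out: Path) -> list:
    traces = pd.read_csv(_require(out / "traces.csv", "simulate", "fit"))
    meta = pd.read_csv(_require(out / "trace_meta.csv", "simulate", "fit"))
    records = _frames_to_records(traces, meta)
    step_fits = fit_records(records)
    step_fits.to_csv(out / "step_fits.csv", index=False)
    uct_fitting.aggregate_eye(step_fits).to_csv(out / "per_eye.csv", index=False)
    return ["step_fits.csv", "per_eye.csv"]


def _stage_analyze(config, seed, out: Path) -> list:
    import tifffile

    from .assays import SlideImageSet, ihc_normalized_intensity, quantify_sgag

    manifest = pd.read_csv(_require(out / "manifest.csv", "simulate", "analyze"))
    step_fits = pd.read_csv(_require(out / "step_fits.csv", "fit", "analyze"))
    table = mechanics_outcome_table(step_fits, manifest)
    results: dict = {"mechanics": {}, "refraction": {}, "biometry": {}, "assays": {}}
    estimates = []
    for arm, grp in table.groupby("arm"):
        results["mechanics"][arm] = {}
        for outcome in ("H_A_plus", "k"):
            fit = stats.fit_paired_log_model(grp, formula=_MECH_FORMULA,
                                             outcome=outcome)
            est = stats.emm_percent_iod(fit, contrast="eye")
            estimates.append((arm, outcome, est))
            results["mechanics"][arm][outcome] = {
                "percent_iod": est.percent_change,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "p_raw": est.p_raw,
            }
    # multivariate-t adjustment across the per-outcome arm contrasts
    for outcome in ("H_A_plus", "k"):
        fam = [(arm, est) for arm, o, est in estimates if o == outcome]
        if len(fam) > 1:
            ests = np.array([e.estimate_log for _, e in fam])
            cov = np.diag([e.se_log**2 for _, e in fam])
            _, p_adj = stats.adjust_multivariate_t(ests, cov, df=np.inf,
                                                   seed=seed)
            for (arm, _), p in zip(fam, p_adj):
                results["mechanics"][arm][outcome]["p_adjusted"] = float(p)

    re_table = pd.read_csv(_require(out / "refraction.csv", "simulate", "analyze"))
    wide = re_table.pivot_table(index=["animal_id", "arm"], columns="eye_role",
                                values="refraction_d").reset_index()
    wide["iod"] = wide["treated"] - wide["contralateral"]
    for arm, grp in wide.groupby("arm"):
        results["refraction"][arm] = stats.paired_gaussian_iod(grp["iod"].to_numpy())

    ifaces = pd.read_csv(_require(out / "interfaces.csv", "simulate", "analyze"))
    bio = biometry.biometry_table(ifaces)
    bio = bio.merge(ifaces[["eye_id", "animal_id", "arm", "eye_role"]], on="eye_id")
    al = bio.pivot_table(index=["animal_id", "arm"], columns="eye_role",
                         values="AL").reset_index()
    al["iod"] = al["treated"] - al["contralateral"]
    for arm, grp in al.groupby("arm"):
        results["biometry"][arm] = {"AL": stats.paired_gaussian_iod(grp["iod"].to_numpy())}

    dmmb = _plate_from_csv(out / "dmmb_plate.csv", "DMMB_525nm")
    pico = _plate_from_csv(out / "picogreen_plate.csv", "picogreen")
    dry = pd.read_csv(out / "dry_mass.csv").set_index("eye_id")["dry_mass_mg"].to_dict()
    sgag = quantify_sgag(dmmb, dry, pico,
                         digest_volume_mL=config.assay.digest_volume_mL)
    sgag.to_csv(out / "sgag.csv", index=False)
    results["assays"]["sgag_mass_fraction_mean"] = float(
        sgag["sgag_mass_fraction_ug_mg"].mean())

    img_dir = out / "images"
    ihc_rows = []
    for eye_id in manifest["eye_id"]:
        mask = tifffile.imread(img_dir / f"{eye_id}_mask.tiff") > 0
        slide = SlideImageSet(
            chac=tifffile.imread(img_dir / f"{eye_id}_chac.tiff"),
            chb=tifffile.imread(img_dir / f"{eye_id}_chb.tiff"),
            buffer_only=tifffile.imread(img_dir / f"{eye_id}_buffer_only.tiff"),
            mask_chac=mask, mask_chb=mask, mask_buffer=mask, slide_id=eye_id,
        )
        ihc_rows.append(ihc_normalized_intensity(slide))
    ihc = pd.DataFrame(ihc_rows).rename(columns={"slide_id": "eye_id"})
    ihc = ihc.merge(manifest[["eye_id", "arm", "eye_role"]], on="eye_id")
    ihc.to_csv(out / "ihc.csv", index=False)
    results["assays"]["ihc_mean_ratios"] = {
        f"{arm}:{role}": {"chac": float(g["chac_ratio"].mean()),
                          "chb": float(g["chb_ratio"].mean())}
        for (arm, role), g in ihc.groupby(["arm", "eye_role"])
    }

    (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True,
                                                 default=float))
    return ["results.json", "sgag.csv", "ihc.csv"]


def _stage_report(config, out: Path) -> list:
    results = json.loads(_require(out / "results.json", "analyze", "report").read_text())
    rows = []
    for arm, arm_cfg in config.arms.items():
        targets = {
            ("mechanics", "H_A_plus"): 100.0 * (arm_cfg.h_effect - 1.0),
            ("mechanics", "k"): 100.0 * (arm_cfg.k_effect - 1.0),
            ("refraction", "RE"): arm_cfg.re_iod_mean,
        }
        mech = results["mechanics"].get(arm, {})
        for outcome in ("H_A_plus", "k"):
            if outcome in mech:
                rows.append({
                    "arm": arm, "outcome": f"percent_iod_{outcome}",
                    "estimate": mech[outcome]["percent_iod"],
                    "target": targets[("mechanics", outcome)],
                    "p_raw": mech[outcome].get("p_raw"),
                    "p_adjusted": mech[outcome].get("p_adjusted"),
                })
        if arm in results["refraction"]:
            rows.append({
                "arm": arm, "outcome": "mean_iod_re_d",
                "estimate": results["refraction"][arm]["mean_iod"],
                "target": targets[("refraction", "RE")],
                "p_raw": results["refraction"][arm]["p"],
                "p_adjusted": None,
            })
    report = pd.DataFrame(rows)
    report.to_csv(out / "report.csv", index=False)
    return ["report.csv"]


STAGES = ("simulate", "fit", "analyze", "report")


def run(command: str, config: CohortConfig | str | None, seed: int,
        out_dir) -> RunManifest:
    """Run one stage (or ``all``) of the pipeline into ``out_dir``."""
    if isinstance(config, (str, Path)):
        config = CohortConfig.from_yaml(config)
    if config is None:
        config = fd_study_config()
    if command not in STAGES + ("all",):
        raise InvalidInputError(f"unknown command {command!r}; choose from "
                                f"{STAGES + ('all',)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "run_manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        manifest.config_hash = config_hash(config)
        manifest.seed = seed
    else:
        manifest = RunManifest(config_hash=config_hash(config), seed=seed,
                               out_dir=str(out))
    todo = STAGES if command == "all" else (command,)
    for stage in todo:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                outputs = _stage_simulate(config, seed, out)
            elif stage == "fit":
                outputs = _stage_fit(out)
            elif stage == "analyze":
                outputs = _stage_analyze(config, seed, out)
            else:
                outputs = _stage_report(config, out)
        except Exception:
            manifest.record(stage, "failed", time.perf_counter() - t0, [])
            manifest.save(manifest_path)
            raise
        manifest.record(stage, "ok", time.perf_counter() - t0, outputs)
        manifest.save(manifest_path)
    return manifest
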