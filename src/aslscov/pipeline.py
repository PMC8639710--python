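"""End-to-end pipeline: simulate -> synthesize -> quantify -> metrics -> stats.

Stages write into an output directory together with a run manifest (config
hash, seeds, package version, stage status).  Re-running with the same
config and seed reproduces the metrics table bit for bit; completed stages
are skipped on resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import GroupSummary, anova_from_summary, partial_corr, pearson_corr
from .kinetic import AcquisitionParams, synthesize_asl
from .nifti_io import save_asl_dataset, save_phantom
from .ordered_bayes import STANDARD_RESTRICTIONS, bf_order_restricted, parse_restriction
from .phantom import CohortConfig, simulate_cohort
from .quantify import average_repeats, calibrate_m0, pvc_regress, quantify_cbf
from .roi import extract_subject_metrics, records_to_frame, roi_set_from_labels

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    restrictions: tuple = ("control<scd<mci<ad", "[control=scd]<mci<ad",
                           "control<scd<[mci=ad]", "[control=scd]<[mci=ad]")
    bayes_rois: tuple = ("gm", "frontal", "parietal", "temporal", "occipital")
    gm_threshold: float = 0.25
    prior_scale: float = 0.5
    n_samples: int = 2000
    n_chains: int = 4
    outdir: str = "aslscov_run"
    seed: int = 1234
    save_nifti: bool = True
    dry_run: bool = False

    def validate(self) -> list:
        problems = []
        try:
            self.cohort.validate()
        except ValueError as e:
            problems.append(f"cohort: {e}")
        for r in self.restrictions:
            try:
                parse_restriction(r)
            except ValueError as e:
                problems.append(f"restriction {r!r}: {e}")
        if not (0 < self.gm_threshold < 1):
            problems.append("gm_threshold must be in (0, 1)")
        if self.n_samples < 10:
            problems.append("n_samples too small")
        if self.seed is None:
            problems.append("seed is mandatory")
        return problems

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        cohort = CohortConfig(**d.pop("cohort", {}))
        acq = AcquisitionParams(**d.pop("acquisition", {}))
        for key in ("restrictions", "bayes_rois"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(cohort=cohort, acquisition=acq, **d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _manifest_path(outdir: Path) -> Path:
    return outdir / "manifest.json"


def _load_manifest(outdir: Path) -> dict:
    p = _manifest_path(outdir)
    if p.exists():
        return json.loads(p.read_text())
    return {}


def _write_manifest(outdir: Path, manifest: dict) -> None:
    _manifest_path(outdir).write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a report bundle of output paths and tables.

    Stage order: simulate (phantoms + cohort table), acquire (synthetic ASL
    + quantification + ROI metrics table), bayes (order-restricted Bayes
    factors per ROI), stats (classical cohort statistics).  A stage whose
    outputs already exist under an unchanged config hash is skipped.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    if config.dry_run:
        return {"dry_run": True, "problems": []}

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(outdir)
    if manifest.get("config_hash") != config.config_hash:
        manifest = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "version": __version__,
            "stages": {},
        }
    stages = manifest.setdefault("stages", {})
    config.to_yaml(outdir / "config.yaml")

    cohort_csv = outdir / "cohort.csv"
    metrics_csv = outdir / "metrics.csv"
    bayes_csv = outdir / "bayes_report.csv"
    stats_csv = outdir / "cohort_stats_report.csv"

    # --- stage 1+2: simulate phantoms, synthesize, quantify, metrics ------
    if stages.get("metrics") == "done" and metrics_csv.exists() and cohort_csv.exists():
        metrics = pd.read_csv(metrics_csv)
    else:
        cohort_cfg = config.cohort.replace(seed=config.seed)
        subjects = simulate_cohort(cohort_cfg)
        pd.DataFrame([meta for _, meta in subjects]).to_csv(cohort_csv, index=False)
        records = []
        params = config.acquisition
        for ph, meta in subjects:
            ds = synthesize_asl(ph, params, seed=meta["seed"])
            mean_diff = average_repeats(ds.diff_volumes)
            m0b = calibrate_m0(ds.m0_volume, params)
            cbf = quantify_cbf(mean_diff, m0b, params)
            cbf_gm_pvc, _ = pvc_regress(cbf, ph.pv_gm, ph.pv_wm)
            roiset = roi_set_from_labels(
                ph.roi_labels, ph.pv_gm, config.gm_threshold
            )
            records.append(extract_subject_metrics(cbf, cbf_gm_pvc, roiset, meta))
            if config.save_nifti:
                sdir = outdir / "subjects" / meta["id"]
                save_phantom(ph, sdir)
                save_asl_dataset(ds, sdir, ph.affine)
                from .nifti_io import save_map

                save_map(cbf.values, sdir / "cbf_nonpvc.nii.gz", ph.affine)
                save_map(cbf_gm_pvc.values, sdir / "cbf_pvc_gm.nii.gz", ph.affine)
        metrics = records_to_frame(records)
        metrics.to_csv(metrics_csv, index=False, float_format="%.10g")
        stages["metrics"] = "done"
        _write_manifest(outdir, manifest)

    # --- stage 3: order-restricted Bayes factors --------------------------
    if stages.get("bayes") == "done" and bayes_csv.exists():
        bayes_report = pd.read_csv(bayes_csv)
    else:
        rows = []
        rng = np.random.default_rng(config.seed)
        for roi in config.bayes_rois:
            df = metrics.rename(columns={f"scov_{roi}": "value"})[
                ["value", "group4", "age", "sex", "site"]
            ].rename(columns={"group4": "group"})
            for rname in config.restrictions:
                restriction = parse_restriction(rname)
                res = bf_order_restricted(
                    df,
                    restriction,
                    prior_scale=config.prior_scale,
                    n_samples=config.n_samples,
                    n_chains=config.n_chains,
                    seed=int(rng.integers(0, 2**31)),
                )
                rows.append(
                    {
                        "roi": roi,
                        "restriction": str(res.restriction),
                        "bf_vs_null": res.bf_vs_null,
                        "bf_full_vs_null": res.bf_full_vs_null,
                        "posterior_constraint_prob": res.posterior_constraint_prob,
                        "prior_constraint_prob": res.prior_constraint_prob,
                        "mc_standard_error": res.mc_standard_error,
                        "ess_min": res.ess_min,
                        "rhat_max": res.rhat_max,
                    }
                )
        bayes_report = pd.DataFrame(rows)
        bayes_report.to_csv(bayes_csv, index=False, float_format="%.10g")
        stages["bayes"] = "done"
        _write_manifest(outdir, manifest)

    # --- stage 4: classical cohort statistics -----------------------------
    if stages.get("stats") == "done" and stats_csv.exists():
        stats_report = pd.read_csv(stats_csv)
    else:
        rows = []
        age_sum = GroupSummary.from_data(metrics["age"], metrics["group4"])
        F, dfb, dfw, p = anova_from_summary(age_sum)
        rows.append({"test": "anova_age", "statistic": F, "df1": dfb, "df2": dfw, "p": p})
        r, p = pearson_corr(metrics["scov_gm"], metrics["cbf_gm"])
        rows.append({"test": "pearson_scov_gm_vs_cbf_gm", "statistic": r, "p": p})
        cov = np.column_stack(
            [
                metrics["age"],
                (metrics["sex"] == "f").astype(float),
                pd.get_dummies(metrics["site"]).to_numpy(dtype=float)[:, :-1],
            ]
        )
        r, p = partial_corr(metrics["scov_gm"], metrics["cbf_gm"], cov)
        rows.append(
            {"test": "partial_scov_gm_vs_cbf_gm", "statistic": r, "p": p}
        )
        stats_report = pd.DataFrame(rows)
        stats_report.to_csv(stats_csv, index=False, float_format="%.10g")
        stages["stats"] = "done"
        _write_manifest(outdir, manifest)

    return {
        "cohort": cohort_csv,
        "metrics": metrics_csv,
        "bayes_report": bayes_csv,
        "stats_report": stats_csv,
        "manifest": _manifest_path(outdir),
        "metrics_frame": metrics,
        "bayes_frame": bayes_report,
        "stats_frame": stats_report,
    }


def validate_inputs(paths: dict) -> list:
    """Validate external inputs; returns a list of problem descriptions.

    ``paths`` may contain ``cbf`` (NIfTI), ``masks`` (dict name -> NIfTI)
    and ``cohort`` (CSV).  Checks that grids and affines agree, masks are
    non-empty, and the cohort table carries the required columns.  Never
    mutates the inputs.
    """
    from .nifti_io import load_map

    problems = []
    ref_shape = ref_affine = None
    cbf_path = paths.get("cbf")
    if cbf_path is not None:
        try:
            data, aff = load_map(cbf_path)
            ref_shape, ref_affine = data.shape, aff
        except Exception as e:  # unreadable file
            problems.append(f"cbf: cannot read {cbf_path}: {e}")
    for name, mpath in (paths.get("masks") or {}).items():
        try:
            m, aff = load_map(mpath)
        except Exception as e:
            problems.append(f"mask {name}: cannot read {mpath}: {e}")
            continue
        if not np.any(m):
            problems.append(f"mask {name}: empty mask")
        if ref_shape is not None and m.shape != ref_shape:
            problems.append(
                f"mask {name}: grid {m.shape} does not match CBF grid {ref_shape}"
            )
        elif ref_affine is not None and not np.allclose(aff, ref_affine, atol=1e-4):
            problems.append(f"mask {name}: affine does not match CBF affine")
    cohort_path = paths.get("cohort")
    if cohort_path is not None:
        try:
            df = pd.read_csv(cohort_path)
        except Exception as e:
            problems.append(f"cohort: cannot read {cohort_path}: {e}")
        else:
            for col in ("id", "group", "age", "sex", "site"):
                if col not in df.columns:
                    problems.append(f"cohort: missing column {col!r}")
    return problems
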