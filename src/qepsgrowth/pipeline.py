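"""End-to-end pipeline orchestration.

Stages run in a fixed order — simulate, qc, fit, derive, reference, sds,
compare, report — and every artifact is listed in a manifest that records
the configuration hash, the seed and per-stage timings, so identical
configurations produce identical manifests (timings excluded from the
hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import compare as compare_mod
from .fitting import (
    FitConfig,
    QCThresholds,
    fit_cohort,
    qc_screen,
    read_records,
    write_fit_results,
    write_records,
)
from .plotting import plot_individual
from .reference import apply_reference, build_reference
from .simulate import generate_cohort, get_preset

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    output_dir: str = "qeps_output"
    seed: int = 1
    n_reference: int = 100
    n_ks: int = 20
    reference_preset: str = "reference"
    ks_preset: str = "ks"
    # When set, fit these files instead of simulating the clinical group.
    input_measurements_csv: str | None = None
    input_covariates_csv: str | None = None
    n_starts: int = 7
    eligibility: str = "pubertal"
    stop_mode: str = "hard_cap"
    max_childhood_gap_years: float = 4.0
    max_puberty_gap_years: float = 2.0
    make_figures: bool = True
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # output_dir is excluded: where artifacts land does not change them
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise PipelineError(name, str(exc)) from exc
                log.info("stage %s: done in %.2fs", name, timings[name])

        return _Stage()

    def register(name: str, path: Path, hashed: bool = True):
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path) if hashed else None,
        }

    # -- simulate ----------------------------------------------------------
    with stage("simulate"):
        ref_spec = get_preset(config.reference_preset, config.n_reference, config.seed)
        ref_records, ref_truth = generate_cohort(ref_spec)
        if config.input_measurements_csv is not None:
            if not Path(config.input_measurements_csv).exists():
                raise FileNotFoundError(
                    f"input measurements not found: {config.input_measurements_csv}"
                )
            ks_records = read_records(
                config.input_measurements_csv, config.input_covariates_csv
            )
            ks_truth = None
        else:
            ks_spec = get_preset(config.ks_preset, config.n_ks, config.seed + 1)
            ks_records, ks_truth = generate_cohort(ks_spec)
        write_records(ref_records, out / "reference_measurements.csv",
                      out / "reference_covariates.csv")
        write_records(ks_records, out / "ks_measurements.csv",
                      out / "ks_covariates.csv")
        ref_truth.to_csv(out / "reference_truth.csv", index=False)
        register("reference_measurements", out / "reference_measurements.csv")
        register("reference_covariates", out / "reference_covariates.csv")
        register("ks_measurements", out / "ks_measurements.csv")
        register("ks_covariates", out / "ks_covariates.csv")
        register("reference_truth", out / "reference_truth.csv")
        if ks_truth is not None:
            ks_truth.to_csv(out / "ks_truth.csv", index=False)
            register("ks_truth", out / "ks_truth.csv")

    # -- qc ----------------------------------------------------------------
    thresholds = QCThresholds(
        max_childhood_gap_years=config.max_childhood_gap_years,
        max_puberty_gap_years=config.max_puberty_gap_years,
    )
    with stage("qc"):
        qc_rows = []
        for name, records in (("reference", ref_records), ("ks", ks_records)):
            for rec in records:
                rep = qc_screen(rec, thresholds)
                qc_rows.append(
                    {
                        "id": rec.id,
                        "group": name,
                        "n_infancy": rep.n_infancy,
                        "n_childhood": rep.n_childhood,
                        "n_puberty": rep.n_puberty,
                        "n_adult": rep.n_adult,
                        "max_gap_childhood_years": rep.max_gap_childhood_years,
                        "max_gap_puberty_years": rep.max_gap_puberty_years,
                        "eligible_prepubertal": rep.eligible_prepubertal,
                        "eligible_pubertal": rep.eligible_pubertal,
                        "exclusion_reasons": "; ".join(rep.exclusion_reasons),
                    }
                )
        qc_df = pd.DataFrame(qc_rows)
        qc_df.to_csv(out / "qc_report.csv", index=False)
        register("qc_report", out / "qc_report.csv")
        manifest["stages"]["qc"] = {
            "n_records": len(qc_rows),
            "n_eligible_pubertal": int(qc_df["eligible_pubertal"].sum()),
        }

    # -- fit + derive ------------------------------------------------------
    fit_config = FitConfig(
        n_starts=config.n_starts,
        seed=config.seed,
        eligibility=config.eligibility,
        stop_mode=config.stop_mode,
        qc_thresholds=thresholds,
    )
    with stage("fit"):
        ref_fits = fit_cohort(ref_records, fit_config)
        ks_fits = fit_cohort(ks_records, fit_config)
        if not ref_fits:
            raise RuntimeError("no eligible reference records survived QC")
        write_fit_results(ref_fits, out / "reference_fits.csv",
                          out / "reference_fit_diagnostics.json")
        write_fit_results(ks_fits, out / "ks_fits.csv",
                          out / "ks_fit_diagnostics.json")
        for n in ("reference_fits", "ks_fits"):
            register(n, out / f"{n}.csv")
        register("reference_fit_diagnostics", out / "reference_fit_diagnostics.json")
        register("ks_fit_diagnostics", out / "ks_fit_diagnostics.json")
        manifest["stages"]["fit"] = {
            "n_reference_fits": len(ref_fits),
            "n_ks_fits": len(ks_fits),
            "n_reference_in": len(ref_records),
            "n_ks_in": len(ks_records),
        }

    # -- reference + sds ---------------------------------------------------
    with stage("reference"):
        ref_model = build_reference(ref_fits, ref_records)
        ref_model.to_json(out / "reference_model.json")
        register("reference_model", out / "reference_model.json")

    with stage("sds"):
        ref_table = apply_reference(ref_fits, ref_records, ref_model)
        ks_table = apply_reference(ks_fits, ks_records, ref_model)
        ref_table.to_csv(out / "reference_variables.csv", index=False)
        ks_table.to_csv(out / "ks_variables.csv", index=False)
        register("reference_variables", out / "reference_variables.csv")
        register("ks_variables", out / "ks_variables.csv")

    # -- compare -----------------------------------------------------------
    with stage("compare"):
        comparisons = compare_mod.compare_groups(ks_table, ref_table)
        table = compare_mod.summary_table(comparisons, "ks", "reference")
        table.to_csv(out / "group_comparison.csv", index=False)
        (out / "group_comparison.txt").write_text(
            compare_mod.render_text(table) + "\n"
        )
        compare_mod.smd_forest_frame(comparisons).to_csv(
            out / "smd_forest.csv", index=False
        )
        register("group_comparison", out / "group_comparison.csv")
        register("group_comparison_text", out / "group_comparison.txt")
        register("smd_forest", out / "smd_forest.csv")
        manifest["stages"]["compare"] = {"n_variables": len(comparisons)}

    # -- report ------------------------------------------------------------
    with stage("report"):
        if config.make_figures and ks_fits:
            figdir = out / "figures"
            figdir.mkdir(exist_ok=True)
            rec_by_id = {r.id: r for r in ks_records}
            fit0 = ks_fits[0]
            rec0 = rec_by_id[fit0.record_id]
            for mode in ("components", "puberty_aligned", "sds"):
                p = figdir / f"{fit0.record_id}_{mode}.png"
                plot_individual(fit0, rec0, mode, ref=ref_model, path=p)
                # figure bytes are not hashed: raster output is not
                # guaranteed byte-stable across matplotlib versions
                register(f"figure_{mode}", p, hashed=False)

    manifest["timings_s"] = timings
    content = {k: v["sha256"] for k, v in manifest["artifacts"].items() if v["sha256"]}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(
            {"config": manifest["config_hash"], "artifacts": content}, sort_keys=True
        ).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
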