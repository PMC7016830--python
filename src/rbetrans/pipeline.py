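"""End-to-end analysis pipeline.

Two lines of work on one paired-dose cohort: (1) per-v-level quadratic
fits of (D_LEM|v, D_MKM|v) pairs, inverted with 95% confidence bands into
translated LEM-language constraints; (2) per-patient gEUD -> LKB NTCP
with per-group bootstrap summaries, plus compliance reports under the
MKM-language limits (on MKM curves) and the translated / absolute-volume
LEM limits (on LEM curves), and cohort-averaged DVH bands.

Deterministic given the seed; a run manifest records the seed, the
configuration hash and the package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    DEFAULT_V_LEVELS,
    Cohort,
    CohortConfig,
    extract_pairs,
    generate_cohort,
)
from .constraints import (
    cohort_compliance,
    compliance_frame,
    evaluate,
    get_constraint_set,
)
from .dvh import VolumeSpec, average_dvh
from .io import read_cohort, write_cohort
from .ntcp import LKBParameters, cohort_ntcp
from .translation import fit_quadratic_xy, translation_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

# MKM-language targets translated into the LEM language, keyed by v-level
DEFAULT_TRANSLATION_TARGETS = {
    VolumeSpec("percent", 20): 28.8,
    VolumeSpec("percent", 10): 46.4,
    VolumeSpec("percent", 5): 60.0,
    VolumeSpec("percent", 1): 66.0,
}


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    manifest_path: str | None = None  # when set, load this cohort instead of simulating
    v_levels: tuple[VolumeSpec, ...] = DEFAULT_V_LEVELS
    translation_targets: dict = field(
        default_factory=lambda: dict(DEFAULT_TRANSLATION_TARGETS)
    )
    mkm_constraint_sets: tuple[str, ...] = ("OLD_MKM",)
    lem_constraint_sets: tuple[str, ...] = ("TRANSLATED_LEM", "NEW_CC")
    lkb: LKBParameters = field(default_factory=LKBParameters)
    n_boot: int = 10_000
    ci_level: float = 0.95
    seed: int = 12345

    def __post_init__(self) -> None:
        if not self.v_levels:
            raise ValueError("v_levels must be non-empty")

    def config_hash(self) -> str:
        payload = {
            "cohort": asdict(self.cohort),
            "manifest_path": self.manifest_path,
            "v_levels": [v.label() for v in self.v_levels],
            "translation_targets": {
                spec.label(): target for spec, target in self.translation_targets.items()
            },
            "mkm_constraint_sets": list(self.mkm_constraint_sets),
            "lem_constraint_sets": list(self.lem_constraint_sets),
            "lkb": asdict(self.lkb),
            "n_boot": self.n_boot,
            "ci_level": self.ci_level,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PipelineResult:
    cohort: Cohort
    pairs: pd.DataFrame
    fits: dict
    translation: pd.DataFrame
    ntcp_table: pd.DataFrame
    ntcp_summary: dict
    compliance: dict
    compliance_summary: dict
    averaged_dvhs: dict
    run_manifest: dict


def _stage(name: str):
    """Label any stage failure with the stage that raised it."""

    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[stage {name}] {exc}") from exc
            return False

    return _StageContext()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis; optionally write all artifacts under ``outdir``."""
    with _stage("cohort"):
        if config.manifest_path is not None:
            cohort = read_cohort(config.manifest_path, config.cohort)
        else:
            cohort = generate_cohort(replace(config.cohort, seed=config.seed))

    with _stage("pairs"):
        pairs = extract_pairs(cohort, config.v_levels)

    with _stage("fit-translate"):
        fits = {}
        for spec in config.v_levels:
            sub = pairs[(pairs.v_kind == spec.kind) & (pairs.v_amount == spec.amount)]
            fits[spec] = fit_quadratic_xy(sub.d_lem.to_numpy(), sub.d_mkm.to_numpy())
        targets = {
            spec: t for spec, t in config.translation_targets.items() if spec in fits
        }
        translation = translation_table(fits, targets, level=config.ci_level)

    with _stage("ntcp"):
        records = [(p.patient_id, p.group, p.dvh_mkm) for p in cohort.patients]
        ntcp_table, ntcp_summary = cohort_ntcp(
            records,
            config.lkb,
            n_boot=config.n_boot,
            seed=config.seed,
            level=config.ci_level,
        )
        group = dict(zip(ntcp_table.patient_id, ntcp_table.group))
        ntcp_table = ntcp_table.assign(group=[group[p] for p in ntcp_table.patient_id])

    with _stage("compliance"):
        compliance = {}
        summary = {}
        for name in config.mkm_constraint_sets:
            cset = get_constraint_set(name)
            reports = [evaluate(p.dvh_mkm, cset) for p in cohort.patients]
            compliance[name] = compliance_frame(reports)
            summary[name] = cohort_compliance(reports)
        for name in config.lem_constraint_sets:
            cset = get_constraint_set(name)
            reports = [evaluate(p.dvh_lem, cset) for p in cohort.patients]
            compliance[name] = compliance_frame(reports)
            summary[name] = cohort_compliance(reports)

    with _stage("average-dvh"):
        averaged = {}
        for model in ("LEM", "MKM"):
            dvhs = [
                p.dvh_lem if model == "LEM" else p.dvh_mkm for p in cohort.patients
            ]
            max_dose = max(d.max_dose for d in dvhs)
            edges = np.arange(0.0, max_dose + 0.1, 0.1)
            edges, mean, sd = average_dvh(dvhs, edges=edges)
            averaged[model] = pd.DataFrame(
                {"dose_gy_rbe": edges, "mean_fraction": mean, "sd_fraction": sd}
            )

    run_manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_patients": len(cohort.patients),
        "artifacts": [
            "translation_table.csv",
            "ntcp_table.csv",
            "ntcp_summary.json",
            "compliance_<set>.csv",
            "averaged_dvh_<model>.csv",
        ],
    }

    result = PipelineResult(
        cohort=cohort,
        pairs=pairs,
        fits=fits,
        translation=translation,
        ntcp_table=ntcp_table,
        ntcp_summary=ntcp_summary,
        compliance=compliance,
        compliance_summary={k: v for k, v in summary.items()},
        averaged_dvhs=averaged,
        run_manifest=run_manifest,
    )

    if outdir is not None:
        with _stage("write"):
            _write_artifacts(result, Path(outdir), config)
    return result


def _write_artifacts(result: PipelineResult, outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if config.manifest_path is None:
        write_cohort(result.cohort, outdir / "cohort")
    result.pairs.to_csv(outdir / "pairs.csv", index=False, float_format="%.6f")
    result.translation.to_csv(
        outdir / "translation_table.csv", index=False, float_format="%.6f"
    )
    result.ntcp_table.to_csv(outdir / "ntcp_table.csv", index=False, float_format="%.6f")
    (outdir / "ntcp_summary.json").write_text(json.dumps(result.ntcp_summary, indent=2))
    for name, frame in result.compliance.items():
        frame.to_csv(outdir / f"compliance_{name}.csv", index=False, float_format="%.6f")
    for name, frame in result.compliance_summary.items():
        frame.to_csv(
            outdir / f"compliance_summary_{name}.csv", index=False, float_format="%.6f"
        )
    for model, frame in result.averaged_dvhs.items():
        frame.to_csv(outdir / f"averaged_dvh_{model}.csv", index=False, float_format="%.6f")
    (outdir / "run_manifest.json").write_text(json.dumps(result.run_manifest, indent=2))
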