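"""Plain-text file formats: DVH CSV, cohort manifest, constraint YAML,
dose-grid fixtures.

DVH CSV layout::

    # structure=rectum
    # volume_cc=59.200000
    # rbe_model=LEM
    # patient_id=P001
    dose_gy_rbe,cum_volume_fraction
    0.000000,1.000000
    ...

Doses are serialized with 6 decimal places (well beyond the 0.1 Gy(RBE)
reporting precision); reading back reproduces curves to that precision.
Malformed headers raise :class:`ParseError` naming the offending line.

Dose-grid fixtures are a JSON sidecar (dims, voxel size, origin, RBE
model, kind) next to a single-column CSV of values in C order — voxel
``(i, j, k)`` of a ``(nx, ny, nz)`` grid is row ``i*ny*nz + j*nz + k``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortConfig, Patient
from .constraints import Constraint, ConstraintSet
from .dvh import DVH, DoseGrid, StructureMask, VolumeSpec

__all__ = [
    "ParseError",
    "read_dvh",
    "write_dvh",
    "read_manifest",
    "write_manifest",
    "read_constraints",
    "write_constraints",
    "write_cohort",
    "read_cohort",
    "read_dose_grid",
    "write_dose_grid",
    "read_structure_mask",
    "write_structure_mask",
]

MANIFEST_COLUMNS = [
    "patient_id",
    "group",
    "prescription_gy_rbe",
    "n_fractions",
    "rectum_volume_cc",
    "dvh_lem_path",
    "dvh_mkm_path",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line number."""


def write_dvh(dvh: DVH, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# structure={dvh.structure}\n")
        fh.write(f"# volume_cc={dvh.total_volume_cc:.9g}\n")
        fh.write(f"# rbe_model={dvh.rbe_model}\n")
        if dvh.patient_id is not None:
            fh.write(f"# patient_id={dvh.patient_id}\n")
        fh.write("dose_gy_rbe,cum_volume_fraction\n")
        # 12 significant digits so a write/read round trip is identity to 1e-9
        for dose, frac in zip(dvh.dose_edges, dvh.cum_volume_fraction):
            fh.write(f"{dose:.12g},{frac:.12g}\n")


def read_dvh(path: str | Path) -> DVH:
    path = Path(path)
    meta: dict[str, str] = {}
    doses: list[float] = []
    fracs: list[float] = []
    header_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise ParseError(f"{path}:{lineno}: metadata line without '='")
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != "dose_gy_rbe,cum_volume_fraction":
                    raise ParseError(
                        f"{path}:{lineno}: expected header 'dose_gy_rbe,cum_volume_fraction'"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 comma-separated values")
            try:
                doses.append(float(parts[0]))
                fracs.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    for key in ("volume_cc", "rbe_model"):
        if key not in meta:
            raise ParseError(f"{path}: missing required metadata '# {key}='")
    if meta["rbe_model"] not in ("LEM", "MKM"):
        raise ParseError(f"{path}: rbe_model must be LEM or MKM, got {meta['rbe_model']!r}")
    if not header_seen or not doses:
        raise ParseError(f"{path}: no DVH data rows found")
    frac_arr = np.asarray(fracs)
    return DVH(
        dose_edges=np.asarray(doses),
        cum_volume_fraction=frac_arr,
        total_volume_cc=float(meta["volume_cc"]),
        rbe_model=meta["rbe_model"],  # type: ignore[arg-type]
        structure=meta.get("structure", "structure"),
        patient_id=meta.get("patient_id"),
    )


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS, float_format="%.6f")


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ParseError(f"{path}:1: manifest is missing columns {missing}")
    return manifest


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write per-patient DVH CSVs plus the cohort manifest; returns the
    manifest path."""
    outdir = Path(outdir)
    dvh_dir = outdir / "dvh"
    dvh_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient in cohort.patients:
        lem_path = dvh_dir / f"{patient.patient_id}_lem.csv"
        mkm_path = dvh_dir / f"{patient.patient_id}_mkm.csv"
        write_dvh(patient.dvh_lem, lem_path)
        write_dvh(patient.dvh_mkm, mkm_path)
        rows.append(
            {
                "patient_id": patient.patient_id,
                "group": patient.group,
                "prescription_gy_rbe": patient.prescription,
                "n_fractions": patient.n_fractions,
                "rectum_volume_cc": patient.rectum_volume_cc,
                "dvh_lem_path": str(lem_path.relative_to(outdir)),
                "dvh_mkm_path": str(mkm_path.relative_to(outdir)),
            }
        )
    manifest_path = outdir / "manifest.csv"
    write_manifest(pd.DataFrame(rows), manifest_path)
    return manifest_path


def read_cohort(manifest_path: str | Path, config: CohortConfig | None = None) -> Cohort:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = read_manifest(manifest_path)
    patients = []
    for record in manifest.itertuples(index=False):
        patients.append(
            Patient(
                patient_id=str(record.patient_id),
                group=str(record.group),
                prescription=float(record.prescription_gy_rbe),
                n_fractions=int(record.n_fractions),
                rectum_volume_cc=float(record.rectum_volume_cc),
                dvh_lem=read_dvh(base / record.dvh_lem_path),
                dvh_mkm=read_dvh(base / record.dvh_mkm_path),
            )
        )
    return Cohort(config=config or CohortConfig(), patients=tuple(patients))


def write_constraints(cset: ConstraintSet, path: str | Path) -> None:
    payload = {
        "name": cset.name,
        "provenance": cset.provenance,
        "constraints": [
            {
                "kind": c.metric.kind,
                "amount": c.metric.amount,
                "limit_gy_rbe": c.limit,
                "rbe_model": c.rbe_model,
                "priority": c.priority,
            }
            for c in cset.constraints
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_constraints(path: str | Path) -> ConstraintSet:
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML: {exc}") from None
    if not isinstance(payload, dict) or "constraints" not in payload:
        raise ParseError(f"{path}: expected a mapping with a 'constraints' list")
    constraints = []
    for i, entry in enumerate(payload["constraints"]):
        try:
            constraints.append(
                Constraint(
                    metric=VolumeSpec(entry["kind"], float(entry["amount"])),
                    limit=float(entry["limit_gy_rbe"]),
                    rbe_model=entry["rbe_model"],
                    priority=entry.get("priority", "hard"),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ParseError(f"{path}: constraint entry {i}: {exc}") from None
    return ConstraintSet(
        name=str(payload.get("name", path.stem)),
        constraints=tuple(constraints),
        provenance=str(payload.get("provenance", "")),
    )


def write_dose_grid(grid: DoseGrid, sidecar_path: str | Path) -> None:
    sidecar_path = Path(sidecar_path)
    csv_path = sidecar_path.with_suffix(".csv")
    meta = {
        "kind": "dose",
        "dims": list(grid.values.shape),
        "voxel_size_mm": list(grid.voxel_size),
        "origin_mm": list(grid.origin),
        "rbe_model": grid.rbe_model,
        "values_csv": csv_path.name,
    }
    sidecar_path.write_text(json.dumps(meta, indent=2))
    # 17 significant digits: float64 -> text -> float64 is bit-exact
    np.savetxt(csv_path, grid.values.ravel(order="C"), fmt="%.17g", header="dose_gy_rbe")


def read_dose_grid(sidecar_path: str | Path) -> DoseGrid:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    if meta.get("kind") != "dose":
        raise ParseError(f"{sidecar_path}: sidecar kind is not 'dose'")
    values = np.loadtxt(sidecar_path.parent / meta["values_csv"])
    return DoseGrid(
        values=values.reshape(meta["dims"], order="C"),
        voxel_size=tuple(meta["voxel_size_mm"]),
        origin=tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
        rbe_model=meta["rbe_model"],
    )


def write_structure_mask(
    mask: StructureMask, sidecar_path: str | Path
) -> None:
    sidecar_path = Path(sidecar_path)
    csv_path = sidecar_path.with_suffix(".csv")
    meta = {
        "kind": "mask",
        "dims": list(mask.mask.shape),
        "name": mask.name,
        "values_csv": csv_path.name,
    }
    sidecar_path.write_text(json.dumps(meta, indent=2))
    np.savetxt(csv_path, mask.mask.ravel(order="C").astype(int), fmt="%d", header="in_structure")


def read_structure_mask(sidecar_path: str | Path) -> StructureMask:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    if meta.get("kind") != "mask":
        raise ParseError(f"{sidecar_path}: sidecar kind is not 'mask'")
    values = np.loadtxt(sidecar_path.parent / meta["values_csv"])
    return StructureMask(
        mask=values.reshape(meta["dims"], order="C").astype(bool),
        name=meta.get("name", "structure"),
    )
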