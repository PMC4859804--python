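"""Readers and writers for the pipeline's delimited table formats.

All tables are UTF-8, tab-delimited, one header row, decimal point only.
Axis conventions (enforced throughout): rc 0 = rostral, dv 0 = ventral,
transverse 0 = proximal/medial. Output files carry a provenance header
comment (config hash, seed) where applicable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .flatmap import SUBDIVISIONS, FlatmapSpec
from .geometry import BorderPolyline
from .labels import FiberPositions, PlexusInterval
from .synth import SyntheticStudy


class TableFormatError(ValueError):
    """A delimited input table violates its schema."""


_MEAS_COLS = {
    "animal_id": str,
    "age_days": float,
    "section_index": int,
    "subdivision": str,
    "transverse_um": float,
    "series_spacing_um": float,
}
_INJ_COLS = {
    "experiment_id": str,
    "animal_id": str,
    "age_days": float,
    "x": float,
    "y": float,
    "z": float,
}
_BORDER_COLS = {"role": str, "point_index": int, "x": float, "y": float, "z": float}
_OBS_COLS = {
    "experiment_id": str,
    "section_index": int,
    "subdivision": str,
    "kind": str,
    "start_um": float,
    "end_um": float,
    "grade": float,
    "section_extent_um": float,
}


def _read_tsv(path, columns: dict, optional: set[str] = frozenset()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in columns if c not in df.columns and c not in optional]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    out = pd.DataFrame(index=df.index)
    for col, typ in columns.items():
        if col not in df.columns:
            continue
        if typ is str:
            out[col] = df[col].astype(str)
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise TableFormatError(
                f"{path}:{line}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col}"
            )
        out[col] = vals if typ is float else vals.astype("Int64")
    out.attrs["path"] = str(path)
    return out


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a section-measurement table."""
    df = _read_tsv(path, _MEAS_COLS)
    if df["transverse_um"].isna().any() or (df["transverse_um"] < 0).any():
        line = int(((df["transverse_um"].isna()) | (df["transverse_um"] < 0)).idxmax()) + 2
        raise TableFormatError(f"{path}:{line}: invalid transverse_um")
    dup = df.duplicated(subset=["animal_id", "section_index", "subdivision"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise TableFormatError(
            f"{path}:{line}: duplicate (animal, section, subdivision)"
        )
    unknown = set(df["subdivision"]) - set(SUBDIVISIONS)
    if unknown:
        raise TableFormatError(f"{path}: unknown subdivision(s) {sorted(unknown)}")
    df["section_index"] = df["section_index"].astype(int)
    return df


def read_injections(path) -> pd.DataFrame:
    """Read and validate an injection-coordinate table."""
    df = _read_tsv(path, _INJ_COLS)
    if df[["x", "y", "z"]].isna().any().any():
        raise TableFormatError(f"{path}: missing coordinate value")
    return df


def read_borders(path) -> dict[str, BorderPolyline]:
    """Read border polylines keyed by role ("dorsal", "ventral", ...)."""
    df = _read_tsv(path, _BORDER_COLS)
    borders = {}
    for role, g in df.groupby("role"):
        g = g.sort_values("point_index")
        borders[str(role)] = BorderPolyline(str(role), g[["x", "y", "z"]].to_numpy(float))
    return borders


def read_observations(path) -> list[PlexusInterval | FiberPositions]:
    """Read labeling observations (plexus intervals and fiber positions)."""
    df = _read_tsv(path, _OBS_COLS, optional={"end_um", "grade"})
    out: list[PlexusInterval | FiberPositions] = []
    fibers: dict[tuple, list[float]] = {}
    extents: dict[tuple, float] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2
        kind = row["kind"]
        key = (row["experiment_id"], int(row["section_index"]), row["subdivision"])
        try:
            if kind == "plexus":
                out.append(
                    PlexusInterval(
                        experiment_id=row["experiment_id"],
                        section_index=int(row["section_index"]),
                        subdivision=row["subdivision"],
                        start_um=float(row["start_um"]),
                        end_um=float(row["end_um"]),
                        grade=int(row["grade"]),
                        section_extent_um=float(row["section_extent_um"]),
                    )
                )
            elif kind == "fiber":
                fibers.setdefault(key, []).append(float(row["start_um"]))
                extents[key] = float(row["section_extent_um"])
            else:
                raise ValueError(f"unknown kind {kind!r}")
        except (ValueError, TypeError) as e:
            raise TableFormatError(f"{path}:{line}: {e}") from e
    for key, positions in fibers.items():
        exp, sec, sub = key
        out.append(
            FiberPositions(
                experiment_id=exp,
                section_index=sec,
                subdivision=sub,
                positions_um=np.asarray(positions),
                section_extent_um=extents[key],
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path, header_note: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_note:
            for line in header_note.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def measurements_table(study: SyntheticStudy) -> pd.DataFrame:
    rows = []
    for rec in study.animals:
        for sub, s in rec.sections.items():
            for j, v in enumerate(s):
                rows.append(
                    {
                        "animal_id": rec.animal_id,
                        "age_days": rec.age_days,
                        "section_index": j,
                        "subdivision": sub,
                        "transverse_um": v,
                        "series_spacing_um": rec.series_spacing_um,
                    }
                )
    return pd.DataFrame(rows)


def observations_table(observations) -> pd.DataFrame:
    rows = []
    for obs in observations:
        if isinstance(obs, PlexusInterval):
            rows.append(
                {
                    "experiment_id": obs.experiment_id,
                    "section_index": obs.section_index,
                    "subdivision": obs.subdivision,
                    "kind": "plexus",
                    "start_um": obs.start_um,
                    "end_um": obs.end_um,
                    "grade": obs.grade,
                    "section_extent_um": obs.section_extent_um,
                }
            )
        else:
            for p in obs.positions_um:
                rows.append(
                    {
                        "experiment_id": obs.experiment_id,
                        "section_index": obs.section_index,
                        "subdivision": obs.subdivision,
                        "kind": "fiber",
                        "start_um": p,
                        "end_um": np.nan,
                        "grade": np.nan,
                        "section_extent_um": obs.section_extent_um,
                    }
                )
    return pd.DataFrame(rows)


def borders_table(borders: dict[str, BorderPolyline]) -> pd.DataFrame:
    rows = []
    for role, poly in borders.items():
        for i, p in enumerate(poly.points):
            rows.append(
                {"role": role, "point_index": i, "x": p[0], "y": p[1], "z": p[2]}
            )
    return pd.DataFrame(rows)


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_study(study: SyntheticStudy, outdir) -> dict[str, Path]:
    """Write a synthetic study in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from dataclasses import asdict

    note = (
        f"synthetic study, seed={study.seed}, "
        f"config_hash={config_hash(asdict(study.config))}\n"
        "units: um (measurements/observations), mm (borders/injections)\n"
        "axes: rc 0=rostral, dv 0=ventral, transverse 0=proximal/medial"
    )
    paths = {
        "measurements": outdir / "measurements.tsv",
        "observations": outdir / "observations.tsv",
        "borders": outdir / "borders.tsv",
        "injections": outdir / "injections.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    _write_tsv(measurements_table(study), paths["measurements"], note)
    _write_tsv(observations_table(study.observations), paths["observations"], note)
    _write_tsv(borders_table(study.borders), paths["borders"], note)
    inj = study.injections[
        ["experiment_id", "animal_id", "age_days", "x", "y", "z"]
    ]
    _write_tsv(inj, paths["injections"], note)
    _write_tsv(study.truth, paths["truth"], note)
    paths["config"].write_text(study.config.to_json())
    return paths


def write_flatmap_specs(specs: dict[str, FlatmapSpec], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps({sub: s.to_dict() for sub, s in specs.items()}, indent=2)
    )


def read_flatmap_specs(path) -> dict[str, FlatmapSpec]:
    data = json.loads(Path(path).read_text())
    return {sub: FlatmapSpec.from_dict(d) for sub, d in data.items()}


# ---------------------------------------------------------------------------
# subgroup assignment
# ---------------------------------------------------------------------------

def assign_subgroups(injections: pd.DataFrame, scheme: str = "area_quarter") -> pd.Series:
    """Group labels for injections.

    Schemes: ``area_quarter`` — (area, rostrocaudal quarter, quarter 1 most
    rostral); ``area`` — A29 vs A30; ``rc_half`` — rostral vs caudal half;
    ``age_group`` — postnatal weeks P1-6, P7-13, >=P14.
    """
    if scheme in ("area_quarter", "rc_half"):
        rc = injections["rc"].to_numpy(dtype=float)
        if np.any((rc < 0) | (rc > 1)):
            raise ValueError("rc outside [0, 1]")
    if scheme == "area_quarter":
        quarter = np.clip(np.floor(injections["rc"] * 4).astype(int), 0, 3) + 1
        return pd.Series(
            [f"{a}_q{q}" for a, q in zip(injections["area"], quarter)],
            index=injections.index,
            name="subgroup",
        )
    if scheme == "area":
        return injections["area"].rename("subgroup")
    if scheme == "rc_half":
        return pd.Series(
            np.where(injections["rc"] < 0.5, "rostral", "caudal"),
            index=injections.index,
            name="subgroup",
        )
    if scheme == "age_group":
        age = injections["age_days"]
        lab = np.where(age <= 6, "P1-6", np.where(age <= 13, "P7-13", "P14+"))
        return pd.Series(lab, index=injections.index, name="subgroup")
    raise ValueError(f"unknown subgroup scheme {scheme!r}")
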