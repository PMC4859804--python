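"""End-to-end orchestration: flatten, build flatmaps, map labels, analyze.

``analyze_study`` runs the whole chain in memory on domain objects (the form
the tests and the synthetic generator use); ``run_pipeline`` is the
file-based variant behind the command line, reading the delimited input
tables and writing every artifact with a provenance block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .flatmap import FlatmapBuilder
from .geometry import SurfaceFlattener
from .io import (
    config_hash,
    read_borders,
    read_injections,
    read_measurements,
    read_observations,
    write_flatmap_specs,
)
from .labels import FIELDS, build_experiment_map, center_of_mass, normalize_map
from .stats import FlatmapKMeans, RegressionResult, fit_topography

log = logging.getLogger("topoflat")

OUTCOMES = [f"{f}:{ax}" for f in FIELDS for ax in ("dv", "tr")]


@dataclass
class PipelineConfig:
    """Configuration of a file-based pipeline run."""

    measurements: str
    observations: str
    injections: str
    borders: str
    out_dir: str
    smax: int | str = "auto"
    span: float = 0.5
    alpha: float = 0.05
    age_max: float = 19.0
    seed: int = 0
    cluster_k_range: tuple[int, int] = (2, 7)
    smoothing_sigma: float = 1.5
    smoothing_size: int = 5

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if not 0 < cfg.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if cfg.age_max <= 0:
            raise ValueError("age_max must be positive")
        if cfg.smax != "auto" and int(cfg.smax) < 1:
            raise ValueError("smax must be 'auto' or a positive integer")
        return cfg


@dataclass
class PipelineResult:
    """All in-memory artifacts of one analysis run."""

    specs: dict
    label_maps: dict
    com_table: pd.DataFrame
    regressions: dict[str, RegressionResult]
    cluster: object | None = None
    exclusions: dict[str, int] = field(default_factory=dict)


def flatten_injections(
    borders: dict, injections: pd.DataFrame, span: float = 0.5
) -> pd.DataFrame:
    """Normalized (rc, dv) coordinates and area for each injection."""
    flattener = SurfaceFlattener(span=span).fit(borders)
    coords = flattener.transform(injections[["x", "y", "z"]])
    out = injections.copy()
    for col in ("rc", "dv", "d_d", "d_v", "d_r", "d_c", "triangle"):
        out[col] = coords[col].to_numpy()
    if "area" in coords:
        out["area"] = coords["area"].to_numpy()
    return out


def build_label_maps(
    observations, specs: dict, n_sections_by_experiment: dict[str, int]
) -> dict:
    """Per-experiment normalized label maps from raw observations."""
    by_exp: dict[str, list] = {}
    for obs in observations:
        by_exp.setdefault(obs.experiment_id, []).append(obs)
    maps = {}
    for exp_id, obs in sorted(by_exp.items()):
        raw = build_experiment_map(
            obs, specs, n_sections_by_experiment[exp_id], exp_id
        )
        maps[exp_id] = normalize_map(raw)
    return maps


def com_table_from_maps(label_maps: dict, injections: pd.DataFrame) -> pd.DataFrame:
    """Center-of-mass table joined with injection coordinates and age.

    One row per experiment; experiments without labeling in a field carry
    NaN for that field's coordinates (excluded later per outcome).
    """
    inj = injections.set_index("experiment_id")
    rows = []
    for exp_id in inj.index:
        row: dict = {
            "experiment_id": exp_id,
            "rc": inj.loc[exp_id, "rc"],
            "dv": inj.loc[exp_id, "dv"],
            "age": inj.loc[exp_id, "age_days"],
        }
        if "area" in inj.columns:
            row["area"] = inj.loc[exp_id, "area"]
        lm = label_maps.get(exp_id)
        for field_name in FIELDS:
            com = center_of_mass(lm, field_name) if lm is not None else None
            row[f"{field_name}:dv"] = com.dv_com if com else np.nan
            row[f"{field_name}:tr"] = com.tr_com if com else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_study(
    study,
    alpha: float = 0.05,
    age_max: float | None = 19,
    span: float = 0.5,
    smax: int | str = "auto",
    run_cluster: bool = False,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis chain on a (synthetic or loaded) study."""
    injections = flatten_injections(study.borders, study.injections, span=span)
    builder = FlatmapBuilder(smax=smax).fit(study.animals)

    n_sections = {
        rec.animal_id: rec.n_sections for rec in study.animals
    }
    n_by_exp = {
        row.experiment_id: n_sections[row.animal_id]
        for row in injections.itertuples()
    }
    label_maps = build_label_maps(study.observations, builder.specs_, n_by_exp)

    n_empty = sum(m.empty for m in label_maps.values())
    n_missing = len(injections) - len(label_maps)
    com = com_table_from_maps(label_maps, injections)
    n_over_age = int((com["age"] > age_max).sum()) if age_max is not None else 0
    log.info(
        "experiments: %d total, %d without labeling, %d above age cutoff",
        len(injections),
        n_empty + n_missing,
        n_over_age,
    )

    regressions = {}
    for outcome in OUTCOMES:
        regressions[outcome] = fit_topography(
            com, outcome, alpha=alpha, age_max=age_max
        )

    cluster = None
    if run_cluster:
        usable = [m for m in label_maps.values() if not m.empty]
        cluster = FlatmapKMeans(random_state=seed).fit(usable)

    return PipelineResult(
        specs=builder.specs_,
        label_maps=label_maps,
        com_table=com,
        regressions=regressions,
        cluster=cluster,
        exclusions={
            "no_labeling": n_empty + n_missing,
            "above_age_max": n_over_age,
        },
    )


def regression_report(regressions: dict[str, RegressionResult]) -> pd.DataFrame:
    """Long-format table of all fitted terms across outcomes."""
    rows = []
    for outcome, res in regressions.items():
        for term, r in res.params.iterrows():
            rows.append(
                {
                    "outcome": outcome,
                    "term": term,
                    "beta": r["beta"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "t": r["t"],
                    "df": res.df_resid,
                    "p": r["p"],
                    "std_beta": r["std_beta"],
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


class _LoadedStudy:
    """Duck-typed study assembled from input files."""

    def __init__(self, borders, animals, injections, observations):
        self.borders = borders
        self.animals = animals
        self.injections = injections
        self.observations = observations


def load_study(
    measurements_path, observations_path, injections_path, borders_path
) -> _LoadedStudy:
    from .flatmap import records_from_table

    meas = read_measurements(measurements_path)
    animals = records_from_table(meas)
    observations = read_observations(observations_path)
    injections = read_injections(injections_path)
    borders = read_borders(borders_path)
    # geometry expects dorsal/ventral keys; accept role names from tables
    key_map = {}
    for role in borders:
        low = role.lower()
        if "boundary" in low:
            key_map["boundary"] = borders[role]
        elif "dorsal" in low:
            key_map["dorsal"] = borders[role]
        elif "ventral" in low:
            key_map["ventral"] = borders[role]
    missing = {"dorsal", "ventral"} - set(key_map)
    if missing:
        raise ValueError(f"borders table lacks roles: {sorted(missing)}")
    return _LoadedStudy(key_map, animals, injections, observations)


def run_pipeline(config: PipelineConfig | dict) -> PipelineResult:
    """File-based pipeline: read inputs, analyze, write artifacts."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read-inputs"
    try:
        study = load_study(
            config.measurements, config.observations, config.injections, config.borders
        )
        stage = "analysis"
        result = analyze_study(
            study,
            alpha=config.alpha,
            age_max=config.age_max,
            span=config.span,
            smax=config.smax,
            run_cluster=True,
            seed=config.seed,
        )
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    chash = config_hash(vars(config))
    provenance = {
        "config": {k: str(v) for k, v in vars(config).items()},
        "config_hash": chash,
        "seed": config.seed,
        "exclusions": result.exclusions,
    }
    write_flatmap_specs(result.specs, out / "flatmap.json")
    result.com_table.to_csv(out / "com_table.tsv", sep="\t", index=False)
    regression_report(result.regressions).to_csv(
        out / "regressions.tsv", sep="\t", index=False
    )
    if result.cluster is not None:
        pd.DataFrame(
            {
                "experiment_id": result.cluster.corr_.index,
                "cluster": result.cluster.labels_,
            }
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(result.cluster.ratio_curve_.items()), columns=["k", "ssw_ssb"]
        ).to_csv(out / "elbow.tsv", sep="\t", index=False)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return result
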