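"""Mapping of labeled-fiber observations onto flatmap bins.

Two kinds of per-section observation are supported: dense-plexus boundary
intervals carrying a subjective density grade 1-3 (the densest plexus of an
experiment is graded 3), and single-fiber positions counted per bin. Each
observation is measured in µm from its subdivision's reference border along
the transverse axis (proximal border for the presubiculum, distal border for
the parasubiculum, medial border for the entorhinal cortices); all values are
re-oriented onto a common proximal/medial = 0 axis before binning.

Per experiment the binned values are normalized to the maximum-valued bin so
that plexus- and fiber-based maps are comparable, maps of groups of interest
are pooled by summation and renormalization (subgroup-balanced if requested),
and the density-weighted center of mass summarizes the labeling position for
the regression analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flatmap import FlatmapSpec

# subdivisions whose reference border is at the distal/lateral end; their
# measurements are mirrored onto the common proximal/medial = 0 axis
FLIPPED_SUBDIVISIONS = frozenset({"PaS_deep"})

# CoM fields assemble subdivisions proximal->distal / medial->lateral
FIELDS: dict[str, tuple[str, ...]] = {
    "PrS_LI_III": ("PrS_sup",),
    "PrS_PaS_deep": ("PrS_deep", "PaS_deep"),
    "EC_deep": ("MEC_deep", "LEC_deep"),
}


@dataclass
class PlexusInterval:
    """A dense-plexus interval in one section, graded 1 (weak) to 3 (dense)."""

    experiment_id: str
    section_index: int
    subdivision: str
    start_um: float
    end_um: float
    grade: int
    section_extent_um: float

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3):
            raise ValueError(f"grade must be 1-3, got {self.grade}")
        if not 0 <= self.start_um < self.end_um <= self.section_extent_um + 1e-9:
            raise ValueError(
                "interval must satisfy 0 <= start < end <= section extent"
            )


@dataclass
class FiberPositions:
    """Single labeled-fiber positions in one section (µm from the
    subdivision's reference border)."""

    experiment_id: str
    section_index: int
    subdivision: str
    positions_um: np.ndarray
    section_extent_um: float

    def __post_init__(self) -> None:
        self.positions_um = np.atleast_1d(np.asarray(self.positions_um, dtype=float))
        if np.any(self.positions_um < 0) or np.any(
            self.positions_um > self.section_extent_um + 1e-9
        ):
            raise ValueError("fiber position outside [0, section extent]")


@dataclass
class ExperimentLabelMap:
    """One experiment's bin values on the flatmap (ragged grid).

    ``grids`` maps subdivision -> list of ``smax`` 1D arrays (row i has the
    spec's ``bin_counts[i]`` bins, proximal/medial bin first).
    """

    experiment_id: str
    specs: dict[str, FlatmapSpec]
    grids: dict[str, list[np.ndarray]] = field(default_factory=dict)
    normalized: bool = False
    empty: bool = False

    def __post_init__(self) -> None:
        for sub, spec in self.specs.items():
            if sub not in self.grids:
                self.grids[sub] = [
                    np.zeros(int(c)) for c in spec.bin_counts
                ]

    def max_value(self) -> float:
        vals = [r.max() if len(r) else 0.0 for g in self.grids.values() for r in g]
        return max(vals) if vals else 0.0

    def dense(self, sub: str) -> np.ndarray:
        """Dense (smax, max_bins) embedding of one subdivision, rows
        left-aligned at the reference border; out-of-region bins are 0."""
        spec = self.specs[sub]
        out = np.zeros((spec.smax, spec.max_bins))
        for i, row in enumerate(self.grids[sub]):
            out[i, : len(row)] = row
        return out

    def copy(self) -> "ExperimentLabelMap":
        return ExperimentLabelMap(
            experiment_id=self.experiment_id,
            specs=self.specs,
            grids={s: [r.copy() for r in g] for s, g in self.grids.items()},
            normalized=self.normalized,
            empty=self.empty,
        )


def section_to_row(section_index: int, n_sections: int, smax: int) -> int:
    """Flatmap row (0-based, dorsal first) containing a section's center."""
    if not 0 <= section_index < n_sections:
        raise ValueError("section index outside the animal's series")
    frac = (section_index + 0.5) / n_sections
    return min(int(frac * smax), smax - 1)


def _orient(x_norm: np.ndarray | float, subdivision: str):
    """Map a normalized transverse position onto the common axis
    (proximal/medial = 0)."""
    if subdivision in FLIPPED_SUBDIVISIONS:
        return 1.0 - np.asarray(x_norm, dtype=float)
    return np.asarray(x_norm, dtype=float)


def map_plexus(obs: PlexusInterval, spec: FlatmapSpec, n_bins: int | None = None) -> np.ndarray:
    """Bin values for one plexus interval on a row of ``n_bins`` bins.

    Interval endpoints are normalized by the section extent and re-oriented;
    bins whose centers fall in ``[start, end)`` receive the grade, others 0.
    """
    n = int(n_bins) if n_bins is not None else spec.max_bins
    lo = obs.start_um / obs.section_extent_um
    hi = obs.end_um / obs.section_extent_um
    if obs.subdivision in FLIPPED_SUBDIVISIONS:
        lo, hi = 1.0 - hi, 1.0 - lo
    centers = (np.arange(n) + 0.5) / n
    values = np.where((centers >= lo) & (centers < hi), float(obs.grade), 0.0)
    return values


def map_fibers(obs: FiberPositions, spec: FlatmapSpec, n_bins: int | None = None) -> np.ndarray:
    """Bin counts for single-fiber positions on a row of ``n_bins`` bins.

    Bins are half-open ``[left, right)`` with the last bin closed on the
    right, so a fiber at the far border still counts.
    """
    n = int(n_bins) if n_bins is not None else spec.max_bins
    x = _orient(obs.positions_um / obs.section_extent_um, obs.subdivision)
    idx = np.minimum((x * n).astype(int), n - 1)
    counts = np.bincount(idx, minlength=n).astype(float)
    return counts


def _resample_row(row: np.ndarray, n_bins: int) -> np.ndarray:
    """Resample a row of bin values to a different bin count by linear
    interpolation at normalized bin-center positions."""
    m = len(row)
    if m == n_bins:
        return row.copy()
    if m == 0:
        return np.zeros(n_bins)
    if m == 1:
        return np.full(n_bins, row[0])
    src = (np.arange(m) + 0.5) / m
    dst = (np.arange(n_bins) + 0.5) / n_bins
    return np.interp(dst, src, row)


def interpolate_missing(
    label_map: ExperimentLabelMap, missing: dict[str, set[int]]
) -> ExperimentLabelMap:
    """Fill missing rows from their neighbors above and below.

    A missing row receives the mean of the nearest non-missing rows above and
    below (values matched across differing bin counts by normalized transverse
    position); edge rows copy their single neighbor. A subdivision with every
    row missing is an error.
    """
    out = label_map.copy()
    for sub, rows_missing in missing.items():
        spec = out.specs[sub]
        grid = out.grids[sub]
        present = [i for i in range(spec.smax) if i not in rows_missing]
        if not present:
            raise ValueError(
                f"{sub}: all rows missing; nothing to interpolate from"
            )
        present_arr = np.asarray(present)
        for i in sorted(rows_missing):
            n_bins = len(grid[i])
            below = present_arr[present_arr > i]
            above = present_arr[present_arr < i]
            neighbors = []
            if len(above):
                neighbors.append(grid[above[-1]])
            if len(below):
                neighbors.append(grid[below[0]])
            resampled = [_resample_row(r, n_bins) for r in neighbors]
            grid[i] = np.mean(resampled, axis=0) if resampled else np.zeros(n_bins)
    return out


def normalize_map(label_map: ExperimentLabelMap) -> ExperimentLabelMap:
    """Normalize all bins to the experiment's maximum-valued bin.

    All-zero maps are flagged empty and left as zeros. Idempotent.
    """
    out = label_map.copy()
    m = out.max_value()
    if m == 0:
        out.empty = True
        out.normalized = True
        return out
    for grid in out.grids.values():
        for i in range(len(grid)):
            grid[i] = grid[i] / m
    out.normalized = True
    return out


def _check_same_spec(maps: list[ExperimentLabelMap]) -> None:
    ref = maps[0].specs
    for m in maps[1:]:
        if set(m.specs) != set(ref):
            raise ValueError("maps are built on different flatmap specs")
        for sub in ref:
            if not np.array_equal(m.specs[sub].bin_counts, ref[sub].bin_counts):
                raise ValueError("maps are built on different flatmap specs")


def pool_maps(
    maps: list[ExperimentLabelMap],
    subgroups: list | None = None,
    experiment_id: str = "pooled",
) -> ExperimentLabelMap:
    """Pool normalized maps by summation and renormalization.

    With ``subgroups`` (one label per map), maps are pooled and normalized
    within each subgroup first and the normalized subgroup maps are then
    summed, so every subgroup has equal impact regardless of its size.
    """
    if not maps:
        raise ValueError("no maps to pool")
    _check_same_spec(maps)
    maps = [m if m.normalized else normalize_map(m) for m in maps]

    if subgroups is not None:
        if len(subgroups) != len(maps):
            raise ValueError("need one subgroup label per map")
        labels = sorted(set(subgroups), key=str)
        parts = [
            pool_maps([m for m, g in zip(maps, subgroups) if g == lab],
                      experiment_id=str(lab))
            for lab in labels
        ]
        return pool_maps(parts, experiment_id=experiment_id)

    out = maps[0].copy()
    out.experiment_id = experiment_id
    for m in maps[1:]:
        for sub in out.grids:
            for i in range(len(out.grids[sub])):
                out.grids[sub][i] = out.grids[sub][i] + m.grids[sub][i]
    out.normalized = False
    return normalize_map(out)


@dataclass
class CenterOfMass:
    """Density-weighted mean labeling position of one field.

    ``dv_com``: 0 = ventral, 1 = dorsal. ``tr_com``: 0 = proximal/medial,
    1 = distal/lateral, normalized by the assembled row width of the field.
    """

    experiment_id: str
    field: str
    dv_com: float
    tr_com: float


def center_of_mass(
    label_map: ExperimentLabelMap, field_name: str
) -> CenterOfMass | None:
    """Center of mass of one field's labeling; None if the field is empty.

    Fields assemble subdivisions along the transverse axis (deep presubiculum
    then parasubiculum; medial then lateral entorhinal cortex). For row i
    (1-based, dorsal first) the dorsoventral bin-center coordinate is
    ``1 - (i - 0.5)/smax``; transverse bin centers are normalized by the row's
    assembled width.
    """
    subs = FIELDS[field_name]
    smax = label_map.specs[subs[0]].smax
    w_sum = 0.0
    dv_acc = 0.0
    tr_acc = 0.0
    for i in range(smax):
        row = np.concatenate([label_map.grids[s][i] for s in subs])
        width = len(row)
        if width == 0:
            continue
        w = row.sum()
        if w == 0:
            continue
        dv_center = 1.0 - (i + 0.5) / smax
        x_centers = (np.arange(width) + 0.5) / width
        w_sum += w
        dv_acc += w * dv_center
        tr_acc += float(np.dot(row, x_centers))
    if w_sum == 0:
        return None
    return CenterOfMass(
        experiment_id=label_map.experiment_id,
        field=field_name,
        dv_com=dv_acc / w_sum,
        tr_com=tr_acc / w_sum,
    )


def build_experiment_map(
    observations: list[PlexusInterval | FiberPositions],
    specs: dict[str, FlatmapSpec],
    n_sections: int,
    experiment_id: str,
    fill_missing: bool = True,
) -> ExperimentLabelMap:
    """Assemble one experiment's raw label map from its observations.

    Section indices are mapped to flatmap rows via the section-center
    fraction of the animal's series. Plexus grades combine across
    observations of a row by maximum, fiber counts by summation. Rows inside
    the observed section range that received no section (young animals have
    fewer sections than ``smax`` rows) are treated as missing and filled from
    their neighbors when ``fill_missing`` is set and any labeling exists.
    """
    label_map = ExperimentLabelMap(experiment_id=experiment_id, specs=specs)
    smax = next(iter(specs.values())).smax
    covered: dict[str, set[int]] = {sub: set() for sub in specs}
    for obs in observations:
        sub = obs.subdivision
        if sub not in specs:
            raise ValueError(f"observation in unknown subdivision {sub}")
        spec = specs[sub]
        row = section_to_row(obs.section_index, n_sections, smax)
        n_bins = int(spec.bin_counts[row])
        covered[sub].add(row)
        if n_bins == 0:
            continue
        if isinstance(obs, PlexusInterval):
            vals = map_plexus(obs, spec, n_bins)
            label_map.grids[sub][row] = np.maximum(label_map.grids[sub][row], vals)
        else:
            vals = map_fibers(obs, spec, n_bins)
            label_map.grids[sub][row] = label_map.grids[sub][row] + vals
    if fill_missing and label_map.max_value() > 0:
        missing: dict[str, set[int]] = {}
        for sub in specs:
            rows = covered[sub]
            if not rows:
                continue
            lo, hi = min(rows), max(rows)
            gaps = {i for i in range(lo, hi + 1) if i not in rows}
            if gaps:
                missing[sub] = gaps
        if missing:
            label_map = interpolate_missing(label_map, missing)
    return label_map


def color_scale(values) -> np.ndarray:
    """Linear color positions with extremes at the mean +/- 2 SD.

    Values between mu - 2*sigma and mu + 2*sigma map linearly onto [0, 1];
    more extreme values are thresholded. With zero spread every value sits at
    the scale midpoint.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mu = v.mean()
    sigma = v.std(ddof=0)
    if sigma == 0:
        return np.full(v.shape, 0.5)
    return np.clip((v - (mu - 2 * sigma)) / (4 * sigma), 0.0, 1.0)
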