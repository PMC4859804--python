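"""Age-normalized average flatmaps of the target region.

Brains of different ages have different sizes, so per-animal transverse
measurements (µm) of each subdivision are normalized by that animal's maximum
measured extent of the subdivision before averaging. The dorsoventral axis is
binned into ``smax`` equal rows (the maximum per-animal section count), each
animal's section profile is resampled onto those rows, and the across-animal
means yield, per row, a transverse extent expressed relative to the
dorsoventral extent of the region. Multiplying by ``smax`` and rounding gives
the integer number of square bins in each row — the ragged bin grid on which
labeling is quantified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

SUBDIVISIONS = ("PrS_sup", "PrS_deep", "PaS_deep", "MEC_deep", "LEC_deep")


@dataclass
class AnimalRecord:
    """One animal's ordered per-section transverse measurements.

    ``sections`` maps subdivision -> 1D array of transverse extents (µm),
    ordered dorsal to ventral. ``dv_extent`` is the dorsoventral extent of the
    region (µm); by default the number of sections containing the region times
    the series spacing.
    """

    animal_id: str
    age_days: float
    sections: dict[str, np.ndarray]
    dv_extent: float | None = None
    series_spacing_um: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.sections = {k: np.asarray(v, dtype=float) for k, v in self.sections.items()}
        for sub, s in self.sections.items():
            if np.any(s < 0):
                raise ValueError(f"negative transverse extent in {sub}")
        if self.dv_extent is None:
            if self.series_spacing_um is None:
                raise ValueError("need dv_extent or series_spacing_um")
            n = max(len(s) for s in self.sections.values())
            self.dv_extent = n * self.series_spacing_um
        if self.dv_extent <= 0:
            raise ValueError("dv_extent must be positive")

    @property
    def n_sections(self) -> int:
        return max(len(s) for s in self.sections.values())


def normalize_animal(rec: AnimalRecord) -> AnimalRecord:
    """Normalize an animal's measurements by its own maxima.

    Each transverse measurement is divided by the maximum measured extent of
    its subdivision in this animal; the dorsoventral extent is likewise
    expressed as a ratio to that per-subdivision maximum, so the normalized
    record carries one dorsoventral ratio per subdivision (stored in
    ``dv_norm``). Subdivisions with an all-zero profile are excluded with a
    warning.
    """
    if rec.normalized:
        return rec
    sections: dict[str, np.ndarray] = {}
    dv_norm: dict[str, float] = {}
    for sub, s in rec.sections.items():
        m = s.max() if len(s) else 0.0
        if m <= 0:
            warnings.warn(
                f"animal {rec.animal_id}: subdivision {sub} has no nonzero "
                "measurement; excluded",
                stacklevel=2,
            )
            continue
        sections[sub] = s / m
        dv_norm[sub] = rec.dv_extent / m
    out = AnimalRecord(
        animal_id=rec.animal_id,
        age_days=rec.age_days,
        sections=sections,
        dv_extent=rec.dv_extent,
        series_spacing_um=rec.series_spacing_um,
        normalized=True,
    )
    out.dv_norm = dv_norm  # type: ignore[attr-defined]
    return out


def resample_to_rows(profile: np.ndarray, smax: int) -> np.ndarray:
    """Resample an ordered section profile onto ``smax`` equal rows.

    Section centers sit at ``(j - 0.5) / n`` of the measured span and row
    centers at ``(i - 0.5) / smax``; values are linearly interpolated, holding
    the end values at the edges (rows beyond the measured span of an empty
    profile are zero).
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    if n == 0:
        return np.zeros(smax)
    if smax < 1:
        raise ValueError("smax must be >= 1")
    centers = (np.arange(n) + 0.5) / n
    rows = (np.arange(smax) + 0.5) / smax
    return np.interp(rows, centers, profile)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class FlatmapSpec:
    """The averaged, binned 2D representation of one subdivision.

    Rows run dorsal (i=1) to ventral (i=smax); every bin is square in
    normalized units (side 1/smax of the dorsoventral extent). ``bin_counts``
    is the integer number of bins per row, ``round(T_i * smax)``.
    """

    subdivision: str
    smax: int
    row_extents: np.ndarray  # t-bar_i, mean normalized transverse extent
    dv_mean: float  # dv-bar, mean normalized dorsoventral extent
    T: np.ndarray = field(init=False)  # t-bar_i / dv-bar
    bin_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.row_extents = np.asarray(self.row_extents, dtype=float)
        if self.smax < 1:
            raise ValueError("smax must be >= 1")
        if len(self.row_extents) != self.smax:
            raise ValueError("row_extents must have length smax")
        if self.dv_mean <= 0:
            raise ValueError("dv_mean must be positive")
        self.T = self.row_extents / self.dv_mean
        self.bin_counts = _round_half_up(self.T * self.smax).astype(int)

    @property
    def max_bins(self) -> int:
        return int(self.bin_counts.max())

    def mask(self) -> np.ndarray:
        """Dense (smax, max_bins) boolean in-region mask, rows left-aligned
        at the reference border."""
        m = np.zeros((self.smax, self.max_bins), dtype=bool)
        for i, c in enumerate(self.bin_counts):
            m[i, :c] = True
        return m

    def to_dict(self) -> dict:
        return {
            "subdivision": self.subdivision,
            "smax": self.smax,
            "row_extents": self.row_extents.tolist(),
            "dv_mean": self.dv_mean,
            "T": self.T.tolist(),
            "bin_counts": self.bin_counts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlatmapSpec":
        return cls(
            subdivision=d["subdivision"],
            smax=int(d["smax"]),
            row_extents=np.asarray(d["row_extents"], dtype=float),
            dv_mean=float(d["dv_mean"]),
        )


def average_flatmap(
    records: list[AnimalRecord], smax: int | str = "auto"
) -> dict[str, FlatmapSpec]:
    """Build per-subdivision FlatmapSpecs from animal records.

    ``smax`` defaults to the maximum per-animal section count across the
    records. Per subdivision: t-bar_i is the across-animal mean of the row-
    resampled normalized transverse extents, dv-bar the mean normalized
    dorsoventral extent, T_i their ratio, and the bin count per row
    ``round(T_i * smax)`` (half-up).
    """
    if not records:
        raise ValueError("no animal records")
    normed = [normalize_animal(r) if not r.normalized else r for r in records]
    if smax == "auto":
        smax_val = max(r.n_sections for r in records)
    else:
        smax_val = int(smax)

    specs: dict[str, FlatmapSpec] = {}
    subs = sorted({s for r in normed for s in r.sections})
    for sub in subs:
        t_rows = []
        dv_vals = []
        for r in normed:
            if sub not in r.sections:
                continue
            t_rows.append(resample_to_rows(r.sections[sub], smax_val))
            dv_vals.append(r.dv_norm[sub])  # type: ignore[attr-defined]
        t_bar = np.mean(t_rows, axis=0)
        dv_bar = float(np.mean(dv_vals))
        if dv_bar == 0:
            raise ValueError(f"zero mean dorsoventral extent for {sub}")
        specs[sub] = FlatmapSpec(sub, smax_val, t_bar, dv_bar)
    return specs


def records_from_table(table: pd.DataFrame) -> list[AnimalRecord]:
    """Assemble AnimalRecords from a long-format measurement table.

    Expected columns: animal_id, age_days, section_index, subdivision,
    transverse_um, series_spacing_um.
    """
    records = []
    for animal_id, g in table.groupby("animal_id", sort=True):
        sections: dict[str, np.ndarray] = {}
        for sub, gs in g.groupby("subdivision"):
            gs = gs.sort_values("section_index")
            if gs["section_index"].duplicated().any():
                raise ValueError(
                    f"animal {animal_id}: duplicate section index in {sub}"
                )
            sections[str(sub)] = gs["transverse_um"].to_numpy(dtype=float)
        records.append(
            AnimalRecord(
                animal_id=str(animal_id),
                age_days=float(g["age_days"].iloc[0]),
                sections=sections,
                series_spacing_um=float(g["series_spacing_um"].iloc[0]),
            )
        )
    return records


class FlatmapBuilder(BaseEstimator):
    """Estimator building the age-normalized average flatmap.

    Parameters
    ----------
    smax : "auto" or int
        Number of dorsoventral rows; "auto" uses the maximum per-animal
        section count in the fitted data.

    Attributes
    ----------
    specs_ : dict[str, FlatmapSpec]
        Per-subdivision flatmap specification.
    smax_ : int
        The row count actually used.
    """

    def __init__(self, smax: int | str = "auto"):
        self.smax = smax

    def fit(self, X, y=None):
        """Fit from a measurement table (DataFrame) or list of AnimalRecord."""
        if isinstance(X, pd.DataFrame):
            records = records_from_table(X)
        else:
            records = list(X)
        self.specs_ = average_flatmap(records, smax=self.smax)
        self.smax_ = next(iter(self.specs_.values())).smax
        self.n_animals_ = len(records)
        return self
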