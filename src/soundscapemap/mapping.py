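"""Spatial outputs, vegetation (NDVI) statistics and aural cross-tabs.

Sites live on a local planar grid in meters (the study areas are on the
order of 100 m, so planar geometry suffices); per-site index values are
classed into equally spaced intervals for choropleth-style maps and
exported as GeoJSON point features plus flat CSV.  Vegetation coverage
around each site is summarized as the mean NDVI = (NIR - R)/(NIR + R)
over a square region of interest (default 60 m side).  Aural-survey
labels are cross-tabulated against cluster membership as per-cluster
proportions of labelled minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterSolution

__all__ = [
    "SiteGeo", "NDVIInput", "AuralLabel", "ACTIVITY_BINS",
    "classify_equal_intervals", "ndvi", "classify_ndvi", "roi_mean_ndvi",
    "aural_cross_tab", "export_map",
]

#: perceived-singing-activity bins (% of the listened minute)
ACTIVITY_BINS = ("[0-10]", "(10-35]", "(35-65]", "(65-85]", "(85-100]")
ABUNDANCE_LEVELS = ("no_birds", "few_birds", "many_birds")


@dataclass(frozen=True)
class SiteGeo:
    """A site's position on the local planar grid (meters)."""

    site_id: str
    x: float
    y: float
    lon: float | None = None
    lat: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for site {self.site_id!r}")


@dataclass
class NDVIInput:
    """Co-registered near-infrared and red reflectance rasters."""

    nir: np.ndarray
    r: np.ndarray
    pixel_size: float            # m per pixel side
    origin: tuple[float, float] = (0.0, 0.0)  # grid coords of pixel (0, 0) centre

    def __post_init__(self) -> None:
        self.nir = np.asarray(self.nir, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.nir.shape != self.r.shape:
            raise ValueError(f"raster shapes differ: {self.nir.shape} vs {self.r.shape}")
        if not (np.isfinite(self.nir).all() and np.isfinite(self.r).all()):
            raise ValueError("reflectance rasters must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class AuralLabel:
    """One listened minute's labels, following the survey vocabulary."""

    site_id: str
    minute_index: int
    singing_activity_bin: str | None = None      # one of ACTIVITY_BINS
    abundance: str | None = None                 # no/few/many birds
    singing_distance: str | None = None          # close | distant
    traffic_intensity: str | None = None         # low | high
    traffic_type: str | None = None              # continuous | irregular
    construction_present: bool | None = None
    source_tags: tuple[str, ...] = ()            # biophony/technophony/...

    def __post_init__(self) -> None:
        if (self.singing_activity_bin is not None
                and self.singing_activity_bin not in ACTIVITY_BINS):
            raise ValueError(
                f"activity bin {self.singing_activity_bin!r} not in {ACTIVITY_BINS}")


def activity_bin(pct: float) -> str:
    """Map a singing-activity percentage to its survey bin."""
    if not 0 <= pct <= 100:
        raise ValueError("activity percentage must be in [0, 100]")
    edges = (10, 35, 65, 85)
    for e, name in zip(edges, ACTIVITY_BINS):
        if pct <= e:
            return name
    return ACTIVITY_BINS[-1]


def classify_equal_intervals(values, n_classes: int = 4) -> np.ndarray:
    """Class ids 1..n for equally spaced intervals over [min, max].

    Intervals are half-open [lo, hi) with the maximum assigned to the
    top class; a constant input puts every site in class 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.isfinite(v).any():
        raise ValueError("no finite values to classify")
    if not np.isfinite(v).all():
        raise ValueError("all values must be finite")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.ones(v.size, dtype=int)
    cls = np.floor((v - lo) / (hi - lo) * n_classes).astype(int) + 1
    return np.minimum(cls, n_classes)


def ndvi(inp: NDVIInput) -> np.ndarray:
    """Elementwise (NIR - R)/(NIR + R); zero-denominator pixels -> 0."""
    den = inp.nir + inp.r
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den != 0, (inp.nir - inp.r) / np.where(den != 0, den, 1.0), 0.0)
    return out


def classify_ndvi(value: float) -> str:
    """Conventional interpretation: <0 water, <0.4 soil, >=0.4 vegetation."""
    if value < 0:
        return "water"
    return "soil" if value < 0.4 else "vegetation"


def roi_mean_ndvi(
    ndvi_map: np.ndarray,
    geo: SiteGeo,
    pixel_size: float,
    side_m: float = 60.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float]:
    """Mean NDVI over a square ROI centred on a site.

    Pixel (row, col) has its centre at ``origin + pixel_size * (col, row)``
    in grid coordinates (x -> columns, y -> rows).  Returns (mean,
    coverage_fraction); the coverage fraction is the share of the ROI's
    nominal pixel count actually inside the raster.
    """
    arr = np.asarray(ndvi_map, dtype=float)
    ny, nx = arr.shape
    xs = origin[0] + pixel_size * np.arange(nx)
    ys = origin[1] + pixel_size * np.arange(ny)
    half = side_m / 2.0
    cx = (xs >= geo.x - half) & (xs <= geo.x + half)
    cy = (ys >= geo.y - half) & (ys <= geo.y + half)
    n_in = int(cx.sum()) * int(cy.sum())
    if n_in == 0:
        raise ValueError(f"ROI of site {geo.site_id!r} does not intersect raster")
    nominal = max(int(np.round(side_m / pixel_size)) ** 2, n_in)
    sub = arr[np.ix_(cy, cx)]
    return float(sub.mean()), n_in / nominal


def aural_cross_tab(
    labels: list[AuralLabel], clusters: ClusterSolution, category: str
) -> pd.DataFrame:
    """Per-cluster proportions of labelled minutes in one label category.

    Rows are the category's values, columns the clusters; each column
    with any labelled minutes sums to 1.  Clusters with no labelled
    minutes keep an all-zero column (flagged by the caller's judgement).
    """
    cl = dict(zip(clusters.site_ids, clusters.labels))
    missing = {l.site_id for l in labels} - set(cl)
    if missing:
        raise ValueError(f"labelled sites without a cluster: {sorted(missing)}")
    rows = []
    for l in labels:
        val = getattr(l, category)
        if val is None:
            continue
        rows.append({"cluster": cl[l.site_id], "value": val})
    if not rows:
        raise ValueError(f"no labels carry category {category!r}")
    df = pd.DataFrame(rows)
    tab = pd.crosstab(df["value"], df["cluster"])
    tab = tab.reindex(columns=sorted(set(cl.values())), fill_value=0)
    sums = tab.sum(axis=0)
    prop = tab / sums.replace(0, 1)
    prop.index.name = category
    return prop


def export_map(
    geo: list[SiteGeo],
    attributes: pd.DataFrame,
    path_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write per-site attributes as GeoJSON point features plus flat CSV.

    ``attributes`` is indexed by site_id; every site must have a full
    attribute row.  Features are emitted in site_id order.  Without
    lon/lat the GeoJSON uses the local planar grid and declares so in a
    top-level ``crs_note``.
    """
    geo_by_id = {g.site_id: g for g in sorted(geo, key=lambda g: g.site_id)}
    missing = set(geo_by_id) - set(attributes.index)
    if missing:
        raise ValueError(f"sites missing attributes: {sorted(missing)}")
    has_lonlat = all(g.lon is not None and g.lat is not None
                     for g in geo_by_id.values())
    features = []
    rows = []
    for sid, g in geo_by_id.items():
        props = {"site_id": sid}
        props.update({k: _jsonable(v) for k, v in attributes.loc[sid].items()})
        coords = [g.lon, g.lat] if has_lonlat else [g.x, g.y]
        features.append({"type": "Feature",
                         "geometry": {"type": "Point", "coordinates": coords},
                         "properties": props})
        rows.append({**{"site_id": sid, "x_m": g.x, "y_m": g.y},
                     **dict(attributes.loc[sid].items())})
    doc = {"type": "FeatureCollection", "features": features}
    if not has_lonlat:
        doc["crs_note"] = ("local planar grid, meters; x increases away "
                          "from the road edge at x=0")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    gj = prefix.with_suffix(".geojson")
    csv = prefix.with_suffix(".csv")
    gj.write_text(json.dumps(doc, indent=1, sort_keys=True))
    pd.DataFrame(rows).to_csv(csv, index=False)
    return gj, csv


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v
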