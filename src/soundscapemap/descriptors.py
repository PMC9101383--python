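"""Statistical descriptors of index time series and the site feature matrix.

Each per-second index series is condensed to seven descriptors — mean,
median, mode, standard deviation, interquartile range, skewness and
kurtosis — and the per-site descriptor vectors are stacked into a
sites x (index x descriptor) feature matrix (16 sites x 49 features for
the full seven-index set, x 35 for the five-index set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .indices import ALL_INDICES, IndexSeries

__all__ = ["DESCRIPTORS", "summarize_series", "build_feature_matrix",
           "FeatureMatrix"]

DESCRIPTORS = ("mean", "median", "mode", "sd", "iqr", "skewness", "kurtosis")


def _histogram_mode(x: np.ndarray) -> float:
    """Mode of a continuous sample: midpoint of the fullest histogram bin.

    Bin width follows the Freedman-Diaconis rule (falling back to
    Sturges when the IQR degenerates, and capped at 1000 bins so heavy
    ties cannot blow up the bin count); ties resolve to the lowest bin.
    For a continuous-valued series the mode is otherwise ill-defined.
    """
    n = x.size
    q1, q3 = np.percentile(x, [25, 75])
    width = 2.0 * (q3 - q1) / n ** (1.0 / 3.0)
    span = np.ptp(x)
    if width > 0:
        nbins = int(np.ceil(span / width))
    else:
        nbins = int(np.ceil(np.log2(n))) + 1  # Sturges
    nbins = min(max(nbins, 1), 1000)
    counts, edges = np.histogram(x, bins=nbins)
    top = int(np.argmax(counts))  # argmax takes the first (lowest) maximum
    return float((edges[top] + edges[top + 1]) / 2.0)


def summarize_series(values) -> dict[str, float]:
    """Seven descriptors of a real-valued series.

    sd is the sample (n-1) standard deviation; the IQR uses
    linear-interpolation quantiles; skewness and kurtosis are the
    biased moment coefficients g1 and g2 (kurtosis as excess).  A
    constant series returns sd = iqr = skewness = kurtosis = 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("summarize_series needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if np.ptp(x) == 0.0:
        v = float(x[0])
        return {"mean": v, "median": v, "mode": v,
                "sd": 0.0, "iqr": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
    return {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "mode": _histogram_mode(x),
        "sd": float(x.std(ddof=1)),
        "iqr": float(q3 - q1),
        "skewness": float(stats.skew(x, bias=True)),
        "kurtosis": float(stats.kurtosis(x, fisher=True, bias=True)),
    }


@dataclass
class FeatureMatrix:
    """Sites x features table; columns named ``INDEX_descriptor``."""

    data: pd.DataFrame  # index = site_id, columns index-major

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy()

    def feature_index(self, column: str) -> str:
        """Map a feature column back to its index name (grouping key)."""
        return column.rsplit("_", 1)[0]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="site_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        return cls(pd.read_csv(path, index_col="site_id"))


def build_feature_matrix(series: list[IndexSeries]) -> FeatureMatrix:
    """Stack per-site descriptor vectors into the feature matrix.

    Rows are ordered by site_id; columns index-major then descriptor
    (ACI_mean, ACI_median, ..., DSC_kurtosis).  All sites must share the
    same index set.
    """
    if not series:
        raise ValueError("no index series supplied")
    ref_cols = tuple(series[0].values.columns)
    rows = {}
    for s in series:
        if tuple(s.values.columns) != ref_cols:
            raise ValueError(
                f"site {s.site_id!r} has index set {tuple(s.values.columns)}, "
                f"expected {ref_cols}")
        row = {}
        for idx in ref_cols:
            desc = summarize_series(s.values[idx].to_numpy())
            for d in DESCRIPTORS:
                row[f"{idx}_{d}"] = desc[d]
        rows[s.site_id] = row
    cols = [f"{i}_{d}" for i in ref_cols for d in DESCRIPTORS]
    df = pd.DataFrame.from_dict(rows, orient="index")[cols]
    df = df.sort_index()
    df.index.name = "site_id"
    return FeatureMatrix(df)
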