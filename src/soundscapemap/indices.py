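"""Eco-acoustic indices computed on 1-second spectrogram blocks.

Seven scalar summaries of a magnitude spectrogram, each a proxy for a
different soundscape attribute:

* **ACI** — acoustic complexity: summed relative frame-to-frame
  amplitude variation per frequency bin.  Sensitive to modulated
  (biotic) sound, nearly blind to steady noise.
* **ADI / AEI** — Shannon entropy / Gini inequality of above-threshold
  occupancy across fixed-width frequency bands; reverse indicators of
  band dominance.
* **H** — acoustic entropy: product of normalized temporal-envelope and
  mean-spectrum entropies, in [0, 1].
* **BI** — bioacoustic index: min-referenced area under the mean dB
  spectrum inside a biophony band, in dB*kHz.
* **NDSI** — (biophony - anthrophony) / (biophony + anthrophony) power
  ratio between two disjoint bands, in [-1, 1].
* **DSC** — dynamic spectral centroid: amplitude-weighted mean frequency
  per frame, averaged over frames, in kHz.

For recordings where broadband traffic noise spills above the
conventional 2 kHz anthrophony ceiling, the NDSI threshold and the BI
band can be lowered to 1 kHz, or BI/NDSI dropped altogether to the
five-index set {ACI, ADI, AEI, H, DSC}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import (AudioClip, Spectrogram, SpectrogramParams, band_mask,
                    compute_spectrogram, tile_windows)

__all__ = [
    "ALL_INDICES",
    "FIVE_INDEX_SET",
    "IndexConfig",
    "IndexSeries",
    "aci",
    "band_occupancy",
    "adi",
    "aei",
    "entropy_h",
    "bi",
    "ndsi",
    "dsc",
    "compute_block",
    "compute_all",
]

ALL_INDICES = ("ACI", "ADI", "AEI", "H", "BI", "NDSI", "DSC")
#: reduced set used when broadband noise invalidates the BI/NDSI bands
FIVE_INDEX_SET = ("ACI", "ADI", "AEI", "H", "DSC")


@dataclass(frozen=True)
class IndexConfig:
    """Band layout and thresholds for the index set.

    ADI/AEI occupancy is thresholded in dB relative to the block maximum
    (default -50 dB) over ``band_width``-Hz bands up to ``max_freq``.
    The NDSI anthrophony band ends and the biophony / BI band starts at
    1 kHz, reflecting low-frequency-dominated traffic noise.
    """

    band_width: float = 1000.0
    max_freq: float = 24000.0
    db_threshold: float = -50.0
    bi_band: tuple[float, float] = (1000.0, 8000.0)
    ndsi_anthro: tuple[float, float] = (100.0, 1000.0)
    ndsi_bio: tuple[float, float] = (1000.0, 8000.0)
    dsc_aggregation: str = "mean_of_frame_centroids"
    index_set: tuple[str, ...] = ALL_INDICES
    mask_lo: float = 100.0
    mask_hi: float = 24000.0

    def __post_init__(self) -> None:
        unknown = set(self.index_set) - set(ALL_INDICES)
        if unknown:
            raise ValueError(f"unknown indices {sorted(unknown)}")
        if self.ndsi_anthro[1] > self.ndsi_bio[0]:
            raise ValueError("NDSI anthrophony and biophony bands overlap")
        if self.dsc_aggregation not in (
            "mean_of_frame_centroids", "centroid_of_mean_spectrum",
        ):
            raise ValueError(f"bad dsc_aggregation {self.dsc_aggregation!r}")


@dataclass
class IndexSeries:
    """Per-second index values for one site/session.

    ``values`` has one row per 1 s window (index = window start time in
    seconds) and one column per index; ``degenerate`` flags windows that
    were effectively silent for that index.
    """

    site_id: str
    values: pd.DataFrame
    degenerate: pd.DataFrame

    def to_csv(self, path) -> None:
        """Tidy CSV: site_id, t_start_s, index, value, degenerate_flag."""
        long = self.values.stack().rename("value").reset_index()
        long.columns = ["t_start_s", "index", "value"]
        flags = self.degenerate.stack().rename("degenerate_flag").reset_index()
        long["degenerate_flag"] = flags["degenerate_flag"].to_numpy()
        long.insert(0, "site_id", self.site_id)
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IndexSeries":
        long = pd.read_csv(path)
        site = str(long["site_id"].iloc[0])
        values = long.pivot(index="t_start_s", columns="index", values="value")
        flags = long.pivot(index="t_start_s", columns="index",
                           values="degenerate_flag").astype(bool)
        # restore canonical index order lost by pivot's lexical sort
        order = [c for c in ALL_INDICES if c in values.columns]
        return cls(site, values[order], flags[order])


def aci(block: Spectrogram) -> float:
    """Acoustic complexity: sum over bins of relative adjacent-frame variation.

    ACI = sum_f [ sum_t |A[f,t+1] - A[f,t]| / sum_t A[f,t] ], with bins of
    zero total amplitude contributing 0.
    """
    A = block.A
    if A.shape[1] < 2:
        raise ValueError("ACI requires at least 2 frames")
    num = np.abs(np.diff(A, axis=1)).sum(axis=1)
    den = A.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(ratio.sum())


def _band_edges(freqs: np.ndarray, cfg: IndexConfig) -> list[np.ndarray]:
    """Row-index masks for consecutive band_width-Hz bands up to max_freq."""
    top = min(cfg.max_freq, float(freqs[-1]) + 1e-9)
    lo = float(freqs[0])
    edges = []
    b = 0
    while True:
        b_lo = lo + b * cfg.band_width
        b_hi = b_lo + cfg.band_width
        if b_lo >= top:
            break
        sel = (freqs >= b_lo) & (freqs < min(b_hi, top + 1e-9))
        if b_hi > top:  # truncated last band
            sel = (freqs >= b_lo) & (freqs <= top)
        if sel.any():
            edges.append(np.flatnonzero(sel))
        if b_hi >= top:
            break
        b += 1
    return edges


def band_occupancy(block: Spectrogram, cfg: IndexConfig) -> np.ndarray:
    """Fraction of cells per band exceeding the dB-re-max threshold.

    Amplitudes are expressed as 20*log10(A / max A) over the whole
    block; a cell is occupied when this exceeds ``cfg.db_threshold``.
    Returns the raw (unnormalized) per-band proportions; an all-zero
    block yields the zero vector.
    """
    bands = _band_edges(block.freqs, cfg)
    if not bands:
        raise ValueError("no analysis band inside the masked range")
    amax = block.A.max()
    if amax <= 0:
        return np.zeros(len(bands))
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.where(block.A > 0, block.A, np.nan) / amax)
    occupied = db > cfg.db_threshold
    return np.array([np.nanmean(occupied[rows]) for rows in bands])


def adi(p: np.ndarray) -> float:
    """Shannon entropy (nats) of the normalized band-occupancy vector."""
    p = np.asarray(p, dtype=float)
    if p.size < 1:
        raise ValueError("ADI needs at least one band")
    if (p < 0).any():
        raise ValueError("band proportions must be non-negative")
    s = p.sum()
    if s == 0:
        return 0.0
    q = p / s
    nz = q[q > 0]
    return float(-(nz * np.log(nz)).sum())


def aei(p: np.ndarray) -> float:
    """Gini inequality of band occupancy: 0 = even, -> 1 = single-band dominance."""
    p = np.asarray(p, dtype=float)
    if p.size < 1:
        raise ValueError("AEI needs at least one band")
    if (p < 0).any():
        raise ValueError("band proportions must be non-negative")
    mu = p.mean()
    if mu == 0:
        return 0.0
    n = p.size
    diff = np.abs(p[:, None] - p[None, :]).sum()
    return float(diff / (2.0 * n * n * mu))


def entropy_h(block: Spectrogram) -> tuple[float, bool]:
    """Acoustic entropy H = Ht * Hf in [0, 1].

    Ht is the normalized Shannon entropy of the per-frame RMS envelope;
    Hf the same for the mean spectrum over bins.  Returns (value,
    degenerate_flag); an all-zero block is degenerate with H = 0.
    """
    A = block.A
    if A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("H requires at least 2 bins and 2 frames")
    if A.max() <= 0:
        return 0.0, True

    def _norm_entropy(v: np.ndarray) -> float:
        s = v.sum()
        if s <= 0:
            return 0.0
        q = v / s
        nz = q[q > 0]
        return float(-(nz * np.log2(nz)).sum() / np.log2(v.size))

    env = np.sqrt((A**2).mean(axis=0))     # temporal envelope per frame
    spec = A.mean(axis=1)                  # mean spectrum per bin
    return _norm_entropy(env) * _norm_entropy(spec), False


def _band_rows(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))


def bi(block: Spectrogram, cfg: IndexConfig) -> float:
    """Bioacoustic index: min-referenced area under the mean dB spectrum.

    Each cell is expressed in dB re the block maximum, averaged over
    frames to a mean dB spectrum, restricted to ``cfg.bi_band``, shifted
    so its band minimum is zero, and summed times the bin width in kHz.
    """
    rows = _band_rows(block.freqs, cfg.bi_band)
    if rows.size < 2:
        raise ValueError(f"BI band {cfg.bi_band} holds fewer than 2 bins")
    amax = block.A.max()
    if amax <= 0:
        return 0.0
    floor = amax * 10.0 ** (-120 / 20)  # silence guard well below any signal
    db = 20.0 * np.log10(np.maximum(block.A[rows], floor) / amax)
    s_db = db.mean(axis=1)
    return float((s_db - s_db.min()).sum() * block.fr / 1000.0)


def ndsi(block: Spectrogram, cfg: IndexConfig) -> tuple[float, bool]:
    """Normalized difference soundscape index (B - A)/(B + A) on band powers."""
    ra = _band_rows(block.freqs, cfg.ndsi_anthro)
    rb = _band_rows(block.freqs, cfg.ndsi_bio)
    if ra.size == 0 or rb.size == 0:
        raise ValueError("NDSI bands contain no spectrogram rows")
    if np.intersect1d(ra, rb).size:
        # shared boundary bin goes to the biophony side
        ra = np.setdiff1d(ra, rb)
        if ra.size == 0:
            raise ValueError("NDSI bands overlap completely")
    pa = float((block.A[ra] ** 2).sum())
    pb = float((block.A[rb] ** 2).sum())
    if pa + pb == 0:
        return 0.0, True
    return (pb - pa) / (pb + pa), False


def dsc(block: Spectrogram, cfg: IndexConfig | None = None) -> tuple[float, bool]:
    """Dynamic spectral centroid in kHz.

    Default: amplitude-weighted mean frequency per frame, averaged over
    frames with nonzero energy.  ``centroid_of_mean_spectrum`` instead
    takes the centroid of the frame-averaged spectrum.
    """
    cfg = cfg or IndexConfig()
    A, f = block.A, block.freqs
    if cfg.dsc_aggregation == "centroid_of_mean_spectrum":
        m = A.mean(axis=1)
        tot = m.sum()
        if tot <= 0:
            return 0.0, True
        return float((f * m).sum() / tot / 1000.0), False
    den = A.sum(axis=0)
    ok = den > 0
    if not ok.any():
        return 0.0, True
    cents = (f[:, None] * A[:, ok]).sum(axis=0) / den[ok]
    return float(cents.mean() / 1000.0), False


def compute_block(block: Spectrogram, cfg: IndexConfig) -> tuple[dict, dict]:
    """All configured indices for one integration block.

    Returns (values, degenerate_flags) keyed by index name.  Silent
    blocks yield flagged zeros rather than errors so long unattended
    recordings never abort.
    """
    vals: dict[str, float] = {}
    flags: dict[str, bool] = {}
    silent = block.A.max() <= 0
    want = cfg.index_set
    if "ACI" in want:
        vals["ACI"], flags["ACI"] = aci(block), silent
    if "ADI" in want or "AEI" in want:
        p = band_occupancy(block, cfg)
        if "ADI" in want:
            vals["ADI"], flags["ADI"] = adi(p), silent
        if "AEI" in want:
            vals["AEI"], flags["AEI"] = aei(p), silent
    if "H" in want:
        vals["H"], flags["H"] = entropy_h(block)
    if "BI" in want:
        vals["BI"], flags["BI"] = bi(block, cfg), silent
    if "NDSI" in want:
        vals["NDSI"], flags["NDSI"] = ndsi(block, cfg)
    if "DSC" in want:
        vals["DSC"], flags["DSC"] = dsc(block, cfg)
    return vals, flags


def compute_all(
    clip: AudioClip,
    params: SpectrogramParams | None = None,
    cfg: IndexConfig | None = None,
    integration: float = 1.0,
) -> IndexSeries:
    """Spectrogram -> frequency mask -> 1 s tiling -> one IndexVector per window."""
    params = params or SpectrogramParams()
    cfg = cfg or IndexConfig()
    spec = compute_spectrogram(clip, params)
    spec = band_mask(spec, cfg.mask_lo, min(cfg.mask_hi, clip.rate / 2))
    blocks = tile_windows(spec, integration)
    rows, frows, ts = [], [], []
    for b in blocks:
        v, fl = compute_block(b, cfg)
        rows.append(v)
        frows.append(fl)
        ts.append(b.times[0])
    cols = [c for c in ALL_INDICES if c in cfg.index_set]
    values = pd.DataFrame(rows, index=pd.Index(ts, name="t_start_s"))[cols]
    flags = pd.DataFrame(frows, index=values.index)[cols].astype(bool)
    return IndexSeries(site_id=clip.site_id, values=values, degenerate=flags)
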