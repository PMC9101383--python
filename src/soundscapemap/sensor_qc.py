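"""Fleet screening for very low-cost recorders (VLCRs).

Consumer-grade recorders vary in microphone sensitivity and frequency
response, so before deployment every unit is exposed to the same white
noise from a calibrated flat loudspeaker and screened on the acoustic
complexity index of its recording: because the per-bin ACI ratio is
insensitive to per-bin gain but collapses in dead frequency regions and
shifts under distribution-distorting faults, a unit whose white-noise
ACI deviates from the fleet centre by more than a small tolerance
(default 3%) is rejected.  The selected units' mean spectrum (+/- SD
band) documents the fleet's common frequency response, and a Pearson
correlation between response and source spectra (in dB) quantifies the
effect of mounting orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import AudioClip, Spectrogram, SpectrogramParams, compute_spectrogram, tile_windows
from .indices import aci

__all__ = ["RecorderResponse", "QCReport", "recorder_response",
           "white_noise_aci_screen", "mean_spectrum_band",
           "orientation_correlation"]

#: QC spectra use a 512-point transform, independent of the 1024-point
#: setting used for the field analysis.
QC_PARAMS = SpectrogramParams(window_len=512)


@dataclass
class RecorderResponse:
    """One recorder's white-noise exposure, reduced to ACI + mean spectrum."""

    recorder_id: str
    aci_white: float
    spectrum: np.ndarray          # mean magnitude per bin (512-point FFT)
    freqs: np.ndarray


def recorder_response(recorder_id: str, clip: AudioClip,
                      integration: float = 1.0) -> RecorderResponse:
    """Reduce a white-noise exposure clip to its QC statistics.

    ACI is computed per 1 s block on the 512-point spectrogram and
    averaged over blocks; the spectrum is the frame-mean magnitude.
    """
    spec = compute_spectrogram(clip, QC_PARAMS)
    blocks = tile_windows(spec, integration)
    mean_aci = float(np.mean([aci(b) for b in blocks]))
    return RecorderResponse(recorder_id=recorder_id, aci_white=mean_aci,
                            spectrum=spec.A.mean(axis=1), freqs=spec.freqs)


@dataclass
class QCReport:
    center: float
    center_statistic: str
    tolerance: float
    table: pd.DataFrame           # recorder_id, aci_white, relative_deviation, selected

    @property
    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "recorder_id"])

    @property
    def rejected(self) -> list[str]:
        return list(self.table.loc[~self.table["selected"], "recorder_id"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def white_noise_aci_screen(
    responses: list[RecorderResponse],
    tolerance: float = 0.03,
    center: str = "mean",
) -> QCReport:
    """Select recorders whose white-noise ACI sits within ``tolerance``
    (relative) of the fleet centre.

    The centre is the fleet mean by default; the median is offered
    because a single gross outlier can drag the mean (and hence the 3%
    band) away from the healthy units.  Single pass, no re-centering.
    The screen is scale-free: rescaling every ACI by a common factor
    leaves the selection unchanged.
    """
    if len(responses) < 2:
        raise ValueError("need at least 2 recorder responses to screen")
    acis = np.array([r.aci_white for r in responses], dtype=float)
    if center == "mean":
        c = float(acis.mean())
    elif center == "median":
        c = float(np.median(acis))
    else:
        raise ValueError(f"unknown center statistic {center!r}")
    rel = np.abs(acis - c) / c if c != 0 else np.where(acis == 0, 0.0, np.inf)
    tab = pd.DataFrame({
        "recorder_id": [r.recorder_id for r in responses],
        "aci_white": acis,
        "relative_deviation": rel,
        "selected": rel <= tolerance,
    }).sort_values(["relative_deviation", "recorder_id"],
                   kind="stable").reset_index(drop=True)
    return QCReport(center=c, center_statistic=center, tolerance=tolerance,
                    table=tab)


def mean_spectrum_band(responses: list[RecorderResponse]) -> pd.DataFrame:
    """Per-bin mean and sample SD of the selected recorders' spectra."""
    if len(responses) < 2:
        raise ValueError("need at least 2 recorders for a mean spectrum")
    shapes = {r.spectrum.shape for r in responses}
    if len(shapes) != 1:
        raise ValueError(f"spectrum geometries differ: {shapes}")
    freqs = responses[0].freqs
    if any(not np.array_equal(r.freqs, freqs) for r in responses):
        raise ValueError("frequency axes differ between recorders")
    S = np.stack([r.spectrum for r in responses])
    return pd.DataFrame({"freq_hz": freqs,
                         "mean": S.mean(axis=0),
                         "sd": S.std(axis=0, ddof=1)})


def orientation_correlation(response_spectrum: np.ndarray,
                            source_spectrum: np.ndarray) -> float:
    """Pearson correlation between response and source spectra in dB.

    Used to compare recorder mounting orientations: the better-aligned
    orientation correlates more strongly with the source spectrum.
    """
    a = np.asarray(response_spectrum, dtype=float)
    b = np.asarray(source_spectrum, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("spectra must share a length of at least 3")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("spectra must be strictly positive to take dB")
    a_db, b_db = 20 * np.log10(a), 20 * np.log10(b)
    if np.ptp(a_db) == 0 or np.ptp(b_db) == 0:
        raise ValueError("constant spectrum: correlation undefined")
    return float(np.corrcoef(a_db, b_db)[0, 1])
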