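"""Seeded synthetic soundscapes with known ground truth.

The generator emulates the acoustic structure of a wooded urban park
bordered by a highway: continuous low-frequency traffic noise whose
level falls off with distance from the road edge, Poisson-arriving bird
chirps in the 1.5-8 kHz band whose rate rises away from the road,
occasional broadband take-off transients, pulsed ~1 kHz construction
beeps, and white-noise calibration clips for recorder QC.  Every source
of randomness flows from an explicit seed, so a study bundle is
bit-reproducible and each pipeline stage can be tested against the
planted near-road / interior grouping without any field recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .audio import AudioClip, write_wav
from .mapping import SiteGeo

__all__ = [
    "SiteSceneConfig", "StudyConfig", "synth_traffic", "synth_chirps",
    "synth_takeoff", "synth_beeps", "white_noise_clip", "render_site",
    "default_grid", "generate_study",
]

RATE = 48000.0


@dataclass(frozen=True)
class SiteSceneConfig:
    """Recipe for one site's scene mix."""

    site_id: str
    distance_to_road: float            # m, > 0
    traffic_level_at_10m: float = -12.0  # dBFS RMS of the traffic bed at 10 m
    #: decay per decade of distance: 20 = point source (inverse-distance),
    #: 10 = line source (a busy road is a line of vehicles)
    traffic_decay_db_per_decade: float = 20.0
    chirp_rate: float = 20.0           # events/minute
    chirp_band: tuple[float, float] = (1500.0, 8000.0)
    takeoff_times: tuple[float, ...] = ()
    beep_rate: float = 0.0             # events/minute
    sensor_noise_dbfs: float = -55.0   # recorder self-noise floor (white)
    duration: float = 60.0             # s
    seed: int = 0
    rate: float = RATE

    def __post_init__(self) -> None:
        if self.distance_to_road <= 0:
            raise ValueError("distance_to_road must be positive")
        if self.duration < 1:
            raise ValueError("duration must be at least 1 s")
        if self.chirp_rate < 0 or self.beep_rate < 0:
            raise ValueError("event rates must be non-negative")


@dataclass
class StudyConfig:
    """A full multi-site study: grid, road, gradients, one master seed.

    The road edge lies at x = 0 by convention; a site's distance to the
    road is its x coordinate.  The highway is modelled as a line source
    (a continuous stream of vehicles), so traffic level decays
    cylindrically at 10 dB per decade of distance from the 10 m
    reference.  Biophony opposes the traffic gradient as a
    road-effect zone: songbird activity is depressed within the edge
    strip (chirp rate ``chirp_rate_near`` for sites up to the median
    distance) and recovers in the interior (``chirp_rate_far`` beyond
    it), the threshold response documented for breeding birds along
    roads.  Near-strip sites also hear pulsed construction-alarm beeps.
    """

    grid: list[SiteGeo] = field(default_factory=lambda: default_grid())
    traffic_level_at_10m: float = -12.0
    chirp_rate_near: float = 8.0
    chirp_rate_far: float = 60.0
    beep_rate_near: float = 30.0         # reversing-alarm beeps near the road (~1/s while active)
    duration: float = 60.0
    seed: int = 0
    traffic_gradient_only: bool = False   # constant chirp rate, no beeps

    def __post_init__(self) -> None:
        ids = [g.site_id for g in self.grid]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids in study grid")
        if len(ids) < 2:
            raise ValueError("a study needs at least 2 sites")
        if any(g.x <= 0 for g in self.grid):
            raise ValueError("all sites must lie at x > 0 (road edge at x = 0)")


def _rms_scale(x: np.ndarray, level_dbfs: float) -> np.ndarray:
    rms = np.sqrt((x**2).mean())
    return x * (10.0 ** (level_dbfs / 20.0) / rms) if rms > 0 else x


def synth_traffic(duration: float, level_dbfs: float = -12.0,
                  seed: int = 0, rate: float = RATE) -> AudioClip:
    """Stationary low-frequency traffic bed.

    Gaussian noise through a 6th-order 400 Hz Butterworth low-pass, so
    at least 90% of the power sits below 1 kHz, RMS-scaled to
    ``level_dbfs`` (exact by construction, i.e. well within 0.5 dB).
    """
    if duration < 1:
        raise ValueError("duration must be at least 1 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    white = rng.standard_normal(n)
    sos = signal.butter(6, 400.0, btype="low", fs=rate, output="sos")
    shaped = signal.sosfilt(sos, white)
    return AudioClip(_rms_scale(shaped, level_dbfs), rate)


def synth_chirps(duration: float, rate_per_min: float,
                 band: tuple[float, float] = (1500.0, 8000.0),
                 seed: int = 0, rate: float = RATE,
                 amplitude: float = 0.1) -> AudioClip:
    """Poisson stream of frequency-modulated bird-like chirps.

    Chirp count ~ Poisson(rate * duration); each chirp is a 0.1-1.0 s
    linear FM tone between two frequencies drawn inside ``band``, with a
    Hann envelope and a random amplitude; overlapping chirps add.
    """
    if band[0] <= 0 or band[1] > rate / 2:
        raise ValueError(f"chirp band {band} outside (0, Nyquist]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    out = np.zeros(n)
    count = rng.poisson(rate_per_min / 60.0 * duration)
    for _ in range(count):
        dur = rng.uniform(0.1, 1.0)
        t0 = rng.uniform(0.0, max(duration - dur, 0.0))
        f0, f1 = np.sort(rng.uniform(band[0], band[1], size=2))
        if rng.random() < 0.5:
            f0, f1 = f1, f0            # downward sweeps too
        m = int(dur * rate)
        if m < 2:
            continue
        t = np.arange(m) / rate
        tone = signal.chirp(t, f0=f0, t1=dur, f1=f1, method="linear")
        env = np.hanning(m)
        amp = amplitude * rng.uniform(0.3, 1.0)
        i0 = int(t0 * rate)
        out[i0:i0 + m] += amp * tone[: n - i0] * env[: n - i0]
    return AudioClip(out, rate) if n else AudioClip(np.zeros(1), rate)


def synth_takeoff(duration_event: float = 40.0, seed: int = 0,
                  rate: float = RATE, amplitude: float = 0.5) -> AudioClip:
    """Broadband take-off transient with a rise-hold-decay envelope.

    Noise with a -12 dB/octave tilt above 800 Hz — a distant aircraft's
    spectrum is low-frequency dominated (atmospheric absorption) but
    still carries energy past 8 kHz — shaped by a linear 20% rise, 30%
    hold, 50% exponential decay.  Against a bird-and-traffic background
    the event depresses band-occupancy diversity and drags the spectral
    centroid down while leaving the complexity index nearly untouched.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_event * rate))
    sos = signal.butter(2, 800.0, btype="low", fs=rate, output="sos")
    noise = signal.sosfilt(sos, rng.standard_normal(n))
    rise, hold = int(0.2 * n), int(0.3 * n)
    env = np.ones(n)
    env[:rise] = np.linspace(0.0, 1.0, rise, endpoint=False)
    decay = n - rise - hold
    env[rise + hold:] = np.exp(-3.0 * np.arange(decay) / decay)
    x = amplitude * noise / np.abs(noise).max() * env
    return AudioClip(x, rate)


def synth_beeps(duration: float, rate_per_min: float, seed: int = 0,
                rate: float = RATE, freq: float = 1000.0,
                amplitude: float = 0.08) -> AudioClip:
    """Pulsed construction-alarm beeps: 0.3 s tone bursts at ``freq``.

    Reversing alarms are square-ish, so the burst carries 2nd and 3rd
    harmonics at -6 and -12 dB relative to the fundamental.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    out = np.zeros(n)
    count = rng.poisson(rate_per_min / 60.0 * duration)
    m = int(0.3 * rate)
    t = np.arange(m) / rate
    tone = (np.sin(2 * np.pi * freq * t)
            + 0.5 * np.sin(2 * np.pi * 2 * freq * t)
            + 0.25 * np.sin(2 * np.pi * 3 * freq * t))
    burst = tone / np.abs(tone).max() * np.hanning(m)
    for _ in range(count):
        i0 = int(rng.uniform(0, max(n - m, 1)))
        out[i0:i0 + m] += amplitude * burst[: n - i0]
    return AudioClip(out, rate)


def white_noise_clip(duration: float = 10.0, level_dbfs: float = -20.0,
                     seed: int = 0, rate: float = RATE) -> AudioClip:
    """Flat white-noise calibration clip for recorder QC."""
    rng = np.random.default_rng(seed)
    x = _rms_scale(rng.standard_normal(int(round(duration * rate))), level_dbfs)
    return AudioClip(x, rate)


def simulate_recorder_fleet(
    n_total: int = 46,
    n_anomalous: int = 24,
    duration: float = 10.0,
    seed: int = 0,
    rate: float = RATE,
) -> list[tuple[str, AudioClip, bool]]:
    """White-noise bench exposures for a fleet with planted faults.

    Every recorder hears the same kind of flat white noise at slightly
    different gains (the complexity-ratio screen is scale-free, so
    unit-to-unit gain spread must not trip it).  Anomalous units carry
    one of two electrical faults common in consumer recorders, both
    visible to a per-bin temporal-variation statistic: a
    switching-supply whine (a strong harmonic comb whose steady tones
    depress the per-bin variation ratio) or storage-write glitches
    (impulsive clicks that inflate it).  Pure amplitude faults
    (mis-gain, clipping) are deliberately not planted: an
    amplitude-ratio screen cannot see them.  Returns (recorder_id,
    clip, is_clean) triples.
    """
    rng = np.random.default_rng(seed)
    anomalous = set(rng.choice(n_total, size=n_anomalous, replace=False))
    fleet = []
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    for i in range(n_total):
        sub = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        x = sub.standard_normal(n)
        x = _rms_scale(x, -20.0) * sub.uniform(0.9, 1.1)  # unit-to-unit gain
        if i in anomalous:
            rms = np.sqrt((x**2).mean())
            if sub.random() < 0.5:  # harmonic whine comb
                f0 = sub.uniform(300.0, 800.0)
                harmonics = np.arange(f0, rate / 2, f0)
                gain = sub.uniform(2.0, 4.0)
                for f in harmonics:
                    x = x + gain * rms / np.sqrt(harmonics.size) * np.sin(
                        2 * np.pi * f * t + sub.uniform(0, 2 * np.pi))
            else:  # impulsive write glitches
                n_clicks = int(sub.uniform(150, 300) * duration)
                idx = sub.integers(0, n, n_clicks)
                x[idx] += sub.choice([-1.0, 1.0], n_clicks) * \
                    sub.uniform(20, 50, n_clicks) * rms
        peak = np.abs(x).max()
        if peak > 1.0:
            x = x / peak
        fleet.append((f"R{i + 1:02d}", AudioClip(x, rate), i not in anomalous))
    return fleet


def render_site(cfg: SiteSceneConfig) -> tuple[AudioClip, dict]:
    """Mix one site's scene and return the clip plus ground-truth metadata.

    The traffic bed is attenuated by
    ``traffic_decay_db_per_decade * log10(distance / 10)`` dB re the
    10 m level (default 20 dB/decade, the inverse-distance law for a
    point source; 10 dB/decade models a road as a line source); chirps,
    take-off
    events and beeps are added on top, plus the recorder's own white
    self-noise floor (cheap sensors are noisy, and the floor — not
    silence — is what occupies signal-free spectrogram cells in real
    recordings); the mix is peak-normalized down to -1 dBFS only if it
    would otherwise clip.
    """
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    level = cfg.traffic_level_at_10m - cfg.traffic_decay_db_per_decade * \
        np.log10(cfg.distance_to_road / 10.0)
    mix = synth_traffic(cfg.duration, level, int(seeds[0]), cfg.rate).samples
    floor_rng = np.random.default_rng(int(seeds[4]))
    mix = mix + _rms_scale(floor_rng.standard_normal(mix.size),
                           cfg.sensor_noise_dbfs)
    chirps = synth_chirps(cfg.duration, cfg.chirp_rate, cfg.chirp_band,
                          int(seeds[1]), cfg.rate)
    mix = mix + chirps.samples
    for i, t0 in enumerate(cfg.takeoff_times):
        ev = synth_takeoff(seed=int(seeds[2]) + i, rate=cfg.rate)
        i0 = int(t0 * cfg.rate)
        seg = ev.samples[: max(mix.size - i0, 0)]
        mix[i0:i0 + seg.size] += seg
    if cfg.beep_rate > 0:
        # construction alarm at the road edge: same spherical decay as traffic
        beep_amp = 0.3 * 10.0 / cfg.distance_to_road
        mix = mix + synth_beeps(cfg.duration, cfg.beep_rate,
                                int(seeds[3]), cfg.rate,
                                amplitude=beep_amp).samples
    peak = np.abs(mix).max()
    ceiling = 10.0 ** (-1.0 / 20.0)      # -1 dBFS
    norm = 1.0
    if peak > ceiling:
        norm = ceiling / peak
        mix = mix * norm
    if np.abs(mix).max() > 1.0:
        raise RuntimeError("internal error: clipping after normalization")
    meta = {
        "site_id": cfg.site_id,
        "distance_to_road_m": cfg.distance_to_road,
        "traffic_level_dbfs": level,
        "chirp_rate_per_min": cfg.chirp_rate,
        "beep_rate_per_min": cfg.beep_rate,
        "n_takeoffs": len(cfg.takeoff_times),
        "normalization_gain": norm,
        "duration_s": cfg.duration,
        "seed": cfg.seed,
    }
    return AudioClip(mix, cfg.rate, site_id=cfg.site_id), meta


def default_grid() -> list[SiteGeo]:
    """16 sites on a 4 x 4 grid covering ~90 x 135 m.

    The first row sits 40 m from the road edge (x = 0): wooded parcels
    along highways begin behind a buffer strip, so the grid spans
    40-130 m of road distance (a ~10 dB spherical-spreading span).
    """
    sites = []
    xs = [40.0, 70.0, 100.0, 130.0]
    ys = [0.0, 45.0, 90.0, 135.0]
    i = 1
    for x in xs:
        for y in ys:
            sites.append(SiteGeo(site_id=f"S{i:02d}", x=x, y=y))
            i += 1
    return sites


def generate_study(
    cfg: StudyConfig | None = None, out_dir: str | Path | None = None
) -> tuple[list[AudioClip], list[SiteGeo], pd.DataFrame]:
    """Render every site of a study with its planted near/far grouping.

    Traffic level decays with road distance while the chirp rate grows
    with it, and sites in the near half additionally hear pulsed
    construction beeps — the technophony mix typical of a park edge
    (unless ``traffic_gradient_only``, which plants the traffic level
    gradient alone).  The ground-truth group splits sites at the median
    road distance (near = 1, far = 2).  If ``out_dir`` is given, writes
    one 16-bit WAV per site plus a ``truth.csv`` table.
    """
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    dists = np.array([g.x for g in cfg.grid])
    lo, hi = dists.min(), dists.max()
    med = float(np.median(dists))
    clips, rows = [], []
    for g in cfg.grid:
        near = g.x <= med
        if cfg.traffic_gradient_only:
            rate_c, rate_b = 0.5 * (cfg.chirp_rate_near + cfg.chirp_rate_far), 0.0
        else:
            rate_c = cfg.chirp_rate_near if near else cfg.chirp_rate_far
            rate_b = cfg.beep_rate_near if near else 0.0
        scene = SiteSceneConfig(
            site_id=g.site_id,
            distance_to_road=g.x,
            traffic_level_at_10m=cfg.traffic_level_at_10m,
            traffic_decay_db_per_decade=10.0,  # highway = line source
            chirp_rate=rate_c,
            beep_rate=rate_b,
            duration=cfg.duration,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        clip, meta = render_site(scene)
        meta["true_group"] = 1 if g.x <= med else 2
        meta["x_m"], meta["y_m"] = g.x, g.y
        clips.append(clip)
        rows.append(meta)
    truth = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for clip in clips:
            write_wav(out / f"{clip.site_id}.wav", clip)
        truth.to_csv(out / "truth.csv", index=False)
    return clips, cfg.grid, truth
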