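"""End-to-end orchestration: audio -> indices -> features -> PCA ->
clusters -> tests -> maps.

``run_pipeline`` takes a single config (synthetic study or a directory
of per-site WAVs plus a coordinate table), runs every stage with fixed
seeds, and writes a deterministic artifact bundle: per-site index
series, the feature matrix, a PCA summary with grouped contributions,
cluster solutions for k in {2, 3, 4} with internal validation, a
rank-test report per index, classical-MDS coordinates, per-site class
maps, and a JSON run manifest recording seeds and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import SpectrogramParams, read_wav
from .cluster import (classical_mds, cluster, run_pca, select_dimensions,
                      validate_clusterings, variable_contributions)
from .descriptors import build_feature_matrix
from .group_tests import compare_clusters
from .indices import ALL_INDICES, IndexConfig, compute_all
from .mapping import SiteGeo, classify_equal_intervals, export_map
from .synth import StudyConfig, generate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; a missing ``wav_dir`` triggers synthesis."""

    out_dir: str | Path = "soundscapemap_run"
    wav_dir: str | Path | None = None
    sites_csv: str | Path | None = None        # site_id, x_m, y_m
    synth: StudyConfig = field(default_factory=StudyConfig)
    index_set: tuple[str, ...] = ALL_INDICES
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    integration: float = 1.0
    cum_var_target: float = 78.0
    algorithms: tuple[str, ...] = ("kmeans", "diana")
    ks: tuple[int, ...] = (2, 3, 4)
    descriptor: str = "mean"
    n_map_classes: int = 4
    seed: int = 0


@dataclass
class PipelineResult:
    feature_matrix: "pd.DataFrame"
    pca_summary: pd.DataFrame
    contributions: pd.DataFrame
    retained_dims: int
    solutions: dict[tuple[str, int], np.ndarray]
    validation: pd.DataFrame
    test_reports: dict[tuple[str, int], pd.DataFrame]
    out_dir: Path


def _config_hash(cfg: PipelineConfig) -> str:
    def enc(o):
        if isinstance(o, Path):
            return str(o)
        if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
            return {k: enc(v) for k, v in asdict(o).items()} if hasattr(o, "__dataclass_fields__") else vars(o)
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        if isinstance(o, dict):
            return {k: enc(v) for k, v in o.items()}
        return o
    blob = json.dumps(enc(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_sites(cfg: PipelineConfig) -> tuple[list, list[SiteGeo]]:
    if cfg.wav_dir is None:
        clips, geo, truth = generate_study(cfg.synth)
        return clips, geo
    sites = pd.read_csv(cfg.sites_csv)
    geo = [SiteGeo(str(r.site_id), float(r.x_m), float(r.y_m))
           for r in sites.itertuples()]
    clips = [read_wav(Path(cfg.wav_dir) / f"{g.site_id}.wav", site_id=g.site_id)
             for g in geo]
    return clips, geo


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write the artifact bundle under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clips, geo = _load_sites(cfg)

    icfg = IndexConfig(index_set=tuple(cfg.index_set))
    series = []
    series_dir = out / "index_series"
    series_dir.mkdir(exist_ok=True)
    for clip in clips:
        s = compute_all(clip, cfg.spectrogram, icfg, cfg.integration)
        n_degen = int(s.degenerate.to_numpy().sum())
        if n_degen:
            logger.info("site %s: %d degenerate index windows", clip.site_id, n_degen)
        s.to_csv(series_dir / f"{clip.site_id}.csv")
        series.append(s)

    fm = build_feature_matrix(series)
    fm.to_csv(out / "feature_matrix.csv")

    pca = run_pca(fm, standardize=True)
    d = select_dimensions(pca, cum_var_target=cfg.cum_var_target)
    pca_summary = pd.DataFrame({
        "dimension": np.arange(1, pca.eigenvalues.size + 1),
        "eigenvalue": pca.eigenvalues,
        "explained_variance_pct": pca.explained_variance_pct,
        "cumulative_pct": pca.cumulative_pct,
    })
    pca_summary.to_csv(out / "pca_summary.csv", index=False)
    contrib = variable_contributions(pca, dims=max(d, 3))
    contrib.to_csv(out / "pca_contributions.csv")

    scores = pca.scores[:, :d]
    solutions, reports = {}, {}
    sols = []
    for algo in cfg.algorithms:
        for k in cfg.ks:
            sol = cluster(scores, algo, k, seed=cfg.seed, site_ids=fm.site_ids)
            sols.append(sol)
            solutions[(algo, k)] = sol.labels
            sol.to_frame().to_csv(out / f"clusters_{algo}_k{k}.csv", index=False)
            rep = compare_clusters(fm, sol, descriptor=cfg.descriptor)
            reports[(algo, k)] = rep
            rep.to_csv(out / f"tests_{algo}_k{k}.csv", index=False)
    validation = validate_clusterings(scores, sols)
    validation.to_csv(out / "validation.csv")

    from scipy.spatial.distance import pdist, squareform
    mds = classical_mds(squareform(pdist(scores)))
    mds.to_csv(out / "mds_coordinates.csv", site_ids=fm.site_ids)

    # per-site map attributes: mean-index classes + primary cluster labels
    attrs = pd.DataFrame(index=pd.Index(fm.site_ids, name="site_id"))
    for idx in cfg.index_set:
        col = f"{idx}_mean"
        if col in fm.data.columns:
            attrs[f"{idx}_mean"] = fm.data[col]
            attrs[f"{idx}_class"] = classify_equal_intervals(
                fm.data[col].to_numpy(), cfg.n_map_classes)
    for (algo, k), labels in solutions.items():
        attrs[f"cluster_{algo}_k{k}"] = labels
    export_map(geo, attrs, out / "site_map")

    manifest = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "index_set": list(cfg.index_set),
        "n_sites": len(fm.site_ids),
        "n_features": fm.data.shape[1],
        "retained_dims": int(d),
        "algorithms": list(cfg.algorithms),
        "ks": list(cfg.ks),
        "synthetic": cfg.wav_dir is None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        feature_matrix=fm.data,
        pca_summary=pca_summary,
        contributions=contrib.table,
        retained_dims=d,
        solutions=solutions,
        validation=validation.table,
        test_reports=reports,
        out_dir=out,
    )
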