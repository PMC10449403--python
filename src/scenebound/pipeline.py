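"""End-to-end orchestration: inputs on disk -> full analysis bundle.

Stage order follows the analysis design: visual features -> semantic
features -> PCA unification (x2) -> boundary scores -> split-half noise
ceiling -> regression models (depth baseline, depth+semantic,
depth+visual, full, per-semantic-feature) -> variance partitioning.
Every artifact is written as plain text together with a manifest
recording parameters, seed, software version, and content hashes, so a
rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as sbio
from .behavior import RESPONSE_CODING, noise_ceiling, score_table
from .inference import (
    fit_ols,
    per_feature_regressions,
    regression_report,
    variance_partition,
)
from .semantic import semantic_feature_table
from .unify import SEMANTIC_METRICS, unify_features
from .visual import visual_feature_table

logger = logging.getLogger("scenebound")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All paths and parameters needed for a full run."""

    images: str
    descriptions: str
    embeddings: str
    depth: str
    responses: str
    out_dir: str = "scenebound_out"
    # visual metric parameters
    blur_kernel: int = 5
    canny_low: float = 30.0
    canny_high: float = 150.0
    color_bins: int = 20
    # unification
    standardize: bool = True
    # resampling
    ceiling_iterations: int = 10_000
    ceiling_interval: float = 0.95
    seed: int = 0
    # response coding convention (label -> +/-1)
    response_coding: dict = field(default_factory=lambda: dict(RESPONSE_CODING))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        for name in ("images", "descriptions", "embeddings", "depth", "responses"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise StageError(f"[config] missing {name} input: {p}")
        if not 0 <= self.canny_low <= self.canny_high:
            raise StageError("[config] need 0 <= canny_low <= canny_high")
        if self.color_bins < 2:
            raise StageError("[config] color_bins must be >= 2")
        if not 0 < self.ceiling_interval < 1:
            raise StageError("[config] ceiling_interval must be in (0, 1)")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc
            logger.info("stage %-18s %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@_stage("visual-features")
def _visual(cfg: PipelineConfig) -> pd.DataFrame:
    images = sbio.read_images(cfg.images)
    return visual_feature_table(
        images,
        blur_kernel=cfg.blur_kernel,
        low_threshold=cfg.canny_low,
        high_threshold=cfg.canny_high,
        bins_per_axis=cfg.color_bins,
    )


@_stage("semantic-features")
def _semantic(cfg: PipelineConfig) -> pd.DataFrame:
    corpora = sbio.read_descriptions(cfg.descriptions)
    emb = sbio.read_embeddings(cfg.embeddings)
    return semantic_feature_table(corpora, emb)


def run_all(cfg: PipelineConfig) -> dict:
    """Execute the whole pipeline and write all artifacts under ``out_dir``.

    Returns a result bundle with the feature tables, unified scores,
    boundary scores, noise ceiling, regression results and the variance
    partition.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    visual = _visual(cfg)
    semantic = _semantic(cfg)
    vis_scores, vis_model = unify_features(visual, "visual", cfg.standardize)
    sem_scores, sem_model = unify_features(semantic, "semantic", cfg.standardize)

    responses = sbio.read_responses(cfg.responses)
    scores = score_table(responses, coding=cfg.response_coding)
    ceiling = noise_ceiling(
        responses,
        n_iterations=cfg.ceiling_iterations,
        interval=cfg.ceiling_interval,
        seed=cfg.seed,
        coding=cfg.response_coding,
    )

    depth = sbio.read_depth(cfg.depth)
    merged = (
        scores[["image_id", "score"]]
        .merge(depth, on="image_id")
        .merge(sem_scores, on="image_id")
        .merge(vis_scores, on="image_id")
        .merge(semantic, on="image_id")
    )
    if merged.empty:
        raise StageError("[merge] no images shared across all input tables")

    y = merged["score"]
    regressions = {
        "depth": fit_ols(y, merged[["depth"]]),
        "depth+semantic": fit_ols(y, merged[["depth", "semantic_info"]]),
        "depth+visual": fit_ols(y, merged[["depth", "visual_info"]]),
        "depth+semantic+visual": fit_ols(
            y, merged[["depth", "semantic_info", "visual_info"]]
        ),
    }
    per_feature = per_feature_regressions(y, merged, SEMANTIC_METRICS)
    partition = variance_partition(
        y, merged["depth"], merged["semantic_info"], merged["visual_info"]
    )

    # ------------------------------------------------------------- outputs
    sbio.write_table(visual, out / "visual_features.csv")
    sbio.write_table(semantic, out / "semantic_features.csv")
    sbio.write_table(vis_scores, out / "visual_info.csv")
    sbio.write_table(sem_scores, out / "semantic_info.csv")
    vis_model.to_json(out / "visual_pca.json")
    sem_model.to_json(out / "semantic_pca.json")
    sbio.write_table(scores, out / "boundary_scores.csv")
    sbio.write_table(merged, out / "merged.csv")
    (out / "noise_ceiling.json").write_text(
        json.dumps(
            {
                "lower": ceiling.lower,
                "upper": ceiling.upper,
                "n_iterations": ceiling.n_iterations,
                "interval_mass": ceiling.interval_mass,
                "seed": ceiling.seed,
            },
            indent=2,
        )
    )
    (out / "regressions.json").write_text(
        json.dumps(
            {
                **{k: v.to_dict() for k, v in regressions.items()},
                **{
                    f"feature:{SEMANTIC_METRICS[i]}": r.to_dict()
                    for i, r in enumerate(per_feature)
                },
            },
            indent=2,
        )
    )
    (out / "partition.json").write_text(json.dumps(partition.to_dict(), indent=2))
    (out / "report.txt").write_text(
        regression_report(regressions)
        + "\n\nnoise ceiling: "
        + f"[{ceiling.lower:.4f}, {ceiling.upper:.4f}] "
        + f"({ceiling.n_iterations} splits, {ceiling.interval_mass:.0%} interval)\n"
    )

    manifest = {
        "version": __version__,
        "config": {
            k: v for k, v in dataclasses.asdict(cfg).items()
        },
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()
            and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "visual_features": visual,
        "semantic_features": semantic,
        "visual_scores": vis_scores,
        "semantic_scores": sem_scores,
        "visual_model": vis_model,
        "semantic_model": sem_model,
        "boundary_scores": scores,
        "noise_ceiling": ceiling,
        "merged": merged,
        "regressions": regressions,
        "per_feature": per_feature,
        "partition": partition,
        "manifest": manifest,
    }
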