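"""Collapse a triple of information metrics into one score via PCA.

The three visual metrics (and, separately, the three semantic metrics) are
strongly collinear by design: each is a different proxy for the same
underlying quantity of information.  Projecting images onto the first
principal component of the (by default z-scored) 3-column metric matrix
yields a single per-image information score.

The PC sign is ambiguous, so it is fixed by an anchor convention: the
loading of a designated anchor metric (``edge_density`` for visual,
``median_length`` for semantic) is made positive, so "higher score = more
information" is stable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

VISUAL_METRICS = ("edge_density", "color_entropy", "gist_entropy")
SEMANTIC_METRICS = ("median_length", "lexical_entropy", "mean_pairwise_distance")
_DEFAULT_ANCHOR = {"visual": "edge_density", "semantic": "median_length"}


class DegenerateInputError(ValueError):
    """Raised for constant columns or too few rows to fit a PCA."""


@dataclass(frozen=True)
class PCAModel:
    """Frozen PCA fit: center/scale per feature plus the PC1 loading vector."""

    feature_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # first-component unit vector
    variance_explained: np.ndarray  # all components, sums to 1
    standardized: bool = field(default=True)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": list(self.feature_names),
                    "center": self.center.tolist(),
                    "scale": self.scale.tolist(),
                    "loadings": self.loadings.tolist(),
                    "variance_explained": self.variance_explained.tolist(),
                    "standardized": self.standardized,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(d["feature_names"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            variance_explained=np.asarray(d["variance_explained"], dtype=float),
            standardized=bool(d["standardized"]),
        )


def _as_matrix(
    rows: pd.DataFrame | np.ndarray, feature_names: Sequence[str] | None
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(rows, pd.DataFrame):
        names = tuple(feature_names) if feature_names else tuple(
            c for c in rows.columns if c != "image_id"
        )
        missing = [c for c in names if c not in rows.columns]
        if missing:
            raise ValueError(f"feature mismatch: missing column(s) {missing}")
        mat = rows.loc[:, list(names)].to_numpy(dtype=float)
    else:
        mat = np.asarray(rows, dtype=float)
        names = tuple(feature_names) if feature_names else tuple(
            f"f{i}" for i in range(mat.shape[1])
        )
    return mat, names


def fit_info_pca(
    rows: pd.DataFrame | np.ndarray,
    feature_names: Sequence[str] | None = None,
    standardize: bool = True,
    anchor: str | None = None,
) -> PCAModel:
    """Fit a PCA to an ``n x 3`` metric matrix.

    Parameters
    ----------
    rows
        Feature matrix (DataFrame columns beyond ``image_id`` or ndarray).
    standardize
        Z-score each column before the PCA (recommended: the metrics live
        on wildly different native scales — edge counts ~1e4 versus
        entropies ~1e0).
    anchor
        Feature whose PC1 loading is forced positive.  Defaults to the
        first feature.
    """
    mat, names = _as_matrix(rows, feature_names)
    n, p = mat.shape
    if n < 3:
        raise DegenerateInputError("need at least 3 rows to fit a PCA")
    if np.isnan(mat).any():
        raise DegenerateInputError("missing values in feature matrix")
    std = mat.std(axis=0, ddof=0)
    if np.any(std == 0):
        bad = [names[i] for i in np.flatnonzero(std == 0)]
        raise DegenerateInputError(f"constant feature column(s): {bad}")

    center = mat.mean(axis=0)
    scale = std if standardize else np.ones(p)
    z = (mat - center) / scale

    pca = PCA(n_components=p)
    pca.fit(z)
    loadings = pca.components_[0].copy()
    var_exp = pca.explained_variance_ratio_.copy()

    anchor = anchor or names[0]
    if anchor not in names:
        raise ValueError(f"anchor {anchor!r} not among features {names}")
    if loadings[names.index(anchor)] < 0:
        loadings = -loadings

    return PCAModel(
        feature_names=names,
        center=center,
        scale=scale,
        loadings=loadings / np.linalg.norm(loadings),
        variance_explained=var_exp,
        standardized=standardize,
    )


def project_pc1(
    rows: pd.DataFrame | np.ndarray, model: PCAModel
) -> np.ndarray:
    """Project rows onto the model's first principal component.

    In-sample projections of the fitted dataset have mean 0 (centering).
    """
    mat, names = _as_matrix(rows, model.feature_names)
    if names != model.feature_names:
        raise ValueError(
            f"feature mismatch: expected {model.feature_names}, got {names}"
        )
    return ((mat - model.center) / model.scale) @ model.loadings


def unify_features(
    table: pd.DataFrame,
    kind: str,
    standardize: bool = True,
    score_column: str | None = None,
) -> tuple[pd.DataFrame, PCAModel]:
    """Fit + project in one step for a visual or semantic feature table.

    Returns a ``(image_id, score)`` DataFrame and the fitted model.  The
    anchor metric is ``edge_density`` for ``kind='visual'`` and
    ``median_length`` for ``kind='semantic'``.
    """
    if kind not in _DEFAULT_ANCHOR:
        raise ValueError("kind must be 'visual' or 'semantic'")
    metrics = VISUAL_METRICS if kind == "visual" else SEMANTIC_METRICS
    model = fit_info_pca(
        table, feature_names=metrics, standardize=standardize,
        anchor=_DEFAULT_ANCHOR[kind],
    )
    scores = project_pc1(table, model)
    col = score_column or f"{kind}_info"
    out = pd.DataFrame({"image_id": table["image_id"].to_numpy(), col: scores})
    return out, model
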