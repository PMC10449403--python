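"""Boundary-transformation scores and the split-half noise ceiling.

In the forced-error paradigm the test image is identical to the study
image, so a "closer"/"farther" judgment is necessarily an error revealing
a memory bias.  A report that the re-presentation looks *closer*
(zoomed-in) implies the remembered view was wider than shown — a boundary
**extension** error, coded +1; "farther" implies **contraction**, coded
-1.  The per-image mean of these codes is the boundary-transformation
score: +1 means every observer extended, -1 every observer contracted.

The noise ceiling estimates how well any image-level model could possibly
do: participants are repeatedly split in half, per-image scores are
computed in each half, and one half's scores are regressed on the other's.
The central percentile interval of the split R^2 distribution bounds the
explainable variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Response label -> error code.  "closer" = extension (+1) because an
#: extended memory makes the identical re-presentation look zoomed-in.
#: Isolated here so the convention can be flipped by configuration.
RESPONSE_CODING: dict[str, int] = {"closer": +1, "farther": -1}


class UnknownResponseError(ValueError):
    """Raised for a response label outside the coding convention."""


class InsufficientDataError(ValueError):
    """Raised when a table is too small for the requested estimate."""


@dataclass(frozen=True)
class BoundaryScore:
    """Per-image summary of forced-error responses."""

    image_id: str
    score: float
    n_extension: int
    n_contraction: int

    @property
    def n_total(self) -> int:
        return self.n_extension + self.n_contraction


@dataclass(frozen=True)
class NoiseCeiling:
    """Central interval of split-half R^2 values."""

    lower: float
    upper: float
    n_iterations: int
    interval_mass: float
    seed: int
    r_squared: np.ndarray  # all iteration R^2 values


def code_response(response: str, coding: dict[str, int] | None = None) -> int:
    """Map a forced-choice label to +1 (extension) or -1 (contraction)."""
    table = RESPONSE_CODING if coding is None else coding
    try:
        return table[response]
    except KeyError:
        raise UnknownResponseError(
            f"unknown response label {response!r}; expected one of {sorted(table)}"
        ) from None


def score_image(
    responses: pd.DataFrame | list,
    image_id: str | None = None,
    coding: dict[str, int] | None = None,
) -> BoundaryScore:
    """Boundary-transformation score for a single image's responses.

    ``responses`` may be a DataFrame with a ``response`` column or a plain
    list of labels.
    """
    if isinstance(responses, pd.DataFrame):
        labels = responses["response"].tolist()
        if image_id is None and "image_id" in responses:
            ids = responses["image_id"].unique()
            if len(ids) != 1:
                raise ValueError("responses span multiple images")
            image_id = str(ids[0])
    else:
        labels = list(responses)
    if not labels:
        raise InsufficientDataError("no responses for image")
    codes = np.array([code_response(r, coding) for r in labels])
    n_ext = int((codes == 1).sum())
    n_con = int((codes == -1).sum())
    return BoundaryScore(
        image_id=image_id or "",
        score=float(codes.mean()),
        n_extension=n_ext,
        n_contraction=n_con,
    )


def score_table(
    responses: pd.DataFrame, coding: dict[str, int] | None = None
) -> pd.DataFrame:
    """Per-image boundary scores for a full trial-response table.

    ``responses`` needs columns ``participant_id``, ``image_id``,
    ``response``; returns columns ``image_id``, ``score``,
    ``n_extension``, ``n_contraction``, ``n_total``.
    """
    table = RESPONSE_CODING if coding is None else coding
    unknown = set(responses["response"]) - set(table)
    if unknown:
        raise UnknownResponseError(f"unknown response label(s): {sorted(unknown)}")
    coded = responses["response"].map(table)
    df = responses.assign(_code=coded)
    grouped = df.groupby("image_id", sort=True)["_code"]
    out = grouped.agg(
        score="mean",
        n_extension=lambda s: int((s == 1).sum()),
        n_contraction=lambda s: int((s == -1).sum()),
        n_total="size",
    ).reset_index()
    return out


def _response_matrix(
    responses: pd.DataFrame, coding: dict[str, int]
) -> tuple[np.ndarray, list[str]]:
    """Pivot to a participant x image matrix of coded responses (NaN = missing)."""
    coded = responses.assign(_code=responses["response"].map(coding))
    pivot = coded.pivot_table(
        index="participant_id", columns="image_id", values="_code", aggfunc="mean"
    )
    return pivot.to_numpy(dtype=float), list(pivot.columns)


def _split_r_squared(a: np.ndarray, b: np.ndarray) -> float:
    """R^2 of the simple regression of ``a`` on ``b``.

    Computed from regression residuals and cross-checked against the
    identity R^2 = corr(a, b)^2, which holds exactly for one predictor.
    """
    vb = b.var()
    if vb == 0 or a.var() == 0:
        return float("nan")
    slope = np.cov(a, b, ddof=0)[0, 1] / vb
    intercept = a.mean() - slope * b.mean()
    resid = a - (intercept + slope * b)
    r2 = 1.0 - resid.var() / a.var()
    r2_corr = float(np.corrcoef(a, b)[0, 1] ** 2)
    assert abs(r2 - r2_corr) < 1e-8, "single-predictor R^2 identity violated"
    return float(r2)


def noise_ceiling(
    responses: pd.DataFrame,
    n_iterations: int = 10_000,
    interval: float = 0.95,
    seed: int = 0,
    coding: dict[str, int] | None = None,
) -> NoiseCeiling:
    """Split-half noise ceiling of per-image boundary scores.

    In each iteration participants are randomly bipartitioned (sizes
    floor(n/2) and ceil(n/2)), per-image scores are computed within each
    half, and the R^2 of predicting one half from the other is recorded.
    Images with no responses in either half are dropped from that
    iteration.  Returns the central ``interval`` percentile interval of
    the R^2 distribution (linear interpolation between order statistics).
    """
    table = RESPONSE_CODING if coding is None else coding
    mat, image_ids = _response_matrix(responses, table)
    n_part, n_img = mat.shape
    if n_part < 4 or n_img < 3:
        raise InsufficientDataError(
            f"need >= 4 participants and >= 3 images, got {n_part} x {n_img}"
        )
    rng = np.random.default_rng(seed)
    half = n_part // 2
    has_nan = np.isnan(mat).any()

    r2s = np.empty(n_iterations)
    for i in range(n_iterations):
        perm = rng.permutation(n_part)
        ga, gb = mat[perm[:half]], mat[perm[half:]]
        if has_nan:
            with np.errstate(invalid="ignore"):
                a, b = np.nanmean(ga, axis=0), np.nanmean(gb, axis=0)
            keep = ~(np.isnan(a) | np.isnan(b))
            a, b = a[keep], b[keep]
        else:
            a, b = ga.mean(axis=0), gb.mean(axis=0)
        r2s[i] = _split_r_squared(a, b)

    alpha = (1.0 - interval) / 2.0
    lo, hi = np.nanpercentile(r2s, [100 * alpha, 100 * (1 - alpha)])
    return NoiseCeiling(
        lower=float(lo),
        upper=float(hi),
        n_iterations=n_iterations,
        interval_mass=interval,
        seed=seed,
        r_squared=r2s,
    )
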