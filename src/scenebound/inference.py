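"""Regression models and variance partitioning for boundary scores.

The analytic core: ordinary least squares of per-image boundary
transformation scores on scene depth and the unified semantic/visual
information scores, plus a commonality (variance-partitioning) analysis.
For three predictor sets d, s, v, seven models are fitted — the full
model, the three pairs, and the three singles — and inclusion-exclusion
on their R^2 values decomposes the full model's R^2 into unique and
shared components:

    unique(d)      = R2(dsv) - R2(sv)
    shared(d,s)    = R2(dv) + R2(sv) - R2(v) - R2(dsv)
    shared(d,s,v)  = R2(d)+R2(s)+R2(v) - R2(ds)-R2(dv)-R2(sv) + R2(dsv)

Components can be slightly negative (suppression) and are reported
unclipped; their sum always equals the full-model R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


class RankDeficiencyError(ValueError):
    """Raised when the design matrix is not full column rank."""


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary with the usual frequentist statistics."""

    predictor_names: tuple[str, ...]  # includes "intercept" first
    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_residual: int
    n_obs: int

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.predictor_names.index(name)])

    def std_error(self, name: str) -> float:
        return float(self.std_errors[self.predictor_names.index(name)])

    def to_dict(self) -> dict:
        return {
            "predictor_names": list(self.predictor_names),
            "coefficients": self.coefficients.tolist(),
            "std_errors": self.std_errors.tolist(),
            "t_values": self.t_values.tolist(),
            "p_values": self.p_values.tolist(),
            "r_squared": self.r_squared,
            "adjusted_r_squared": self.adjusted_r_squared,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "df_model": self.df_model,
            "df_residual": self.df_residual,
            "n_obs": self.n_obs,
        }


@dataclass(frozen=True)
class PartitionResult:
    """Unique/shared explained-variance decomposition over three predictors."""

    unique_depth: float
    unique_semantic: float
    unique_visual: float
    shared_depth_semantic: float
    shared_depth_visual: float
    shared_semantic_visual: float
    shared_all: float
    total_r_squared: float
    model_r_squared: dict = field(default_factory=dict)  # the 7 fitted models

    def components(self) -> dict[str, float]:
        return {
            "unique_depth": self.unique_depth,
            "unique_semantic": self.unique_semantic,
            "unique_visual": self.unique_visual,
            "shared_depth_semantic": self.shared_depth_semantic,
            "shared_depth_visual": self.shared_depth_visual,
            "shared_semantic_visual": self.shared_semantic_visual,
            "shared_all": self.shared_all,
        }

    def to_dict(self) -> dict:
        d = self.components()
        d["total_r_squared"] = self.total_r_squared
        d["model_r_squared"] = dict(self.model_r_squared)
        return d


def fit_ols(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame,
    predictor_names: Sequence[str] | None = None,
) -> RegressionResult:
    """Ordinary least squares with an intercept.

    Predictors are used as supplied (no internal re-standardization), so
    coefficients are interpretable on input scales.
    """
    yv = np.asarray(y, dtype=float).ravel()
    if isinstance(X, pd.DataFrame):
        names = predictor_names or list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = list(predictor_names) if predictor_names else [
            f"x{i}" for i in range(Xv.shape[1])
        ]
    n, p = Xv.shape
    if n <= p + 1:
        raise RankDeficiencyError(f"need n > p + 1; got n={n}, p={p}")
    design = sm.add_constant(Xv, has_constant="raise")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient")
    fit = sm.OLS(yv, design).fit()
    return RegressionResult(
        predictor_names=("intercept", *names),
        coefficients=np.asarray(fit.params, dtype=float),
        std_errors=np.asarray(fit.bse, dtype=float),
        t_values=np.asarray(fit.tvalues, dtype=float),
        p_values=np.asarray(fit.pvalues, dtype=float),
        r_squared=float(fit.rsquared),
        adjusted_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_residual=int(fit.df_resid),
        n_obs=n,
    )


def variance_partition(
    y: np.ndarray | pd.Series,
    depth: np.ndarray | pd.Series,
    semantic: np.ndarray | pd.Series,
    visual: np.ndarray | pd.Series,
    atol: float = 1e-9,
) -> PartitionResult:
    """Commonality analysis over depth, semantic and visual predictors.

    Fits exactly seven models and decomposes the full-model R^2 by
    inclusion-exclusion; the identity ``sum(components) == R2(full)`` is
    enforced within ``atol``.
    """
    cols = {
        "d": np.asarray(depth, dtype=float).ravel(),
        "s": np.asarray(semantic, dtype=float).ravel(),
        "v": np.asarray(visual, dtype=float).ravel(),
    }
    subsets = ["dsv", "ds", "dv", "sv", "d", "s", "v"]
    r2: dict[str, float] = {}
    for sub in subsets:
        X = np.column_stack([cols[c] for c in sub])
        r2[sub] = fit_ols(y, X, predictor_names=list(sub)).r_squared

    # Nesting monotonicity: adding a predictor never decreases R^2.
    for sub in subsets[1:]:
        supersets = [s2 for s2 in subsets if set(sub) < set(s2)]
        for s2 in supersets:
            assert r2[s2] >= r2[sub] - 1e-12, "R^2 nesting violated"

    u_d = r2["dsv"] - r2["sv"]
    u_s = r2["dsv"] - r2["dv"]
    u_v = r2["dsv"] - r2["ds"]
    c_ds = r2["dv"] + r2["sv"] - r2["v"] - r2["dsv"]
    c_dv = r2["ds"] + r2["sv"] - r2["s"] - r2["dsv"]
    c_sv = r2["ds"] + r2["dv"] - r2["d"] - r2["dsv"]
    c_dsv = (
        r2["d"] + r2["s"] + r2["v"]
        - r2["ds"] - r2["dv"] - r2["sv"]
        + r2["dsv"]
    )
    total = u_d + u_s + u_v + c_ds + c_dv + c_sv + c_dsv
    if abs(total - r2["dsv"]) > atol:
        raise AssertionError(
            f"partition identity violated: {total} != {r2['dsv']}"
        )
    return PartitionResult(
        unique_depth=u_d,
        unique_semantic=u_s,
        unique_visual=u_v,
        shared_depth_semantic=c_ds,
        shared_depth_visual=c_dv,
        shared_semantic_visual=c_sv,
        shared_all=c_dsv,
        total_r_squared=r2["dsv"],
        model_r_squared={
            "depth+semantic+visual": r2["dsv"],
            "depth+semantic": r2["ds"],
            "depth+visual": r2["dv"],
            "semantic+visual": r2["sv"],
            "depth": r2["d"],
            "semantic": r2["s"],
            "visual": r2["v"],
        },
    )


def per_feature_regressions(
    y: np.ndarray | pd.Series,
    features: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
) -> list[RegressionResult]:
    """One simple regression of ``y`` per feature column."""
    names = list(feature_names) if feature_names else [
        c for c in features.columns if c != "image_id"
    ]
    return [
        fit_ols(y, features[name].to_numpy(dtype=float), predictor_names=[name])
        for name in names
    ]


def correlate_features(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame | None = None,
    on: str = "image_id",
) -> pd.DataFrame:
    """Pearson correlation matrix between two per-image metric tables.

    Rows are the metrics of ``table_a``, columns those of ``table_b``
    (or ``table_a`` itself).  Tables are aligned on ``on``.
    """
    if table_b is None:
        table_b = table_a
    merged = table_a.merge(table_b, on=on, suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("need >= 3 matched rows for correlation")
    a_cols = [c for c in table_a.columns if c != on]
    b_cols = [c for c in table_b.columns if c != on]

    def col(df_cols: list[str], name: str, suffix: str) -> np.ndarray:
        key = name if name in merged.columns else name + suffix
        return merged[key].to_numpy(dtype=float)

    out = pd.DataFrame(index=a_cols, columns=b_cols, dtype=float)
    for ca in a_cols:
        x = col(a_cols, ca, "_a")
        for cb in b_cols:
            yv = col(b_cols, cb, "_b")
            out.loc[ca, cb] = float(np.corrcoef(x, yv)[0, 1])
    return out


def plot_partition(result: PartitionResult, path=None):
    """Bar chart of the variance-partition components (display only:
    negative suppression components are clipped at 0 in the figure).

    Requires matplotlib; returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = result.components()
    names = list(comps)
    vals = [max(0.0, v) for v in comps.values()]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(range(len(names)), vals, color="steelblue")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels([n.replace("_", "\n") for n in names], fontsize=7)
    ax.set_ylabel("explained variance (R$^2$)")
    ax.set_title(f"Variance partition (total R$^2$ = {result.total_r_squared:.3f})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def regression_report(results: Mapping[str, RegressionResult]) -> str:
    """Human-readable table of several regression fits."""
    lines = []
    for name, res in results.items():
        lines.append(f"== {name} ==")
        lines.append(
            f"  R^2 = {res.r_squared:.4f}  adj R^2 = {res.adjusted_r_squared:.4f}  "
            f"F({res.df_model}, {res.df_residual}) = {res.f_statistic:.2f}  "
            f"p = {res.f_pvalue:.3g}"
        )
        for i, pname in enumerate(res.predictor_names):
            lines.append(
                f"  {pname:>12s}  b = {res.coefficients[i]:+.4f}  "
                f"t = {res.t_values[i]:+.2f}  p = {res.p_values[i]:.3g}"
            )
    return "\n".join(lines)
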