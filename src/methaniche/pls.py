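"""Per-cluster partial least squares with VIP-based variable selection.

Each co-abundance cluster is scored for its association with methane yield
in two passes:

1. a selection PLS on the cluster's features plus diet/breed dummy
   predictors (the study design's fixed effects), ranking features by their
   variable importance for projection (VIP) on one latent component and
   keeping at most ``max_vars`` features with VIP above a threshold;
2. a final PLS on the selected features alone, whose in-sample variance
   explained (x100) is the cluster's reported "% of CH4 variability
   explained", with signed regression coefficients per variable.

The PLS fit is NIPALS PLS1. For one latent component VIP_j reduces to
sqrt(p) * |w_j| with a unit-norm weight vector, so sum VIP^2 = p always.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AbundanceTable, SampleMetadata

__all__ = [
    "PlsModel",
    "ClusterPlsReport",
    "fit_pls1",
    "vip",
    "select_cluster_variables",
    "final_cluster_pls",
    "run_all_clusters",
]


@dataclass
class PlsModel:
    """A fitted NIPALS PLS1 model (X-side deflation, single response)."""

    predictor_ids: list[str]
    n_components: int
    scale: bool
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    weights: np.ndarray  # p x A, each column unit norm
    scores: np.ndarray  # n x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    coefficients: np.ndarray  # p, on the original predictor scale
    intercept: float
    fitted: np.ndarray
    variance_explained: float
    ssy_per_component: np.ndarray = field(repr=False, default=None)

    def predict(self, x: np.ndarray | pd.DataFrame) -> np.ndarray:
        x = np.asarray(x, float)
        return self.intercept + x @ self.coefficients

    @property
    def vip(self) -> pd.Series:
        return pd.Series(vip(self), index=self.predictor_ids)


def fit_pls1(
    x: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    n_components: int = 1,
    scale: bool = True,
) -> PlsModel:
    """NIPALS PLS1: project predictors on components maximizing covariance with y.

    Predictors (and y) are centered, and autoscaled to unit variance when
    ``scale``. Per component: w = X'y / ||X'y||, t = Xw, p = X't/t't,
    q = y't/t't, then X and y are deflated. Coefficients are returned on the
    original predictor scale; ``variance_explained`` is the in-sample R^2 of
    the fitted values.
    """
    ids = list(x.columns) if isinstance(x, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(x).shape[1])
    ]
    x = np.asarray(x, float)
    yv = np.asarray(y, float).ravel()
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if len(yv) != n:
        raise ValueError("y length does not match X rows")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")

    x_mean = x.mean(axis=0)
    x_sd = x.std(axis=0, ddof=1)
    if (x_sd == 0).any():
        bad = ids[int(np.argmax(x_sd == 0))]
        raise ValueError(f"constant predictor {bad!r}")
    y_mean = float(yv.mean())
    y_sd = float(yv.std(ddof=1))
    if y_sd == 0:
        raise ValueError("response has zero variance")

    x_scale = x_sd if scale else np.ones(p)
    y_scale = y_sd if scale else 1.0
    xc = (x - x_mean) / x_scale
    yc = (yv - y_mean) / y_scale

    w_list, t_list, p_list, q_list, ssy = [], [], [], [], []
    xd, yd = xc.copy(), yc.copy()
    for _ in range(n_components):
        cov = xd.T @ yd
        norm = np.linalg.norm(cov)
        if norm == 0:
            break
        w = cov / norm
        t = xd @ w
        tt = float(t @ t)
        p_a = xd.T @ t / tt
        q_a = float(yd @ t / tt)
        w_list.append(w)
        t_list.append(t)
        p_list.append(p_a)
        q_list.append(q_a)
        ssy.append(q_a**2 * tt)
        xd = xd - np.outer(t, p_a)
        yd = yd - q_a * t

    weights = np.column_stack(w_list)
    scores = np.column_stack(t_list)
    x_load = np.column_stack(p_list)
    y_load = np.array(q_list)

    # b = W (P'W)^-1 q on the scaled space, mapped back to original units
    b_scaled = weights @ np.linalg.solve(x_load.T @ weights, y_load)
    coefficients = b_scaled * y_scale / x_scale
    intercept = y_mean - float(x_mean @ coefficients)
    fitted = intercept + x @ coefficients
    ss_res = float(((yv - fitted) ** 2).sum())
    ss_tot = float(((yv - y_mean) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot

    return PlsModel(
        predictor_ids=ids,
        n_components=weights.shape[1],
        scale=scale,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        weights=weights,
        scores=scores,
        x_loadings=x_load,
        y_loadings=y_load,
        coefficients=coefficients,
        intercept=intercept,
        fitted=fitted,
        variance_explained=float(np.clip(r2, 0.0, 1.0)),
        ssy_per_component=np.array(ssy),
    )


def vip(model: PlsModel) -> np.ndarray:
    """Variable importance for projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a ), where
    SSY_a is the response variance captured by component a. Satisfies
    sum_j VIP_j^2 = p.
    """
    p = len(model.predictor_ids)
    w = model.weights / np.linalg.norm(model.weights, axis=0, keepdims=True)
    ssy = model.ssy_per_component
    return np.sqrt(p * (w**2 @ ssy) / ssy.sum())


@dataclass
class ClusterPlsReport:
    """One cluster's PLS scorecard: selected variables and % CH4 explained."""

    cluster: int
    selected: pd.DataFrame  # columns: feature_id, vip, coefficient
    variance_explained_percent: float
    direction: str | None  # "positive" | "negative" | None when empty
    informative: bool = True

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ClusterPlsReport(cluster={self.cluster}, "
            f"n_selected={len(self.selected)}, "
            f"explained={self.variance_explained_percent:.1f}%, "
            f"direction={self.direction})"
        )


def _design(
    cluster_table: AbundanceTable, metadata: SampleMetadata
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    meta = metadata.aligned_to(cluster_table.sample_ids)
    x = cluster_table.values.T.copy()  # samples x features
    dummies = ["diet_FOR", "breed_AA"]
    x["diet_FOR"] = (meta["diet"] == "FOR").to_numpy(float)
    x["breed_AA"] = (meta["breed"] == "AA").to_numpy(float)
    y = pd.Series(meta["ch4"].to_numpy(), index=x.index)
    return x, y, dummies


def select_cluster_variables(
    cluster_table: AbundanceTable,
    metadata: SampleMetadata,
    vip_threshold: float = 0.8,
    max_vars: int = 5,
    scale: bool = True,
    residualize_fixed_effects: bool = False,
) -> pd.DataFrame:
    """Rank one cluster's features by VIP against methane yield.

    Fits a one-component PLS of CH4 on the cluster's features together with
    diet and breed dummy predictors (excluded from the ranking), keeps
    features with VIP strictly above ``vip_threshold`` and truncates to the
    ``max_vars`` best. Ties are broken by larger |coefficient|, then id.
    With ``residualize_fixed_effects`` the dummies are regressed out of y
    first instead of entering the predictor block.
    """
    if cluster_table.n_features == 0:
        raise ValueError("empty cluster")
    if residualize_fixed_effects:
        x, y, _ = _design(cluster_table, metadata)
        d = np.column_stack([np.ones(len(y)), x["diet_FOR"], x["breed_AA"]])
        beta, *_ = np.linalg.lstsq(d, y.to_numpy(), rcond=None)
        y = pd.Series(y.to_numpy() - d @ beta + y.mean(), index=y.index)
        x = x.drop(columns=["diet_FOR", "breed_AA"])
        dummies: list[str] = []
    else:
        x, y, dummies = _design(cluster_table, metadata)
    model = fit_pls1(x, y, n_components=1, scale=scale)
    scores = pd.DataFrame(
        {
            "feature_id": model.predictor_ids,
            "vip": vip(model),
            "coefficient": model.coefficients,
        }
    )
    scores = scores[~scores["feature_id"].isin(dummies)]
    scores = scores[scores["vip"] > vip_threshold]
    scores = (
        scores.assign(_abs=scores["coefficient"].abs())
        .sort_values(by=["vip", "_abs", "feature_id"], ascending=[False, False, True])
        .drop(columns="_abs")
    )
    return scores.head(max_vars).reset_index(drop=True)


def final_cluster_pls(
    selected_table: AbundanceTable,
    y: pd.Series | np.ndarray,
    cluster: int = 0,
    scale: bool = True,
) -> ClusterPlsReport:
    """Refit the selected variables alone (no fixed effects) and report.

    The report carries the percentage of CH4 variance explained and the
    consensus direction (sign of the majority of coefficients, ties decided
    by their sum).
    """
    if selected_table.n_features == 0:
        return ClusterPlsReport(
            cluster=cluster,
            selected=pd.DataFrame(columns=["feature_id", "vip", "coefficient"]),
            variance_explained_percent=0.0,
            direction=None,
            informative=False,
        )
    x = selected_table.values.T
    model = fit_pls1(x, np.asarray(y, float), n_components=1, scale=scale)
    coefs = model.coefficients
    n_pos, n_neg = int((coefs > 0).sum()), int((coefs < 0).sum())
    if n_pos != n_neg:
        direction = "positive" if n_pos > n_neg else "negative"
    else:
        direction = "positive" if coefs.sum() >= 0 else "negative"
    selected = pd.DataFrame(
        {
            "feature_id": model.predictor_ids,
            "vip": vip(model),
            "coefficient": coefs,
        }
    )
    return ClusterPlsReport(
        cluster=cluster,
        selected=selected,
        variance_explained_percent=100.0 * model.variance_explained,
        direction=direction,
    )


def run_all_clusters(
    assignment,
    merged_table: AbundanceTable,
    metadata: SampleMetadata,
    vip_threshold: float = 0.8,
    max_vars: int = 5,
    scale: bool = True,
    residualize_fixed_effects: bool = False,
) -> list[ClusterPlsReport]:
    """Select + score every cluster; sorted by variance explained, descending.

    For each cluster the selection VIPs are retained in the report (the
    selection-model VIP is what the threshold acted on) while coefficients
    come from the final fixed-effect-free fit.
    """
    meta = metadata.aligned_to(merged_table.sample_ids)
    y = pd.Series(meta["ch4"].to_numpy(), index=merged_table.sample_ids)
    reports = []
    for c in range(1, assignment.n_clusters + 1):
        members = [m for m in assignment.members(c) if m in merged_table.values.index]
        if not members:
            continue
        cluster_table = merged_table.subset_features(members)
        sel = select_cluster_variables(
            cluster_table,
            metadata,
            vip_threshold=vip_threshold,
            max_vars=max_vars,
            scale=scale,
            residualize_fixed_effects=residualize_fixed_effects,
        )
        if len(sel) == 0:
            reports.append(final_cluster_pls(merged_table.subset_features([]), y, c, scale))
            continue
        report = final_cluster_pls(
            merged_table.subset_features(list(sel["feature_id"])), y, c, scale
        )
        # keep the selection VIPs (thresholded quantity) alongside final coefs
        vip_map = dict(zip(sel["feature_id"], sel["vip"]))
        report.selected["selection_vip"] = report.selected["feature_id"].map(vip_map)
        reports.append(report)
    reports.sort(key=lambda r: -r.variance_explained_percent)
    return reports
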