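"""Empirical-Bayes multi-site harmonization (ComBat) and its PCA diagnostic.

Removes per-center location/scale batch effects from a subjects x features
table while preserving the effects of biological covariates (age, sex,
diagnosis). Parametric ComBat:

1. least-squares fit of grand mean (weighted by batch proportions), batch
   offsets and covariate effects;
2. pooled residual variance per feature;
3. standardization of the data;
4. per-batch, per-feature sample location/scale of the standardized data;
5. moment-matched parametric priors — normal for locations, inverse-gamma
   for scales;
6. iteration of the conditional posterior means to convergence.

``mean_only`` mode adjusts locations but leaves per-batch scales untouched.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "CombatModel",
    "PCADiagnostic",
    "fit_combat",
    "apply_combat",
    "pca_diagnostic",
]


@dataclass
class CombatModel:
    """Fitted standardization, covariate fit, and per-batch EB adjustments."""

    feature_names: list[str]
    batch_levels: list[str]
    covariate_names: list[str]
    grand_mean: np.ndarray            # (n_features,)
    covariate_coefficients: np.ndarray  # (n_covariates, n_features)
    pooled_sd: np.ndarray             # (n_features,)
    gamma_star: np.ndarray            # (n_batches, n_features) EB locations
    delta_star: np.ndarray            # (n_batches, n_features) EB scales (variances)
    gamma_bar: np.ndarray             # (n_batches,) location prior mean
    tau2: np.ndarray                  # (n_batches,) location prior variance
    a_prior: np.ndarray               # (n_batches,) inverse-gamma shape
    b_prior: np.ndarray               # (n_batches,) inverse-gamma scale
    mode: str = "full"
    n_iterations: list[int] = field(default_factory=list)
    final_change: list[float] = field(default_factory=list)
    identity: bool = False            # single-batch degenerate model

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            d[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CombatModel":
        arrays = {
            "grand_mean", "covariate_coefficients", "pooled_sd",
            "gamma_star", "delta_star", "gamma_bar", "tau2",
            "a_prior", "b_prior",
        }
        kwargs = {k: (np.asarray(v, dtype=float) if k in arrays else v) for k, v in d.items()}
        if kwargs["covariate_coefficients"].size == 0:
            kwargs["covariate_coefficients"] = np.zeros((0, len(kwargs["grand_mean"])))
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "CombatModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_frame(features, name="features") -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    arr = np.asarray(features, dtype=float)
    return pd.DataFrame(arr, columns=[f"{name}_{i}" for i in range(arr.shape[1])])


def _covariate_matrix(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), [str(c) for c in covariates.columns]
    arr = np.atleast_2d(np.asarray(covariates, dtype=float))
    if arr.shape[0] != n:
        arr = arr.T
    return arr, [f"cov_{i}" for i in range(arr.shape[1])]


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    if s2 <= 0:
        return 2.0  # flat-ish prior when the scales do not vary across features
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    if s2 <= 0:
        return m
    return (m * s2 + m**3) / s2


def fit_combat(
    features,
    batch,
    covariates=None,
    *,
    mode: str = "full",
    tol: float = 1e-4,
    max_iter: int = 100,
) -> CombatModel:
    """Fit the empirical-Bayes location/scale model of per-batch effects.

    Parameters
    ----------
    features : (n_subjects, n_features) table; no missing values.
    batch : length-n center labels.
    covariates : optional (n_subjects, k) biological design columns whose
        effects are preserved (do not include an intercept).
    mode : "full" (location and scale) or "mean_only" (location only).
    tol : convergence threshold on the absolute change of every EB
        location/scale between iterations.
    """
    if mode not in ("full", "mean_only"):
        raise ValueError(f"mode must be 'full' or 'mean_only', got {mode!r}")
    X_df = _as_frame(features)
    X = X_df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain missing values; drop or impute rows first")
    n, p = X.shape
    batch = np.asarray([str(b) for b in batch])
    if batch.shape[0] != n:
        raise ValueError("batch length does not match number of subjects")
    levels = sorted(set(batch))
    cov, cov_names = _covariate_matrix(covariates, n)

    if len(levels) == 1:
        warnings.warn("single batch: returning identity model, no correction estimated")
        return CombatModel(
            feature_names=list(X_df.columns), batch_levels=levels,
            covariate_names=cov_names,
            grand_mean=X.mean(axis=0),
            covariate_coefficients=np.zeros((cov.shape[1], p)),
            pooled_sd=np.ones(p),
            gamma_star=np.zeros((1, p)), delta_star=np.ones((1, p)),
            gamma_bar=np.zeros(1), tau2=np.ones(1),
            a_prior=np.ones(1), b_prior=np.ones(1),
            mode=mode, identity=True,
        )

    counts = np.array([(batch == lv).sum() for lv in levels])
    if np.any(counts < 2):
        small = [lv for lv, c in zip(levels, counts) if c < 2]
        raise ValueError(f"batches with < 2 subjects: {small}")

    onehot = np.column_stack([(batch == lv).astype(float) for lv in levels])
    design = np.column_stack([onehot, cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "design is rank deficient: covariates are collinear with batch "
            f"(rank {rank} < {design.shape[1]})"
        )

    b_hat, *_ = np.linalg.lstsq(design, X, rcond=None)
    batch_props = counts / n
    grand_mean = batch_props @ b_hat[: len(levels)]
    cov_coef = b_hat[len(levels):]

    resid = X - design @ b_hat
    var_pooled = (resid**2).mean(axis=0)
    # relative threshold: an exactly-constant feature leaves ~1e-30 residual
    zero_var = var_pooled <= 1e-12 * ((X**2).mean(axis=0) + 1e-30)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s): location adjusted, "
            "scale left untouched"
        )
        var_pooled = np.where(zero_var, 1.0, var_pooled)
    pooled_sd = np.sqrt(var_pooled)

    stand = grand_mean[None, :] + cov @ cov_coef
    Z = (X - stand) / pooled_sd[None, :]

    n_b = len(levels)
    gamma_hat = np.vstack([Z[batch == lv].mean(axis=0) for lv in levels])
    delta_hat = np.vstack([Z[batch == lv].var(axis=0, ddof=1) for lv in levels])
    flat_scale = delta_hat <= 1e-12
    if flat_scale.any():
        warnings.warn(
            "zero within-batch variance for some (batch, feature) cells: "
            "scale adjustment disabled there"
        )
        delta_hat = np.where(flat_scale, 1.0, delta_hat)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    a_prior = np.array([_aprior(delta_hat[i]) for i in range(n_b)])
    b_prior = np.array([_bprior(delta_hat[i]) for i in range(n_b)])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    n_iters, finals = [], []
    for i, lv in enumerate(levels):
        Zi = Z[batch == lv]
        ni = counts[i]
        g_old = gamma_hat[i].copy()
        d_old = delta_hat[i].copy()
        change = np.inf
        it = 0
        while change > tol and it < max_iter:
            g_new = _postmean(gamma_hat[i], gamma_bar[i], ni, d_old, tau2[i])
            if mode == "mean_only":
                d_new = np.ones_like(d_old)
            else:
                sum2 = ((Zi - g_new[None, :]) ** 2).sum(axis=0)
                d_new = _postvar(sum2, ni, a_prior[i], b_prior[i])
            change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
            g_old, d_old = g_new, d_new
            it += 1
        gamma_star[i], delta_star[i] = g_old, d_old
        n_iters.append(it)
        finals.append(float(change))

    if mode == "mean_only":
        delta_star = np.ones_like(delta_star)
    delta_star = np.where(flat_scale, 1.0, delta_star)
    gamma_star = np.where(zero_var[None, :], 0.0, gamma_star)
    delta_star = np.where(zero_var[None, :], 1.0, delta_star)

    return CombatModel(
        feature_names=list(X_df.columns), batch_levels=levels,
        covariate_names=cov_names,
        grand_mean=grand_mean, covariate_coefficients=cov_coef,
        pooled_sd=pooled_sd,
        gamma_star=gamma_star, delta_star=delta_star,
        gamma_bar=gamma_bar, tau2=tau2, a_prior=a_prior, b_prior=b_prior,
        mode=mode, n_iterations=n_iters, final_change=finals,
    )


def apply_combat(model: CombatModel, features, batch, covariates=None):
    """Adjust a feature table with a fitted model.

    y* = pooled_sd / sqrt(delta_star) * (z - gamma_star) + grand_mean
    + covariate effects. Shape- and index-preserving; raises on a batch
    level unseen at fit time.
    """
    X_df = _as_frame(features)
    X = X_df.to_numpy(dtype=float)
    n = X.shape[0]
    batch = np.asarray([str(b) for b in batch])
    if model.identity:
        return X_df.copy()
    unseen = sorted(set(batch) - set(model.batch_levels))
    if unseen:
        raise ValueError(f"unseen batch level(s): {unseen}")
    cov, _ = _covariate_matrix(covariates, n)
    stand = model.grand_mean[None, :] + cov @ model.covariate_coefficients
    Z = (X - stand) / model.pooled_sd[None, :]
    out = np.empty_like(X)
    for i, lv in enumerate(model.batch_levels):
        m = batch == lv
        if not m.any():
            continue
        out[m] = (Z[m] - model.gamma_star[i]) / np.sqrt(model.delta_star[i])
    out = out * model.pooled_sd[None, :] + stand
    return pd.DataFrame(out, index=X_df.index, columns=X_df.columns)


@dataclass
class PCADiagnostic:
    """Two-component projections before/after harmonization plus summaries.

    ``separation_*`` is the between-center over within-center variance of
    the first principal component — it should shrink after harmonization.
    """

    scores_before: np.ndarray
    scores_after: np.ndarray
    explained_before: np.ndarray
    explained_after: np.ndarray
    separation_before: float
    separation_after: float
    by_center_before: pd.DataFrame
    by_center_after: pd.DataFrame


def _pc_scores(X: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd <= 0, 1.0, sd)
    Z = (X - mu) / sd
    k = min(n_components, np.linalg.matrix_rank(Z), *Z.shape)
    if k < n_components:
        warnings.warn(f"rank-deficient input: returning {k} component(s)")
    pca = PCA(n_components=k, svd_solver="full")
    return pca.fit_transform(Z), pca.explained_variance_ratio_


def _separation(pc1: np.ndarray, batch: np.ndarray) -> float:
    groups = [pc1[batch == lv] for lv in np.unique(batch)]
    grand = pc1.mean()
    between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / len(pc1)
    within = sum(((g - g.mean()) ** 2).sum() for g in groups) / len(pc1)
    return float(between / within) if within > 0 else float("inf")


def pca_diagnostic(features_before, features_after, batch) -> PCADiagnostic:
    """Standardized two-component PCA of the table before and after harmonization."""
    before = _as_frame(features_before)
    after = _as_frame(features_after)
    if before.shape[0] < 3 or before.shape[1] < 1:
        raise ValueError("need at least 3 subjects and 1 feature")
    batch = np.asarray([str(b) for b in batch])
    sb, eb = _pc_scores(before.to_numpy(dtype=float), 2)
    sa, ea = _pc_scores(after.to_numpy(dtype=float), 2)

    def _summary(df: pd.DataFrame) -> pd.DataFrame:
        g = df.groupby(pd.Series(batch, index=df.index, name="center"))
        return g.agg(["mean", "std"])

    return PCADiagnostic(
        scores_before=sb, scores_after=sa,
        explained_before=eb, explained_after=ea,
        separation_before=_separation(sb[:, 0], batch),
        separation_after=_separation(sa[:, 0], batch),
        by_center_before=_summary(before),
        by_center_after=_summary(after),
    )
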