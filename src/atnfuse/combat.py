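"""Parametric empirical-Bayes location-scale batch harmonization (ComBat).

Removes scanner/batch effects from a subjects-by-features matrix (here,
component loadings) using the standard location-scale model: per-feature
grand mean and optional covariate effects, per-batch additive shifts gamma
and multiplicative scales delta, with empirical-Bayes shrinkage of the batch
parameters toward pooled priors (normal prior for locations, inverse-gamma
for scales; method-of-moments hyperpriors, iterated conditional updates).

Model/Results convention: ``ComBat(features, batch).fit()`` returns a
:class:`ComBatResults` whose :meth:`~ComBatResults.transform` harmonizes the
fitted or new data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


class ComBat:
    """Location-scale empirical-Bayes harmonization model.

    Parameters
    ----------
    features : (N, K) array of values to harmonize.
    batch : length-N batch labels (>= 2 levels, each with >= 2 subjects).
    covariates : optional (N, C) design of biological covariates whose
        effects are preserved by the adjustment.
    tau_sq_scale : multiplier on the location-prior variance; values below 1
        strengthen shrinkage of the batch locations toward their prior mean.
    """

    def __init__(self, features: np.ndarray, batch: np.ndarray,
                 covariates: np.ndarray | None = None, tau_sq_scale: float = 1.0):
        self.X = np.asarray(features, dtype=float)
        self.batch = np.asarray(batch)
        self.covariates = None if covariates is None else np.atleast_2d(
            np.asarray(covariates, dtype=float))
        if self.covariates is not None and self.covariates.shape[0] != self.X.shape[0]:
            self.covariates = self.covariates.T
        self.tau_sq_scale = float(tau_sq_scale)
        self.levels, self.batch_idx = np.unique(self.batch, return_inverse=True)
        if len(self.levels) < 2:
            raise ValueError("harmonization needs at least 2 batch levels")
        counts = np.bincount(self.batch_idx)
        if counts.min() < 2:
            small = self.levels[counts < 2]
            raise ValueError(f"singleton batch level(s): {list(small)}")

    def fit(self, max_iter: int = 200, tol: float = 1e-6) -> "ComBatResults":
        X = self.X
        n, k = X.shape
        nb = len(self.levels)
        counts = np.bincount(self.batch_idx).astype(float)
        # design: batch indicators plus covariates; per-feature OLS
        D = np.zeros((n, nb))
        D[np.arange(n), self.batch_idx] = 1.0
        if self.covariates is not None:
            D = np.hstack([D, self.covariates])
            if np.linalg.matrix_rank(D) < D.shape[1]:
                raise ValueError("rank-deficient covariate design")
        B, *_ = np.linalg.lstsq(D, X, rcond=None)
        batch_eff = B[:nb]                       # (nb, k)
        cov_coef = B[nb:]                        # (C, k)
        alpha = (counts / n) @ batch_eff         # grand per-feature intercept
        cov_part = (self.covariates @ cov_coef) if self.covariates is not None else 0.0
        stand_mean = alpha[None, :] + cov_part
        resid = X - D @ B
        pooled_var = (resid ** 2).sum(axis=0) / n
        pooled_sd = np.sqrt(np.maximum(pooled_var, 1e-12))
        Zs = (X - stand_mean) / pooled_sd

        # per-batch location/scale estimates on standardized data
        g_hat = np.vstack([Zs[self.batch_idx == b].mean(axis=0) for b in range(nb)])
        d_hat = np.vstack([Zs[self.batch_idx == b].var(axis=0, ddof=1) for b in range(nb)])
        d_hat = np.maximum(d_hat, 1e-12)

        # method-of-moments hyperpriors
        g_bar = g_hat.mean(axis=1)                       # (nb,)
        tau_sq = g_hat.var(axis=1, ddof=1) * self.tau_sq_scale
        tau_sq = np.maximum(tau_sq, 1e-12)
        d_bar = d_hat.mean(axis=1)
        d_var = d_hat.var(axis=1, ddof=1)
        lam = np.where(d_var > 1e-12, (2 * d_var + d_bar ** 2) / np.maximum(d_var, 1e-12), 1e6)
        theta = np.where(d_var > 1e-12, (d_bar * d_var + d_bar ** 3) / np.maximum(d_var, 1e-12),
                         d_bar * 1e6)

        # iterated conditional posterior updates of gamma*, delta*^2
        g_star = g_hat.copy()
        d_star = d_hat.copy()
        for b in range(nb):
            nb_i = counts[b]
            Zb = Zs[self.batch_idx == b]
            g, d = g_hat[b].copy(), d_hat[b].copy()
            for _ in range(max_iter):
                g_new = (tau_sq[b] * nb_i * g_hat[b] + d * g_bar[b]) / (tau_sq[b] * nb_i + d)
                ssq = ((Zb - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (theta[b] + 0.5 * ssq) / (nb_i / 2 + lam[b] - 1)
                d_new = np.maximum(d_new, 1e-12)
                change = max(np.max(np.abs(g_new - g)), np.max(np.abs(d_new - d)))
                g, d = g_new, d_new
                if change < tol:
                    break
            g_star[b], d_star[b] = g, d
        return ComBatResults(model=self, levels=self.levels, alpha=alpha,
                             cov_coef=cov_coef, pooled_sd=pooled_sd,
                             gamma_hat=g_hat, delta_hat=d_hat,
                             gamma_star=g_star, delta_star_sq=d_star,
                             gamma_bar=g_bar, tau_sq=tau_sq, lam=lam, theta=theta)


@dataclass
class ComBatResults:
    """Fitted harmonization parameters.

    gamma_star / delta_star_sq : shrunken per-batch location and squared
    scale on the standardized scale; alpha / cov_coef / pooled_sd restore the
    grand location/scale and covariate structure.
    """

    model: ComBat
    levels: np.ndarray
    alpha: np.ndarray
    cov_coef: np.ndarray
    pooled_sd: np.ndarray
    gamma_hat: np.ndarray
    delta_hat: np.ndarray
    gamma_star: np.ndarray
    delta_star_sq: np.ndarray
    gamma_bar: np.ndarray
    tau_sq: np.ndarray
    lam: np.ndarray
    theta: np.ndarray

    def transform(self, features: np.ndarray | None = None, batch: np.ndarray | None = None,
                  covariates: np.ndarray | None = None) -> np.ndarray:
        """Harmonize data: standardize, remove gamma*/delta*, restore structure."""
        if features is None:
            features, batch = self.model.X, self.model.batch
            covariates = self.model.covariates
        X = np.asarray(features, dtype=float)
        batch = np.asarray(batch)
        lut = {lev: i for i, lev in enumerate(self.levels)}
        try:
            idx = np.array([lut[b] for b in batch])
        except KeyError as exc:
            raise ValueError(f"unseen batch level {exc.args[0]!r}") from None
        cov_part = 0.0
        if self.cov_coef.size:
            if covariates is None:
                raise ValueError("model was fit with covariates; provide them")
            cov_part = np.atleast_2d(np.asarray(covariates, dtype=float)) @ self.cov_coef
        stand_mean = self.alpha[None, :] + cov_part
        Zs = (X - stand_mean) / self.pooled_sd
        adj = (Zs - self.gamma_star[idx]) / np.sqrt(self.delta_star_sq[idx])
        return adj * self.pooled_sd + stand_mean

    def summary(self) -> str:
        lines = ["ComBat harmonization results", "=" * 40,
                 f"batch levels: {', '.join(map(str, self.levels))}",
                 f"features:     {self.alpha.size}",
                 "per-batch mean |gamma*| and mean delta*:"]
        for i, lev in enumerate(self.levels):
            lines.append(f"  {lev}: |gamma*|={np.abs(self.gamma_star[i]).mean():.4f} "
                         f"delta*={np.sqrt(self.delta_star_sq[i]).mean():.4f}")
        return "\n".join(lines)


def fit_combat(features: np.ndarray, batch: np.ndarray,
               covariates: np.ndarray | None = None, **kw) -> ComBatResults:
    """Fit the empirical-Bayes harmonization model (shorthand)."""
    return ComBat(features, batch, covariates=covariates, **kw).fit()


def apply_combat(results: ComBatResults, features: np.ndarray, batch: np.ndarray,
                 covariates: np.ndarray | None = None) -> np.ndarray:
    return results.transform(features, batch, covariates=covariates)


def batch_leakage_auc(features: np.ndarray, batch: np.ndarray, folds: int = 5,
                      seed: int = 0) -> float:
    """Cross-validated AUROC of an L1-logistic classifier predicting batch.

    Near 0.5 means the features carry no batch information.  Multi-level
    batches are binarized as largest level vs rest.
    """
    X = np.asarray(features, dtype=float)
    batch = np.asarray(batch)
    levels, counts = np.unique(batch, return_counts=True)
    y = (batch == levels[np.argmax(counts)]).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("batch is single-class after binarization")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, te in cv.split(X, y):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("single-class training fold; reduce fold count")
        mu, sd = X[tr].mean(0), X[tr].std(0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0,
                                 random_state=seed)
        clf.fit((X[tr] - mu) / sd, y[tr])
        scores[te] = clf.decision_function((X[te] - mu) / sd)
    return float(roc_auc_score(y, scores))
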