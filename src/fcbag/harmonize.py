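"""Empirical-Bayes ComBat site harmonization with preserved covariates.

Removes additive and multiplicative site (batch) effects from
connectivity features while preserving the signal of age, sex and mean
framewise displacement.  The model is fitted once on an independent
healthy-reference pool and then *applied* to held-out clinical data, so
no downstream statistic ever sees data that trained the harmonizer.

Model per feature g, subject j of site i:

    y_ijg = alpha_g + x_j' beta_g + gamma_ig + delta_ig eps_ijg

Location (gamma) and scale (delta^2) parameters are shrunk per site
toward normal / inverse-gamma priors by iterated parametric
empirical-Bayes moment matching, then removed:

    y*_ijg = sigma_g (z_ijg - gamma*_ig) / delta*_ig + alpha_g + x_j' beta_g
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HarmonizationModel",
    "fit_combat",
    "apply_combat",
    "residualize_nuisance",
]


@dataclass
class HarmonizationModel:
    """Fitted ComBat parameters; serializable to JSON."""

    site_table: list[str]
    feature_labels: list[str]
    cov_columns: list[str]
    grand_mean: np.ndarray          # (G,)
    beta_cov: np.ndarray            # (p, G)
    pooled_var: np.ndarray          # (G,)
    gamma_star: np.ndarray          # (S, G)
    delta_star_sq: np.ndarray       # (S, G)
    prior_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.delta_star_sq <= 0):
            raise ValueError("delta_star_sq must be strictly positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "site_table": self.site_table,
            "feature_labels": self.feature_labels,
            "cov_columns": self.cov_columns,
            "grand_mean": self.grand_mean.tolist(),
            "beta_cov": self.beta_cov.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star_sq": self.delta_star_sq.tolist(),
            "prior_params": {k: np.asarray(v).tolist() for k, v in self.prior_params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            site_table=d["site_table"],
            feature_labels=d["feature_labels"],
            cov_columns=d["cov_columns"],
            grand_mean=np.asarray(d["grand_mean"]),
            beta_cov=np.asarray(d["beta_cov"]),
            pooled_var=np.asarray(d["pooled_var"]),
            gamma_star=np.asarray(d["gamma_star"]),
            delta_star_sq=np.asarray(d["delta_star_sq"]),
            prior_params={k: np.asarray(v) for k, v in d["prior_params"].items()},
        )


def _check_features(features: pd.DataFrame) -> None:
    sd = features.to_numpy().std(axis=0)
    bad = [features.columns[i] for i in np.flatnonzero(sd == 0)]
    if bad:
        raise ValueError(f"zero-variance feature(s): {bad[:5]}")


def _aprior(delta_hat_sq: np.ndarray) -> tuple[float, float]:
    m = delta_hat_sq.mean()
    s2 = delta_hat_sq.var(ddof=1)
    lam = (2 * s2 + m**2) / s2
    theta = (m * s2 + m**3) / s2
    return float(lam), float(theta)


def _eb_site(
    z_site: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat_sq: np.ndarray,
    gamma_bar: float,
    tau_sq: float,
    lam: float,
    theta: float,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterated moment-matching EB updates for one site (n x G data)."""
    n = z_site.shape[0]
    gamma_star = gamma_hat.copy()
    delta_star_sq = delta_hat_sq.copy()
    for _ in range(max_iter):
        g_new = (n * tau_sq * gamma_hat + delta_star_sq * gamma_bar) / (
            n * tau_sq + delta_star_sq
        )
        ssq = ((z_site - g_new) ** 2).sum(axis=0)
        d_new = (theta + 0.5 * ssq) / (n / 2.0 + lam - 1.0)
        change = max(
            np.max(np.abs(g_new - gamma_star)), np.max(np.abs(d_new - delta_star_sq))
        )
        gamma_star, delta_star_sq = g_new, d_new
        if change < tol:
            break
    return gamma_star, delta_star_sq


def fit_combat(
    features: pd.DataFrame,
    site: pd.Series,
    covariates: pd.DataFrame,
) -> HarmonizationModel:
    """Fit ComBat on a reference pool, preserving the given covariates.

    Steps: (1) per-feature least squares on [site indicators + covariates]
    for grand/covariate effects and pooled variance, (2) standardization
    of residual data, (3) parametric empirical-Bayes shrinkage of per-site
    location/scale, iterated to convergence.

    A single-site pool is accepted with a warning; the resulting model has
    no batch contrast and applies as the identity.
    """
    y = features.to_numpy(dtype=float)
    site = pd.Series(site).astype(str).reset_index(drop=True)
    cov = covariates.reset_index(drop=True)
    if covariates.isna().any().any():
        raise ValueError("covariates must be complete")
    _check_features(features)

    sites = sorted(site.unique())
    counts = site.value_counts()
    small = [s for s in sites if counts[s] < 2]
    if small:
        raise ValueError(f"site(s) with fewer than 2 subjects: {small}")
    if len(sites) < 2:
        warnings.warn("single site in reference pool: no batch contrast to remove",
                      stacklevel=2)

    n, n_features = y.shape
    batch = np.column_stack([(site == s).to_numpy(float) for s in sites])
    x_cov = cov.to_numpy(dtype=float)
    design = np.hstack([batch, x_cov])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    site_effects = beta[: len(sites)]
    beta_cov = beta[len(sites):]

    weights = batch.sum(axis=0) / n
    grand_mean = weights @ site_effects
    fitted = design @ beta
    pooled_var = ((y - fitted) ** 2).mean(axis=0)
    if np.any(pooled_var <= 0):
        bad = [features.columns[i] for i in np.flatnonzero(pooled_var <= 0)]
        raise ValueError(f"feature(s) with zero residual variance: {bad[:5]}")

    stand_mean = grand_mean[None, :] + x_cov @ beta_cov
    z = (y - stand_mean) / np.sqrt(pooled_var)[None, :]

    gamma_star = np.zeros((len(sites), n_features))
    delta_star_sq = np.ones((len(sites), n_features))
    priors: dict[str, list] = {"gamma_bar": [], "tau_sq": [], "lambda": [], "theta": []}
    if len(sites) >= 2:
        for k, s in enumerate(sites):
            rows = (site == s).to_numpy()
            z_site = z[rows]
            gamma_hat = z_site.mean(axis=0)
            delta_hat_sq = z_site.var(axis=0, ddof=1)
            gamma_bar = float(gamma_hat.mean())
            tau_sq = float(gamma_hat.var(ddof=1))
            lam, theta = _aprior(delta_hat_sq)
            priors["gamma_bar"].append(gamma_bar)
            priors["tau_sq"].append(tau_sq)
            priors["lambda"].append(lam)
            priors["theta"].append(theta)
            gamma_star[k], delta_star_sq[k] = _eb_site(
                z_site, gamma_hat, delta_hat_sq, gamma_bar, tau_sq, lam, theta
            )

    return HarmonizationModel(
        site_table=sites,
        feature_labels=list(features.columns),
        cov_columns=list(covariates.columns),
        grand_mean=grand_mean,
        beta_cov=beta_cov,
        pooled_var=pooled_var,
        gamma_star=gamma_star,
        delta_star_sq=delta_star_sq,
        prior_params=priors,
    )


def apply_combat(
    model: HarmonizationModel,
    features: pd.DataFrame,
    site: pd.Series,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Apply a fitted model to (possibly held-out) data.

    Every site label must be in the model's site table: an unseen site is
    rejected rather than refit, which forces the reference pool to
    contain held-out subjects from every clinical site.
    """
    if list(features.columns) != model.feature_labels:
        raise ValueError("feature labels do not match the fitted model")
    if list(covariates.columns) != model.cov_columns:
        raise ValueError("covariate columns (and order) must match the fit")
    site = pd.Series(site).astype(str).reset_index(drop=True)
    unseen = sorted(set(site.unique()) - set(model.site_table))
    if unseen:
        raise ValueError(f"site(s) unseen by the harmonization model: {unseen}")

    y = features.to_numpy(dtype=float)
    x_cov = covariates.to_numpy(dtype=float)
    stand_mean = model.grand_mean[None, :] + x_cov @ model.beta_cov
    z = (y - stand_mean) / np.sqrt(model.pooled_var)[None, :]
    out = np.empty_like(y)
    for k, s in enumerate(model.site_table):
        rows = (site == s).to_numpy()
        if not rows.any():
            continue
        adj = (z[rows] - model.gamma_star[k]) / np.sqrt(model.delta_star_sq[k])
        out[rows] = adj * np.sqrt(model.pooled_var)[None, :] + stand_mean[rows]
    return pd.DataFrame(out, index=features.index, columns=features.columns)


def residualize_nuisance(features: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-feature OLS residuals on [intercept + covariates] (sex, mean FD).

    Residuals are orthogonal to every design column; a rank-deficient
    design is rejected.
    """
    y = features.to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(features)), covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient nuisance design")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return pd.DataFrame(resid, index=features.index, columns=features.columns)
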