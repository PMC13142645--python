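"""Inference on the brain-age gap: robust GLMs, rank-INT, FDR, Welch.

The BAG is first residualized on sex, mean FD, age and age^2 and z-scored
within the pooled sample; all models then use that z-score.  Group and
clinical-association models are ordinary least squares with HC3
heteroskedasticity-robust standard errors and site fixed effects;
clinical variables are rank-based inverse-normal transformed so that
coefficients read as change in BAG (SD units) per 1 SD of the clinical
measure.  p values are corrected per analysis family with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "SiteContrast",
    "residualize_bag",
    "hc3_inference",
    "group_difference_glm",
    "welch_contrast",
    "per_site_welch",
    "rank_int",
    "clinical_association",
    "associations_table",
    "longitudinal_delta",
    "delta_associations",
    "bh_fdr",
    "posthoc_extreme_groups",
]


@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    beta: float
    se_hc3: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    q_fdr: float = np.nan
    n: int = 0


@dataclass
class SiteContrast:
    site: str
    mean_hc: float
    sd_hc: float
    n_hc: int
    mean_ssd: float
    sd_ssd: float
    n_ssd: int
    welch_t: float
    welch_df: float
    p: float
    cohens_d: float
    hedges_g: float


def residualize_bag(
    bag: np.ndarray,
    sex: np.ndarray,
    mean_fd: np.ndarray,
    age: np.ndarray,
) -> pd.DataFrame:
    """OLS residuals of BAG on [1, sex, FD, age, age^2], z-scored in the
    pooled sample (sample SD, ddof=1)."""
    bag = np.asarray(bag, float)
    x = np.column_stack([
        np.ones_like(bag),
        np.asarray(sex, float),
        np.asarray(mean_fd, float),
        np.asarray(age, float),
        np.asarray(age, float) ** 2,
    ])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(x, bag, rcond=None)
    resid = bag - x @ beta
    sd = resid.std(ddof=1)
    if sd < 1e-10 * max(1.0, float(np.abs(bag).max())):
        raise ValueError("zero-variance residual: BAG is fully explained by covariates")
    return pd.DataFrame({"bag_raw": bag, "bag_resid": resid,
                         "bag_z": (resid - resid.mean()) / sd})


def hc3_inference(y: np.ndarray, x: np.ndarray, names: list[str] | None = None) -> pd.DataFrame:
    """OLS coefficients with HC3 robust covariance.

    cov = (X'X)^-1 X' diag(e_i^2/(1-h_ii)^2) X (X'X)^-1, leverages h_ii
    from the hat matrix; two-sided p from t with n-p df, 95% CI from the
    same t quantile.  A unit leverage (zero-residual point) is rejected.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n, p = x.shape
    if n <= p:
        raise ValueError("need n > p")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    h = np.einsum("ij,jk,ik->i", x, xtx_inv, x)
    if np.any(h >= 1 - 1e-12):
        raise ValueError("leverage of 1 encountered (zero-residual point)")
    omega = (resid / (1.0 - h)) ** 2
    cov = xtx_inv @ (x.T * omega) @ x @ xtx_inv
    se = np.sqrt(np.diag(cov))
    df = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    pval = 2 * sps.t.sf(np.abs(tval), df)
    crit = sps.t.ppf(0.975, df)
    if np.allclose(resid, 0):
        warnings.warn("exact fit: robust SEs are zero, p degenerate", stacklevel=2)
    out = pd.DataFrame({
        "beta": beta, "se_hc3": se,
        "ci_low": beta - crit * se, "ci_high": beta + crit * se,
        "p": pval,
    })
    if names is not None:
        out.index = names
    return out


def _site_dummies(site: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Indicator columns for every site except the alphabetically first."""
    levels = sorted(pd.Series(site).astype(str).unique())
    cols = [(pd.Series(site).astype(str) == s).to_numpy(float) for s in levels[1:]]
    names = [f"site[{s}]" for s in levels[1:]]
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(site), 0)), names


def group_difference_glm(df: pd.DataFrame, outcome: str = "bag_z") -> AssociationResult:
    """Diagnosis effect on the BAG z-score with HC3 robust inference.

    Design: intercept, diagnosis (SSD=1, HC=0), sex, centered age,
    centered age squared, centered mean FD, site fixed effects
    (reference = alphabetically first site).
    """
    for g in (0, 1):
        if (df["diagnosis"] == g).sum() < 2:
            raise ValueError("need >= 2 subjects per diagnosis group")
    site = df["site"].astype(str)
    cross = pd.crosstab(site, df["diagnosis"])
    if (cross == 0).any().any():
        warnings.warn("a site contains a single diagnosis group; site fixed "
                      "effects may absorb part of the group contrast", stacklevel=2)
    age_c = df["age"] - df["age"].mean()
    fd_c = df["mean_fd"] - df["mean_fd"].mean()
    dummies, dummy_names = _site_dummies(site)
    x = np.column_stack([
        np.ones(len(df)), df["diagnosis"].to_numpy(float), df["sex"].to_numpy(float),
        age_c.to_numpy(), (age_c**2).to_numpy(), fd_c.to_numpy(), dummies,
    ])
    names = ["intercept", "diagnosis", "sex", "age_c", "age_c2", "fd_c"] + dummy_names
    res = hc3_inference(df[outcome].to_numpy(float), x, names)
    row = res.loc["diagnosis"]
    return AssociationResult(
        outcome=outcome, predictor="diagnosis",
        beta=float(row["beta"]), se_hc3=float(row["se_hc3"]),
        ci_low=float(row["ci_low"]), ci_high=float(row["ci_high"]),
        p_two_sided=float(row["p"]), n=len(df),
    )


def welch_contrast(x_hc: np.ndarray, x_ssd: np.ndarray, site: str = "") -> SiteContrast:
    """Welch t-test with Satterthwaite df plus Cohen's d / Hedges' g."""
    x_hc = np.asarray(x_hc, float)
    x_ssd = np.asarray(x_ssd, float)
    n1, n2 = len(x_hc), len(x_ssd)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 subjects per group")
    v1, v2 = x_hc.var(ddof=1), x_ssd.var(ddof=1)
    if v1 == 0 or v2 == 0:
        raise ValueError("zero-variance group")
    tt = sps.ttest_ind(x_ssd, x_hc, equal_var=False)
    se2 = v1 / n1 + v2 / n2
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    sd_pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = (x_ssd.mean() - x_hc.mean()) / sd_pooled
    g = d * (1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0))
    return SiteContrast(
        site=site,
        mean_hc=float(x_hc.mean()), sd_hc=float(np.sqrt(v1)), n_hc=n1,
        mean_ssd=float(x_ssd.mean()), sd_ssd=float(np.sqrt(v2)), n_ssd=n2,
        welch_t=float(tt.statistic), welch_df=float(df), p=float(tt.pvalue),
        cohens_d=float(d), hedges_g=float(g),
    )


def per_site_welch(df: pd.DataFrame, value_col: str = "bag_resid") -> pd.DataFrame:
    """Per-site Welch contrasts of SSD vs HC on within-site z-scores.

    ``value_col`` is z-scored inside each site before testing, so group
    separation is expressed on that site's own scale.
    """
    rows = []
    for site_name, grp in df.groupby(df["site"].astype(str)):
        vals = grp[value_col].to_numpy(float)
        z = (vals - vals.mean()) / vals.std(ddof=1)
        hc = z[grp["diagnosis"].to_numpy() == 0]
        ssd = z[grp["diagnosis"].to_numpy() == 1]
        rows.append(welch_contrast(hc, ssd, site=site_name).__dict__)
    return pd.DataFrame(rows)


def rank_int(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, rescaled to unit sample SD.

    Average ranks (ties share a rank), empirical probabilities
    p = rank/(n+1), z = sqrt(2) * erfinv(2p - 1); missing values are
    excluded from ranking and preserved as NaN.
    """
    values = np.asarray(values, float)
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    v = values[mask]
    if v.size < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.all(v == v[0]):
        raise ValueError("all values identical: rank-INT undefined")
    ranks = sps.rankdata(v, method="average")
    p = ranks / (v.size + 1)
    z = np.sqrt(2.0) * special.erfinv(2.0 * p - 1.0)
    out[mask] = z / z.std(ddof=1)
    return out


def clinical_association(
    bag_z: np.ndarray,
    clinical_z: np.ndarray,
    covariates: pd.DataFrame,
    site: pd.Series,
    outcome: str = "bag_z",
    predictor: str = "clinical",
) -> AssociationResult | None:
    """BAG z-score regressed on a rank-INT clinical variable with HC3.

    Design: intercept, clinical z, covariates (as given), site dummies.
    Complete cases only; fewer than 10 leads to a warning and None.
    """
    bag_z = np.asarray(bag_z, float)
    clinical_z = np.asarray(clinical_z, float)
    cov = covariates.to_numpy(float)
    keep = ~np.isnan(clinical_z) & ~np.isnan(bag_z) & ~np.isnan(cov).any(axis=1)
    if keep.sum() < 10:
        warnings.warn(f"{predictor}: fewer than 10 complete cases, skipped", stacklevel=2)
        return None
    site_keep = pd.Series(site).astype(str)[keep].reset_index(drop=True)
    dummies, dummy_names = _site_dummies(site_keep)
    x = np.column_stack([np.ones(keep.sum()), clinical_z[keep], cov[keep], dummies])
    names = ["intercept", predictor] + list(covariates.columns) + dummy_names
    res = hc3_inference(bag_z[keep], x, names)
    row = res.loc[predictor]
    return AssociationResult(
        outcome=outcome, predictor=predictor,
        beta=float(row["beta"]), se_hc3=float(row["se_hc3"]),
        ci_low=float(row["ci_low"]), ci_high=float(row["ci_high"]),
        p_two_sided=float(row["p"]), n=int(keep.sum()),
    )


def associations_table(
    bag_z: np.ndarray,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame,
    site: pd.Series,
    variables: list[str],
) -> pd.DataFrame:
    """One association per clinical variable (rank-INT applied here), with
    BH-FDR q-values over the whole family."""
    rows = []
    for var in variables:
        try:
            z = rank_int(clinical[var].to_numpy(float))
        except ValueError as exc:
            warnings.warn(f"{var}: {exc}", stacklevel=2)
            continue
        res = clinical_association(bag_z, z, covariates, site, predictor=var)
        if res is not None:
            rows.append(res.__dict__)
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q_fdr"] = bh_fdr(table["p_two_sided"].to_numpy())
    return table


def longitudinal_delta(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    variables: list[str],
    bag_col: str = "bag",
    id_col: str = "subject_id",
) -> pd.DataFrame:
    """Per-subject change scores, delta = baseline - follow-up.

    Clinical variables are rank-INT transformed within each visit before
    differencing; only subjects present at both visits are kept.
    Duplicated subject ids within a visit are rejected.
    """
    for frame, name in ((baseline, "baseline"), (followup, "followup")):
        if frame[id_col].duplicated().any():
            raise ValueError(f"duplicated subject ids in {name} visit")
    common = baseline[baseline[id_col].isin(followup[id_col])]
    b = common.set_index(id_col)
    f = followup.set_index(id_col).loc[b.index]
    out = pd.DataFrame(index=b.index)
    out["delta_" + bag_col] = b[bag_col].to_numpy(float) - f[bag_col].to_numpy(float)
    for var in variables:
        zb = rank_int(b[var].to_numpy(float))
        zf = rank_int(f[var].to_numpy(float))
        out["delta_" + var] = zb - zf
    return out.reset_index()


def delta_associations(deltas: pd.DataFrame, variables: list[str],
                       bag_col: str = "bag") -> pd.DataFrame:
    """HC3 regression of the BAG change on each clinical change score, with
    BH-FDR over the longitudinal family."""
    rows = []
    y = deltas["delta_" + bag_col].to_numpy(float)
    for var in variables:
        d = deltas["delta_" + var].to_numpy(float)
        keep = ~np.isnan(d) & ~np.isnan(y)
        if keep.sum() < 10:
            warnings.warn(f"{var}: fewer than 10 complete pairs, skipped", stacklevel=2)
            continue
        dz = d[keep]
        sd = dz.std(ddof=1)
        if sd == 0:
            warnings.warn(f"{var}: constant change score, skipped", stacklevel=2)
            continue
        dz = dz / sd
        x = np.column_stack([np.ones(keep.sum()), dz])
        res = hc3_inference(y[keep], x, ["intercept", var])
        row = res.loc[var]
        rows.append(AssociationResult(
            outcome="delta_" + bag_col, predictor=var,
            beta=float(row["beta"]), se_hc3=float(row["se_hc3"]),
            ci_low=float(row["ci_low"]), ci_high=float(row["ci_high"]),
            p_two_sided=float(row["p"]), n=int(keep.sum()),
        ).__dict__)
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q_fdr"] = bh_fdr(table["p_two_sided"].to_numpy())
    return table


def bh_fdr(p_values: np.ndarray, family_labels: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, applied within each family."""
    p = np.asarray(p_values, float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = np.empty_like(p)
    if family_labels is None:
        family_labels = np.zeros(len(p))
    family_labels = np.asarray(family_labels)
    for fam in np.unique(family_labels):
        m = family_labels == fam
        q[m] = multipletests(p[m], method="fdr_bh")[1]
    return q


def posthoc_extreme_groups(
    bag_z: np.ndarray,
    clinical: pd.DataFrame,
    variables: list[str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Welch comparison of younger- vs older-appearing patients.

    Groups are bag_z <= -threshold ("younger") and bag_z >= +threshold
    ("older"); the middle band is excluded.  Inference is skipped with a
    warning when either extreme group has fewer than 3 subjects.
    """
    bag_z = np.asarray(bag_z, float)
    younger = bag_z <= -threshold
    older = bag_z >= threshold
    rows = []
    for var in variables:
        v = clinical[var].to_numpy(float)
        vy = v[younger & ~np.isnan(v)]
        vo = v[older & ~np.isnan(v)]
        base = {"variable": var, "n_younger": len(vy), "n_older": len(vo),
                "mean_younger": float(np.mean(vy)) if len(vy) else np.nan,
                "mean_older": float(np.mean(vo)) if len(vo) else np.nan}
        if len(vy) < 3 or len(vo) < 3:
            warnings.warn(f"{var}: an extreme group has < 3 subjects, "
                          "inference skipped", stacklevel=2)
            rows.append({**base, "welch_t": np.nan, "p": np.nan})
            continue
        c = welch_contrast(vy, vo, site="")  # "ssd" slot = older group
        rows.append({**base, "welch_t": c.welch_t, "welch_df": c.welch_df,
                     "p": c.p, "cohens_d": c.cohens_d, "hedges_g": c.hedges_g})
    table = pd.DataFrame(rows)
    tested = table["p"].notna()
    table["q_fdr"] = np.nan
    if tested.any():
        table.loc[tested, "q_fdr"] = bh_fdr(table.loc[tested, "p"].to_numpy())
    return table
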