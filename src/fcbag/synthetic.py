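"""Synthetic lifespan cohorts with known brain-age ground truth.

Generates ROI time series, subject metadata and clinical scores for a
multi-site case-control cohort in which every effect the downstream
pipeline must detect or remove is injected with known parameters:

* an age-dependent drift on a subset of connectivity edges,
* additive and multiplicative site batch effects,
* sex and head-motion (mean framewise displacement) nuisance effects,
* a diagnosis-linked shift along the age axis (a known true brain-age
  gap, BAG), plus subject-level BAG heterogeneity,
* clinical scores correlated with the true BAG (sign convention: a
  more-negative BAG, i.e. a younger-appearing brain, goes with higher
  symptom scores and worse cognition),
* optionally a second visit with change scores coupled to the BAG change.

All effects live in Fisher-z connectivity space; per-subject correlation
matrices are back-transformed, projected to the nearest positive
semi-definite correlation matrix, and time series are drawn from a
zero-mean multivariate normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "CLINICAL_VARIABLES",
    "generate_cohort",
    "generate_followup",
    "nearest_psd_correlation",
    "write_cohort",
]

#: name -> (mean, sd, direction, patient_only).  direction=+1 means
#: "higher is worse" (score rises as true BAG falls); -1 marks
#: higher-is-better measures (DSST, CF), whose sign flips accordingly.
CLINICAL_VARIABLES: dict[str, tuple[float, float, int, bool]] = {
    "panss_total": (60.0, 15.0, +1, True),
    "panss_positive": (14.0, 5.0, +1, True),
    "panss_negative": (16.0, 6.0, +1, True),
    "panss_general": (30.0, 8.0, +1, True),
    "tmt": (40.0, 15.0, +1, False),
    "dsst": (50.0, 12.0, -1, False),
    "cf": (22.0, 6.0, -1, False),
    "nss_total": (14.0, 7.0, +1, True),
    "nss_moco": (4.0, 2.5, +1, True),
    "nss_if": (3.0, 2.0, +1, True),
    "nss_comt": (2.0, 1.5, +1, True),
    "nss_rlspo": (2.5, 1.8, +1, True),
    "nss_hs": (1.5, 1.2, +1, True),
    "doi": (8.0, 7.0, +1, True),
    "olz_eq": (12.0, 8.0, +1, True),
}


@dataclass
class SyntheticConfig:
    """Generative parameters for one cohort.

    Units: ages and BAG offsets in years; edge effects in Fisher-z units;
    mean FD in mm.
    """

    n_subjects: int = 400
    n_regions: int = 39
    n_timepoints: int = 200
    age_range: tuple[float, float] = (18.0, 80.0)
    n_sites: int = 2
    site_shift_sd: float = 0.1
    site_scale_sd: float = 0.1
    frac_age_edges: float = 0.3
    age_slope: float = 0.01
    case_fraction: float = 0.25
    bag_shift_years: float = 0.0
    bag_sd: float = 5.0
    clinical_loading: float = 0.4
    sex_effect: float = 0.05
    fd_effect: float = 0.1
    noise_sd: float = 0.05
    longitudinal: bool = False
    delta_bag_mean: float = 0.0
    delta_bag_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_subjects, self.n_regions, self.n_timepoints, self.n_sites) < 1:
            raise ValueError("counts must be positive")
        for name in ("site_shift_sd", "site_scale_sd", "noise_sd", "bag_sd",
                     "sex_effect", "fd_effect", "delta_bag_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("frac_age_edges", "case_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.clinical_loading <= 1.0:
            raise ValueError("clinical_loading must lie in [-1, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")


@dataclass
class SyntheticCohort:
    """One generated visit: time series, metadata and generative truth.

    ``truth`` holds per-subject true brain age / true BAG plus the
    cohort-level generative parameters (age-carrying edges and their
    slopes, site offsets/scales, the Fisher-z template).  Downstream
    pipeline code must only ever read ``timeseries`` and ``metadata``.
    """

    timeseries: list[np.ndarray]
    region_labels: list[str]
    metadata: pd.DataFrame
    truth: dict = field(default_factory=dict)
    config: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        if len(self.timeseries) != len(self.metadata):
            raise ValueError("metadata rows must match number of time-series matrices")


def nearest_psd_correlation(mat: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal renormalized
    to one.  Deterministic; raises if the result is not finite.
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eig_floor, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    if not np.all(np.isfinite(out)):
        raise ValueError("nearest-PSD projection produced non-finite entries")
    return out


def _edge_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(n_regions, k=-1)


def _base_template(rng: np.random.Generator, n_regions: int) -> np.ndarray:
    """Random Wishart-derived correlation template, mean off-diagonal ~0.2."""
    a = rng.standard_normal((n_regions, 2 * n_regions))
    s = a @ a.T
    d = np.sqrt(np.diag(s))
    w = s / np.outer(d, d)
    c = 0.8 * w + 0.2 * np.ones_like(w)
    np.fill_diagonal(c, 1.0)
    return c


def _clinical_scores(
    rng: np.random.Generator,
    z_anchor: np.ndarray,
    loading: float,
    mask: np.ndarray,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Scores whose correlation with the (standardized) anchor is -loading
    for higher-is-worse variables, +loading for higher-is-better ones."""
    out = {}
    for name, (mu, sd, direction, patient_only) in CLINICAL_VARIABLES.items():
        rows = mask & ~np.isnan(z_anchor) if patient_only else ~np.isnan(z_anchor)
        col = np.full(z_anchor.shape, np.nan)
        z = z_anchor[rows]
        if z.size >= 2 and np.std(z) > 0:
            z = (z - z.mean()) / z.std(ddof=1)
        eps = rng.standard_normal(rows.sum())
        latent = -direction * loading * z + np.sqrt(max(0.0, 1.0 - loading**2)) * eps
        col[rows] = mu + sd * scale * latent
        out[name] = col
    return pd.DataFrame(out)


def _subject_timeseries(
    rng: np.random.Generator,
    z_edges: np.ndarray,
    n_regions: int,
    n_timepoints: int,
) -> np.ndarray:
    rows, cols = _edge_index(n_regions)
    corr = np.eye(n_regions)
    r = np.tanh(z_edges)
    corr[rows, cols] = r
    corr[cols, rows] = r
    corr = nearest_psd_correlation(corr)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_regions))
    return rng.standard_normal((n_timepoints, n_regions)) @ chol.T


def _edge_effects(
    cfg: SyntheticConfig, rng: np.random.Generator, n_edges: int
) -> dict[str, np.ndarray]:
    n_age = int(round(cfg.frac_age_edges * n_edges))
    age_edges = rng.choice(n_edges, size=n_age, replace=False)
    age_edges.sort()
    signs = rng.choice([-1.0, 1.0], size=n_age)
    slopes = np.zeros(n_edges)
    slopes[age_edges] = signs * cfg.age_slope
    gamma = (
        rng.normal(0.0, cfg.site_shift_sd, size=(cfg.n_sites, n_edges))
        if cfg.site_shift_sd > 0
        else np.zeros((cfg.n_sites, n_edges))
    )
    log_delta = (
        rng.normal(0.0, cfg.site_scale_sd, size=(cfg.n_sites, n_edges))
        if cfg.site_scale_sd > 0
        else np.zeros((cfg.n_sites, n_edges))
    )
    sex_coef = rng.normal(0.0, cfg.sex_effect, size=n_edges) if cfg.sex_effect > 0 else np.zeros(n_edges)
    fd_coef = rng.normal(0.0, cfg.fd_effect, size=n_edges) if cfg.fd_effect > 0 else np.zeros(n_edges)
    return {
        "age_edges": age_edges,
        "edge_slopes": slopes,
        "site_gamma": gamma,
        "site_log_delta": log_delta,
        "sex_coef": sex_coef,
        "fd_coef": fd_coef,
    }


def _edges_for_subject(
    cfg: SyntheticConfig,
    truth: dict,
    z_base: np.ndarray,
    eff_age: float,
    mean_age: float,
    sex: int,
    fd: float,
    fd_mean: float,
    site_idx: int,
    noise: np.ndarray,
) -> np.ndarray:
    z = z_base + truth["edge_slopes"] * (eff_age - mean_age)
    z = z + truth["site_gamma"][site_idx]
    z = z + truth["sex_coef"] * sex
    z = z + truth["fd_coef"] * (fd - fd_mean)
    z = z + np.exp(truth["site_log_delta"][site_idx]) * cfg.noise_sd * noise
    return z


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a baseline visit under ``config``.

    One global seed fans out to per-subject substreams, so individual
    subjects are reproducible under cohort subsetting.
    """
    cfg = config
    cfg.validate()
    if cfg.n_timepoints <= cfg.n_regions:
        warnings.warn(
            "n_timepoints <= n_regions: sample correlation matrices will be rank-deficient",
            stacklevel=2,
        )
    root = np.random.SeedSequence(cfg.seed)
    ss_cohort, ss_base, _ss_fu = root.spawn(3)
    rng = np.random.default_rng(ss_cohort)
    subject_streams = ss_base.spawn(cfg.n_subjects)

    n = cfg.n_subjects
    n_regions = cfg.n_regions
    rows, _cols = _edge_index(n_regions)
    n_edges = rows.size

    template = _base_template(rng, n_regions)
    z_base = np.arctanh(template[_edge_index(n_regions)])
    effects = _edge_effects(cfg, rng, n_edges)

    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    sex = rng.integers(0, 2, size=n)
    site_idx = rng.integers(0, cfg.n_sites, size=n)
    diagnosis = (rng.uniform(size=n) < cfg.case_fraction).astype(int)

    # mean FD: log-normal, mildly age-correlated (r ~ 0.2)
    z_age = (age - age.mean()) / age.std(ddof=1)
    u = 0.2 * z_age + np.sqrt(1 - 0.2**2) * rng.standard_normal(n)
    mean_fd = np.exp(-2.0 + 0.4 * u)

    true_bag = cfg.bag_shift_years * diagnosis + cfg.bag_sd * rng.standard_normal(n)
    true_brain_age = age + true_bag
    true_bag = true_brain_age - age  # identity holds bitwise in the truth table
    mean_age = age.mean()
    fd_mean = mean_fd.mean()

    region_labels = [f"roi{i:03d}" for i in range(n_regions)]
    timeseries = []
    for i in range(n):
        sub_rng = np.random.default_rng(subject_streams[i])
        noise = sub_rng.standard_normal(n_edges)
        z = _edges_for_subject(
            cfg, effects, z_base, true_brain_age[i], mean_age,
            int(sex[i]), mean_fd[i], fd_mean, int(site_idx[i]), noise,
        )
        timeseries.append(_subject_timeseries(sub_rng, z, n_regions, cfg.n_timepoints))

    subject_id = [f"sub-{i:04d}" for i in range(n)]
    clinical = _clinical_scores(rng, true_bag.astype(float), cfg.clinical_loading,
                                mask=diagnosis == 1)
    metadata = pd.DataFrame(
        {
            "subject_id": subject_id,
            "age": age,
            "sex": sex,
            "site": [f"site{s:02d}" for s in site_idx],
            "diagnosis": diagnosis,
            "mean_fd": mean_fd,
            "visit": "baseline",
        }
    )
    metadata = pd.concat([metadata, clinical], axis=1)

    truth_subjects = pd.DataFrame(
        {
            "subject_id": subject_id,
            "true_brain_age": true_brain_age,
            "true_bag": true_bag,
        }
    )
    truth = {
        "subjects": truth_subjects,
        "template": template,
        "z_base": z_base,
        "mean_age": mean_age,
        "fd_mean": fd_mean,
        "site_index": site_idx,
        **effects,
    }
    return SyntheticCohort(
        timeseries=timeseries,
        region_labels=region_labels,
        metadata=metadata,
        truth=truth,
        config=replace(cfg),
    )


def generate_followup(
    cohort: SyntheticCohort,
    delta_bag_mean: float = 0.0,
    coupling: float = 0.0,
    delta_bag_sd: float | None = None,
) -> SyntheticCohort:
    """Second visit for all case subjects of ``cohort``.

    Each case receives a subject-level true BAG change
    ``delta = baseline - follow-up`` drawn from
    N(delta_bag_mean, delta_bag_sd); clinical change scores correlate with
    that delta at ``-coupling`` (a BAG increase accompanies a clinical
    score decrease).  Time series are regenerated at the shifted effective
    age from dedicated follow-up substreams.
    """
    cfg = cohort.config
    if cfg is None or not cfg.longitudinal:
        raise ValueError("cohort was not generated with the longitudinal flag")
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    if delta_bag_sd is None:
        delta_bag_sd = cfg.delta_bag_sd

    root = np.random.SeedSequence(cfg.seed)
    _ss_cohort, _ss_base, ss_fu = root.spawn(3)
    rng = np.random.default_rng(ss_fu.spawn(1)[0])
    subject_streams = ss_fu.spawn(1 + cfg.n_subjects)[1:]

    meta = cohort.metadata
    truth = cohort.truth
    case_rows = np.flatnonzero(meta["diagnosis"].to_numpy() == 1)
    if case_rows.size == 0:
        raise ValueError("no case subjects to follow up")

    delta_bag = delta_bag_mean + delta_bag_sd * rng.standard_normal(case_rows.size)
    base_bag = truth["subjects"]["true_bag"].to_numpy()[case_rows]
    fu_bag = base_bag - delta_bag
    age = meta["age"].to_numpy()[case_rows]
    fu_brain_age = age + fu_bag
    fu_bag = fu_brain_age - age

    n_regions = cfg.n_regions
    rows_idx, _ = _edge_index(n_regions)
    n_edges = rows_idx.size
    timeseries = []
    for k, i in enumerate(case_rows):
        sub_rng = np.random.default_rng(subject_streams[i])
        noise = sub_rng.standard_normal(n_edges)
        z = _edges_for_subject(
            cfg, truth, truth["z_base"], fu_brain_age[k], truth["mean_age"],
            int(meta["sex"].iat[i]), meta["mean_fd"].iat[i], truth["fd_mean"],
            int(truth["site_index"][i]), noise,
        )
        timeseries.append(_subject_timeseries(sub_rng, z, n_regions, cfg.n_timepoints))

    # clinical change scores: corr(delta_bag, delta_clin) = -coupling for
    # higher-is-worse variables, on the change-score scale (half the
    # cross-sectional SD)
    z_delta = delta_bag.copy()
    deltas = _clinical_scores(
        rng, z_delta, coupling, mask=np.ones(case_rows.size, dtype=bool), scale=0.5
    )
    # _clinical_scores returns mu + sd*scale*latent; changes are latent only
    for name, (mu, _sd, _d, _p) in CLINICAL_VARIABLES.items():
        deltas[name] = deltas[name] - mu

    fu_meta = meta.iloc[case_rows].copy().reset_index(drop=True)
    fu_meta["visit"] = "followup"
    for name in CLINICAL_VARIABLES:
        fu_meta[name] = fu_meta[name].to_numpy() - deltas[name].to_numpy()

    truth_subjects = pd.DataFrame(
        {
            "subject_id": fu_meta["subject_id"].to_numpy(),
            "true_brain_age": fu_brain_age,
            "true_bag": fu_bag,
            "true_delta_bag": delta_bag,
        }
    )
    fu_truth = dict(truth)
    fu_truth["subjects"] = truth_subjects
    fu_truth["clinical_deltas"] = deltas.assign(subject_id=fu_meta["subject_id"].to_numpy())
    return SyntheticCohort(
        timeseries=timeseries,
        region_labels=list(cohort.region_labels),
        metadata=fu_meta,
        truth=fu_truth,
        config=replace(cfg),
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write per-subject time-series TSVs plus metadata and truth CSVs."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, ts in zip(cohort.metadata["subject_id"], cohort.timeseries):
        pd.DataFrame(ts, columns=cohort.region_labels).to_csv(
            out / f"{sid}_timeseries.tsv", sep="\t", index=False
        )
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
    cohort.truth["subjects"].to_csv(out / "truth.csv", index=False)
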