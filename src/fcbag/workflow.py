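"""End-to-end pipeline orchestration over plain-file intermediates.

Stage order mirrors the analysis design: simulate (or ingest) -> connectome
features -> reference/analysis split -> ComBat harmonization fitted on the
healthy reference pool only -> nuisance residualization -> propensity
matching -> nested-CV brain-age training on the reference -> prediction and
BAG on the held-out analysis sample -> robust group, clinical and
longitudinal statistics.  The harmonization/training reference pool and the
statistics sample are disjoint by construction and the pipeline asserts it.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from fcbag import brainage, connectome, harmonize, match, stats
from fcbag.synthetic import (
    CLINICAL_VARIABLES,
    SyntheticConfig,
    generate_cohort,
    generate_followup,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "calibrated_group_analysis"]

CLINICAL_VARS = list(CLINICAL_VARIABLES)


@dataclass
class RunConfig:
    """One pipeline run: cohort conditions, CV layout, thresholds, paths."""

    cohort: SyntheticConfig
    seed: int
    ref_fraction: float = 0.5
    fisher_z: bool = False
    families: list[str] = field(default_factory=lambda: ["ridge", "svr_rbf"])
    cv: brainage.CVSpec = field(default_factory=lambda: brainage.CVSpec(outer_repeats=2))
    caliper_sd: float = 0.3
    posthoc_threshold: float = 0.5
    clinical_variables: list[str] = field(default_factory=lambda: CLINICAL_VARS)
    longitudinal: dict | None = None  # {"delta_bag_mean": .., "coupling": ..}
    outdir: str | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic stage")
        if not 0.0 < self.ref_fraction < 1.0:
            raise ValueError("ref_fraction must lie in (0, 1)")
        self.cohort.validate()
        self.cv.validate()


@dataclass
class RunManifest:
    config: dict
    package_version: str
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def reference_split(metadata: pd.DataFrame, ref_fraction: float, seed: int):
    """Healthy-reference pool (HC only) vs analysis sample, disjoint ids."""
    rng = np.random.default_rng(seed)
    hc_ids = metadata.loc[metadata["diagnosis"] == 0, "subject_id"].to_numpy()
    n_ref = int(round(ref_fraction * hc_ids.size))
    ref_ids = set(rng.choice(hc_ids, size=n_ref, replace=False))
    analysis_ids = [s for s in metadata["subject_id"] if s not in ref_ids]
    assert not ref_ids & set(analysis_ids), "reference and analysis samples overlap"
    return sorted(ref_ids), analysis_ids


def _covariates(meta: pd.DataFrame) -> pd.DataFrame:
    return meta[["age", "sex", "mean_fd"]].astype(float).reset_index(drop=True)


def harmonize_stage(features: pd.DataFrame, meta: pd.DataFrame,
                    ref_ids: list[str], analysis_ids: list[str]):
    """Fit ComBat on the reference pool, apply to both samples, then
    residualize sex and mean FD."""
    meta_i = meta.set_index("subject_id")
    out = {}
    model = harmonize.fit_combat(
        features.loc[ref_ids],
        meta_i.loc[ref_ids, "site"],
        _covariates(meta_i.loc[ref_ids]),
    )
    for name, ids in (("reference", ref_ids), ("analysis", analysis_ids)):
        harm = harmonize.apply_combat(
            model, features.loc[ids], meta_i.loc[ids, "site"], _covariates(meta_i.loc[ids])
        )
        out[name] = harmonize.residualize_nuisance(
            harm, meta_i.loc[ids, ["sex", "mean_fd"]].astype(float)
        )
    return model, out["reference"], out["analysis"]


def train_stage(ref_x: pd.DataFrame, ref_age: np.ndarray, config: RunConfig):
    bench = brainage.nested_cv_benchmark(ref_x, ref_age, config.families, config.cv)
    bias = brainage.fit_bias_correction(bench.oof["pred"].to_numpy(),
                                        bench.oof["age"].to_numpy())
    model = brainage.refit_final(ref_x, ref_age, bench.winner, bench.winner_params,
                                 bias, seed=config.cv.seed)
    return bench, model


def predict_stage(model: brainage.BrainAgeModel, x: pd.DataFrame,
                  meta: pd.DataFrame) -> pd.DataFrame:
    corrected = brainage.predict_brainage(model, x)
    bag = brainage.compute_bag(corrected, meta["age"].to_numpy(float))
    return pd.DataFrame({
        "subject_id": meta["subject_id"].to_numpy(),
        "brain_age": corrected,
        "bag": bag,
    })


def stats_stage(bag_df: pd.DataFrame, meta: pd.DataFrame, config: RunConfig) -> dict:
    """Group GLM, per-site Welch, clinical associations and post-hoc split."""
    df = meta.merge(bag_df, on="subject_id")
    rb = stats.residualize_bag(df["bag"], df["sex"], df["mean_fd"], df["age"])
    df = pd.concat([df.reset_index(drop=True), rb[["bag_resid", "bag_z"]]], axis=1)
    out: dict = {"bag_table": df}
    out["group"] = stats.group_difference_glm(df)
    try:
        out["per_site"] = stats.per_site_welch(df)
    except ValueError as exc:
        warnings.warn(f"per-site Welch skipped: {exc}", stacklevel=2)
        out["per_site"] = pd.DataFrame()
    ssd = df[df["diagnosis"] == 1].reset_index(drop=True)
    if len(ssd) >= 10:
        age_c = ssd["age"] - ssd["age"].mean()
        cov = pd.DataFrame({
            "sex": ssd["sex"].astype(float),
            "age_c": age_c,
            "age_c2": age_c**2,
            "fd_c": ssd["mean_fd"] - ssd["mean_fd"].mean(),
        })
        out["clinical"] = stats.associations_table(
            ssd["bag_z"].to_numpy(), ssd, cov, ssd["site"],
            [v for v in config.clinical_variables if v in ssd.columns],
        )
        out["posthoc"] = stats.posthoc_extreme_groups(
            ssd["bag_z"].to_numpy(), ssd,
            [v for v in config.clinical_variables if v in ssd.columns],
            threshold=config.posthoc_threshold,
        )
    return out


def run_pipeline(config: RunConfig) -> tuple[RunManifest, dict]:
    """Run every stage in dependency order; the manifest records stage
    timings and is written (when ``outdir`` is set) even on failure."""
    from fcbag import __version__

    config.validate()
    manifest = RunManifest(config=_config_snapshot(config), package_version=__version__)
    results: dict = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:
            manifest.failed_stage = name
            manifest.error = f"{type(exc).__name__}: {exc}"
            if outdir:
                manifest.write(outdir / "manifest.json")
            raise
        manifest.stages.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        return value

    cohort = stage("simulate", lambda: generate_cohort(config.cohort))
    features = stage("connectome", lambda: connectome.cohort_features(
        cohort.timeseries, cohort.region_labels,
        cohort.metadata["subject_id"].tolist(), fisher_z=config.fisher_z))
    ref_ids, analysis_ids = stage("split", lambda: reference_split(
        cohort.metadata, config.ref_fraction, config.seed))
    combat_model, ref_x, clin_x = stage("harmonize", lambda: harmonize_stage(
        features, cohort.metadata, ref_ids, analysis_ids))

    meta_i = cohort.metadata.set_index("subject_id")
    analysis_meta = meta_i.loc[analysis_ids].reset_index()

    def do_match():
        ps = match.propensity_scores(analysis_meta)
        return match.caliper_knn_match(ps, analysis_meta.set_index("subject_id")["diagnosis"],
                                       config.caliper_sd)

    matched = stage("match", do_match)
    matched_ids = [s for s in analysis_ids if s in set(matched.matched_ids())]

    ref_age = meta_i.loc[ref_ids, "age"].to_numpy(float)
    bench, brain_model = stage("train", lambda: train_stage(ref_x, ref_age, config))
    bag_df = stage("predict", lambda: predict_stage(
        brain_model, clin_x.loc[matched_ids], meta_i.loc[matched_ids].reset_index()))
    stat_out = stage("stats", lambda: stats_stage(
        bag_df, meta_i.loc[matched_ids].reset_index(), config))

    results.update(
        cohort=cohort, features=features, ref_ids=ref_ids, analysis_ids=analysis_ids,
        combat_model=combat_model, ref_x=ref_x, clin_x=clin_x, matched=matched,
        matched_ids=matched_ids, benchmark=bench, brain_model=brain_model,
        bag=bag_df, **{f"stats_{k}": v for k, v in stat_out.items()},
    )

    if config.longitudinal is not None:
        def do_longitudinal():
            fu = generate_followup(cohort, **config.longitudinal)
            fu_ids = fu.metadata["subject_id"].tolist()
            fu_feat = connectome.cohort_features(
                fu.timeseries, fu.region_labels, fu_ids, fisher_z=config.fisher_z)
            fu_meta = fu.metadata.set_index("subject_id")
            fu_harm = harmonize.apply_combat(
                combat_model, fu_feat, fu_meta["site"], _covariates(fu_meta))
            fu_x = harmonize.residualize_nuisance(
                fu_harm, fu_meta[["sex", "mean_fd"]].astype(float))
            fu_bag = predict_stage(brain_model, fu_x, fu.metadata)
            base = stat_out["bag_table"][stat_out["bag_table"]["diagnosis"] == 1]
            base = base.merge(cohort.metadata[["subject_id"] + CLINICAL_VARS],
                              on="subject_id", how="left", suffixes=("", "_dup"))
            fu_tab = fu.metadata.merge(fu_bag, on="subject_id")
            variables = [v for v in config.clinical_variables
                         if v in base.columns and v in fu_tab.columns]
            deltas = stats.longitudinal_delta(base, fu_tab, variables, bag_col="bag")
            return {"followup": fu, "deltas": deltas,
                    "delta_associations": stats.delta_associations(deltas, variables)}

        results["longitudinal"] = stage("longitudinal", do_longitudinal)

    if outdir:
        stat_out["bag_table"].to_csv(outdir / "bag_table.csv", index=False)
        bench.table.to_csv(outdir / "benchmark.csv", index=False)
        if "clinical" in stat_out and isinstance(stat_out["clinical"], pd.DataFrame):
            stat_out["clinical"].to_csv(outdir / "clinical_associations.csv", index=False)
        manifest.write(outdir / "manifest.json")
    return manifest, results


def _config_snapshot(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def calibrated_group_analysis(
    base_config: RunConfig, target_shift_sd: float
) -> dict:
    """Two-pass case-shift analysis with the shift stated in SD units.

    Pass 1 runs the full pipeline with zero diagnosis shift and measures
    the control residualized-BAG dispersion sigma (years).  Pass 2
    regenerates the cohort with ``bag_shift_years = target_shift_sd *
    sigma`` — controls and all seeds unchanged — and re-applies the
    already-fitted harmonizer and brain-age model, so the injected group
    effect equals ``target_shift_sd`` standard deviations of the
    pipeline's own BAG scale by construction.
    """
    cfg0 = replace(base_config, cohort=replace(base_config.cohort, bag_shift_years=0.0))
    _, pass1 = run_pipeline(cfg0)
    tab = pass1["stats_bag_table"]
    sigma = float(tab.loc[tab["diagnosis"] == 0, "bag_resid"].std(ddof=1))

    shifted = replace(base_config.cohort, bag_shift_years=target_shift_sd * sigma)
    cohort2 = generate_cohort(shifted)
    features2 = connectome.cohort_features(
        cohort2.timeseries, cohort2.region_labels,
        cohort2.metadata["subject_id"].tolist(), fisher_z=base_config.fisher_z)
    meta_i = cohort2.metadata.set_index("subject_id")
    analysis_ids = pass1["analysis_ids"]
    combat_model = pass1["combat_model"]
    harm = harmonize.apply_combat(
        combat_model, features2.loc[analysis_ids],
        meta_i.loc[analysis_ids, "site"], _covariates(meta_i.loc[analysis_ids]))
    clin_x = harmonize.residualize_nuisance(
        harm, meta_i.loc[analysis_ids, ["sex", "mean_fd"]].astype(float))

    analysis_meta = meta_i.loc[analysis_ids].reset_index()
    ps = match.propensity_scores(analysis_meta)
    matched = match.caliper_knn_match(
        ps, analysis_meta.set_index("subject_id")["diagnosis"], base_config.caliper_sd)
    matched_ids = [s for s in analysis_ids if s in set(matched.matched_ids())]

    bag_df = predict_stage(pass1["brain_model"], clin_x.loc[matched_ids],
                           meta_i.loc[matched_ids].reset_index())
    stat_out = stats_stage(bag_df, meta_i.loc[matched_ids].reset_index(), base_config)
    return {
        "sigma_years": sigma,
        "bag_shift_years": target_shift_sd * sigma,
        "pass1": pass1,
        "cohort": cohort2,
        "bag": bag_df,
        "matched_ids": matched_ids,
        **{f"stats_{k}": v for k, v in stat_out.items()},
    }
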