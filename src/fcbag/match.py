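"""Propensity-score matching of case and control age/sex distributions.

Propensity scores come from a maximum-likelihood logistic regression of
group on age and sex; pairs are formed by greedy 1:1 nearest-neighbour
matching without replacement on the logit of the propensity score, with
a caliper expressed in standard deviations of the pooled logit scores
(default 0.3).  Cases without an eligible match inside the caliper are
excluded from all group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["MatchResult", "propensity_scores", "caliper_knn_match"]


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]
    excluded_ids: list[str]
    caliper_logit: float
    ps: pd.Series = field(repr=False)

    def matched_ids(self) -> list[str]:
        return [i for pair in self.pairs for i in pair]


def propensity_scores(
    meta: pd.DataFrame,
    group_col: str = "diagnosis",
    age_col: str = "age",
    sex_col: str = "sex",
) -> pd.Series:
    """Fitted P(group=1 | age, sex) from a logistic regression.

    Rejects degenerate inputs: a single group, incomplete covariates, or
    perfect separation (detected via non-finite/diverging coefficients).
    """
    cols = [age_col, sex_col]
    if meta[cols + [group_col]].isna().any().any():
        raise ValueError("age/sex/group must be complete")
    g = meta[group_col].to_numpy()
    if len(np.unique(g)) < 2:
        raise ValueError("both groups must be present")
    x = sm.add_constant(meta[cols].to_numpy(dtype=float))
    try:
        fit = sm.Logit(g, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and kin
        raise ValueError(f"propensity model failed to fit: {exc}") from exc
    if not np.all(np.isfinite(fit.params)) or np.max(np.abs(fit.params)) > 1e6:
        raise ValueError("perfect separation in propensity model")
    ps = np.clip(fit.predict(x), 1e-12, 1 - 1e-12)
    index = meta["subject_id"] if "subject_id" in meta.columns else meta.index
    return pd.Series(ps, index=pd.Index(index, name="subject_id"), name="ps")


def caliper_knn_match(
    ps: pd.Series,
    group: pd.Series,
    caliper_sd: float = 0.3,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on logit(ps) without replacement.

    The smaller group drives the matching, processed in descending logit
    order (ties broken by subject id); a candidate pair farther apart than
    ``caliper_sd`` pooled-logit standard deviations is dropped and the
    subject excluded.
    """
    ps = pd.Series(ps)
    group = pd.Series(np.asarray(group), index=ps.index)
    if ps.empty:
        raise ValueError("empty propensity series")
    logit = np.log(ps / (1 - ps))
    sd = float(logit.std(ddof=1))
    caliper = caliper_sd * sd

    levels = sorted(group.unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    n_by_level = {lv: int((group == lv).sum()) for lv in levels}
    if min(n_by_level.values()) == 0:
        raise ValueError("empty group")
    # ties in group size resolve to the later level (cases when 0/1 coded)
    minority = min(levels, key=lambda lv: (n_by_level[lv], -levels.index(lv)))
    majority = [lv for lv in levels if lv != minority][0]

    minor = logit[group == minority].sort_index().sort_values(ascending=False, kind="stable")
    major = logit[group == majority]
    available = dict(major.items())

    pairs: list[tuple[str, str]] = []
    excluded: list[str] = []
    for sid, lg in minor.items():
        if not available:
            excluded.append(sid)
            continue
        ids = list(available)
        dists = np.abs(np.array([available[i] for i in ids]) - lg)
        k = int(np.argmin(dists))
        if dists[k] <= caliper:
            pairs.append((sid, ids[k]))
            del available[ids[k]]
        else:
            excluded.append(sid)

    used = [i for p in pairs for i in p]
    if len(used) != len(set(used)):
        raise AssertionError("matching reused a subject")
    return MatchResult(pairs=pairs, excluded_ids=excluded, caliper_logit=float(caliper), ps=ps)
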