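"""Study-level statistics on vessel-metric tables.

Reproduces the analysis stages of the longitudinal corneal-vascularisation
study design: mixed-effects contrasts of vessel metrics across ICGA stage
groups (random intercept per eye, since the same eyes are imaged
repeatedly), simple linear regression of dye leakage time on vessel
density, a Spearman correlation matrix between aqueous cytokines and
vessel metrics, and paired/independent t-tests for within-eye and
between-arm changes.  No multiple-testing correction is applied by
default; Holm adjustment is available as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import StudyRecord

__all__ = [
    "STAGE_GROUPS",
    "StageContrastResult",
    "RegressionResult",
    "CorrelationMatrix",
    "records_to_frame",
    "stage_contrasts",
    "group_mean_differences",
    "leakage_regression",
    "cytokine_matrix",
    "group_change_tests",
    "paired_ttest",
    "independent_ttest",
    "holm_adjust",
]

log = logging.getLogger(__name__)

#: ICGA stages pooled as in the study's contrast layout: active (1-2) as
#: reference, partial regression (3), strong regression/ghost vessels (4-5).
STAGE_GROUPS: dict[int, str] = {1: "1-2", 2: "1-2", 3: "3", 4: "4-5", 5: "4-5"}
REFERENCE_GROUP = "1-2"
_GROUP_ORDER = ["1-2", "3", "4-5"]


@dataclass
class StageContrastResult:
    """Stage-group contrast of one metric under a random-intercept model.

    ``mean_differences[g]`` follows the convention reference mean minus
    comparison-group mean, so a positive difference means the metric is
    higher in active (stage 1-2) vessels.
    """

    metric: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    mean_differences: dict[str, float | None]
    p_values: dict[str, float | None]
    model: str = "mixedlm-random-intercept"


@dataclass
class RegressionResult:
    """Simple linear regression summary with signed correlation."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class CorrelationMatrix:
    """Spearman rho and two-tailed p per analyte x metric cell.

    Cells with fewer than 3 complete pairs carry ``rho=None``; analytes
    with every sample below the limit of detection are excluded entirely
    and listed in ``excluded_below_lod``.
    """

    rho: dict[str, dict[str, float | None]]
    p_values: dict[str, dict[str, float | None]]
    n: dict[str, dict[str, int]]
    excluded_below_lod: list[str] = field(default_factory=list)


def records_to_frame(records: list[StudyRecord]) -> pd.DataFrame:
    """Flatten study records into a tidy table, one row per eye-visit."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "eye": r.eye, "week": r.week, "arm": r.arm,
            "stage": r.stage, "leakage_s": r.leakage_s, "true_vd": r.true_vd,
        }
        if r.metrics is not None:
            row.update({"VD": r.metrics.vd, "VBA": r.metrics.vba,
                        "VW": r.metrics.vw, "roi_px": r.metrics.roi_px})
        for name, val in r.cytokines.items():
            row[name] = val
        rows.append(row)
    return pd.DataFrame(rows)


def _metric_values(records: list[StudyRecord] | pd.DataFrame, metric: str) -> pd.DataFrame:
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if metric not in df.columns:
        raise ValueError(f"metric {metric!r} not present in records")
    return df


def stage_contrasts(records: list[StudyRecord] | pd.DataFrame,
                    metric: str = "VD") -> StageContrastResult:
    """Contrast a vessel metric across pooled ICGA stage groups.

    Fits ``metric ~ stage_group`` with a random intercept per eye by
    restricted maximum likelihood; when every eye contributes a single
    record the random intercept is unidentifiable and the fit falls back
    to ordinary least squares (logged).  Groups with no observations are
    reported as missing contrasts, not zeros.
    """
    df = _metric_values(records, metric)
    df = df.dropna(subset=[metric, "stage"])
    df = df[df["stage"].isin(STAGE_GROUPS)]
    df["stage_group"] = df["stage"].map(STAGE_GROUPS)

    present = [g for g in _GROUP_ORDER if (df["stage_group"] == g).any()]
    if len(present) < 2 or REFERENCE_GROUP not in present:
        raise ValueError("need the reference group and at least one other "
                         f"stage group; present: {present}")

    means = {g: float(df.loc[df.stage_group == g, metric].mean()) for g in present}
    sds = {g: float(df.loc[df.stage_group == g, metric].std(ddof=1)) for g in present}
    ns = {g: int((df.stage_group == g).sum()) for g in present}

    import statsmodels.formula.api as smf

    df = df.rename(columns={metric: "y"})
    formula = "y ~ C(stage_group, Treatment(reference='1-2'))"
    one_per_eye = df.groupby("eye").size().max() <= 1
    if one_per_eye:
        log.info("single record per eye: falling back to OLS for %s", metric)
        fit = smf.ols(formula, data=df).fit()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, data=df, groups=df["eye"]).fit(reml=True)

    diffs: dict[str, float | None] = {}
    pvals: dict[str, float | None] = {}
    for g in _GROUP_ORDER[1:]:
        if g not in present:
            diffs[g] = None
            pvals[g] = None
            continue
        term = f"C(stage_group, Treatment(reference='1-2'))[T.{g}]"
        # model coefficient is comparison - reference; report ref - comparison
        diffs[g] = -float(fit.params[term])
        pvals[g] = float(fit.pvalues[term])
    return StageContrastResult(metric=metric, group_means=means, group_sds=sds,
                               group_ns=ns, mean_differences=diffs, p_values=pvals,
                               model="ols" if one_per_eye else "mixedlm-random-intercept")


def group_mean_differences(group_means: dict[str, float],
                           reference: str = REFERENCE_GROUP) -> dict[str, float]:
    """Reference-minus-comparison differences of a group-mean summary."""
    ref = group_means[reference]
    return {g: ref - m for g, m in group_means.items() if g != reference}


def leakage_regression(records: list[StudyRecord] | pd.DataFrame,
                       metric: str = "VD") -> RegressionResult:
    """OLS of dye leakage time (s) on a vessel metric (default VD %).

    Reports the signed Pearson correlation ``r`` and ``r^2`` separately;
    with an inverse relationship the slope and ``r`` are negative while
    ``r^2`` is, as always, non-negative.
    """
    df = _metric_values(records, metric).dropna(subset=[metric, "leakage_s"])
    if len(df) < 3:
        raise ValueError(f"need >= 3 records with {metric} and leakage time, "
                         f"got {len(df)}")
    x = df[metric].to_numpy(dtype=float)
    y = df["leakage_s"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate predictor: {metric} has zero variance")
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r=float(res.rvalue), r_squared=float(res.rvalue**2),
                            p_value=float(res.pvalue), n=len(df))


def cytokine_matrix(records: list[StudyRecord] | pd.DataFrame,
                    analytes: list[str] | None = None,
                    metrics: tuple[str, ...] = ("VD", "VBA"),
                    max_week: float | None = None) -> CorrelationMatrix:
    """Spearman correlation of each cytokine with each vessel metric.

    Below-LOD concentrations (stored as NaN) are excluded pairwise; an
    analyte with no detectable sample at all is dropped from the matrix and
    logged as below limits of detection.  Ties are handled by mid-ranks.
    ``max_week`` restricts the rows (e.g. to pre-injection visits).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        known = {"eye", "week", "arm", "stage", "leakage_s", "true_vd",
                 "VD", "VBA", "VW", "roi_px", "converged"}
        if analytes is None:
            analytes = [c for c in df.columns if c not in known]
    else:
        if analytes is None:
            names: list[str] = []
            for r in records:
                for k in r.cytokines:
                    if k not in names:
                        names.append(k)
            analytes = names
        df = records_to_frame(records)
    if max_week is not None:
        df = df[df["week"] <= max_week]

    rho: dict[str, dict[str, float | None]] = {}
    pvals: dict[str, dict[str, float | None]] = {}
    ncell: dict[str, dict[str, int]] = {}
    excluded: list[str] = []
    for a in analytes:
        vals = df[a] if a in df.columns else pd.Series(dtype=float)
        if vals.dropna().empty:
            excluded.append(a)
            log.info("analyte %s below limits of detection; excluded", a)
            continue
        rho[a], pvals[a], ncell[a] = {}, {}, {}
        for m in metrics:
            sub = df[[a, m]].dropna()
            ncell[a][m] = len(sub)
            if len(sub) < 3:
                rho[a][m] = None
                pvals[a][m] = None
                continue
            r, p = sps.spearmanr(sub[a], sub[m])
            rho[a][m] = float(r)
            pvals[a][m] = float(p)
    return CorrelationMatrix(rho=rho, p_values=pvals, n=ncell,
                             excluded_below_lod=excluded)


def paired_ttest(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Two-tailed paired t-test on matched samples.

    Identical samples are the exact null and return ``(0, 1)`` rather than
    the indeterminate 0/0 statistic.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    delta = post - pre
    if len(delta) < 2:
        return float("nan"), float("nan")
    if np.ptp(delta) == 0 and delta[0] == 0:
        return 0.0, 1.0
    t, p = sps.ttest_rel(post, pre)
    return float(t), float(p)


def independent_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed two-sample t-test (pooled variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) + len(b) < 3 or min(len(a), len(b)) < 1:
        return float("nan"), float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b)
    return float(t), float(p)


def group_change_tests(records: list[StudyRecord] | pd.DataFrame,
                       metric: str = "VD",
                       pre_week: float = 2, post_week: float = 4,
                       arms: tuple[str, str] = ("aflibercept", "saline")) -> dict:
    """Within-eye paired t-tests and a between-arm independent t-test.

    For each arm, the paired test compares the metric at ``pre_week`` vs
    ``post_week`` within eyes (every eye must have both visits; orphaned
    eyes abort with an explicit error).  The independent test compares the
    two arms' within-eye changes at ``post_week``.  All p-values are
    two-tailed.
    """
    df = _metric_values(records, metric)
    out: dict[str, dict] = {"paired": {}, "independent": None}
    changes: dict[str, np.ndarray] = {}
    for arm in arms:
        sub = df[df["arm"] == arm]
        if sub.empty:
            raise ValueError(f"arm {arm!r} has no records")
        pre = sub[sub["week"] == pre_week].set_index("eye")[metric]
        post = sub[sub["week"] == post_week].set_index("eye")[metric]
        orphans = sorted(set(pre.index) ^ set(post.index))
        if orphans:
            raise ValueError(f"unmatched pre/post pairs in arm {arm!r}: {orphans}")
        eyes = sorted(pre.index)
        delta = post.loc[eyes].to_numpy(float) - pre.loc[eyes].to_numpy(float)
        changes[arm] = delta
        t, p = paired_ttest(pre.loc[eyes].to_numpy(float), post.loc[eyes].to_numpy(float))
        out["paired"][arm] = {"t": t, "p": p, "n": len(eyes),
                              "mean_change": float(delta.mean())}
    t, p = independent_ttest(changes[arms[0]], changes[arms[1]])
    out["independent"] = {"t": float(t), "p": float(p),
                          "n": (len(changes[arms[0]]), len(changes[arms[1]])),
                          "arms": arms}
    return out


def holm_adjust(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
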