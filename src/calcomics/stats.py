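"""Cohort-level group contrasts, multiple-testing control, and survival models.

Contrasts follow the regression conventions of the study design: a binary
feature (mutation present, subtype membership) is modelled with a
binomial-family logistic regression of the feature on the calcification-group
indicator (odds ratio + Wald CI, with a Fisher's-exact fallback for separable
tables), and a continuous feature (signature or infiltration score) with a
Gaussian-family linear model (a rank-test P is reported alongside). P values
across a feature family are adjusted by Benjamini-Hochberg FDR. Survival
endpoints (OS/DMFS/RFS) are contrasted with covariate-adjusted Cox
proportional-hazards models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    contrast: str
    estimate: float  # odds ratio (categorical) or mean difference (continuous)
    ci_low: float
    ci_high: float
    p_value: float
    rank_p: float | None = None
    fisher_fallback: bool = False
    fdr: float | None = None


@dataclass(frozen=True)
class SurvivalResult:
    endpoint: str
    contrast: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    converged: bool = True


def _two_group_frame(feature: pd.Series, groups: pd.Series, positive: str, reference: str):
    keep = groups.isin([positive, reference])
    g = (groups[keep] == positive).astype(int)
    y = feature.loc[g.index]
    return y, g


def compare_categorical(
    feature: pd.Series,
    groups: pd.Series,
    positive_group: str,
    reference_group: str,
    covariates: pd.DataFrame | None = None,
) -> ComparisonResult:
    """Logistic contrast of a binary feature between two groups.

    Fits feature ~ group (+ covariates) with a binomial GLM; the estimate is
    the odds ratio for the positive group with its Wald 95% CI. Tables with a
    zero cell (or a non-converging fit) fall back to Fisher's exact test with
    the conditional odds ratio, flagged via ``fisher_fallback``.
    """
    y, g = _two_group_frame(feature.astype(int), groups, positive_group, reference_group)
    if g.nunique() < 2:
        raise ValueError("contrast requires samples from both groups")
    contrast = f"{positive_group}_vs_{reference_group}"
    name = str(feature.name or "feature")

    table = np.array(
        [
            [(y[g == 1] == 1).sum(), (y[g == 1] == 0).sum()],
            [(y[g == 0] == 1).sum(), (y[g == 0] == 0).sum()],
        ]
    )
    if (table == 0).any():
        orr, p = sps.fisher_exact(table)
        return ComparisonResult(name, contrast, float(orr), np.nan, np.nan, float(p), fisher_fallback=True)

    x = pd.DataFrame({"group": g})
    if covariates is not None:
        x = x.join(covariates.loc[g.index])
    x = sm.add_constant(x.astype(float))
    try:
        fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        if not np.isfinite(fit.bse["group"]) or fit.bse["group"] > 50:
            raise ValueError("quasi-separation")
    except Exception:
        orr, p = sps.fisher_exact(table)
        return ComparisonResult(name, contrast, float(orr), np.nan, np.nan, float(p), fisher_fallback=True)
    coef = fit.params["group"]
    lo, hi = fit.conf_int().loc["group"]
    return ComparisonResult(
        name,
        contrast,
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p_value=float(fit.pvalues["group"]),
    )


def compare_continuous(
    feature: pd.Series,
    groups: pd.Series,
    positive_group: str,
    reference_group: str,
    covariates: pd.DataFrame | None = None,
) -> ComparisonResult:
    """Gaussian-family contrast of a continuous feature between two groups.

    The estimate is the adjusted mean difference (positive minus reference)
    with its Wald 95% CI; a two-sided Mann-Whitney P on the raw values is
    reported alongside as ``rank_p``. A constant feature yields P = 1 with a
    zero estimate.
    """
    y, g = _two_group_frame(feature.astype(float), groups, positive_group, reference_group)
    if (g == 1).sum() < 2 or (g == 0).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    contrast = f"{positive_group}_vs_{reference_group}"
    name = str(feature.name or "feature")
    if y.nunique() <= 1:
        import warnings

        warnings.warn(f"feature {name!r} is constant", stacklevel=2)
        return ComparisonResult(name, contrast, 0.0, 0.0, 0.0, 1.0, rank_p=1.0)
    x = pd.DataFrame({"group": g})
    if covariates is not None:
        x = x.join(covariates.loc[g.index])
    x = sm.add_constant(x.astype(float))
    fit = sm.OLS(y, x).fit()
    lo, hi = fit.conf_int().loc["group"]
    rank_p = float(sps.mannwhitneyu(y[g == 1], y[g == 0], alternative="two-sided").pvalue)
    return ComparisonResult(
        name,
        contrast,
        estimate=float(fit.params["group"]),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(fit.pvalues["group"]),
        rank_p=rank_p,
    )


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: list[ComparisonResult]) -> list[ComparisonResult]:
    """Return the results with BH-adjusted P values attached (one family)."""
    fdrs = adjust_fdr([r.p_value for r in results])
    return [
        ComparisonResult(**{**r.__dict__, "fdr": float(q)}) for r, q in zip(results, fdrs)
    ]


def feature_frequency_table(
    events: pd.DataFrame,
    groups: pd.Series,
    positive_group: str,
    reference_group: str,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-feature event frequencies per group plus the two-group contrast.

    ``events`` is a feature x sample binary matrix (mutation presence or
    GISTIC-derived calls). Frequencies are reported for every calcification
    group present; the contrast (logistic OR, raw P, BH FDR across features)
    compares the two named groups.
    """
    samples = [s for s in events.columns if s in groups.index]
    missing_groups = [g for g in (positive_group, reference_group) if (groups[samples] == g).sum() == 0]
    if missing_groups:
        raise ValueError(f"empty group(s) in contrast: {missing_groups}")
    ev = events[samples]
    grp = groups[samples]
    rows = []
    results = []
    for feat in ev.index:
        y = ev.loc[feat]
        freq = {f"freq_{g}": float(y[grp == g].mean()) for g in grp.unique()}
        res = compare_categorical(
            y.rename(feat), grp, positive_group, reference_group, covariates=covariates
        )
        results.append(res)
        rows.append({"feature": feat, **freq})
    results = attach_fdr(results)
    out = pd.DataFrame(rows).set_index("feature")
    out["odds_ratio"] = [r.estimate for r in results]
    out["p_value"] = [r.p_value for r in results]
    out["fdr"] = [r.fdr for r in results]
    out["fisher_fallback"] = [r.fisher_fallback for r in results]
    return out.reset_index()


DEFAULT_COX_COVARIATES = ("age", "tumor_size_cat", "node_status")


def cox_hazard(
    cohort: pd.DataFrame,
    endpoint: str,
    positive_group: str,
    reference_group: str,
    covariates: tuple[str, ...] = DEFAULT_COX_COVARIATES,
    min_events: int = 10,
) -> SurvivalResult:
    """Adjusted hazard ratio for one endpoint (os, dmfs or rfs) between two
    calcification groups via a multivariate Cox proportional-hazards model.

    The contrast enters as a binary indicator for the positive group; the
    default covariate set (age, tumor size category, nodal status) is
    configurable and recorded by the pipeline manifest.
    """
    time_col, event_col = f"{endpoint}_months", f"{endpoint}_event"
    for col in (time_col, event_col):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks column {col!r} for endpoint {endpoint!r}")
    sub = cohort[cohort["group"].isin([positive_group, reference_group])].copy()
    n_events = int(sub[event_col].sum())
    if n_events == 0:
        raise ValueError(f"no events for endpoint {endpoint!r} in the contrasted groups")
    if n_events < min_events:
        raise ValueError(
            f"only {n_events} events for endpoint {endpoint!r}; floor is {min_events}"
        )
    sub["exposure"] = (sub["group"] == positive_group).astype(int)
    cols = ["exposure"] + [c for c in covariates if c in sub.columns]
    frame = sub[[time_col, event_col, *cols]].astype(float)
    cph = CoxPHFitter()
    converged = True
    try:
        cph.fit(frame, duration_col=time_col, event_col=event_col)
    except Exception:
        converged = False
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(frame, duration_col=time_col, event_col=event_col)
    hr = float(np.exp(cph.params_["exposure"]))
    ci = cph.confidence_intervals_.loc["exposure"]
    return SurvivalResult(
        endpoint=endpoint,
        contrast=f"{positive_group}_vs_{reference_group}",
        hazard_ratio=hr,
        ci_low=float(np.exp(ci.iloc[0])),
        ci_high=float(np.exp(ci.iloc[1])),
        p_value=float(cph.summary.loc["exposure", "p"]),
        n_events=n_events,
        converged=converged,
    )
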