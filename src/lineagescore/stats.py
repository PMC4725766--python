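"""Association stages downstream of a CLS matrix.

Survival models (Cox proportional hazards, Kaplan-Meier/log-rank with
mode-based dichotomization), annotation correlations with rank-based
subtype enrichment, infiltration group tests, and cross-species profile
matching. Standard fits go through lifelines / scipy / statsmodels; the
contracts here fix the variants used (Welch t-test, BH step-up, exact
rank-sum below n=20, KDE mode with Silverman bandwidth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class SurvivalAssociation:
    """Cox PH result for one lineage's CLS as a continuous covariate."""

    lineage: str
    hazard_ratio: float
    coef: float
    se: float
    wald_p: float
    n_used: int
    adj_p: float | None = None
    converged: bool = True
    note: str = ""


def _align_clinical(
    cls: pd.Series, clinical: pd.DataFrame, covariates: list[str] | None = None
) -> pd.DataFrame:
    cols = ["time", "event"] + list(covariates or [])
    df = clinical[cols].join(cls.rename("cls"), how="inner").dropna()
    dropped = len(clinical) - len(df)
    if dropped:
        logger.info("survival fit: dropped %d samples with missing fields", dropped)
    return df


def _fit_cox(df: pd.DataFrame, lineage: str) -> SurvivalAssociation:
    n_events = int(df["event"].sum())
    if n_events < 2:
        return SurvivalAssociation(lineage, np.nan, np.nan, np.nan, np.nan,
                                   len(df), converged=False,
                                   note=f"only {n_events} events")
    if df["cls"].nunique() <= 1:
        return SurvivalAssociation(lineage, np.nan, np.nan, np.nan, np.nan,
                                   len(df), converged=False,
                                   note="constant CLS vector")
    fitter = CoxPHFitter()
    try:
        # lifelines handles ties by Efron's method
        fitter.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence / collinearity
        return SurvivalAssociation(lineage, np.nan, np.nan, np.nan, np.nan,
                                   len(df), converged=False, note=str(exc))
    row = fitter.summary.loc["cls"]
    return SurvivalAssociation(
        lineage=lineage,
        hazard_ratio=float(np.exp(row["coef"])),
        coef=float(row["coef"]),
        se=float(row["se(coef)"]),
        wald_p=float(row["p"]),
        n_used=len(df),
    )


def univariate_cox(cls: pd.Series, clinical: pd.DataFrame,
                   lineage: str = "") -> SurvivalAssociation:
    """Univariate Cox PH fit of survival on one lineage's CLS.

    The CLS enters as a continuous covariate; the hazard ratio is per
    unit CLS and significance is Wald's test. Non-convergent or
    event-free fits return a flagged result (``converged=False``) that is
    excluded from the BH family.
    """
    return _fit_cox(_align_clinical(cls, clinical), lineage or str(cls.name))


def multivariate_cox(
    cls: pd.Series, covariates: list[str], clinical: pd.DataFrame,
    lineage: str = "",
) -> SurvivalAssociation:
    """Cox PH fit adjusting for clinical covariates; reports the CLS term."""
    df = _align_clinical(cls, clinical, covariates)
    return _fit_cox(df, lineage or str(cls.name))


def adjust_bh(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def survival_scan(
    cls_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Fit one Cox model per lineage and BH-adjust across the run.

    The adjustment family is all lineages that converged in this scan;
    flagged fits keep ``adj_p = NaN``.
    """
    results = []
    for lineage in cls_matrix.columns:
        cls = cls_matrix[lineage]
        if covariates:
            res = multivariate_cox(cls, covariates, clinical, lineage=lineage)
        else:
            res = univariate_cox(cls, clinical, lineage=lineage)
        results.append(res)
    ok = [r for r in results if r.converged]
    if ok:
        adj = adjust_bh([r.wald_p for r in ok])
        for r, a in zip(ok, adj):
            r.adj_p = float(a)
    for r in results:
        if not r.converged:
            logger.warning("lineage %s excluded from BH family: %s", r.lineage, r.note)
    return pd.DataFrame(
        {
            "lineage": [r.lineage for r in results],
            "hazard_ratio": [r.hazard_ratio for r in results],
            "coef": [r.coef for r in results],
            "se": [r.se for r in results],
            "wald_p": [r.wald_p for r in results],
            "adj_p": [r.adj_p for r in results],
            "n_used": [r.n_used for r in results],
            "converged": [r.converged for r in results],
            "note": [r.note for r in results],
        }
    ).set_index("lineage")


def dichotomize_at_mode(cls: pd.Series | np.ndarray,
                        fallback_median: bool = False) -> tuple[np.ndarray, float]:
    """Split samples into high/low groups about the mode of the CLS density.

    The cutpoint is the argmax of a Gaussian KDE (Silverman bandwidth)
    evaluated on a fine grid over the data range; ``high`` means
    CLS > cutpoint. If the split empties one group, an error suggests the
    median fallback (``fallback_median=True`` splits at the median
    instead).
    """
    values = np.asarray(cls, dtype=float)
    if values.size < 20:
        raise ValueError("mode dichotomization needs >= 20 samples")
    if np.unique(values).size == 1:
        raise ValueError("all CLS values identical; no split possible")
    if fallback_median:
        cut = float(np.median(values))
    else:
        kde = stats.gaussian_kde(values, bw_method="silverman")
        grid = np.linspace(values.min(), values.max(), 2048)
        cut = float(grid[np.argmax(kde(grid))])
    labels = (values > cut).astype(int)
    if labels.all() or not labels.any():
        raise ValueError(
            "mode split leaves one group empty; consider fallback_median=True"
        )
    return labels, cut


def km_logrank(labels: np.ndarray, clinical: pd.DataFrame) -> dict:
    """Log-rank test between two labelled groups plus KM step curves.

    Returns ``{"p": ..., "statistic": ..., "curves": {label: DataFrame}}``
    where each curve is a step-function table (time, survival).
    """
    labels = np.asarray(labels)
    time = clinical["time"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    if len(labels) != len(clinical):
        raise ValueError("labels must align with clinical rows")
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("need exactly two non-empty groups")
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank undefined")
    mask = labels == groups[1]
    res = logrank_test(time[mask], time[~mask], event[mask], event[~mask])
    curves = {}
    for grp in groups:
        sel = labels == grp
        km = KaplanMeierFitter()
        km.fit(time[sel], event[sel], label=str(grp))
        sf = km.survival_function_
        curves[int(grp)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return {"p": float(res.p_value), "statistic": float(res.test_statistic),
            "curves": curves}


def annotation_correlation(
    cls_matrix: pd.DataFrame, annotation: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of each lineage's CLS with a per-sample scalar.

    Computed on the sample intersection; lineages are returned ranked by
    r, descending (rank 1 = most positively correlated).
    """
    shared = cls_matrix.index.intersection(annotation.dropna().index)
    if len(shared) < 3:
        raise ValueError("need >= 3 overlapping samples")
    ann = annotation.loc[shared].to_numpy(dtype=float)
    if np.std(ann) == 0:
        raise ValueError("annotation has zero variance")
    rows = []
    for lineage in cls_matrix.columns:
        r, p = stats.pearsonr(cls_matrix.loc[shared, lineage].to_numpy(), ann)
        rows.append((lineage, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["lineage", "r", "p"]).set_index("lineage")
    out = out.sort_values("r", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    out["n_used"] = len(shared)
    return out


def rank_enrichment(
    ranked: pd.DataFrame, subtype_members: list[str], exact_max_n: int = 20
) -> dict:
    """Rank-sum enrichment of a lineage subtype within a correlation ranking.

    Tests whether the subtype members' correlation coefficients sit
    higher (side ``"top"``) or lower (``"bottom"``) than the background of
    all other lineages, via a one-sided Wilcoxon rank-sum test on each
    side; the reported side is the smaller p. Exact enumeration is used
    when both groups have <= ``exact_max_n`` members, the normal
    approximation with continuity correction otherwise.
    """
    members = [m for m in subtype_members if m in ranked.index]
    others = [l for l in ranked.index if l not in set(subtype_members)]
    if not members:
        raise ValueError("subtype has no members in the ranking")
    if not others:
        raise ValueError("subtype covers every lineage; no background")
    x = ranked.loc[members, "r"].to_numpy()
    y = ranked.loc[others, "r"].to_numpy()
    method = "exact" if max(len(x), len(y)) <= exact_max_n else "asymptotic"
    p_top = stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    p_bottom = stats.mannwhitneyu(x, y, alternative="less", method=method).pvalue
    if p_top <= p_bottom:
        return {"p": float(p_top), "side": "top", "n_subtype": len(x),
                "n_background": len(y), "method": method}
    return {"p": float(p_bottom), "side": "bottom", "n_subtype": len(x),
            "n_background": len(y), "method": method}


def li_group_test(cls: pd.Series, li_scores: pd.Series) -> dict:
    """Compare CLS between high and low lymphocytic-infiltration groups.

    Samples are dichotomized about the median LI score; CLS means of the
    two groups are compared with a two-sided Welch t-test.
    """
    shared = cls.index.intersection(li_scores.dropna().index)
    li = li_scores.loc[shared].to_numpy(dtype=float)
    vals = cls.loc[shared].to_numpy(dtype=float)
    cut = np.median(li)
    high = vals[li > cut]
    low = vals[li <= cut]
    if len(high) < 3 or len(low) < 3:
        raise ValueError("degenerate median split: need >= 3 samples per group")
    t, p = stats.ttest_ind(high, low, equal_var=False)
    return {"t": float(t), "p": float(p), "mean_high": float(high.mean()),
            "mean_low": float(low.mean()), "n_high": len(high), "n_low": len(low)}


def best_match_profile(
    query: pd.Series, panel: pd.DataFrame, min_shared: int = 100
) -> pd.DataFrame:
    """Rank panel profiles by Pearson correlation with a query z-profile.

    Used to map a lineage profiled on one platform/species onto its
    closest counterpart in another panel, over the shared gene space.
    """
    shared = query.dropna().index.intersection(panel.index)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared genes (< {min_shared}); "
            "cannot match profiles reliably"
        )
    q = query.loc[shared].to_numpy(dtype=float)
    rows = []
    for col in panel.columns:
        r, _ = stats.pearsonr(q, panel.loc[shared, col].to_numpy(dtype=float))
        rows.append((col, float(r)))
    out = pd.DataFrame(rows, columns=["lineage", "r"]).set_index("lineage")
    out = out.sort_values("r", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    out["n_shared"] = len(shared)
    return out
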