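"""Cohort statistics: group comparisons, co-occurrence, regression, ROC,
Kaplan-Meier, log-rank and Cox proportional hazards.

Conventions: two-sided tests throughout; pooled-variance Student's t by
default (Welch behind a flag); Fisher exact p by the point-probability
method; Benjamini-Hochberg for multiplicity; Efron tie handling for Cox.
Model building follows a univariate screen — covariates with p < 0.05 enter
the multivariable model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "PairAssociation",
    "bh_adjust",
    "compare_scores_by_alteration",
    "fisher_cooccurrence",
    "component_relation",
    "roc_auc",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_univariate_then_multivariable",
]


@dataclass(frozen=True)
class GroupComparison:
    gene: str
    mean_altered: float
    mean_wild: float
    t_stat: float
    p_value: float
    p_adjusted: float | None
    direction: str  # "positive" | "negative"


@dataclass(frozen=True)
class PairAssociation:
    gene_a: str
    gene_b: str
    table: tuple  # ((both, a_only), (b_only, neither))
    direction: str  # "co_occurrence" | "exclusivity"
    p_value: float
    p_adjusted: float | None


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_scores_by_alteration(
    scores: pd.Series, alterations: pd.DataFrame, welch: bool = False
) -> list[GroupComparison]:
    """Per-gene two-sided t test of GI/HRD scores in altered vs wild-type
    samples, BH-adjusted across genes.

    Genes with fewer than two samples in either group are skipped.
    """
    scores = scores.loc[alterations.index]
    results: list[GroupComparison] = []
    for gene in alterations.columns:
        mask = alterations[gene].astype(bool)
        a, w = scores[mask].to_numpy(float), scores[~mask].to_numpy(float)
        if len(a) < 2 or len(w) < 2:
            continue
        t, p = sps.ttest_ind(a, w, equal_var=not welch)
        if np.isnan(t):  # zero variance in both groups
            t, p = 0.0, 1.0
        results.append(
            GroupComparison(
                gene=gene,
                mean_altered=float(a.mean()),
                mean_wild=float(w.mean()),
                t_stat=float(t),
                p_value=float(p),
                p_adjusted=None,
                direction="positive" if a.mean() >= w.mean() else "negative",
            )
        )
    if results:
        adj = bh_adjust([r.p_value for r in results])
        results = [
            GroupComparison(r.gene, r.mean_altered, r.mean_wild, r.t_stat, r.p_value, float(q), r.direction)
            for r, q in zip(results, adj)
        ]
    return results


def fisher_cooccurrence(alterations: pd.DataFrame) -> list[PairAssociation]:
    """Pairwise co-occurrence / mutual exclusivity of gene alterations.

    Each gene pair gets a 2x2 table, a two-sided Fisher exact p, and a
    direction from the odds ratio; constant columns are skipped.  BH is
    applied across all tested pairs.
    """
    genes = [g for g in alterations.columns if alterations[g].nunique() > 1]
    results: list[PairAssociation] = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            a = alterations[ga].astype(bool)
            b = alterations[gb].astype(bool)
            both = int((a & b).sum())
            a_only = int((a & ~b).sum())
            b_only = int((~a & b).sum())
            neither = int((~a & ~b).sum())
            table = np.array([[both, a_only], [b_only, neither]])
            odds, p = sps.fisher_exact(table, alternative="two-sided")
            direction = "co_occurrence" if both * neither >= a_only * b_only else "exclusivity"
            results.append(
                PairAssociation(ga, gb, ((both, a_only), (b_only, neither)), direction, float(p), None)
            )
    if results:
        adj = bh_adjust([r.p_value for r in results])
        results = [
            PairAssociation(r.gene_a, r.gene_b, r.table, r.direction, r.p_value, float(q))
            for r, q in zip(results, adj)
        ]
    return results


def component_relation(results_table: pd.DataFrame) -> pd.DataFrame:
    """OLS of the GI/HRD score on each component (LOH, TAI, LST).

    ``results_table`` needs columns loh/tai/lst/gi_score; returns one row
    per component with slope, intercept and R^2.  Zero-variance components
    are skipped.
    """
    if len(results_table) < 3:
        raise ValueError("component_relation requires at least 3 samples")
    y = results_table["gi_score"].to_numpy(float)
    rows = []
    for comp in ("loh", "tai", "lst"):
        x = results_table[comp].to_numpy(float)
        if np.allclose(x, x[0]):
            continue
        fit = sps.linregress(x, y)
        rows.append(
            {
                "component": comp,
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r_squared": float(fit.rvalue) ** 2,
                "p_value": float(fit.pvalue),
            }
        )
    return pd.DataFrame(rows)


def roc_auc(labels, scores) -> tuple[float, pd.DataFrame]:
    """AUC (Mann-Whitney formulation; ties count one half) plus the ROC curve."""
    labels = np.asarray(list(labels), dtype=int)
    scores = np.asarray(list(scores), dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


def km_estimate(times, events, label: str = "KM") -> pd.DataFrame:
    """Product-limit survival curve: time, at-risk count, survival probability."""
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_[label]
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(float),
            "at_risk": table["at_risk"].to_numpy(int),
            "observed": table["observed"].to_numpy(int),
            "survival": surv.reindex(table.index).to_numpy(float),
        }
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square statistic and p across two or more groups."""
    res = multivariate_logrank_test(
        np.asarray(list(times), dtype=float),
        np.asarray(list(groups)),
        np.asarray(list(events), dtype=int),
    )
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    df: pd.DataFrame, time_col: str, event_col: str, variables: list[str]
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) for the given covariates.

    Returns one row per covariate: coefficient, HR, 95% CI, p.  Constant
    covariates and datasets without events are rejected; non-convergence
    surfaces as a diagnostic error from the optimizer.
    """
    data = df[[time_col, event_col] + list(variables)].dropna()
    if data[event_col].sum() == 0:
        raise ValueError("cox_fit: no events observed (all rows censored)")
    for v in variables:
        if data[v].nunique() <= 1:
            raise ValueError(f"cox_fit: covariate {v!r} is constant")
    cph = CoxPHFitter()
    cph.fit(data, duration_col=time_col, event_col=event_col)
    summary = cph.summary
    return pd.DataFrame(
        {
            "variable": summary.index,
            "coef": summary["coef"].to_numpy(float),
            "hr": summary["exp(coef)"].to_numpy(float),
            "hr_lower95": summary["exp(coef) lower 95%"].to_numpy(float),
            "hr_upper95": summary["exp(coef) upper 95%"].to_numpy(float),
            "p_value": summary["p"].to_numpy(float),
        }
    ).reset_index(drop=True)


def cox_univariate_then_multivariable(
    df: pd.DataFrame,
    time_col: str,
    event_col: str,
    variables: list[str],
    entry_p: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate Cox screen per variable, then one multivariable model over
    the variables with univariate p below ``entry_p``."""
    uni_rows = []
    for v in variables:
        try:
            row = cox_fit(df, time_col, event_col, [v]).iloc[0]
        except ValueError:
            continue
        uni_rows.append(row)
    univariate = pd.DataFrame(uni_rows).reset_index(drop=True)
    selected = (
        univariate.loc[univariate["p_value"] < entry_p, "variable"].tolist()
        if len(univariate)
        else []
    )
    if len(selected) >= 1:
        multivariable = cox_fit(df, time_col, event_col, selected)
    else:
        multivariable = univariate.iloc[0:0]
    return univariate, multivariable
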