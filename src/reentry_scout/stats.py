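"""Cohort statistics: group comparisons, Cox proportional-hazards models,
sensitivity-targeted ROC cutoffs, and Kaplan-Meier survival.

The analysis mirrors a standard arrhythmia risk-stratification workflow:
the endpoint is the first appropriate device therapy or sustained VT;
continuous variables are compared with the Mann-Whitney U test and
categorical ones with the Fisher exact test; univariable and multivariable
Cox regressions quantify hazard ratios on interpretable scales (e.g. per
10 cm^2 of interface area); cutoffs at a target sensitivity dichotomize
the cohort for Kaplan-Meier curves with log-rank tests.  All tests are
two-sided and no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_EVENT_COL = "event"
DEFAULT_TIME_COL = "time_years"


@dataclass
class GroupComparison:
    variable: str
    kind: str
    statistic: float
    p_value: float
    summary_event: str
    summary_no_event: str


@dataclass
class HazardResult:
    """A hazard ratio on a stated per-unit scale with Wald CI and p."""

    variable: str
    scale: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    flag: Optional[str] = None


def _split_groups(table: pd.DataFrame, variable: str, event_col: str):
    g1 = table.loc[table[event_col] == 1, variable].to_numpy(dtype=float)
    g0 = table.loc[table[event_col] == 0, variable].to_numpy(dtype=float)
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both outcome groups must be non-empty")
    return g1, g0


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    kind: str = "continuous",
    event_col: str = DEFAULT_EVENT_COL,
) -> GroupComparison:
    """Two-group comparison by outcome status.

    Continuous variables use the Mann-Whitney U test (exact when both
    groups have <= 20 observations and no ties, normal approximation with
    tie correction otherwise) and are summarized as mean +/- SD.
    Categorical (binary) variables use the Fisher exact test on the 2x2
    table and are summarized as counts.
    """
    g1, g0 = _split_groups(table, variable, event_col)
    if kind == "continuous":
        exact = len(g1) <= 20 and len(g0) <= 20
        method = "exact" if exact and len(np.unique(np.r_[g1, g0])) == len(g1) + len(g0) else "asymptotic"
        # no continuity correction in the normal approximation, so exactly
        # symmetric samples give p = 1 rather than ~0.9
        res = sps.mannwhitneyu(
            g1, g0, alternative="two-sided", method=method, use_continuity=False
        )
        return GroupComparison(
            variable=variable,
            kind=kind,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            summary_event=f"{g1.mean():.2f} +/- {g1.std(ddof=1):.2f}",
            summary_no_event=f"{g0.mean():.2f} +/- {g0.std(ddof=1):.2f}",
        )
    if kind == "categorical":
        tab = np.array(
            [
                [(g1 == 1).sum(), (g1 != 1).sum()],
                [(g0 == 1).sum(), (g0 != 1).sum()],
            ]
        )
        odds, p = sps.fisher_exact(tab, alternative="two-sided")
        return GroupComparison(
            variable=variable,
            kind=kind,
            statistic=float(odds),
            p_value=float(p),
            summary_event=f"{tab[0, 0]}/{tab[0].sum()}",
            summary_no_event=f"{tab[1, 0]}/{tab[1].sum()}",
        )
    raise ValueError("kind must be 'continuous' or 'categorical'")


def cox_fit(
    table: pd.DataFrame,
    variables: Sequence[str],
    scales: Optional[dict] = None,
    mode: str = "univariable",
    event_col: str = DEFAULT_EVENT_COL,
    time_col: str = DEFAULT_TIME_COL,
):
    """Cox proportional-hazards regression (Efron tie handling).

    mode "univariable" fits one single-covariate model per variable; mode
    "multivariable" fits one joint model over all supplied variables.
    `scales` maps variable -> per-unit multiplier (e.g. 10 for a hazard
    ratio per 10 cm^2); hazard ratios are reported on that scale.
    Degenerate covariates (zero variance) and non-converged fits are
    returned flagged rather than silently dropped.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    scales = scales or {}
    n_events = int(table[event_col].sum())
    if n_events < 5:
        warnings.warn(f"only {n_events} events; hazard estimates are unstable")

    def _fit_one(cols):
        df = table[[*cols, event_col, time_col]].dropna().copy()
        dropped = len(table) - len(df)
        if dropped:
            warnings.warn(f"dropped {dropped} subjects with missing values")
        for c in cols:
            df[c] = df[c] / scales.get(c, 1.0)
        cph = CoxPHFitter()
        cph.fit(df, duration_col=time_col, event_col=event_col)
        return cph

    def _null_result(v):
        return HazardResult(
            variable=v, scale=scales.get(v, 1.0), hazard_ratio=1.0,
            ci_low=1.0, ci_high=1.0, p_value=1.0, n_events=n_events,
            flag="degenerate",
        )

    results = []
    if mode == "univariable":
        groups = [[v] for v in variables]
    elif mode == "multivariable":
        groups = [list(variables)]
    else:
        raise ValueError("mode must be 'univariable' or 'multivariable'")

    for cols in groups:
        live = [v for v in cols if table[v].nunique() > 1]
        for v in cols:
            if v not in live:
                results.append(_null_result(v))
        if not live:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = _fit_one(live)
        except (ConvergenceError, ValueError) as exc:
            for v in live:
                r = _null_result(v)
                r.flag = f"non-convergence: {exc}"
                results.append(r)
            continue
        summ = cph.summary
        for v in live:
            results.append(
                HazardResult(
                    variable=v,
                    scale=scales.get(v, 1.0),
                    hazard_ratio=float(summ.loc[v, "exp(coef)"]),
                    ci_low=float(summ.loc[v, "exp(coef) lower 95%"]),
                    ci_high=float(summ.loc[v, "exp(coef) upper 95%"]),
                    p_value=float(summ.loc[v, "p"]),
                    n_events=n_events,
                )
            )
    return results


def select_multivariable(
    table: pd.DataFrame,
    candidates: Sequence[str],
    clinical: Sequence[str] = ("lvef_pct", "lvedv_ml"),
    alpha: float = 0.05,
    event_col: str = DEFAULT_EVENT_COL,
    time_col: str = DEFAULT_TIME_COL,
    scales: Optional[dict] = None,
):
    """Compose the multivariable model: univariably significant candidates
    (p < alpha) plus the standard clinical covariates."""
    uni = cox_fit(table, candidates, scales=scales, mode="univariable",
                  event_col=event_col, time_col=time_col)
    keep = [r.variable for r in uni if r.flag is None and r.p_value < alpha]
    for c in clinical:
        if c in table.columns and c not in keep:
            keep.append(c)
    return uni, keep


def roc_cutoff_at_sensitivity(
    table: pd.DataFrame,
    variable: str,
    sensitivity_target: float = 0.90,
    event_col: str = DEFAULT_EVENT_COL,
):
    """Largest cutoff t keeping the event-detection sensitivity >= target.

    Subjects with value > t are called high-risk.  The variable is assumed
    higher-is-riskier; if the AUC orientation disagrees a warning is
    emitted (the cutoff is still computed on the raw scale).  Candidate
    thresholds are the observed values plus one sentinel below the
    minimum, so "all events above cutoff" is always achievable.
    """
    if not 0 < sensitivity_target <= 1:
        raise ValueError("sensitivity_target must be in (0, 1]")
    vals = table[variable].to_numpy(dtype=float)
    ev = table[event_col].to_numpy(dtype=int)
    ev_vals = vals[ev == 1]
    if len(ev_vals) == 0:
        raise ValueError("no events; cannot place a sensitivity cutoff")
    try:
        from sklearn.metrics import roc_auc_score

        if len(np.unique(ev)) == 2 and roc_auc_score(ev, vals) < 0.5:
            warnings.warn(
                f"{variable}: higher values appear protective (AUC < 0.5); "
                "cutoff still assumes higher = riskier"
            )
    except ImportError:  # pragma: no cover - sklearn is a soft dependency here
        pass
    cands = np.unique(vals)
    cands = np.concatenate([[cands.min() - 1.0], cands])
    ok = [t for t in cands if (ev_vals > t).mean() >= sensitivity_target]
    return float(max(ok))


@dataclass
class KMResult:
    """Two-group Kaplan-Meier estimate with a log-rank comparison."""

    curves: dict  # label -> DataFrame(time, survival, at_risk)
    chi_sq: float
    p_value: float

    def survival_at(self, label, t: float) -> float:
        df = self.curves[label]
        s = 1.0
        for tt, sv in zip(df["time"], df["survival"]):
            if tt <= t:
                s = sv
            else:
                break
        return float(s)


def kaplan_meier(
    table: pd.DataFrame,
    group_col: str,
    event_col: str = DEFAULT_EVENT_COL,
    time_col: str = DEFAULT_TIME_COL,
) -> KMResult:
    """Product-limit survival curves per group and the two-group log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    labels = sorted(table[group_col].unique())
    if len(labels) != 2:
        raise ValueError("kaplan_meier expects exactly two groups")
    curves = {}
    subsets = {}
    for lab in labels:
        sub = table[table[group_col] == lab]
        if len(sub) == 0:
            raise ValueError(f"group {lab!r} is empty")
        subsets[lab] = sub
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["at_risk"] = [
            int((sub[time_col] >= t).sum()) for t in sf["time"]
        ]
        curves[lab] = sf
    a, b = labels
    res = logrank_test(
        subsets[a][time_col], subsets[b][time_col],
        event_observed_A=subsets[a][event_col],
        event_observed_B=subsets[b][event_col],
    )
    return KMResult(
        curves=curves,
        chi_sq=float(res.test_statistic),
        p_value=float(res.p_value),
    )
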