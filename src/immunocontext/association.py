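"""Endpoint derivation and biomarker association models.

Implements the association stage of the pipeline: overall response rate
(ORR) via multivariable logistic regression (odds ratios with Wald 95% CI),
progression-free and overall survival via Cox proportional-hazards models
(Efron tie handling; OS models additionally adjust for subsequent
immunotherapy), Kaplan-Meier curves with median/quartile times, and the
auxiliary chi-square and Kruskal-Wallis tests.

Categorical terms are dummy-coded against explicit reference levels chosen
so that reported contrasts read in the conventional direction: the
immune-hostile combination group (group 3, low CD8 / high CD163) and the
"low"/"negative"/"no" levels are baselines.  Rows with missing values in
any model column are dropped (complete-case), and the n actually used is
reported.  No multiple-testing adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError

RESPONDER_CATEGORIES = ("CR", "PR")

#: Default reference level per categorical column (first sorted level
#: otherwise).  Chosen so estimated contrasts are "favorable vs hostile".
DEFAULT_REFS: dict[str, object] = {
    "group": 3, "cd8_i": "low", "cd163_i": "low",
    "cd8_p": "low", "cd163_p": "low",
    "stage": "other", "ecog_ps": 0, "ldh_elevated": 0,
    "treatment": "BRAFi", "subsequent_it": "no",
    "pdl1_pos": False, "pdl2_pos": False, "bcat_over": False,
}

DEFAULT_COVARIATES = ("stage", "ecog_ps", "ldh_elevated", "treatment")


def derive_endpoints(records: pd.DataFrame) -> pd.DataFrame:
    """Validate endpoint columns and add the ORR responder indicator.

    Responder means best response CR or PR; NE responses yield a missing
    indicator and are excluded from response models.  Durations must be
    non-negative and event flags binary.
    """
    out = records.copy()
    for col in ("pfs_time_months", "os_time_months"):
        if col in out.columns:
            t = out[col].astype(float)
            if (t.dropna() < 0).any():
                raise DataError(f"negative durations in {col}")
    for col in ("pfs_event", "os_event"):
        if col in out.columns:
            e = out[col].dropna()
            if not e.isin([0, 1]).all():
                raise DataError(f"{col} must be 0/1")
    if "response" in out.columns:
        resp = out["response"]
        known = {"CR", "PR", "SD", "PD", "NE"}
        bad = resp.dropna()[~resp.dropna().isin(known)]
        if len(bad):
            raise DataError(f"unknown response value {bad.iloc[0]!r}")
        out["responder"] = pd.Series(
            np.where(resp.isin(RESPONDER_CATEGORIES), 1.0,
                     np.where(resp.isin(["SD", "PD"]), 0.0, np.nan)),
            index=out.index)
    return out


def durations_from_dates(start, event_date, censor_date,
                         days_per_month: float = 30.44
                         ) -> tuple[float, int]:
    """Duration in months and event flag from dates.

    Event when ``event_date`` is present; otherwise censored at
    ``censor_date`` (last disease assessment).
    """
    start = pd.Timestamp(start)
    if event_date is not None and not pd.isna(event_date):
        delta, flag = pd.Timestamp(event_date) - start, 1
    elif censor_date is not None and not pd.isna(censor_date):
        delta, flag = pd.Timestamp(censor_date) - start, 0
    else:
        raise DataError("need an event date or a censoring date")
    months = delta.days / days_per_month
    if months < 0:
        raise DataError("negative duration")
    return months, flag


def cohort_summary(records: pd.DataFrame,
                   columns: list[str] | None = None) -> pd.DataFrame:
    """Counts and percentages per categorical variable.

    Denominators are the evaluable (non-missing, non-"NE") patients of each
    variable; percentages are rounded to one decimal.
    """
    if not len(records):
        raise DataError("empty cohort")
    if columns is None:
        columns = [c for c in records.columns
                   if records[c].dtype == object or
                   records[c].nunique(dropna=True) <= 10]
    rows = []
    for col in columns:
        vals = records[col]
        vals = vals[vals.notna() & (vals.astype(str) != "NE")]
        denom = len(vals)
        if denom == 0:
            continue
        for level, count in vals.value_counts().sort_index().items():
            rows.append({"variable": col, "level": level,
                         "count": int(count), "denominator": denom,
                         "pct": round(100.0 * count / denom, 1)})
    return pd.DataFrame(rows)


# -- model results ---------------------------------------------------------

@dataclass(frozen=True)
class ModelResult:
    """A fitted association model on the ratio (OR/HR) scale."""

    model: str                      # "logistic" or "cox"
    endpoint: str                   # "response", "pfs" or "os"
    table: pd.DataFrame             # index: term labels; estimate, ci, p
    n: int
    n_events: int | None = None
    estimable: bool = True
    message: str = ""

    def estimate(self, label: str) -> float:
        return float(self.table.loc[label, "estimate"])

    def ci(self, label: str) -> tuple[float, float]:
        row = self.table.loc[label]
        return float(row["ci_low"]), float(row["ci_high"])


def _dummy_code(df: pd.DataFrame, col: str,
                refs: dict | None) -> pd.DataFrame:
    """Dummy-code one column against its reference level."""
    refs = {**DEFAULT_REFS, **(refs or {})}
    levels = sorted(df[col].dropna().unique(), key=str)
    ref = refs.get(col, levels[0] if levels else None)
    out = pd.DataFrame(index=df.index)
    for lvl in levels:
        if lvl == ref:
            continue
        out[f"{col}={lvl}"] = (df[col] == lvl).astype(float)
    return out


def build_design(records: pd.DataFrame, term: str,
                 covariates=DEFAULT_COVARIATES,
                 refs: dict | None = None) -> pd.DataFrame:
    """Complete-case design matrix with the biomarker term first."""
    cols = [term, *covariates]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise DataError(f"missing model columns: {missing}")
    sub = records[cols].dropna()
    parts = [_dummy_code(sub, c, refs) for c in cols]
    X = pd.concat(parts, axis=1)
    return X.loc[:, X.std() > 0]  # drop constant columns


def fit_response_model(records: pd.DataFrame, term: str = "group",
                       covariates=DEFAULT_COVARIATES,
                       refs: dict | None = None) -> ModelResult:
    """Multivariable logistic model of the responder indicator.

    Reports odds ratios with Wald 95% CIs for every non-reference level of
    ``term`` and the covariates.  Complete separation or non-convergence is
    reported as a non-estimable result rather than raised.
    """
    df = records if "responder" in records.columns else derive_endpoints(records)
    keep = df["responder"].notna()
    df = df.loc[keep]
    X = build_design(df, term, covariates, refs)
    y = df.loc[X.index, "responder"].astype(float)
    n = len(X)
    if y.nunique() < 2:
        return ModelResult("logistic", "response", _empty_table(), n,
                           estimable=False,
                           message="single outcome class present")
    Xc = sm.add_constant(X, prepend=True)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = fit.params.drop("const")
        if not np.isfinite(fit.bse).all() or np.abs(params).max() > 15:
            raise ValueError("separation suspected")
        conf = fit.conf_int().drop(index="const")
        table = pd.DataFrame({
            "estimate": np.exp(params),
            "ci_low": np.exp(conf[0]),
            "ci_high": np.exp(conf[1]),
            "p": fit.pvalues.drop("const"),
        })
        return ModelResult("logistic", "response", table, n,
                           n_events=int(y.sum()))
    except Exception as exc:  # separation / convergence failure
        return ModelResult("logistic", "response", _empty_table(), n,
                           estimable=False,
                           message=f"non-estimable: {exc}")


def fit_survival_model(records: pd.DataFrame, endpoint: str = "os",
                       term: str = "group",
                       covariates=DEFAULT_COVARIATES,
                       refs: dict | None = None,
                       add_subsequent_it_for_os: bool = True) -> ModelResult:
    """Multivariable Cox model of PFS or OS (Efron ties).

    OS models adjust additionally for subsequent immunotherapy unless
    disabled.  Returns hazard ratios with Wald 95% CIs.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    endpoint = endpoint.lower()
    if endpoint not in ("pfs", "os"):
        raise DataError(f"endpoint must be 'pfs' or 'os', got {endpoint!r}")
    covs = list(covariates)
    if (endpoint == "os" and add_subsequent_it_for_os
            and "subsequent_it" in records.columns
            and "subsequent_it" not in covs):
        covs.append("subsequent_it")
    time_col, event_col = f"{endpoint}_time_months", f"{endpoint}_event"
    for c in (time_col, event_col):
        if c not in records.columns:
            raise DataError(f"missing column {c}")
    X = build_design(records, term, covs, refs)
    df = pd.concat([X, records.loc[X.index, [time_col, event_col]]], axis=1)
    df = df.dropna()
    n = len(df)
    n_events = int(df[event_col].sum())
    if n_events < 1:
        return ModelResult("cox", endpoint, _empty_table(), n, 0,
                           estimable=False, message="no events")
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col=time_col, event_col=event_col)
        conf = cph.confidence_intervals_
        table = pd.DataFrame({
            "estimate": cph.hazard_ratios_,
            "ci_low": np.exp(conf.iloc[:, 0]),
            "ci_high": np.exp(conf.iloc[:, 1]),
            "p": cph.summary["p"],
        })
        table.index.name = None
        return ModelResult("cox", endpoint, table, n, n_events)
    except ConvergenceError as exc:
        return ModelResult("cox", endpoint, _empty_table(), n, n_events,
                           estimable=False,
                           message=f"non-estimable: {exc}")


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["estimate", "ci_low", "ci_high", "p"])


# -- Kaplan-Meier ----------------------------------------------------------

@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve with quantile times.

    Quantile convention: the q-quantile time is the earliest observed time
    with S(t) <= 1 - q; ``inf`` means not reached.
    """

    endpoint: str
    curve: pd.DataFrame          # time, survival, at_risk
    median: float
    q25: float                   # first t with S(t) <= 0.75
    q75: float                   # first t with S(t) <= 0.25
    n: int
    n_events: int


def km_estimate(records: pd.DataFrame, endpoint: str = "os") -> KMEstimate:
    """Kaplan-Meier estimate of PFS or OS."""
    from lifelines import KaplanMeierFitter
    from lifelines.utils import qth_survival_time

    endpoint = endpoint.lower()
    time_col, event_col = f"{endpoint}_time_months", f"{endpoint}_event"
    sub = records[[time_col, event_col]].dropna()
    t = sub[time_col].astype(float)
    e = sub[event_col].astype(int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_.iloc[:, 0]
    curve = pd.DataFrame({
        "time": sf.index.to_numpy(dtype=float),
        "survival": sf.to_numpy(),
        "at_risk": kmf.event_table["at_risk"].reindex(sf.index).to_numpy(),
    })
    return KMEstimate(
        endpoint=endpoint, curve=curve,
        median=float(qth_survival_time(0.5, sf)),
        q25=float(qth_survival_time(0.75, sf)),
        q75=float(qth_survival_time(0.25, sf)),
        n=len(sub), n_events=int(e.sum()))


# -- auxiliary tests -------------------------------------------------------

@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p: float
    dof: int
    low_expected: bool   # any expected cell count < 1


def chi_square_assoc(table, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of a two-way contingency table.

    Continuity correction is off by default.  Expected cell counts below 1
    are flagged rather than raised.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DataError("need a 2-way contingency table")
    res = stats.chi2_contingency(arr, correction=correction)
    return ChiSquareResult(statistic=float(res.statistic), p=float(res.pvalue),
                           dof=int(res.dof),
                           low_expected=bool((res.expected_freq < 1).any()))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across >= 2 groups.

    All-identical values across groups give H = 0, p = 1.
    """
    if len(groups) == 1:
        groups = tuple(groups[0])
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise DataError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
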