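"""Survival evaluation and general statistics.

Classifier evaluation follows the standard route for prognostic-signature
studies: an unadjusted Cox proportional-hazards model with a single binary
covariate (high vs low risk), a Wald test of whether the hazard ratio
differs from unity, and Kaplan-Meier curves.  The binary Cox fit is a 1-D
Newton maximizer of the Efron-corrected partial likelihood, written here
because ensemble-size sweeps and per-gene screens need tens of thousands of
fits; lifelines provides the Kaplan-Meier estimator, the continuous-covariate
fit, and (in the test suite) an independent cross-check of the binary fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, InputError
from .scoring import RiskClassification

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in consistent units, event in {0, 1}."""

    patient_id: str
    time: float
    event: int


def survival_frame(records) -> pd.DataFrame:
    """Validate survival data into a DataFrame indexed by patient id.

    Accepts a DataFrame with columns ``time`` and ``event`` (index =
    patient id) or an iterable of :class:`SurvivalRecord`.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if not {"time", "event"} <= set(df.columns):
            raise InputError("survival table must have 'time' and 'event' columns")
    else:
        recs = list(records)
        df = pd.DataFrame(
            {"time": [r.time for r in recs], "event": [r.event for r in recs]},
            index=pd.Index([r.patient_id for r in recs], name="patient_id"),
        )
    if df.empty:
        raise InputError("survival table is empty")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate patient ids in survival table: {dupes}")
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy()
    if not np.isfinite(time).all() or (time <= 0).any():
        raise InputError("survival times must be finite and > 0")
    if not np.isin(event, (0, 1)).all():
        raise InputError("event indicator must be 0 or 1")
    df["time"] = time
    df["event"] = event.astype(int)
    return df[["time", "event"]]


@dataclass
class CoxResult:
    """Hazard ratio of high vs low risk from a univariate Cox model.

    ``estimable`` is False (all statistics NaN) when the fit is undefined:
    one group empty, no events, or a monotone partial likelihood.
    """

    hr: float
    log_hr: float
    log_hr_se: float
    wald_p: float
    ci95: tuple[float, float]
    n_events: int
    n_high: int
    n_low: int
    estimable: bool = True
    reason: str | None = None
    ties: str = "efron"

    @classmethod
    def not_estimable(cls, reason: str, n_events=0, n_high=0, n_low=0) -> "CoxResult":
        nan = float("nan")
        return cls(
            hr=nan, log_hr=nan, log_hr_se=nan, wald_p=nan, ci95=(nan, nan),
            n_events=int(n_events), n_high=int(n_high), n_low=int(n_low),
            estimable=False, reason=reason,
        )


def _efron_terms(time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Constant structure of the Efron partial likelihood for binary x.

    For each distinct event time k with d_k events (d1_k of them in the
    x=1 group) and risk-set counts (n0_k, n1_k), the likelihood involves
    denominators A_{k,l} = a0 + a1*e^b with
        a0 = n0_k - (l/d_k) d0_k,  a1 = n1_k - (l/d_k) d1_k,  l = 0..d_k-1.
    Returns (a0, a1, D1) flattened over (k, l); these do not depend on b.
    """
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], x[order]
    ev_times = np.unique(t[e == 1])
    # counts at risk (t >= tau): suffix sums over the sorted arrays
    n_total = len(t)
    idx = np.searchsorted(t, ev_times, side="left")
    csum1 = np.concatenate([[0], np.cumsum(g)])
    n1 = csum1[-1] - csum1[idx]
    n_at = n_total - idx
    n0 = n_at - n1
    # tied events at each event time, split by group
    d = np.zeros(len(ev_times), dtype=float)
    d1 = np.zeros(len(ev_times), dtype=float)
    pos = np.searchsorted(ev_times, t[e == 1])
    np.add.at(d, pos, 1.0)
    np.add.at(d1, pos, g[e == 1].astype(float))
    d0 = d - d1
    # flatten (k, l)
    reps = d.astype(int)
    frac = np.concatenate([np.arange(r) / r for r in reps]) if len(reps) else np.array([])
    a0 = np.repeat(n0.astype(float), reps) - frac * np.repeat(d0, reps)
    a1 = np.repeat(n1.astype(float), reps) - frac * np.repeat(d1, reps)
    return a0, a1, float(d1.sum()), float(d0.sum())


def _efron_fit(time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Newton-Raphson on the 1-D Efron partial log-likelihood.

    Returns (coef, se) or raises ValueError with a reason string.
    """
    a0, a1, events1, events0 = _efron_terms(time, event, x)
    if events1 == 0 or events0 == 0:
        raise ValueError("all events in one group (monotone likelihood)")

    def loglik(b: float) -> float:
        return b * events1 - np.log(a0 + a1 * np.exp(b)).sum()

    b = 0.0
    ll = loglik(b)
    for _ in range(100):
        eb = np.exp(b)
        u = a1 * eb / (a0 + a1 * eb)
        grad = events1 - u.sum()
        hess = -(u * (1.0 - u)).sum()
        if hess >= 0:  # flat likelihood: no information
            raise ValueError("non-identifiable (zero information)")
        step = -grad / hess
        # damped update, keep the likelihood increasing
        while abs(step) > 1e-12:
            b_new = b + step
            ll_new = loglik(b_new)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        b, ll = b + step, loglik(b + step)
        if abs(b) > 15:
            raise ValueError("non-convergence (diverging coefficient)")
        if abs(grad) < 1e-9 and abs(step) < 1e-8:
            break
    eb = np.exp(b)
    u = a1 * eb / (a0 + a1 * eb)
    info = (u * (1.0 - u)).sum()
    if info <= 0:
        raise ValueError("non-identifiable (zero information)")
    return float(b), float(1.0 / np.sqrt(info))


def fit_cox_binary(survival, group) -> CoxResult:
    """Univariate Cox PH fit of survival on a high/low risk grouping.

    ``group`` is a per-patient mapping to {"high", "low"} (a Series aligned
    to the survival table's patients).  The hazard ratio is oriented
    high-over-low.  Ties are handled with the Efron correction.  Degenerate
    inputs yield an explicit non-estimable :class:`CoxResult`, never an
    exception.
    """
    df = survival_frame(survival)
    group = pd.Series(group)
    if not df.index.isin(group.index).all():
        missing = df.index.difference(group.index).tolist()
        raise InputError(f"patients missing from group labels: {missing[:5]}")
    g = group.reindex(df.index)
    bad = set(g.unique()) - {"high", "low"}
    if bad:
        raise InputError(f"group labels must be 'high'/'low', got {sorted(bad)}")
    x = (g == "high").to_numpy().astype(float)
    n_high, n_low = int(x.sum()), int((1 - x).sum())
    n_events = int(df["event"].sum())
    if n_high == 0 or n_low == 0:
        return CoxResult.not_estimable("one group is empty", n_events, n_high, n_low)
    if n_events == 0:
        return CoxResult.not_estimable("no events observed", n_events, n_high, n_low)
    try:
        coef, se = _efron_fit(
            df["time"].to_numpy(), df["event"].to_numpy(), x
        )
    except ValueError as exc:
        return CoxResult.not_estimable(str(exc), n_events, n_high, n_low)
    z = coef / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    lo, hi = np.exp(coef - _Z975 * se), np.exp(coef + _Z975 * se)
    return CoxResult(
        hr=float(np.exp(coef)), log_hr=coef, log_hr_se=se, wald_p=p,
        ci95=(float(lo), float(hi)), n_events=n_events,
        n_high=n_high, n_low=n_low,
    )


def fit_cox_continuous(survival, covariate: pd.Series) -> CoxResult:
    """Univariate Cox PH fit on a continuous covariate (lifelines backend).

    Used to validate synthetic cohorts: the coefficient on the latent risk
    variable should recover the generating log-hazard beta.
    """
    from lifelines import CoxPHFitter

    df = survival_frame(survival)
    cov = pd.Series(covariate).reindex(df.index)
    if cov.isna().any():
        raise InputError("covariate missing for some patients")
    data = df.assign(covariate=cov.to_numpy(dtype=float))
    cph = CoxPHFitter()
    cph.fit(data, duration_col="time", event_col="event")
    coef = float(cph.params_["covariate"])
    se = float(cph.standard_errors_["covariate"])
    z = coef / se
    return CoxResult(
        hr=float(np.exp(coef)), log_hr=coef, log_hr_se=se,
        wald_p=float(2.0 * stats.norm.sf(abs(z))),
        ci95=(float(np.exp(coef - _Z975 * se)), float(np.exp(coef + _Z975 * se))),
        n_events=int(df["event"].sum()),
        n_high=0, n_low=0,
    )


def kaplan_meier(survival) -> pd.Series:
    """Product-limit survival estimate as a right-continuous step function.

    Returns S(t) indexed by time, starting at S(0) = 1.
    """
    from lifelines import KaplanMeierFitter

    df = survival_frame(survival)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    sf = kmf.survival_function_["KM_estimate"]
    sf.index.name = "time"
    sf.name = "survival"
    return sf


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TTestResult:
    t: float
    p: float
    df: int


def paired_t_test(x, y) -> TTestResult:
    """Two-sided paired Student's t-test on n-1 degrees of freedom."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired t-test needs two equal-length vectors")
    if len(x) < 2:
        raise InputError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateInputError("paired differences have zero variance")
    res = stats.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=len(x) - 1)


def spearman(x, y) -> float:
    """Spearman rank correlation with midrank ties; NaN on constant input."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise InputError("spearman needs two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def percent_agreement(a: RiskClassification, b: RiskClassification) -> float:
    """Percent of patients with identical labels (unclassified is a label)."""
    if set(a.labels.index) != set(b.labels.index):
        raise InputError("classifications cover different patient sets")
    bl = b.labels.reindex(a.labels.index)
    return float(100.0 * (a.labels == bl).mean())


def superior(a: CoxResult, b: CoxResult) -> int:
    """Compare two classifications by hazard-ratio point estimate.

    Returns 1 if a stratifies risk more strongly (higher HR), -1 if b does,
    0 on a tie.  Non-estimable results always lose to estimable ones.
    """
    if not a.estimable and not b.estimable:
        return 0
    if not b.estimable:
        return 1
    if not a.estimable:
        return -1
    if a.hr > b.hr:
        return 1
    if b.hr > a.hr:
        return -1
    return 0


@dataclass
class ClassificationEvaluation:
    """A classification's survival evaluation plus its group sizes."""

    source: str
    cox: CoxResult
    n_high: int
    n_low: int
    n_unclassified: int

    @property
    def pct_classified(self) -> float:
        n = self.n_high + self.n_low + self.n_unclassified
        return 100.0 * (self.n_high + self.n_low) / n if n else float("nan")


def evaluate_classification(
    rc: RiskClassification, survival
) -> ClassificationEvaluation:
    """Cox-evaluate a risk classification on its classified patients only."""
    df = survival_frame(survival)
    if not rc.labels.index.isin(df.index).all():
        missing = rc.labels.index.difference(df.index).tolist()
        raise InputError(f"patients missing from survival table: {missing[:5]}")
    counts = rc.counts()
    classified = rc.classified
    if counts["high"] == 0 or counts["low"] == 0:
        cox = CoxResult.not_estimable(
            "one risk group is empty", n_high=counts["high"], n_low=counts["low"]
        )
    else:
        cox = fit_cox_binary(df.loc[classified], rc.labels.loc[classified])
    return ClassificationEvaluation(
        source=rc.source, cox=cox,
        n_high=counts["high"], n_low=counts["low"],
        n_unclassified=counts["unclassified"],
    )
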