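"""Survival and association statistics.

Kaplan-Meier curves and the log-rank test are delegated to lifelines; the
Cox proportional-hazards model is fit here by Newton-Raphson on the partial
likelihood with Efron (default) or Breslow tie handling, which also exposes
the score test at beta = 0 (identical to the log-rank chi-square for a single
binary covariate without ties).  Contingency-table and two-sample tests wrap
scipy with the conventions documented per function.

Survival records are rows of a DataFrame with ``time`` (months, positive)
and ``event`` (1 = event, 0 = censored) columns plus covariates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    times: np.ndarray  # ascending observed times
    survival: np.ndarray  # S(t) at those times
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValidationError("survival function must be non-increasing")


@dataclass
class CoxModel:
    summary: pd.DataFrame  # index covariate; coef, hr, se, ci_low, ci_high, z, p
    log_likelihood: float
    converged: bool
    ties: str

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = group, columns = outcome (yes, no)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("counts must be non-negative")
        if self.total < 1:
            raise ValidationError("table must contain at least one count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row1_rate(self) -> float:
        """Outcome rate in the first group, a / (a + b)."""
        return self.a / (self.a + self.b)

    @property
    def row2_rate(self) -> float:
        return self.c / (self.c + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def proportion_pct(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage rounded to the precision clinical tables print."""
    if total <= 0:
        raise ValidationError("total must be positive")
    return round(100.0 * count / total, ndigits)


def prepare_survival(records: pd.DataFrame, time_col: str = "time",
                     event_col: str = "event") -> pd.DataFrame:
    """Validate and clean survival records.

    Rows with missing time are dropped (logged); zero times are bumped to
    half the smallest positive time, since registry follow-up is recorded in
    whole months and a same-month event otherwise has no risk interval.
    """
    df = records.copy()
    n_missing = int(df[time_col].isna().sum())
    if n_missing:
        logger.info("dropping %d records with missing survival time", n_missing)
        df = df.dropna(subset=[time_col])
    if (df[time_col] < 0).any():
        raise ValidationError("negative survival times")
    if not set(df[event_col].unique()) <= {0, 1}:
        raise ValidationError("event flags must be 0/1")
    zero = df[time_col] == 0
    if zero.any():
        positive = df.loc[~zero, time_col]
        if positive.empty:
            raise DegenerateDataError("all survival times are zero")
        bump = float(positive.min()) / 2.0
        logger.warning("bumping %d zero survival times to %g", int(zero.sum()), bump)
        df.loc[zero, time_col] = bump
    return df


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_curve(records: pd.DataFrame) -> KMCurve:
    """Product-limit estimate of the survival function."""
    if records.empty:
        raise ValidationError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"])
    table = kmf.event_table
    table = table[table.index > 0]
    times = table.index.values.astype(float)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).values
    return KMCurve(times=times, survival=surv,
                   at_risk=table["at_risk"].values.astype(int))


def logrank_test(records: pd.DataFrame, group_col: str) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p."""
    groups = records[group_col].unique()
    if len(groups) != 2:
        raise ValidationError(f"expected 2 groups, got {len(groups)}")
    g1 = records[records[group_col] == groups[0]]
    g2 = records[records[group_col] == groups[1]]
    if g1["event"].sum() == 0 and g2["event"].sum() == 0:
        logger.warning("no events in either group; log-rank p set to 1")
        return 0.0, 1.0
    res = _ll_logrank(g1["time"], g2["time"],
                      event_observed_A=g1["event"], event_observed_B=g2["event"])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards (partial likelihood, Newton-Raphson)


def _cox_quantities(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                    event: np.ndarray, ties: str):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Samples must be sorted by descending time so risk sets are prefixes.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard overflow; constant shift cancels in all ratios
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    c0 = np.cumsum(w)
    c1 = np.cumsum(wx, axis=0)
    c2 = np.cumsum(wxx, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j + 1) if event[k] == 1]
        if d_idx:
            d = len(d_idx)
            s0, s1, s2 = c0[j], c1[j], c2[j]
            t0 = w[d_idx].sum()
            t1 = wx[d_idx].sum(axis=0)
            t2 = wxx[d_idx].sum(axis=0)
            xsum = X[d_idx].sum(axis=0)
            ll += eta[d_idx].sum()
            grad += xsum
            for l in range(d):
                f = l / d if ties == "efron" else 0.0
                D0 = s0 - f * t0
                D1 = s1 - f * t1
                D2 = s2 - f * t2
                ll -= np.log(D0)
                grad -= D1 / D0
                hess -= D2 / D0 - np.outer(D1, D1) / D0**2
        i = j + 1
    return ll, grad, hess


def cox_fit(records: pd.DataFrame, covariates: list[str],
            ties: str = "efron") -> CoxModel:
    """Fit a Cox proportional-hazards model.

    Newton-Raphson with step-halving on the partial likelihood; convergence
    at relative log-likelihood change < 1e-9 or 50 iterations.  Wald CIs and
    p-values from the observed information.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown tie method {ties!r}")
    df = prepare_survival(records)
    if df["event"].sum() < 1:
        raise ValidationError("need at least one event")
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValidationError(f"covariate {c!r} is constant")
    order = np.argsort(-df["time"].values, kind="stable")
    time = df["time"].values[order]
    event = df["event"].values[order].astype(int)
    X = df[covariates].values[order].astype(float)
    X = X - X.mean(axis=0)  # centering improves conditioning; HRs unchanged
    p = X.shape[1]

    beta = np.zeros(p)
    ll, grad, hess = _cox_quantities(beta, X, time, event, ties)
    converged = False
    diverged = False
    for _ in range(50):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            diverged = True
            break
        new_beta, new_ll = beta, ll
        for halving in range(30):
            cand = beta + step / (2**halving)
            cand_ll, cand_grad, cand_hess = _cox_quantities(cand, X, time, event, ties)
            if np.isfinite(cand_ll) and cand_ll >= ll - 1e-12:
                new_beta, new_ll = cand, cand_ll
                grad, hess = cand_grad, cand_hess
                break
        if np.abs(new_ll - ll) < 1e-9 * max(1.0, np.abs(ll)):
            beta, ll = new_beta, new_ll
            converged = True
            break
        beta, ll = new_beta, new_ll
    if np.any(np.abs(beta) > 50):
        diverged = True
    if diverged or not converged:
        logger.warning("Cox fit did not converge (possible monotone likelihood)")
        converged = False

    info = -hess
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "z": z,
            "p": pvals,
        },
        index=covariates,
    )
    return CoxModel(summary=summary, log_likelihood=float(ll),
                    converged=converged, ties=ties)


def cox_score_test(records: pd.DataFrame, covariate: str,
                   ties: str = "breslow") -> tuple[float, float]:
    """Score (Rao) test of beta = 0 for a single covariate.

    With Breslow ties and a binary covariate this is the classical log-rank
    identity (exact in the absence of tied event times).
    """
    df = prepare_survival(records)
    order = np.argsort(-df["time"].values, kind="stable")
    time = df["time"].values[order]
    event = df["event"].values[order].astype(int)
    X = df[[covariate]].values[order].astype(float)
    _, grad, hess = _cox_quantities(np.zeros(1), X, time, event, ties)
    info = float(-hess[0, 0])
    if info <= 0:
        raise DegenerateDataError("zero information at beta = 0")
    chi2 = float(grad[0] ** 2) / info
    return chi2, float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# contingency-table and two-sample tests


def fisher_exact(table: ContingencyTable2x2,
                 convention: str = "minlike") -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    ``minlike`` sums hypergeometric probabilities <= that of the observed
    table (the R convention); ``doubled`` doubles the smaller one-sided tail
    (the convention several clinical packages print).  Returns
    (odds_ratio, p); the odds ratio is the sample ad/bc, infinite when
    bc = 0 and nan for 0/0.
    """
    arr = table.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        oddsratio = float(np.float64(table.a * table.d) /
                          np.float64(table.b * table.c))
    if convention == "minlike":
        p = float(sps.fisher_exact(arr).pvalue)
    elif convention == "doubled":
        p_less = float(sps.fisher_exact(arr, alternative="less").pvalue)
        p_greater = float(sps.fisher_exact(arr, alternative="greater").pvalue)
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValidationError(f"unknown convention {convention!r}")
    return oddsratio, p


def chi_square_test(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on an r x c table; Yates only for 2x2."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("table must be at least 2x2")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("zero margin: expected counts undefined")
    res = sps.chi2_contingency(arr, correction=yates and arr.shape == (2, 2))
    return float(res.statistic), float(res.pvalue)


def t_test(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test (pooled-variance Student or Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs >= 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise DegenerateDataError("both groups have zero variance")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
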