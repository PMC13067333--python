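"""Psychometric analysis of the temporal prediction task.

A binomial logistic model P(late | delta-t) = logistic(b0 + b1 delta-t) is
fitted per participant and condition by iteratively reweighted least squares
(IRLS).  Two quantities summarize the curve:

* the point of subjective equality, PSE = -b0/b1, the timing offset judged
  "late" on 50% of trials;
* the steepness, 1 / (delta-t at 75% - delta-t at 25%) = b1 / (2 ln 3),
  a precision measure in 1/ms.

Perfectly separating observers (ideal synthetic participants) break plain
maximum likelihood; the fit then falls back to Firth-type penalization
(Jeffreys-prior score correction) and is flagged as non-converged.

Group statistics reproduce the printed conventions: paired, independent
(pooled-variance and Welch) and one-sample t-tests with Cohen's d, reported
against a comparison-wise alpha of 0.05/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = ["PsychometricFit", "proportions", "fit_psychometric",
           "subjectively_correct", "group_stats", "rt_summary", "GroupTest"]

ALPHA_ADJUSTED = 0.05 / 3.0


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic coefficients and the derived psychometric quantities."""

    b0: float
    b1: float
    se_b0: float
    se_b1: float
    converged: bool
    table: pd.DataFrame  # per level: delta_ms, n, n_late, p_late

    @property
    def pse_ms(self) -> float:
        return -self.b0 / self.b1

    @property
    def steepness(self) -> float:
        """1 / (delta-t at 75% late - delta-t at 25% late) = b1 / (2 ln 3)."""
        return self.b1 / (2.0 * np.log(3.0))

    def predict(self, delta_ms) -> np.ndarray:
        return expit(self.b0 + self.b1 * np.asarray(delta_ms, float))


def proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-level response counts and proportion of "late" responses.

    Input columns: delta_ms, response ("early"/"late").  Output rows sorted
    by delta_ms with columns delta_ms, n, n_late, p_late.
    """
    if len(table) == 0:
        raise ValueError("empty behavioral table")
    bad = set(table["response"]) - {"early", "late"}
    if bad:
        raise ValueError(f"responses must be early/late, got {bad}")
    grp = table.assign(late=(table["response"] == "late").astype(int)) \
               .groupby("delta_ms", sort=True)["late"].agg(["count", "sum"])
    out = grp.reset_index().rename(columns={"count": "n", "sum": "n_late"})
    out["p_late"] = out["n_late"] / out["n"]
    return out


def _irls(x: np.ndarray, n: np.ndarray, k: np.ndarray, firth: bool,
          tol: float = 1e-8, max_iter: int = 100):
    """Binomial logistic IRLS on grouped data; optional Firth correction."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    # sensible slope start: scale by spread of x
    beta[1] = 1.0 / max(np.std(x), 1.0)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = n * p * (1 - p)
        W = np.clip(w, 1e-12, None)
        XtWX = X.T @ (X * W[:, None])
        score = X.T @ (k - n * p)
        if firth:
            # Jeffreys-prior correction: score += H-diagonal shift
            try:
                Vinv = np.linalg.inv(XtWX)
            except np.linalg.LinAlgError:
                Vinv = np.linalg.pinv(XtWX)
            h = np.einsum("ij,jk,ik->i", X * W[:, None], Vinv, X)
            score = X.T @ (k - n * p + h * (0.5 - p))
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, score, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    p = expit(eta)
    W = np.clip(n * p * (1 - p), 1e-12, None)
    try:
        cov = np.linalg.inv(X.T @ (X * W[:, None]))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(X.T @ (X * W[:, None]))
    se = np.sqrt(np.diag(cov))
    return beta, se, converged


def fit_psychometric(per_level: pd.DataFrame) -> PsychometricFit:
    """Maximum-likelihood logistic fit to a per-level proportion table.

    Falls back to Firth-type penalized likelihood when the data are
    completely separated (then flagged ``converged=False`` with a warning).
    """
    x = per_level["delta_ms"].to_numpy(float)
    n = per_level["n"].to_numpy(float)
    k = per_level["n_late"].to_numpy(float)
    if k.sum() == 0 or k.sum() == n.sum():
        raise ValueError("need both response categories present overall")
    beta, se, conv = _irls(x, n, k, firth=False)
    separated = not conv or not np.all(np.isfinite(beta)) or np.abs(beta[1]) > 1e3
    if separated:
        warnings.warn("complete separation: falling back to Firth-penalized fit",
                      stacklevel=2)
        beta, se, _ = _irls(x, n, k, firth=True)
        conv = False
    return PsychometricFit(float(beta[0]), float(beta[1]), float(se[0]),
                           float(se[1]), bool(conv), per_level.copy())


def subjectively_correct(table: pd.DataFrame, fit: PsychometricFit) -> np.ndarray:
    """Boolean per trial: judged on the correct side of the subjective boundary.

    A trial is correct iff (delta > PSE and "late") or (delta < PSE and
    "early").  A delta exactly at the PSE counts as correct (deterministic
    tie rule; probability ~0 under a continuous PSE).
    """
    pse = fit.pse_ms
    delta = table["delta_ms"].to_numpy(float)
    late = (table["response"] == "late").to_numpy()
    correct = np.where(delta > pse, late, np.where(delta < pse, ~late, True))
    return correct.astype(bool)


@dataclass(frozen=True)
class GroupTest:
    t: float
    df: float
    p: float
    cohens_d: float
    kind: str
    alpha_adjusted: float = ALPHA_ADJUSTED
    flagged: bool = False  # zero variance etc.
    # pooled-variance companion for the independent design (printed convention)
    t_pooled: float | None = None
    df_pooled: float | None = None
    p_pooled: float | None = None

    @property
    def significant(self) -> bool:
        return (not self.flagged) and self.p < self.alpha_adjusted


def group_stats(a, b=None, design: str = "paired") -> GroupTest:
    """t statistics and Cohen's d for the three printed designs.

    paired: t on within-subject differences, d = mean(diff)/sd(diff);
    independent: Welch t (default report) plus the pooled-variance/df
    companion, d from the pooled sd; one-sample-vs-zero: t of ``a`` against 0.
    """
    a = np.asarray(a, float)
    if design == "one-sample-vs-zero":
        if len(a) < 2:
            raise ValueError("need n >= 2")
        sd = a.std(ddof=1)
        if sd == 0:
            return GroupTest(0.0, len(a) - 1, np.nan, 0.0, design, flagged=True)
        res = stats.ttest_1samp(a, 0.0)
        d = a.mean() / sd
        return GroupTest(float(res.statistic), float(len(a) - 1),
                         float(res.pvalue), float(d), design)
    b = np.asarray(b, float)
    if design == "paired":
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired design needs equal n >= 2")
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            return GroupTest(0.0 if diff.mean() == 0 else np.inf, len(a) - 1,
                             np.nan, 0.0, design, flagged=True)
        res = stats.ttest_rel(a, b)
        return GroupTest(float(res.statistic), float(len(a) - 1),
                         float(res.pvalue), float(diff.mean() / sd), design)
    if design == "independent":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need n >= 2 per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            return GroupTest(0.0, len(a) + len(b) - 2, np.nan, 0.0, design,
                             flagged=True)
        welch = stats.ttest_ind(a, b, equal_var=False)
        pooled = stats.ttest_ind(a, b, equal_var=True)
        n1, n2 = len(a), len(b)
        sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
                     / (n1 + n2 - 2))
        d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
        return GroupTest(float(welch.statistic), float(welch.df),
                         float(welch.pvalue), float(d), design,
                         t_pooled=float(pooled.statistic),
                         df_pooled=float(n1 + n2 - 2),
                         p_pooled=float(pooled.pvalue))
    raise ValueError(f"unknown design {design!r}")


def rt_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-level mean and SEM of reaction times (SEM NaN for single trials)."""
    if (table["rt_ms"] <= 0).any():
        raise ValueError("RTs must be positive")
    grp = table.groupby("delta_ms", sort=True)["rt_ms"]
    out = grp.agg(n="count", mean_rt_ms="mean",
                  sem_rt_ms=lambda v: v.std(ddof=1) / np.sqrt(len(v))
                  if len(v) > 1 else np.nan).reset_index()
    return out
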