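"""Self-contained statistical layer for the association and group analyses.

Implemented from first principles (scipy supplies only reference
distributions): univariate logistic regression by iteratively reweighted
least squares with Wald inference, Pearson 2x2 chi-square (no continuity
correction — the variant that reproduces the study's printed incidence
p-values from its printed counts), Student's two-sample t, paired
minute-vs-baseline contrasts with Bonferroni correction, ordinary least
squares, and a Lilliefors-style Kolmogorov-Smirnov normality test with a
seeded Monte Carlo null.

Odds ratios are reported per 1 ms of the predictor with symmetric
95% Wald intervals on the log scale, exp(beta +/- 1.96 se).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as spstats

from .errors import ConvergenceError, ParameterError, SeparationError

_Z975 = 1.959963984540054


@dataclass
class AssociationResult:
    """One univariate logistic fit: log-odds per unit of the predictor."""

    predictor: str
    beta: float
    se: float
    p: float
    n: int
    n_events: int
    n_iter: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - _Z975 * self.se)),
            float(np.exp(self.beta + _Z975 * self.se)),
        )

    def row(self) -> dict:
        lo, hi = self.ci95
        return {
            "predictor": self.predictor,
            "beta": self.beta,
            "se": self.se,
            "or": self.odds_ratio,
            "ci95_low": lo,
            "ci95_high": hi,
            "p": self.p,
            "n": self.n,
            "n_events": self.n_events,
        }


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: log sigma(eta)*y + log sigma(-eta)*(1-y)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_univariate(
    x: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
    name: str = "x",
) -> AssociationResult:
    """Maximum-likelihood univariate logistic regression (intercept + slope).

    Newton/IRLS iterations; convergence when the log-likelihood change
    drops below ``tol``.  The Wald standard error comes from the inverse
    observed information at the optimum.  Complete separation and constant
    predictors are rejected explicitly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    if not np.all(np.isfinite(x)):
        raise ParameterError("x contains non-finite values")
    if not np.all((y == 0) | (y == 1)):
        raise ParameterError("y must be binary (0/1)")
    if y.min() == y.max():
        raise ParameterError("both outcome classes must be present")
    if x.min() == x.max():
        raise ParameterError("predictor is constant")
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        raise SeparationError(
            "complete separation: predictor perfectly splits the outcome classes"
        )

    # standardize internally for conditioning; back-transform at the end
    mu_x, sd_x = x.mean(), x.std()
    z = (x - mu_x) / sd_x
    design = np.column_stack([np.ones_like(z), z])
    beta = np.zeros(2)
    beta[0] = np.log(y.mean() / (1.0 - y.mean()))
    ll_old = _log_likelihood(design @ beta, y)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = design.T @ (design * w[:, None])
        score = design.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        beta = beta + step
        ll = _log_likelihood(design @ beta, y)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = design.T @ (design * w[:, None])
    cov = np.linalg.inv(info)
    slope = beta[1] / sd_x
    se = float(np.sqrt(cov[1, 1]) / sd_x)
    wald = slope / se
    p = float(2.0 * spstats.norm.sf(abs(wald)))
    return AssociationResult(
        predictor=name,
        beta=float(slope),
        se=se,
        p=max(p, np.finfo(float).tiny),
        n=int(x.size),
        n_events=int(y.sum()),
        n_iter=n_iter,
    )


class Chi2Result(NamedTuple):
    statistic: float
    df: int
    p: float


def chisq_2x2(table) -> Chi2Result:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ParameterError("table must hold nonnegative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ParameterError("all table margins must be positive")
    n = t.sum()
    expected = np.outer(rows, cols) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    return Chi2Result(stat, 1, float(spstats.chi2.sf(stat, 1)))


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p (alternative to the Pearson chi-square)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    return float(spstats.fisher_exact(t, alternative="two-sided")[1])


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def two_sample_t(x1, x2, equal_var: bool = True) -> TTestResult:
    """Two-sided two-sample t-test (pooled by default, Welch otherwise)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ParameterError("each group needs n >= 2")
    m1, m2 = x1.mean(), x2.mean()
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if equal_var:
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        denom = np.sqrt(v1 / n1 + v2 / n2)
        if denom > 0:
            df = float(
                (v1 / n1 + v2 / n2) ** 2
                / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            )
        else:
            df = float(n1 + n2 - 2)
    if denom == 0.0:
        if m1 == m2:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(float(np.sign(m1 - m2) * np.inf), df, 0.0)
    t = float((m1 - m2) / denom)
    return TTestResult(t, df, float(2.0 * spstats.t.sf(abs(t), df)))


def _paired_t(diffs: np.ndarray) -> tuple[float, float]:
    n = diffs.size
    if n < 2:
        raise ParameterError("paired contrast needs n >= 2 complete pairs")
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        return (0.0, 1.0) if diffs.mean() == 0.0 else (np.inf, 0.0)
    t = diffs.mean() / (sd / np.sqrt(n))
    return float(t), float(2.0 * spstats.t.sf(abs(t), n - 1))


def rm_contrasts_bonferroni(matrix, minutes=None):
    """Paired contrasts of every minute against baseline, Bonferroni-adjusted.

    ``matrix`` is subjects x minutes with the baseline in column 0; rows
    with a missing value are dropped per contrast.  Adjusted p is the raw
    paired-t p multiplied by the number of contrasts, capped at 1.
    """
    import pandas as pd

    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ParameterError("matrix must be subjects x minutes with >= 2 columns")
    n_contrasts = m.shape[1] - 1
    labels = list(minutes) if minutes is not None else list(range(m.shape[1]))
    rows = []
    for j in range(1, m.shape[1]):
        diffs = m[:, j] - m[:, 0]
        diffs = diffs[np.isfinite(diffs)]
        t, p = _paired_t(diffs)
        rows.append(
            {
                "minute": labels[j],
                "n": int(diffs.size),
                "t": t,
                "p_raw": p,
                "p_adjusted": min(1.0, p * n_contrasts),
            }
        )
    return pd.DataFrame(rows).set_index("minute")


class LinRegResult(NamedTuple):
    slope: float
    intercept: float
    se: float
    ci95: tuple[float, float]
    p: float


def linear_regression(x, y) -> LinRegResult:
    """Ordinary least squares of y on x with t-based slope CI and p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ParameterError("linear regression needs n >= 3")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0.0:
        raise ParameterError("predictor is constant")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    sse = float(np.sum(resid**2))
    df = n - 2
    if sse == 0.0:
        p = 1.0 if slope == 0.0 else 0.0
        return LinRegResult(slope, intercept, 0.0, (slope, slope), p)
    se = float(np.sqrt(sse / df / sxx))
    tcrit = float(spstats.t.ppf(0.975, df))
    t = slope / se
    return LinRegResult(
        slope,
        intercept,
        se,
        (slope - tcrit * se, slope + tcrit * se),
        float(2.0 * spstats.t.sf(abs(t), df)),
    )


class KSResult(NamedTuple):
    D: float
    p: float


def _lilliefors_stat(sample: np.ndarray) -> float:
    n = sample.size
    z = np.sort((sample - sample.mean()) / sample.std(ddof=1))
    cdf = spstats.norm.cdf(z)
    upper = np.max(np.arange(1, n + 1) / n - cdf)
    lower = np.max(cdf - np.arange(0, n) / n)
    return float(max(upper, lower))


def ks_normality(x, n_sim: int = 2000, seed: int = 0) -> KSResult:
    """Kolmogorov-Smirnov normality test with estimated mean/sd.

    Because the null parameters are estimated from the sample, the
    classical KS null distribution does not apply; the p-value is obtained
    Lilliefors-style from a seeded Monte Carlo of Gaussian samples of the
    same size.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ParameterError("normality test needs n >= 5")
    if x.std(ddof=1) == 0.0:
        raise ParameterError("sample is constant")
    d_obs = _lilliefors_stat(x)
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_sim, x.size))
    z = np.sort(
        (sims - sims.mean(axis=1, keepdims=True))
        / sims.std(axis=1, ddof=1, keepdims=True),
        axis=1,
    )
    cdf = spstats.norm.cdf(z)
    n = x.size
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d_sim = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
    p = (1.0 + np.sum(d_sim >= d_obs)) / (n_sim + 1.0)
    return KSResult(d_obs, float(p))
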