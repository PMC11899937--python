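"""Case-control statistics: rank tests, contingency tests, logistic odds ratios.

The analysis stage mirrors a standard cardiogenetics case-control workup:
Kruskal-Wallis rank comparison of quantitative variables (tie-corrected,
chi-square reference), Pearson chi-square WITHOUT continuity correction and
Fisher's exact test for categorical variables, dichotomisation of LDL-C at
the familial-hypercholesterolemia-suggestive 4.9 mmol/L threshold, and
logistic regression reported as odds ratios with Wald 95% confidence
intervals, with backward elimination of non-significant terms.

Logistic fitting is by iteratively reweighted least squares (Newton scoring)
with explicit separation diagnostics; the log-likelihood trace is retained so
monotone convergence can be checked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


class StatError(ValueError):
    """Invalid input to a statistical routine."""


class SeparationError(RuntimeError):
    """The logistic likelihood is maximised at infinity (complete or
    quasi-complete separation); coefficient estimates are not finite."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


# ---------------------------------------------------------------------------
# Rank test


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    median: float
    minimum: float
    maximum: float


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    df: int
    p_value: float
    groups: tuple[GroupSummary, ...]


def kruskal_wallis(groups: dict[str, Sequence[float]]) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H test across two or more groups.

    The p-value is the chi-square upper tail with k-1 degrees of freedom.
    If every pooled value is tied the statistic is 0 by convention (the tie
    correction removes all rank variance) and p = 1.
    """
    if len(groups) < 2:
        raise StatError("kruskal_wallis needs at least two groups")
    arrays = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 1:
            raise StatError(f"group {label!r} has no observations")
        arrays[label] = arr

    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays.values())
    summaries = tuple(
        GroupSummary(label, arr.size, float(np.median(arr)), float(arr.min()), float(arr.max()))
        for label, arr in arrays.items()
    )
    return RankTestResult(float(h), len(arrays) - 1, float(p), summaries)


# ---------------------------------------------------------------------------
# Contingency tests


def _validate_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2:
        raise StatError("contingency table must be two-dimensional")
    if (table < 0).any():
        raise StatError("contingency table counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise StatError("contingency table has a zero row or column margin")
    return table


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def pearson_chi2(table) -> Chi2Result:
    """Pearson chi-square on an r x c table, no continuity correction.

    chi2 = sum (O-E)^2 / E with expecteds from the margins; df = (r-1)(c-1).
    """
    table = _validate_table(table)
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return Chi2Result(float(stat), int(df), float(p))


_FISHER_ENUM_CAP = 2_000_000


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 or 2xK table.

    Convention: p is the total probability, over all tables with the observed
    margins, of tables whose point probability does not exceed that of the
    observed table (with a 1+1e-7 relative tolerance against floating-point
    ties). 2x2 tables use the hypergeometric distribution; wider tables are
    enumerated over the margin-fixed polytope, which is refused above
    ~2e6 candidate tables.
    """
    table = _validate_table(table)
    if table.shape[0] != 2:
        raise StatError("fisher_exact supports 2xK tables only")
    if table.shape[1] == 2:
        return float(stats.fisher_exact(table, alternative="two-sided")[1])

    row1 = table[0]
    cols = table.sum(axis=0)
    r1 = int(row1.sum())
    n_tables = np.prod([min(r1, c) + 1 for c in cols])
    if n_tables > _FISHER_ENUM_CAP:
        raise StatError(
            f"table too large for exact enumeration (~{n_tables:.0f} candidates); "
            "use pearson_chi2"
        )

    # log P(x1..xK | margins) = sum log C(c_j, x_j) - log C(N, r1)
    def log_prob(xs: tuple[int, ...]) -> float:
        lp = -(gammaln(table.sum() + 1) - gammaln(r1 + 1) - gammaln(table.sum() - r1 + 1))
        for c, x in zip(cols, xs):
            lp += gammaln(c + 1) - gammaln(x + 1) - gammaln(c - x + 1)
        return float(lp)

    observed_lp = log_prob(tuple(int(x) for x in row1))
    cutoff = observed_lp + 1e-7
    total = 0.0
    ranges = [range(min(r1, int(c)) + 1) for c in cols[:-1]]
    for xs in itertools.product(*ranges):
        rest = r1 - sum(xs)
        if rest < 0 or rest > cols[-1]:
            continue
        lp = log_prob(xs + (rest,))
        if lp <= cutoff:
            total += np.exp(lp)
    return float(min(total, 1.0))


# ---------------------------------------------------------------------------
# Logistic regression


@dataclass(frozen=True)
class TermEstimate:
    term: str
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class LogisticFitResult:
    outcome: str
    terms: tuple[TermEstimate, ...]
    n: int
    log_likelihood: float
    n_iter: int
    ll_trace: tuple[float, ...]

    def estimate(self, term: str) -> TermEstimate:
        for t in self.terms:
            if t.term == term:
                return t
        raise KeyError(term)


_Z975 = 1.959963984540054  # 97.5th standard-normal percentile


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_fit(
    outcome: Sequence[int],
    design: pd.DataFrame,
    outcome_name: str = "outcome",
    add_intercept: bool = True,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> LogisticFitResult:
    """Maximum-likelihood logistic regression via IRLS.

    ``design`` holds one labelled column per model term; an intercept column
    is prepended unless ``add_intercept=False``. Convergence when the maximum
    absolute score (gradient) falls below ``score_tol`` or the relative
    log-likelihood change falls below ``ll_tol``. Odds ratios are exp(beta)
    with Wald 95% CIs exp(beta +/- 1.96*SE).

    Raises :class:`SeparationError` when the fitted probabilities classify
    the outcome perfectly (the MLE is at infinity) and
    :class:`ConvergenceError` when the iteration budget is exhausted.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise StatError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise StatError("outcome is constant; logistic model is undefined")
    labels = list(design.columns)
    X = np.asarray(design, dtype=float)
    if add_intercept:
        if any((X[:, j] == X[0, j]).all() for j in range(X.shape[1])):
            raise StatError("design contains a constant column besides the intercept")
        X = np.column_stack([np.ones(len(y)), X])
        labels = ["intercept"] + labels
    n, p = X.shape
    if n <= p:
        raise StatError(f"n={n} must exceed the number of terms p={p}")

    beta = np.zeros(p)
    ll_trace = []
    ll = _log_likelihood(y, X @ beta)
    ll_trace.append(ll)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "Fisher information is singular (separation or collinearity)"
            ) from None
        # Step-halving keeps the log-likelihood monotone.
        new_beta, new_ll = beta + step, _log_likelihood(y, X @ (beta + step))
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta, new_ll = beta + step, _log_likelihood(y, X @ (beta + step))
            halvings += 1
        beta, ll = new_beta, new_ll
        ll_trace.append(ll)
        _check_separation(y, X @ beta)
        if np.max(np.abs(X.T @ (y - 1.0 / (1.0 + np.exp(-(X @ beta)))))) < score_tol:
            break
        if abs(ll_trace[-1] - ll_trace[-2]) < ll_tol * (abs(ll_trace[-2]) + ll_tol):
            break
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(|score|max={np.max(np.abs(score)):.3g}, ll={ll:.6g})"
        )

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = (X * (mu * (1 - mu))[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    def _exp(x: float) -> float:
        return float(np.exp(min(x, 700.0)))  # avoid overflow warning; inf-ish CI stays inf-ish

    terms = tuple(
        TermEstimate(
            term=label,
            beta=float(b),
            se=float(s),
            odds_ratio=_exp(b),
            ci_low=_exp(b - _Z975 * s),
            ci_high=_exp(b + _Z975 * s),
            p_value=float(2 * stats.norm.sf(abs(b / s))),
        )
        for label, b, s in zip(labels, beta, se)
    )
    return LogisticFitResult(
        outcome=outcome_name,
        terms=terms,
        n=n,
        log_likelihood=ll,
        n_iter=it,
        ll_trace=tuple(ll_trace),
    )


def _check_separation(y: np.ndarray, eta: np.ndarray) -> None:
    # A finite MLE implies some overlap in fitted probabilities; perfect
    # classification at the 1e-5 level means the likelihood is maximised at
    # infinity and the iterates are diverging.
    mu = 1.0 / (1.0 + np.exp(-eta))
    perfect = np.all(mu[y == 1] > 1 - 1e-5) and np.all(mu[y == 0] < 1e-5)
    if perfect:
        raise SeparationError(
            "complete separation: fitted probabilities reached 0/1 for every "
            "observation; coefficient estimates diverge"
        )


# ---------------------------------------------------------------------------
# Backward selection


@dataclass(frozen=True)
class SelectionStep:
    dropped: str
    p_value: float
    surviving: tuple[str, ...]


@dataclass(frozen=True)
class SelectionTrace:
    steps: tuple[SelectionStep, ...]
    final_terms: tuple[str, ...]


def backward_select(
    outcome: Sequence[int],
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    outcome_name: str = "outcome",
    **fit_kwargs,
) -> tuple[SelectionTrace, LogisticFitResult]:
    """Backward elimination on Wald p-values.

    Repeatedly refits and drops the term with the largest p-value >= alpha
    until every surviving term is significant at alpha. The intercept is
    never a candidate. If all terms are eliminated the intercept-only model
    is returned with the full trace.
    """
    if candidates.shape[1] < 1:
        raise StatError("backward_select needs at least one candidate term")
    surviving = list(candidates.columns)
    steps: list[SelectionStep] = []
    while surviving:
        fit = logistic_fit(
            outcome, candidates[surviving], outcome_name=outcome_name, **fit_kwargs
        )
        pvals = {t.term: t.p_value for t in fit.terms if t.term != "intercept"}
        worst = max(pvals, key=lambda t: pvals[t])
        if pvals[worst] < alpha:
            return SelectionTrace(tuple(steps), tuple(surviving)), fit
        surviving.remove(worst)
        steps.append(SelectionStep(worst, pvals[worst], tuple(surviving)))

    # Intercept-only fallback.
    fit = logistic_fit(
        outcome,
        pd.DataFrame(index=np.arange(len(outcome))),
        outcome_name=outcome_name,
        **fit_kwargs,
    )
    return SelectionTrace(tuple(steps), ()), fit


# ---------------------------------------------------------------------------
# LDL-C dichotomisation


def dichotomize_ldl(ldl_c: Sequence[float], threshold: float = 4.9) -> pd.Series:
    """1 where LDL-C strictly exceeds the threshold (mmol/L), else 0;
    missing stays missing. Non-positive concentrations are rejected."""
    s = pd.Series(ldl_c, dtype=float)
    if (s.dropna() <= 0).any():
        bad = s[s <= 0].index[0]
        raise StatError(f"non-positive LDL-C value at index {bad}")
    out = (s > threshold).astype("float")
    out[s.isna()] = np.nan
    return out
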