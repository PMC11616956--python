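"""Statistical battery for the case-control analysis.

Group contrasts use the two-sided Wilcoxon rank-sum test (exact enumeration
at small n, tie-corrected normal approximation otherwise) and Pearson
chi-square / Fisher exact tests on contingency tables.  Modelling uses
maximum-likelihood simple logistic regression and conditional logistic
regression over 1:m matched strata, Box–Tidwell linearity checks, quartile
categorisation of non-linear covariates, AIC-driven stepwise/backward
selection, and Hosmer–Lemeshow plus ROC-AUC fit diagnostics.  Post-hoc
power for a two-proportion comparison is computed by exact enumeration of
the binomial outcome grid against the Fisher rejection region.

Standard fits are delegated to ``scipy``/``statsmodels``/``scikit-learn``;
the exact Wilcoxon enumeration, Fisher power grid and Hosmer–Lemeshow
statistic are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    HessianInversionWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

import warnings


def _safe_exp(x: float) -> float:
    try:
        return math.exp(x)
    except OverflowError:
        return float("inf")


class StatsError(ValueError):
    """Raised when a test's preconditions are violated."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    method: str
    statistic: float
    p_value: float
    df: Optional[float] = None
    n: tuple[int, ...] = ()
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class LogisticModelFit:
    """A fitted (conditional) logistic regression.

    Odds ratios are ``exp(estimate)`` with Wald 95% confidence intervals;
    ``aic = 2k - 2 loglik``.  ``outcome`` and ``fitted`` are retained for
    goodness-of-fit diagnostics.
    """

    method: str
    names: tuple[str, ...]
    estimates: tuple[float, ...]
    std_errors: tuple[float, ...]
    p_values: tuple[float, ...]
    loglik: float
    loglik_null: float
    aic: float
    n: int
    outcome: tuple[int, ...]
    fitted: tuple[float, ...]
    converged: bool = True

    @property
    def odds_ratios(self) -> tuple[float, ...]:
        return tuple(_safe_exp(b) for b in self.estimates)

    @property
    def or_conf_int(self) -> tuple[tuple[float, float], ...]:
        z = sps.norm.ppf(0.975)
        return tuple(
            (_safe_exp(b - z * s), _safe_exp(b + z * s))
            for b, s in zip(self.estimates, self.std_errors)
        )

    @property
    def lr_test_p(self) -> float:
        """Global likelihood-ratio test against the null model."""

        k = sum(1 for n in self.names if n != "intercept")
        if k == 0:
            return 1.0
        stat = 2.0 * (self.loglik - self.loglik_null)
        return float(sps.chi2.sf(max(stat, 0.0), k))

    def coef_frame(self) -> pd.DataFrame:
        ci = self.or_conf_int
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.estimates,
                "std_error": self.std_errors,
                "odds_ratio": self.odds_ratios,
                "or_ci_low": [lo for lo, _ in ci],
                "or_ci_high": [hi for _, hi in ci],
                "p_value": self.p_values,
            }
        )


def _clean(sample: Iterable[float]) -> np.ndarray:
    arr = np.asarray([v for v in sample if v is not None], dtype=float)
    return arr[~np.isnan(arr)]


# ---------------------------------------------------------------------------
# Rank and contingency tests


def _exact_ranksum_p(ranks: np.ndarray, n1: int, obs_dev: float) -> float:
    """Exact two-sided p for the rank-sum statistic over all group splits.

    Counts, by subset-sum dynamic programming over the (tie-averaged)
    pooled ranks, the number of size-``n1`` subsets whose rank-sum deviates
    from its expectation by at least the observed deviation.  Equivalent to
    exhaustive enumeration of all C(n, n1) assignments, tie-safe.
    """

    # tie-averaged ranks are multiples of 1/2; double them to get integers
    doubled = np.rint(ranks * 2).astype(np.int64)
    n = len(doubled)
    max_sum = int(doubled.sum())
    # counts[k, s] = number of subsets of size k with doubled-rank sum s
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in doubled:
        counts[1 : n1 + 1, r:] += counts[0:n1, : max_sum + 1 - r]
    total = counts[n1].sum()
    sums = np.arange(max_sum + 1) / 2.0
    expect = n1 * (n + 1) / 2.0
    hit = np.abs(sums - expect) >= obs_dev - 1e-9
    return float(counts[n1, hit].sum() / total)


def wilcoxon_rank_sum(
    x: Iterable[float], y: Iterable[float], exact_max_n: int = 10
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    When both groups have at most ``exact_max_n`` observations the p-value
    is computed by exhaustive enumeration of all group assignments of the
    pooled sample (tie-safe).  Otherwise the tie-corrected normal
    approximation with continuity correction is used.
    """

    xa, ya = _clean(x), _clean(y)
    if len(xa) == 0 or len(ya) == 0:
        raise StatsError("wilcoxon: both samples must contain at least one non-missing value")
    n1, n2 = len(xa), len(ya)
    pooled = np.concatenate([xa, ya])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    expect = n1 * (n1 + n2 + 1) / 2.0
    if n1 <= exact_max_n and n2 <= exact_max_n:
        p = _exact_ranksum_p(ranks, n1, abs(w - expect))
        method = "wilcoxon_exact"
    else:
        res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "wilcoxon_normal"
    return TestResult(method=method, statistic=w, p_value=min(p, 1.0), n=(n1, n2))


def chi_square(table: Sequence[Sequence[float]], continuity: bool = False) -> TestResult:
    """Pearson chi-square test on an r x c contingency table.

    ``continuity`` applies the Yates correction and is valid for 2x2 tables
    only.  Any zero row or column marginal is an error.
    """

    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or (arr < 0).any():
        raise StatsError("chi_square: table must be a 2-D array of non-negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise StatsError("chi_square: zero marginal in table")
    if continuity and arr.shape != (2, 2):
        raise StatsError("chi_square: continuity correction applies to 2x2 tables only")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=continuity)
    return TestResult(
        method="chi_square_yates" if continuity else "chi_square",
        statistic=float(stat),
        p_value=float(p),
        df=float(df),
        n=tuple(int(v) for v in arr.sum(axis=1)),
    )


def fisher_exact(table: Sequence[Sequence[float]]) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Two-sided rule: sum the probabilities of all hypergeometric outcomes no
    more probable than the observed table.  A zero marginal yields p = 1 by
    convention (flagged in ``note``).
    """

    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise StatsError("fisher_exact: table must be 2x2 non-negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return TestResult(
            method="fisher_exact",
            statistic=float("nan"),
            p_value=1.0,
            n=tuple(int(v) for v in arr.sum(axis=1)),
            note="zero marginal; p = 1 by convention",
        )
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        method="fisher_exact",
        statistic=float(odds),
        p_value=float(p),
        n=tuple(int(v) for v in arr.sum(axis=1)),
    )


def fisher_power_two_proportions(
    n1: int, n2: int, p1: float, p2: float, alpha: float = 0.05
) -> float:
    """Exact post-hoc power of the two-sided Fisher test for two
    independent proportions.

    Enumerates the full ``(n1+1) x (n2+1)`` grid of binomial outcomes under
    the true proportions and sums the probability of the Fisher rejection
    region (p-value <= alpha).
    """

    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise StatsError("power: proportions must lie strictly inside (0, 1)")
    if not (0 < alpha < 1):
        raise StatsError("power: alpha must lie in (0, 1)")
    pmf1 = sps.binom.pmf(np.arange(n1 + 1), n1, p1)
    pmf2 = sps.binom.pmf(np.arange(n2 + 1), n2, p2)
    power = 0.0
    # Fisher p-values for all outcomes, grouped by the first-column total k:
    # within fixed margins the conditional distribution is hypergeometric,
    # and the two-sided p of x1 sums all outcomes no more probable than it.
    for k in range(n1 + n2 + 1):
        lo, hi = max(0, k - n2), min(n1, k)
        xs = np.arange(lo, hi + 1)
        pmf = sps.hypergeom.pmf(xs, n1 + n2, n1, k)
        order = np.argsort(pmf, kind="stable")
        csum = np.cumsum(pmf[order])
        # rank of each outcome's pmf among the sorted values (ties included)
        pvals = np.empty_like(pmf)
        sorted_pmf = pmf[order]
        idx = np.searchsorted(sorted_pmf, pmf * (1 + 1e-7), side="right") - 1
        pvals = csum[idx]
        reject = pvals <= alpha
        power += float(np.sum(pmf1[xs[reject]] * pmf2[k - xs[reject]]))
    return float(power)


# ---------------------------------------------------------------------------
# Logistic regression


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> Optional[str]:
    """Return the name of a covariate that perfectly separates the outcome."""

    for name in X.columns:
        if name == "intercept":
            continue
        v = X[name].to_numpy(dtype=float)
        v1, v0 = v[y == 1], v[y == 0]
        if len(v1) == 0 or len(v0) == 0:
            continue
        if v1.min() > v0.max() or v0.min() > v1.max():
            return name
    return None


def _design(design: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    X = pd.DataFrame(design).copy()
    X.columns = [str(c) for c in X.columns]
    return X.astype(float)


def logistic_fit(design: pd.DataFrame | np.ndarray, outcome: Iterable[int]) -> LogisticModelFit:
    """Maximum-likelihood simple logistic regression with Wald inference.

    An intercept is always added.  Zero-variance covariates and constant
    outcomes are errors; perfect separation raises an error naming the
    offending covariate.
    """

    X = _design(design)
    y = np.asarray(list(outcome), dtype=int)
    if X.isna().any().any() or len(X) != len(y):
        raise StatsError("logistic_fit: design must be complete and match the outcome length")
    if y.min() == y.max():
        raise StatsError("logistic_fit: outcome is constant")
    for name in X.columns:
        if X[name].nunique() <= 1:
            raise StatsError(f"logistic_fit: covariate {name!r} has zero variance")
    Xc = sm.add_constant(X, prepend=True).rename(columns={"const": "intercept"})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", HessianInversionWarning)
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        sep = _check_separation(X, y) or "joint"
        raise StatsError(f"logistic_fit: perfect separation on covariate {sep!r}") from exc
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
        sep = _check_separation(X, y) or "joint"
        raise StatsError(f"logistic_fit: perfect separation on covariate {sep!r}")
    try:
        bse, pvalues = res.bse, res.pvalues
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise StatsError("logistic_fit: singular information matrix") from exc
    if not np.isfinite(bse).all():
        raise StatsError("logistic_fit: singular information matrix")
    return LogisticModelFit(
        method="logistic",
        names=tuple(Xc.columns),
        estimates=tuple(float(b) for b in res.params),
        std_errors=tuple(float(s) for s in bse),
        p_values=tuple(float(p) for p in pvalues),
        loglik=float(res.llf),
        loglik_null=float(res.llnull),
        aic=float(res.aic),
        n=len(y),
        outcome=tuple(int(v) for v in y),
        fitted=tuple(float(p) for p in res.predict()),
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def conditional_logistic_fit(
    design: pd.DataFrame | np.ndarray,
    outcome: Iterable[int],
    strata: Iterable,
) -> LogisticModelFit:
    """Conditional logistic regression over matched strata.

    Maximises the product over strata of
    ``exp(x_case . beta) / sum_j exp(x_j . beta)`` (each stratum has
    exactly one case).  Stratum-constant covariates carry no information;
    a covariate constant within every stratum is an error.  Fitted values
    are within-stratum case probabilities at the MLE.
    """

    X = _design(design)
    y = np.asarray(list(outcome), dtype=int)
    groups = np.asarray(list(strata))
    if len(X) != len(y) or len(y) != len(groups):
        raise StatsError("conditional_logistic_fit: length mismatch")
    for g in np.unique(groups):
        if y[groups == g].sum() != 1:
            raise StatsError(f"conditional_logistic_fit: stratum {g!r} must have exactly one case")
    informative = []
    for name in X.columns:
        v = X[name].to_numpy()
        if any(len(np.unique(v[groups == g])) > 1 for g in np.unique(groups)):
            informative.append(name)
    if not informative:
        raise StatsError(
            "conditional_logistic_fit: every covariate is constant within every stratum"
        )
    model = ConditionalLogit(y, X[informative].to_numpy(), groups=groups)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", HessianInversionWarning)
            res = model.fit(disp=0, maxiter=200)
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise StatsError(f"conditional_logistic_fit: fit failed ({exc})") from exc
    if np.abs(np.asarray(res.params)).max() > 50 or not np.isfinite(res.params).all():
        raise StatsError("conditional_logistic_fit: estimates diverged (separation)")
    try:
        cond_bse, cond_pvalues = res.bse, res.pvalues
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise StatsError("conditional_logistic_fit: singular information matrix") from exc
    if not np.isfinite(cond_bse).all():
        raise StatsError("conditional_logistic_fit: singular information matrix")
    k = len(informative)
    llf = float(res.llf)
    llnull = float(model.loglike(np.zeros(k)))
    # within-stratum case probabilities at the MLE
    eta = X[informative].to_numpy() @ np.asarray(res.params, dtype=float)
    fitted = np.empty_like(eta)
    for g in np.unique(groups):
        m = groups == g
        ex = np.exp(eta[m] - eta[m].max())
        fitted[m] = ex / ex.sum()
    return LogisticModelFit(
        method="conditional_logistic",
        names=tuple(informative),
        estimates=tuple(float(b) for b in res.params),
        std_errors=tuple(float(s) for s in cond_bse),
        p_values=tuple(float(p) for p in cond_pvalues),
        loglik=llf,
        loglik_null=llnull,
        aic=2.0 * k - 2.0 * llf,
        n=len(y),
        outcome=tuple(int(v) for v in y),
        fitted=tuple(float(p) for p in fitted),
        converged=bool(getattr(res, "mle_retvals", {}).get("converged", True)),
    )


def box_tidwell(
    covariate: Iterable[float],
    outcome: Iterable[int],
    adjusters: Optional[pd.DataFrame] = None,
) -> TestResult:
    """Box–Tidwell check of linearity of the logit in a covariate.

    Augments the logistic model with ``x * ln(x)`` and reports the Wald
    p-value of the augmentation term; a small p indicates non-linearity.
    Zeros are shifted by +1 before transforming (documented shift rule);
    negative values are an error.
    """

    x = np.asarray(list(covariate), dtype=float)
    if np.isnan(x).any():
        raise StatsError("box_tidwell: covariate contains missing values")
    if (x < 0).any():
        raise StatsError("box_tidwell: covariate must be non-negative")
    if (x == 0).any():
        x = x + 1.0
    X = pd.DataFrame({"x": x, "x_log_x": x * np.log(x)})
    if adjusters is not None:
        adj = _design(adjusters)
        for c in adj.columns:
            X[c] = adj[c].to_numpy()
    fit = logistic_fit(X, outcome)
    i = fit.names.index("x_log_x")
    return TestResult(
        method="box_tidwell",
        statistic=fit.estimates[i] / fit.std_errors[i],
        p_value=fit.p_values[i],
        n=(fit.n,),
    )


def quartile_categorize(x: Iterable[float]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Categorise a continuous covariate into four ordered quartile bands.

    Returns ``(codes, cutpoints, labels)``: integer band codes 0-3 (band 0,
    the lowest, is the reference), the three empirical quartile cutpoints,
    and human-readable band labels.  Assignment is left-closed: a value
    equal to a cutpoint falls in the lower band.  Requires at least four
    distinct values.
    """

    arr = _clean(x)
    if len(np.unique(arr)) < 4:
        raise StatsError("quartile_categorize: need at least 4 distinct values")
    cuts = np.quantile(arr, [0.25, 0.5, 0.75])
    xs = np.asarray(list(x), dtype=float)
    codes = np.searchsorted(cuts, xs, side="left")
    lo, hi = arr.min(), arr.max()
    labels = [
        f"{lo:g}-{cuts[0]:g}",
        f">{cuts[0]:g}-{cuts[1]:g}",
        f">{cuts[1]:g}-{cuts[2]:g}",
        f">{cuts[2]:g}-{hi:g}",
    ]
    return codes, cuts, labels


@dataclass
class StepwiseResult:
    """Final AIC-selected model plus the selection trace."""

    fit: LogisticModelFit
    selected: tuple[str, ...]
    screen: pd.DataFrame
    trace: list[str] = field(default_factory=list)
    flagged_empty: bool = False


def _intercept_only_fit(y: np.ndarray) -> LogisticModelFit:
    p = y.mean()
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    b0 = math.log(p / (1 - p))
    se = math.sqrt(1.0 / (len(y) * p * (1 - p)))
    return LogisticModelFit(
        method="logistic",
        names=("intercept",),
        estimates=(b0,),
        std_errors=(se,),
        p_values=(2 * sps.norm.sf(abs(b0 / se)),),
        loglik=ll,
        loglik_null=ll,
        aic=2.0 - 2.0 * ll,
        n=len(y),
        outcome=tuple(int(v) for v in y),
        fitted=tuple(float(p) for _ in y),
    )


def stepwise_aic(
    candidates: pd.DataFrame,
    outcome: Iterable[int],
    direction: str = "stepwise",
    screen_p: float = 0.20,
    always_candidates: Sequence[str] = (),
) -> StepwiseResult:
    """AIC-driven logistic model selection.

    Candidates are first screened by univariable Wald p < ``screen_p``;
    covariates in ``always_candidates`` (age, sex in the study design) stay
    in the candidate pool regardless of their univariable p.  ``stepwise``
    alternates add/drop moves from the intercept-only model; ``backward``
    starts from the full screened model and only drops.  The move that
    lowers AIC most is taken; ties break on covariate name.  An empty
    post-screen pool returns the intercept-only model, flagged.
    """

    if direction not in ("stepwise", "backward"):
        raise StatsError(f"stepwise_aic: unknown direction {direction!r}")
    X = _design(candidates)
    y = np.asarray(list(outcome), dtype=int)
    screen_rows = []
    pool = []
    for name in sorted(X.columns):
        try:
            uni = logistic_fit(X[[name]], y)
            p = uni.p_values[uni.names.index(name)]
        except StatsError as exc:
            screen_rows.append({"term": name, "p_value": float("nan"), "kept": False,
                                "note": str(exc)})
            continue
        kept = bool(p < screen_p) or name in always_candidates
        screen_rows.append({"term": name, "p_value": p, "kept": kept, "note": ""})
        if kept:
            pool.append(name)
    screen = pd.DataFrame(screen_rows, columns=["term", "p_value", "kept", "note"])

    def aic_of(names: Sequence[str]) -> float:
        if not names:
            return _intercept_only_fit(y).aic
        try:
            return logistic_fit(X[list(names)], y).aic
        except StatsError:
            return float("inf")

    trace: list[str] = []
    if not pool:
        fit = _intercept_only_fit(y)
        return StepwiseResult(fit=fit, selected=(), screen=screen, trace=trace, flagged_empty=True)

    current = list(pool) if direction == "backward" else []
    current_aic = aic_of(current)
    while True:
        moves: list[tuple[float, str, str]] = []  # (aic, kind, name)
        if direction == "stepwise":
            for name in sorted(set(pool) - set(current)):
                moves.append((aic_of(current + [name]), "add", name))
        for name in sorted(current):
            moves.append((aic_of([c for c in current if c != name]), "drop", name))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        best_aic, kind, name = moves[0]
        if best_aic >= current_aic - 1e-9:
            break
        if kind == "add":
            current = sorted(current + [name])
        else:
            current = [c for c in current if c != name]
        current_aic = best_aic
        trace.append(f"{kind} {name} -> AIC {best_aic:.4f}")

    fit = logistic_fit(X[current], y) if current else _intercept_only_fit(y)
    return StepwiseResult(
        fit=fit,
        selected=tuple(current),
        screen=screen,
        trace=trace,
        flagged_empty=not current,
    )


# ---------------------------------------------------------------------------
# Diagnostics


def hosmer_lemeshow(fit: LogisticModelFit, groups: int = 10) -> TestResult:
    """Hosmer–Lemeshow decile-of-risk goodness-of-fit test.

    Observations are binned into ``groups`` quantile groups of fitted
    probability; the chi-square statistic over observed and expected
    event/non-event counts has ``groups - 2`` degrees of freedom.
    """

    if groups < 3:
        raise StatsError("hosmer_lemeshow: need at least 3 groups (df = groups - 2)")
    p = np.asarray(fit.fitted, dtype=float)
    y = np.asarray(fit.outcome, dtype=float)
    if len(np.unique(p)) < groups:
        raise StatsError(
            f"hosmer_lemeshow: only {len(np.unique(p))} distinct fitted values; "
            "use fewer groups"
        )
    try:
        bins = pd.qcut(p, groups, labels=False, duplicates="raise")
    except ValueError as exc:
        raise StatsError("hosmer_lemeshow: duplicate quantile edges; use fewer groups") from exc
    stat = 0.0
    for g in range(groups):
        m = bins == g
        ng = int(m.sum())
        o1, e1 = y[m].sum(), p[m].sum()
        o0, e0 = ng - o1, ng - e1
        if e1 <= 0 or e0 <= 0:
            raise StatsError(
                "hosmer_lemeshow: zero expected count in a risk group; use fewer groups"
            )
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = groups - 2
    return TestResult(
        method="hosmer_lemeshow",
        statistic=float(stat),
        p_value=float(sps.chi2.sf(stat, df)),
        df=float(df),
        n=(len(y),),
    )


def roc_auc(fit: LogisticModelFit) -> float:
    """Area under the ROC curve of the fitted probabilities.

    Equal to the concordance probability, ties counted one half.
    """

    y = np.asarray(fit.outcome, dtype=int)
    if y.min() == y.max():
        raise StatsError("roc_auc: both outcome classes must be present")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, np.asarray(fit.fitted, dtype=float)))
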