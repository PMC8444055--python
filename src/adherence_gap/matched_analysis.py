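"""Exact conditional logistic regression on matched sets, with the
stratified, trend, homogeneity and sensitivity machinery around it.

For a matched set ``s`` with members ``i``, covariate rows ``x_i`` and
``d_s`` members experiencing the outcome, the conditional likelihood
contribution is

    exp(sum_{cases} x_i' beta) / sum_{J subset, |J| = d_s} exp(sum_{J} x_i' beta)

i.e. the probability of the observed case pattern given the set's case
total, which eliminates the set-specific intercepts.  Set sizes here
are at most 1 + matching ratio, so the denominator is enumerated
exactly (no Breslow/Efron approximation) and maximised by
Newton-Raphson with step-halving.

Effects are presented as (odds ratio - 1) x 100, the percentage
variation in the likelihood of high adherence for exposed versus
unexposed patients, with Wald 95% confidence intervals transformed the
same way.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError, ConvergenceError

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class AnalysisSpec:
    """What to estimate: outcome column, adjustment covariates and the
    optional stratification."""

    outcome: str = "pdc_high_75"
    adjustment_covariates: tuple[str, ...] = ()
    strata_variable: str | None = None
    strata_scores: dict | None = None  # stratum label -> numeric score (trend)


@dataclass
class EffectEstimate:
    """Fitted log-odds ratio for the exposure term with its Wald
    uncertainty and the (OR - 1) x 100 presentation."""

    beta: float
    se: float
    n_sets_informative: int
    n_sets_total: int
    term: str = "exposed"
    covariate_coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        with np.errstate(over="ignore"):
            lo = float(np.exp(self.beta - Z975 * self.se))
            hi = float(np.exp(self.beta + Z975 * self.se))
        return lo, hi

    @property
    def pct_variation(self) -> tuple[float, float, float]:
        lo, hi = self.ci95
        return ((self.or_value - 1) * 100, (lo - 1) * 100, (hi - 1) * 100)

    @property
    def pvalue(self) -> float:
        return float(2 * stats.norm.sf(abs(self.beta) / self.se))


@dataclass
class PercentVariation:
    point: float
    low: float
    high: float
    #: 'reduced' iff the CI upper bound is < 0, 'increased' iff the
    #: lower bound is > 0, else 'indeterminate'
    direction: str


def percent_variation(est: EffectEstimate) -> PercentVariation:
    """Present a fitted estimate as percentage variation of the
    likelihood of high adherence, x -> (x - 1) x 100."""
    point, lo, hi = est.pct_variation
    if hi < 0:
        direction = "reduced"
    elif lo > 0:
        direction = "increased"
    else:
        direction = "indeterminate"
    return PercentVariation(point=point, low=lo, high=hi, direction=direction)


# ---------------------------------------------------------------------------
# Exact conditional likelihood core
# ---------------------------------------------------------------------------

_COMBO_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _combos(n: int, d: int) -> np.ndarray:
    key = (n, d)
    if key not in _COMBO_CACHE:
        _COMBO_CACHE[key] = np.array(list(combinations(range(n), d)), dtype=np.intp)
    return _COMBO_CACHE[key]


class _ExactCLogit:
    """Stacked subset enumeration for all informative sets."""

    def __init__(self, y: np.ndarray, X: np.ndarray, set_ids: np.ndarray):
        order = np.argsort(set_ids, kind="stable")
        y, X, set_ids = y[order], X[order], set_ids[order]
        _, starts_rows = np.unique(set_ids, return_index=True)
        bounds = list(starts_rows) + [len(y)]

        S_blocks, T = [], np.zeros(X.shape[1])
        offsets, n_info, n_total = [], 0, len(starts_rows)
        pos = 0
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            ys, Xs = y[b0:b1], X[b0:b1]
            d = int(ys.sum())
            n = b1 - b0
            if d == 0 or d == n:
                continue  # concordant: no information on beta
            C = _combos(n, d)
            S_blocks.append(Xs[C].sum(axis=1))
            T += Xs[ys == 1].sum(axis=0)
            offsets.append(pos)
            pos += len(C)
            n_info += 1
        if n_info == 0:
            raise AnalysisError("no informative (outcome-discordant) matched sets")
        self.S = np.vstack(S_blocks)
        self.T = T
        self.offsets = np.array(offsets, dtype=np.intp)
        self.set_of_row = np.repeat(
            np.arange(n_info), np.diff(np.append(self.offsets, len(self.S)))
        )
        self.n_informative = n_info
        self.n_total = n_total
        self.p = X.shape[1]

    def loglik(self, beta: np.ndarray) -> float:
        eta = self.S @ beta
        mx = np.maximum.reduceat(eta, self.offsets)
        z = np.add.reduceat(np.exp(eta - mx[self.set_of_row]), self.offsets)
        return float(self.T @ beta - (mx + np.log(z)).sum())

    def derivatives(self, beta: np.ndarray):
        eta = self.S @ beta
        mx = np.maximum.reduceat(eta, self.offsets)
        w = np.exp(eta - mx[self.set_of_row])
        z = np.add.reduceat(w, self.offsets)
        ll = float(self.T @ beta - (mx + np.log(z)).sum())
        w_norm = w / z[self.set_of_row]
        mu = np.add.reduceat(w_norm[:, None] * self.S, self.offsets, axis=0)  # (K, p)
        grad = self.T - mu.sum(axis=0)
        info = np.empty((self.p, self.p))
        for i in range(self.p):
            for j in range(i, self.p):
                e2 = np.add.reduceat(w_norm * self.S[:, i] * self.S[:, j], self.offsets)
                v = (e2 - mu[:, i] * mu[:, j]).sum()
                info[i, j] = info[j, i] = v
        return ll, grad, info


def _fit_exact_clogit(
    y: np.ndarray,
    X: np.ndarray,
    set_ids: np.ndarray,
    names: list[str],
    tol: float = 1e-8,
    max_iter: int = 100,
):
    model = _ExactCLogit(y, X, set_ids)
    beta = np.zeros(model.p)
    ll, grad, info = model.derivatives(beta)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(
                "singular information matrix (separation or collinearity)",
                covariate=names[int(np.argmax(np.abs(beta)))],
            ) from err
        # step-halving on likelihood decrease
        factor = 1.0
        for _half in range(40):
            cand = beta + factor * step
            if model.loglik(cand) >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        # |beta| = 15 is an OR above 3e6: no matched-set contrast this
        # side of separation produces that, so treat it as divergence.
        if np.max(np.abs(beta)) > 15:
            raise ConvergenceError(
                "likelihood is unbounded (separation)",
                covariate=names[int(np.argmax(np.abs(beta)))],
            )
        ll, grad, info = model.derivatives(beta)
    else:
        raise ConvergenceError(
            "Newton-Raphson did not converge",
            covariate=names[int(np.argmax(np.abs(beta)))],
        )
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return beta, se, model


def fit_conditional_logistic(
    members: pd.DataFrame,
    spec: AnalysisSpec | None = None,
    *,
    outcome: str | None = None,
    adjustment_covariates: tuple[str, ...] | None = None,
) -> EffectEstimate:
    """Fit the exposure -> outcome conditional logistic model on matched
    sets given in long format.

    ``members`` needs columns ``set_id``, ``exposed`` (the term of
    interest), the outcome column, and any adjustment covariates.
    Covariates with no within-set variation carry no conditional
    information and are dropped with a log message; if the exposure
    itself never varies within sets the model is inestimable and an
    :class:`AnalysisError` is raised.  Concordant sets are dropped as
    uninformative (counted in ``n_sets_informative`` vs
    ``n_sets_total``).
    """
    spec = spec or AnalysisSpec()
    outcome = outcome or spec.outcome
    adj = tuple(adjustment_covariates if adjustment_covariates is not None
                else spec.adjustment_covariates)

    if outcome not in members.columns:
        raise AnalysisError(f"outcome column {outcome!r} not present")
    y = members[outcome].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise AnalysisError(f"outcome {outcome!r} is not defined for every member")

    cols = ["exposed", *adj]
    X_df = pd.DataFrame(index=members.index)
    X_df["exposed"] = members["exposed"].astype(float)
    for c in adj:
        col = members[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            X_df = pd.concat([X_df, dummies], axis=1)
        else:
            X_df[c] = col.astype(float)
    names = list(X_df.columns)
    X = X_df.to_numpy(dtype=float)
    set_ids = members["set_id"].to_numpy()

    # drop columns with zero within-set variance (set-constant): the
    # conditional likelihood is invariant to them.
    keep = []
    grp = pd.DataFrame(X, columns=names)
    grp["__set"] = set_ids
    wvar = grp.groupby("__set").var(ddof=0).sum(axis=0)
    for i, name in enumerate(names):
        if wvar[name] > 0:
            keep.append(i)
        elif name == "exposed":
            raise AnalysisError(
                "exposure is constant within every matched set; inestimable"
            )
        else:
            logger.info("dropping set-constant covariate %r", name)
    names = [names[i] for i in keep]
    X = X[:, keep]

    beta, se, model = _fit_exact_clogit(y.astype(int), X, set_ids, names)
    i_exp = names.index("exposed")
    others = {
        n: (float(beta[i]), float(se[i]))
        for i, n in enumerate(names)
        if i != i_exp
    }
    n_dropped = model.n_total - model.n_informative
    if n_dropped:
        logger.info("dropped %d concordant sets as uninformative", n_dropped)
    return EffectEstimate(
        beta=float(beta[i_exp]),
        se=float(se[i_exp]),
        n_sets_informative=model.n_informative,
        n_sets_total=model.n_total,
        covariate_coefficients=others,
    )


def conditional_loglik(members: pd.DataFrame, beta: float, outcome: str = "pdc_high_75") -> float:
    """Exact conditional log-likelihood of an exposure-only model at a
    given coefficient value (useful for profiling and oracles)."""
    y = members[outcome].to_numpy(dtype=int)
    X = members[["exposed"]].to_numpy(dtype=float)
    model = _ExactCLogit(y, X, members["set_id"].to_numpy())
    return model.loglik(np.array([beta]))


# ---------------------------------------------------------------------------
# Stratified analysis, between-strata tests, sensitivity suite
# ---------------------------------------------------------------------------

def stratified_estimates(
    members: pd.DataFrame, spec: AnalysisSpec
) -> dict[object, EffectEstimate]:
    """Independent fits per stratum.

    The stratum of a set is the exposed member's value of the
    stratification variable (for matched variables this equals every
    member's value).  Strata with no informative sets are absent from
    the result.
    """
    if spec.strata_variable is None:
        raise AnalysisError("spec.strata_variable is not set")
    var = spec.strata_variable
    stratum_of_set = (
        members[members["exposed"]]
        .drop_duplicates("set_id")
        .set_index("set_id")[var]
    )
    labels = members["set_id"].map(stratum_of_set)
    out: dict[object, EffectEstimate] = {}
    for level in sorted(stratum_of_set.dropna().unique()):
        sub = members[labels == level]
        try:
            out[level] = fit_conditional_logistic(
                sub, AnalysisSpec(outcome=spec.outcome,
                                  adjustment_covariates=spec.adjustment_covariates)
            )
        except AnalysisError:
            logger.info("stratum %r has no informative sets; omitted", level)
    return out


@dataclass
class HomogeneityTest:
    statistic: float
    df: int
    pvalue: float


def homogeneity_test(betas, ses) -> HomogeneityTest:
    """Inverse-variance chi-square test of between-strata homogeneity:
    Q = sum w_k (b_k - b_w)^2 with w_k = 1/se_k^2, on K-1 df."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(b) < 2:
        raise AnalysisError("homogeneity test needs >= 2 strata")
    if np.any(s <= 0):
        raise AnalysisError("standard errors must be positive")
    w = 1.0 / s**2
    b_bar = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - b_bar) ** 2))
    df = len(b) - 1
    return HomogeneityTest(statistic=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


@dataclass
class TrendTest:
    slope: float
    se: float
    pvalue: float


def trend_test(betas, ses, scores) -> TrendTest:
    """Along-strata trend: inverse-variance weighted linear regression
    of stratum log-odds ratios on their category scores, with a Wald
    test of the slope."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    x = np.asarray(scores, dtype=float)
    if len(b) < 2:
        raise AnalysisError("trend test needs >= 2 strata")
    if np.any(s <= 0):
        raise AnalysisError("standard errors must be positive")
    if np.ptp(x) == 0:
        raise AnalysisError("scores are constant; trend undefined")
    w = 1.0 / s**2
    xb = np.sum(w * x) / np.sum(w)
    sxx = np.sum(w * (x - xb) ** 2)
    bb = np.sum(w * b) / np.sum(w)
    slope = float(np.sum(w * (x - xb) * (b - bb)) / sxx)
    se_slope = float(np.sqrt(1.0 / sxx))
    z = slope / se_slope
    return TrendTest(slope=slope, se=se_slope, pvalue=float(2 * stats.norm.sf(abs(z))))


def compare_coefficients_z(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """z-test comparing two independent regression coefficients."""
    if se1 <= 0 or se2 <= 0:
        raise AnalysisError("standard errors must be positive")
    z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def sensitivity_suite(
    members: pd.DataFrame,
    outcomes: tuple[str, ...] = ("pdc_high_70", "pdc_high_75", "pdc_high_80"),
    adjustment_covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """One fitted estimate per outcome definition, side by side.

    Outcomes whose sets are all concordant (or otherwise inestimable)
    are reported with an ``error`` note instead of numbers.
    """
    rows = []
    for oc in outcomes:
        try:
            est = fit_conditional_logistic(
                members, outcome=oc, adjustment_covariates=adjustment_covariates
            )
            point, lo, hi = est.pct_variation
            rows.append(
                dict(
                    outcome=oc,
                    beta=est.beta,
                    se=est.se,
                    or_value=est.or_value,
                    pct=point,
                    pct_low=lo,
                    pct_high=hi,
                    n_sets_informative=est.n_sets_informative,
                    error="",
                )
            )
        except AnalysisError as err:
            rows.append(
                dict(
                    outcome=oc, beta=np.nan, se=np.nan, or_value=np.nan,
                    pct=np.nan, pct_low=np.nan, pct_high=np.nan,
                    n_sets_informative=0, error=str(err),
                )
            )
    return pd.DataFrame(rows)
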