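"""Benchmarking objective quality scores against subjective opinion scores.

The standard IQA evaluation protocol: objective scores ``Q`` are passed
through a five-parameter monotone logistic mapping

    Qp = b1 * (1/2 - 1/(1 + exp(b2 * (Q - b3)))) + b4 * Q + b5

fitted by nonlinear least squares against the mean opinion scores (MOS),
after which four criteria are reported: PLCC and RMSE on the mapped
scores, SRCC and KRCC on the raw scores (rank criteria are invariant to
any monotone mapping).  Residuals ``Qp - MOS`` feed two significance
checks: a Jarque-Bera normality gate, and a variance-ratio F-test on
samples resampled from normals fitted to each method's residuals.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "ScorePair",
    "LogisticMapping",
    "EvaluationReport",
    "JarqueBeraResult",
    "FTestResult",
    "fit_logistic",
    "apply_logistic",
    "plcc",
    "srcc",
    "krcc",
    "rmse",
    "jarque_bera",
    "residual_f_test",
    "evaluate_scores",
]


@dataclass(frozen=True)
class ScorePair:
    """Matched objective scores and mean opinion scores for m images."""

    Q: np.ndarray
    MOS: np.ndarray
    ids: tuple = ()

    def __post_init__(self) -> None:
        q = np.asarray(self.Q, dtype=np.float64)
        mos = np.asarray(self.MOS, dtype=np.float64)
        if q.ndim != 1 or mos.ndim != 1 or q.shape != mos.shape:
            raise ValueError("Q and MOS must be 1-D vectors of equal length")
        if q.shape[0] < 4:
            raise ValueError(f"need at least 4 score pairs, got {q.shape[0]}")
        if np.any(mos < 1.0) or np.any(mos > 5.0):
            raise ValueError("MOS values must lie in [1, 5]")
        ids = tuple(self.ids) if len(self.ids) else tuple(range(q.shape[0]))
        if len(ids) != q.shape[0]:
            raise ValueError("ids length must match the score vectors")
        object.__setattr__(self, "Q", q)
        object.__setattr__(self, "MOS", mos)
        object.__setattr__(self, "ids", ids)

    @property
    def m(self) -> int:
        return int(self.Q.shape[0])


@dataclass(frozen=True)
class LogisticMapping:
    """Fitted parameters b1..b5 of the monotone logistic regression model."""

    beta: tuple

    def __post_init__(self) -> None:
        beta = tuple(float(b) for b in self.beta)
        if len(beta) != 5 or not all(math.isfinite(b) for b in beta):
            raise ValueError("beta must be 5 finite parameters")
        object.__setattr__(self, "beta", beta)

    def __call__(self, Q: np.ndarray) -> np.ndarray:
        return apply_logistic(np.asarray(Q, dtype=np.float64), self.beta)


def apply_logistic(Q: np.ndarray, beta: Sequence[float]) -> np.ndarray:
    """Evaluate the five-parameter logistic mapping (overflow-safe)."""
    b1, b2, b3, b4, b5 = beta
    # 1/(1+exp(b2*(Q-b3))) == expit(-b2*(Q-b3))
    return b1 * (0.5 - special.expit(-b2 * (Q - b3))) + b4 * Q + b5


def _residuals(beta: np.ndarray, Q: np.ndarray, MOS: np.ndarray) -> np.ndarray:
    return apply_logistic(Q, beta) - MOS


def fit_logistic(pair: ScorePair, max_iter: int = 2000, tol: float = 1e-8) -> LogisticMapping:
    """Least-squares fit of the five-parameter logistic mapping.

    Deterministic multi-start Levenberg-Marquardt: the standard start
    spans the data ranges (b1 = MOS range, b2 = 1/std(Q), b3 = mean(Q),
    b4 = 0, b5 = mean(MOS)), plus its sign-flipped variant and a start at
    the ordinary linear fit, which is nested in the model (b1 = 0).  The
    best final sum of squares wins, so the fit never ends worse than the
    plain linear regression of MOS on Q.
    """
    Q, MOS = pair.Q, pair.MOS
    if pair.m < 6:
        raise ValueError(f"logistic fit needs at least 6 pairs, got {pair.m}")
    q_std = float(np.std(Q))
    if q_std == 0.0:
        raise ValueError("objective scores are constant; logistic fit is degenerate")
    mos_range = float(np.max(MOS) - np.min(MOS))
    slope, intercept = np.polyfit(Q, MOS, 1)
    starts = [
        np.array([mos_range, 1.0 / q_std, float(np.mean(Q)), 0.0, float(np.mean(MOS))]),
        np.array([-mos_range, 1.0 / q_std, float(np.mean(Q)), 0.0, float(np.mean(MOS))]),
        np.array([0.0, 1.0 / q_std, float(np.mean(Q)), float(slope), float(intercept)]),
    ]
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                _residuals,
                x0,
                args=(Q, MOS),
                method="lm",
                max_nfev=max_iter,
                xtol=tol,
                ftol=tol,
                gtol=tol,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("logistic fit failed to converge from all starting points")
    return LogisticMapping(beta=tuple(best.x))


def plcc(Qp: np.ndarray, MOS: np.ndarray) -> float:
    """Pearson linear correlation of the mean-removed vectors."""
    Qp = np.asarray(Qp, dtype=np.float64)
    MOS = np.asarray(MOS, dtype=np.float64)
    if Qp.shape != MOS.shape or Qp.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    x = Qp - Qp.mean()
    y = MOS - MOS.mean()
    denom = math.sqrt(float(x @ x) * float(y @ y))
    if denom == 0.0:
        raise ValueError("correlation undefined for a zero-variance input")
    return float(x @ y) / denom


def srcc(Q: np.ndarray, MOS: np.ndarray) -> float:
    """Spearman rank correlation.

    Tie-free data uses the closed form 1 - 6*sum(d_i^2)/(m(m^2-1));
    with ties it falls back to Pearson correlation of average ranks.
    """
    Q = np.asarray(Q, dtype=np.float64)
    MOS = np.asarray(MOS, dtype=np.float64)
    if Q.shape != MOS.shape or Q.ndim != 1 or Q.shape[0] < 2:
        raise ValueError("need two 1-D vectors of equal length >= 2")
    m = Q.shape[0]
    rq = stats.rankdata(Q)
    rm = stats.rankdata(MOS)
    ties = (np.unique(Q).size < m) or (np.unique(MOS).size < m)
    if not ties:
        d = rq - rm
        return float(1.0 - 6.0 * float(d @ d) / (m * (m * m - 1)))
    return plcc(rq, rm)


def krcc(Q: np.ndarray, MOS: np.ndarray) -> float:
    """Kendall rank correlation by exhaustive pair enumeration (tau-a).

    (m_c - m_d) / (0.5 * m * (m - 1)); pairs tied in either vector are
    counted as neither concordant nor discordant.
    """
    Q = np.asarray(Q, dtype=np.float64)
    MOS = np.asarray(MOS, dtype=np.float64)
    if Q.shape != MOS.shape or Q.ndim != 1 or Q.shape[0] < 2:
        raise ValueError("need two 1-D vectors of equal length >= 2")
    m = Q.shape[0]
    sq = np.sign(Q[:, None] - Q[None, :])
    sm = np.sign(MOS[:, None] - MOS[None, :])
    prod = sq * sm
    iu = np.triu_indices(m, k=1)
    concordant = int(np.count_nonzero(prod[iu] > 0))
    discordant = int(np.count_nonzero(prod[iu] < 0))
    return (concordant - discordant) / (0.5 * m * (m - 1))


def rmse(Qp: np.ndarray, MOS: np.ndarray) -> float:
    """Root mean squared residual between mapped scores and MOS."""
    Qp = np.asarray(Qp, dtype=np.float64)
    MOS = np.asarray(MOS, dtype=np.float64)
    if Qp.shape != MOS.shape or Qp.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    d = Qp - MOS
    return math.sqrt(float(d @ d) / d.shape[0])


@dataclass(frozen=True)
class JarqueBeraResult:
    statistic: float
    critical_value: float
    alpha: float
    n: int
    is_normal: bool  # null (normality) retained at alpha


@functools.lru_cache(maxsize=64)
def _jb_critical_value_mc(n: int, alpha: float, n_sim: int = 50_000) -> float:
    """Small-sample critical value of the JB statistic by Monte Carlo.

    The chi2(2) asymptote is badly anti-conservative for moderate n, so
    the null distribution is simulated from standard-normal samples with
    a fixed internal seed (the critical value is a property of n, not of
    the data).
    """
    rng = np.random.default_rng(20_220_220)
    chunk = max(1, int(2e7 // n))
    sims = []
    done = 0
    while done < n_sim:
        k = min(chunk, n_sim - done)
        x = rng.standard_normal((k, n))
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        m2 = np.mean(xc**2, axis=1)
        skew = np.mean(xc**3, axis=1) / m2**1.5
        kurt = np.mean(xc**4, axis=1) / m2**2
        sims.append(n / 6.0 * (skew**2 + (kurt - 3.0) ** 2 / 4.0))
        done += k
    return float(np.quantile(np.concatenate(sims), 1.0 - alpha))


def jarque_bera(residuals: np.ndarray, alpha: float = 0.05) -> JarqueBeraResult:
    """Moment-based normality test JB = n/6 * (skew^2 + (kurt-3)^2/4).

    Uses the asymptotic chi2(2) critical value for n >= 2000 and a
    simulated small-sample critical value below that.
    """
    x = np.asarray(residuals, dtype=np.float64)
    if x.ndim != 1 or x.shape[0] < 8:
        raise ValueError("need a 1-D residual vector of length >= 8")
    n = x.shape[0]
    xc = x - x.mean()
    m2 = float(np.mean(xc**2))
    if m2 == 0.0:
        raise ValueError("residuals are constant; normality test undefined")
    skew = float(np.mean(xc**3)) / m2**1.5
    kurt = float(np.mean(xc**4)) / m2**2
    jb = n / 6.0 * (skew**2 + (kurt - 3.0) ** 2 / 4.0)
    if n >= 2000:
        crit = float(stats.chi2.ppf(1.0 - alpha, df=2))
    else:
        crit = _jb_critical_value_mc(n, alpha)
    return JarqueBeraResult(
        statistic=jb, critical_value=crit, alpha=alpha, n=n, is_normal=jb <= crit
    )


@dataclass(frozen=True)
class FTestResult:
    variance_ratio: float  # var(draws_A) / var(draws_B)
    df: tuple
    p_two_sided: float
    p_one_sided_less: float  # H1: var_A < var_B
    reject_two_sided: bool
    reject_one_sided_less: bool
    alpha: float
    seed: int


def residual_f_test(
    residuals_A: np.ndarray,
    residuals_B: np.ndarray,
    n_draws: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    require_normal: bool = True,
) -> FTestResult:
    """Variance-ratio F-test on samples resampled from fitted normals.

    A normal distribution (sample mean and variance) is fitted to each
    residual vector, ``n_draws`` samples are drawn from each with the
    given seed, and the ratio of the two drawn sample variances is
    referred to an F distribution with (n_draws-1, n_draws-1) degrees of
    freedom.  Both the two-sided decision (different variances) and the
    one-sided decision (variance of A smaller than B) are reported.

    The resampling step is only exactly sized when the fitted normals are
    close to the truth, i.e. for long residual vectors; the test is run
    only after both vectors pass the Jarque-Bera gate.
    """
    a = np.asarray(residuals_A, dtype=np.float64)
    b = np.asarray(residuals_B, dtype=np.float64)
    if require_normal:
        for name, vec in (("A", a), ("B", b)):
            jb = jarque_bera(vec, alpha=alpha)
            if not jb.is_normal:
                raise ValueError(
                    f"residuals {name} fail the Jarque-Bera normality gate "
                    f"(JB={jb.statistic:.3f} > {jb.critical_value:.3f}); "
                    "the variance F-test assumes Gaussian residuals"
                )
    rng = np.random.default_rng(seed)
    draws_a = rng.normal(a.mean(), a.std(ddof=1), size=n_draws)
    draws_b = rng.normal(b.mean(), b.std(ddof=1), size=n_draws)
    va = float(np.var(draws_a, ddof=1))
    vb = float(np.var(draws_b, ddof=1))
    ratio = va / vb
    dfn = dfd = n_draws - 1
    cdf = float(stats.f.cdf(ratio, dfn, dfd))
    p_two = 2.0 * min(cdf, 1.0 - cdf)
    p_less = cdf  # small ratio -> var_A smaller
    return FTestResult(
        variance_ratio=ratio,
        df=(dfn, dfd),
        p_two_sided=p_two,
        p_one_sided_less=p_less,
        reject_two_sided=p_two < alpha,
        reject_one_sided_less=p_less < alpha,
        alpha=alpha,
        seed=seed,
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Four IQA criteria plus the fitted mapping and residual diagnostics."""

    plcc: float
    srcc: float
    krcc: float
    rmse: float
    mapping: LogisticMapping
    residuals: np.ndarray
    jb: JarqueBeraResult | None = None
    f_test: FTestResult | None = None
    ids: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = {
            "plcc": self.plcc,
            "srcc": self.srcc,
            "krcc": self.krcc,
            "rmse": self.rmse,
            "beta": list(self.mapping.beta),
        }
        if self.jb is not None:
            d["jarque_bera"] = {
                "statistic": self.jb.statistic,
                "critical_value": self.jb.critical_value,
                "alpha": self.jb.alpha,
                "is_normal": self.jb.is_normal,
            }
        if self.f_test is not None:
            d["f_test"] = {
                "variance_ratio": self.f_test.variance_ratio,
                "p_two_sided": self.f_test.p_two_sided,
                "p_one_sided_less": self.f_test.p_one_sided_less,
                "reject_two_sided": self.f_test.reject_two_sided,
                "reject_one_sided_less": self.f_test.reject_one_sided_less,
                "seed": self.f_test.seed,
            }
        return d


def evaluate_scores(
    pair: ScorePair,
    reference_residuals: np.ndarray | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Full evaluation of one objective measure against MOS.

    Fits the logistic mapping, computes PLCC/RMSE on mapped scores and
    SRCC/KRCC on raw scores, runs the Jarque-Bera check on the residuals
    and, when a competing measure's residual vector is supplied, the
    resampled variance-ratio F-test against it.
    """
    mapping = fit_logistic(pair)
    qp = mapping(pair.Q)
    residuals = qp - pair.MOS
    jb = jarque_bera(residuals) if pair.m >= 8 else None
    f_res = None
    if reference_residuals is not None and jb is not None and jb.is_normal:
        f_res = residual_f_test(residuals, reference_residuals, seed=seed)
    return EvaluationReport(
        plcc=plcc(qp, pair.MOS),
        srcc=srcc(pair.Q, pair.MOS),
        krcc=krcc(pair.Q, pair.MOS),
        rmse=rmse(qp, pair.MOS),
        mapping=mapping,
        residuals=residuals,
        jb=jb,
        f_test=f_res,
        ids=pair.ids,
    )
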