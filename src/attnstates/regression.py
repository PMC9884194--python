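"""Moderated regression of RTV on thought immersion, and power utilities.

The focal analysis regresses pre-probe response-time variability on centered
task-focus immersion, centered task-unrelated-thought (TUT) immersion, and
their interaction, pooling valid pre-probe windows across participants.
Standardised betas, VIFs and mean±1SD simple slopes mirror the conventional
reporting of a moderated regression.  Power utilities cover the two designs
used to justify the sample size: a two-sided test of a Pearson correlation
and a one-way k-group ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.power import FTestAnovaPower


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass
class RegressionResult:
    """OLS fit of y ~ x1 + x2 + x1:x2 with reporting extras."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    beta: np.ndarray          # standardised (response-scaled) coefficients
    tvalues: np.ndarray
    pvalues: np.ndarray
    adj_r2: float
    r2: float
    F: float
    F_df: tuple[int, int]
    F_p: float
    vif: dict[str, float]
    n: int
    df_resid: int
    cov: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "coef": self.coef,
            "se": self.se,
            "beta": self.beta,
            "t": self.tvalues,
            "p": self.pvalues,
            "vif": [self.vif.get(t, np.nan) for t in self.terms],
        })


def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    ``R^2_j`` comes from regressing predictor j on all other predictors
    (with intercept).  Perfectly collinear predictors report ``inf``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        yj = X[:, j]
        others = np.column_stack([np.ones(len(X)),
                                  np.delete(X, j, axis=1)])
        bhat, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ bhat
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def ols_interaction(rtv, task_focus, tut,
                    names: tuple[str, str] = ("task_focus", "tut")
                    ) -> RegressionResult:
    """OLS of RTV on two (centered) predictors and their product."""
    y = np.asarray(rtv, dtype=float)
    x1 = np.asarray(task_focus, dtype=float)
    x2 = np.asarray(tut, dtype=float)
    if not len(y) == len(x1) == len(x2):
        raise ValueError("response and predictors must have equal length")
    inter = x1 * x2
    terms = [names[0], names[1], f"{names[0]}:{names[1]}"]
    X = np.column_stack([x1, x2, inter])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < 4:
        corr = np.corrcoef(X, rowvar=False)
        bad = [f"{terms[i]}~{terms[j]}" for i in range(3)
               for j in range(i + 1, 3) if abs(corr[i, j]) > 1 - 1e-10]
        raise CollinearityError(
            "rank-deficient design; collinear terms: " + ", ".join(bad))
    res = sm.OLS(y, sm.add_constant(X)).fit()
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    return RegressionResult(
        terms=["const"] + terms,
        coef=res.params,
        se=res.bse,
        beta=np.concatenate([[np.nan], res.params[1:] * sx / sy]),
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        adj_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        F=float(res.fvalue),
        F_df=(int(res.df_model), int(res.df_resid)),
        F_p=float(res.f_pvalue),
        vif=dict(zip(terms, vif(X))),
        n=len(y),
        df_resid=int(res.df_resid),
        cov=np.asarray(res.cov_params()),
        X=X,
        y=y,
    )


@dataclass
class SimpleSlopeResult:
    moderator: str
    moderator_level: float
    slope: float
    se: float
    t: float
    p: float


def simple_slopes(result: RegressionResult, focal: str = "task_focus",
                  moderator: str = "tut",
                  levels: np.ndarray | None = None) -> list[SimpleSlopeResult]:
    """Conditional slopes of the focal predictor at fixed moderator levels.

    Default levels are the moderator's mean ± 1 SD.  The slope at level m0
    is b_focal + b_int * m0; its variance follows from the coefficient
    covariance (var_f + m0^2 var_i + 2 m0 cov_fi); p-values use the t
    distribution on the residual df.
    """
    try:
        i_f = result.terms.index(focal)
        inter = (f"{focal}:{moderator}"
                 if f"{focal}:{moderator}" in result.terms
                 else f"{moderator}:{focal}")
        i_i = result.terms.index(inter)
    except ValueError as exc:
        raise ValueError(
            f"model does not contain the {focal} x {moderator} "
            "interaction") from exc
    i_m = result.terms.index(moderator)
    m = result.X[:, i_m - 1]   # X excludes the constant column
    if levels is None:
        mu, sd = m.mean(), m.std(ddof=1)
        levels = np.array([mu + sd, mu - sd])
    out = []
    for m0 in np.atleast_1d(levels):
        slope = result.coef[i_f] + result.coef[i_i] * m0
        var = (result.cov[i_f, i_f] + m0 ** 2 * result.cov[i_i, i_i]
               + 2 * m0 * result.cov[i_f, i_i])
        se = float(np.sqrt(var))
        t = slope / se
        p = 2 * float(stats.t.sf(abs(t), result.df_resid))
        out.append(SimpleSlopeResult(moderator, float(m0), float(slope),
                                     se, float(t), p))
    return out


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

def correlation_power(n: float, r: float, alpha: float = 0.05) -> float:
    """Power of the two-sided test of H0: rho = 0 at true correlation ``r``.

    Uses the exact-r convention: the critical correlation comes from the t
    distribution on n-2 df, and the sampling distribution of the observed
    correlation is approximated on the Fisher-z scale with the
    r/(2(n-1)) bias correction and SD 1/sqrt(n-3).
    """
    df = n - 2
    tcrit = stats.t.isf(alpha / 2, df)
    rc = np.sqrt(tcrit ** 2 / (tcrit ** 2 + df))
    zr = np.arctanh(r) + r / (2 * (n - 1))
    return float(stats.norm.cdf((zr - np.arctanh(rc)) * np.sqrt(n - 3)))


def power_sample_size(test: str, effect_size: float, alpha: float = 0.05,
                      power: float = 0.8, k_groups: int = 4) -> float:
    """Smallest real n achieving the target power; returned unrounded.

    ``test='correlation'`` solves the two-sided Pearson-correlation test at
    true r = ``effect_size`` (total n).  ``test='oneway_anova'`` solves the
    one-way ``k_groups``-group design at Cohen's f = ``effect_size``
    (per-group n, via the noncentral-F power function).
    """
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if test == "correlation":
        f = lambda n: correlation_power(n, effect_size, alpha) - power
        hi = 10.0
        while f(hi) < 0:
            hi *= 2
            if hi > 1e8:
                raise ValueError("requested power unreachable")
        return float(optimize.brentq(f, 4.0 + 1e-9, hi, xtol=1e-6))
    if test == "oneway_anova":
        total = FTestAnovaPower().solve_power(
            effect_size=effect_size, alpha=alpha, power=power,
            k_groups=k_groups)
        return float(total) / k_groups
    raise ValueError(f"unknown test: {test!r}")
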