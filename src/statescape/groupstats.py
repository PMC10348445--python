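"""Group-level statistics: contrasts, correlations, FDR, mediation.

Thin, explicitly-parameterized wrappers over scipy/statsmodels for the
tests used throughout cohort analyses (pooled-variance t with Cohen's d,
two-way ANOVA interaction with partial η², Pearson and partial
correlation, Benjamini–Hochberg and Bonferroni control), plus a
bootstrap mediation model.

Mediation decomposes the effect of ``x`` on ``y`` through a mediator
``m`` with three OLS fits::

    m = a0 + α x            (path α)
    y = c0 + γ x            (total effect γ)
    y = c0' + γ' x + β m    (direct effect γ', path β)

The indirect effect is α×β, equal to γ − γ' by the OLS identity, and its
uncertainty is assessed by a seeded percentile case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "MediationResult",
    "Mediation",
    "two_sample_t",
    "two_way_anova_interaction",
    "pearson_correlation",
    "partial_correlation",
    "bh_fdr",
    "bonferroni",
    "mediation_bootstrap",
]


@dataclass
class TestResult:
    """A single hypothesis test: statistic, dfs, p-values, effect size."""

    statistic: float
    df: tuple
    p_raw: float
    effect_size: float
    method: str
    p_adjusted: float | None = None
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": list(self.df),
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "effect_size": self.effect_size,
            "method": self.method,
            "undefined": self.undefined,
        }


def two_sample_t(a, b) -> TestResult:
    """Pooled-variance two-sample t test with Cohen's d (pooled SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two observations")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    return TestResult(
        statistic=float(t),
        df=(na + nb - 2,),
        p_raw=float(p),
        effect_size=float(d),
        method="two-sample t (pooled), Cohen's d",
    )


def two_way_anova_interaction(y, factor1, factor2) -> TestResult:
    """Interaction term of a 2×2 ANOVA with type-II sums of squares.

    Type-II SS keeps main effects interpretable with unbalanced cell
    sizes.  Effect size is partial η² = SS_int / (SS_int + SS_error).
    A constant response yields an undefined-flagged result rather than
    an exception.
    """
    frame = pd.DataFrame(
        {
            "y": np.asarray(y, dtype=float),
            "f1": np.asarray(factor1),
            "f2": np.asarray(factor2),
        }
    )
    cells = frame.groupby(["f1", "f2"], observed=True).size()
    if len(cells) < 4:
        raise ValueError("all four factor cells must be nonempty")
    if frame["y"].nunique() == 1:
        return TestResult(
            statistic=float("nan"),
            df=(1, frame.shape[0] - 4),
            p_raw=float("nan"),
            effect_size=float("nan"),
            method="two-way ANOVA interaction (type II), partial eta^2",
            undefined=True,
        )
    fit = smf.ols("y ~ C(f1) * C(f2)", data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    inter = table.loc["C(f1):C(f2)"]
    resid = table.loc["Residual"]
    ss_int, ss_err = float(inter["sum_sq"]), float(resid["sum_sq"])
    return TestResult(
        statistic=float(inter["F"]),
        df=(int(inter["df"]), int(resid["df"])),
        p_raw=float(inter["PR(>F)"]),
        effect_size=ss_int / (ss_int + ss_err),
        method="two-way ANOVA interaction (type II), partial eta^2",
    )


def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Pearson r with its t-based p-value; returns (r, p, df = n − 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), x.shape[0] - 2


def partial_correlation(x, y, control) -> tuple[float, float]:
    """Correlation of x and y after removing linear effects of controls.

    Both variables are residualized on the control matrix (with
    intercept) by OLS; the partial r is the Pearson correlation of the
    residuals with p from a t statistic on df = n − k − 2 for k controls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(control, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = Z.shape
    if n <= k + 2:
        raise ValueError("need n > number of controls + 2")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("control design matrix is rank deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if rx.std() < 1e-12 or ry.std() < 1e-12:
        raise ValueError("zero residual variance after controlling")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    t = r * np.sqrt(df / max(1e-300, 1 - r**2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up; returns (adjusted p, significance mask)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(1, p × m)``."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


@dataclass
class MediationResult:
    """Path coefficients, bootstrap CIs and the indirect effect α×β."""

    alpha: float
    beta: float
    gamma: float
    gamma_prime: float
    indirect: float
    ci: dict  # name -> (low, high) percentile bootstrap interval
    n_boot: int
    seed: int | None
    n_obs: int

    def significant_indirect(self) -> bool:
        lo, hi = self.ci["indirect"]
        return not (lo <= 0.0 <= hi)

    def summary(self) -> str:
        rows = [
            ("alpha (x -> m)", self.alpha),
            ("beta (m -> y | x)", self.beta),
            ("gamma (total x -> y)", self.gamma),
            ("gamma' (direct x -> y | m)", self.gamma_prime),
            ("alpha x beta (indirect)", self.indirect),
        ]
        keys = ["alpha", "beta", "gamma", "gamma_prime", "indirect"]
        lines = [
            "Mediation analysis (percentile bootstrap, "
            f"{self.n_boot} resamples, n={self.n_obs})",
            "=" * 62,
        ]
        for (name, value), key in zip(rows, keys):
            lo, hi = self.ci[key]
            star = "*" if not (lo <= 0.0 <= hi) else " "
            lines.append(f"{name:<28s} {value:+.4f}  95% CI [{lo:+.4f}, {hi:+.4f}] {star}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "gamma_prime": self.gamma_prime,
            "indirect": self.indirect,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_obs": self.n_obs,
        }


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS path coefficients (alpha, beta, gamma, gamma_prime)."""
    n = x.shape[0]
    Xi = np.column_stack([np.ones(n), x])
    alpha = np.linalg.lstsq(Xi, m, rcond=None)[0][1]
    gamma = np.linalg.lstsq(Xi, y, rcond=None)[0][1]
    Xim = np.column_stack([np.ones(n), x, m])
    coef = np.linalg.lstsq(Xim, y, rcond=None)[0]
    gamma_prime, beta = coef[1], coef[2]
    return float(alpha), float(beta), float(gamma), float(gamma_prime)


class Mediation:
    """Bootstrap mediation model for a single mediator.

    ``Mediation(x, m, y).fit(n_boot=5000, seed=0)`` returns a
    :class:`MediationResult`.  Case resampling: subjects are drawn with
    replacement and all three regressions are refit per resample; CIs
    are percentile intervals.
    """

    def __init__(self, x, m, y) -> None:
        self.x = np.asarray(x, dtype=float)
        self.m = np.asarray(m, dtype=float)
        self.y = np.asarray(y, dtype=float)
        n = self.x.shape[0]
        if not (self.m.shape[0] == n and self.y.shape[0] == n):
            raise ValueError("x, m, y must have equal length")
        if n < 10:
            raise ValueError("mediation needs at least 10 observations")
        if self.x.std() == 0 or self.m.std() == 0:
            raise ValueError("x and m must vary")
        if abs(np.corrcoef(self.x, self.m)[0, 1]) > 1 - 1e-8:
            raise ValueError("x and m are collinear; paths not identifiable")

    def fit(
        self,
        n_boot: int = 5000,
        seed: int | np.random.Generator | None = None,
        ci_level: float = 0.95,
    ) -> MediationResult:
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        alpha, beta, gamma, gamma_prime = _paths(self.x, self.m, self.y)
        identity_gap = abs(gamma - (gamma_prime + alpha * beta))
        if identity_gap > 1e-8:  # pragma: no cover - algebraic identity
            raise AssertionError(f"OLS identity violated by {identity_gap:.2e}")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        n = self.x.shape[0]
        draws = np.empty((n_boot, 5))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            a, bb, g, gp = _paths(self.x[idx], self.m[idx], self.y[idx])
            draws[b] = (a, bb, g, gp, a * bb)
        lo_q = 100 * (1 - ci_level) / 2
        hi_q = 100 - lo_q
        lo, hi = np.percentile(draws, [lo_q, hi_q], axis=0)
        names = ["alpha", "beta", "gamma", "gamma_prime", "indirect"]
        ci = {k: (float(lo[i]), float(hi[i])) for i, k in enumerate(names)}
        return MediationResult(
            alpha=alpha,
            beta=beta,
            gamma=gamma,
            gamma_prime=gamma_prime,
            indirect=alpha * beta,
            ci=ci,
            n_boot=n_boot,
            seed=seed if isinstance(seed, int) else None,
            n_obs=n,
        )


def mediation_bootstrap(x, m, y, n_boot: int = 5000, seed=None) -> MediationResult:
    """Functional wrapper around :class:`Mediation`."""
    return Mediation(x, m, y).fit(n_boot=n_boot, seed=seed)
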