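"""Inverse-variance meta-analysis of site means and sample-size planning.

Meta-analysis: site summaries (mean, sd, n) are pooled by generic inverse
variance.  The common-effects model uses weights 1/SE²; heterogeneity is
summarised by Cochran's Q (chi-squared with k−1 df) and I² = (Q − df)/Q.
Between-site variance τ² is estimated by restricted maximum likelihood
(fixed-point iteration on the REML score equation, tolerance 1e-10, max 100
iterations, non-negativity projection), and the random-effects mean is
reported with the Knapp–Hartung adjustment: the RE variance is rescaled by
q = Σ wᵢ*(xᵢ − x̄*)² / (k−1) and the CI uses a t quantile with k−1 df.  By
default q is floored at 1 so the adjusted interval is never narrower than
the unadjusted one.

Sample-size planning: exact noncentral-t search for the one-tailed paired
t-test, exact Pearson-r power (numerical integration of the sampling density
of r under bivariate normality, with a Fisher-z cross-check mode), AIPE
(accuracy in parameter estimation, targeting an expected CI width), and a
TOST equivalence design solved by exact intersection power.  All solvers
return the smallest n meeting the criterion (the criterion fails at n−1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special
from scipy import stats as sst

__all__ = [
    "SiteSummary",
    "MetaResult",
    "inverse_variance_meta",
    "forest_table",
    "power_paired_t",
    "power_correlation_exact",
    "correlation_power",
    "aipe_mean_n",
    "tost_equivalence_n",
    "tost_power",
    "inflate",
]

_MAX_N = 1_000_000


@dataclass(frozen=True)
class SiteSummary:
    """Per-site mean n-NRF lance magnitude with its sd and sample size."""

    site: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @property
    def se(self) -> float:
        return self.sd / math.sqrt(self.n)


@dataclass(frozen=True)
class MetaResult:
    k: int
    ce_mean: float
    ce_se: float
    ce_ci95: tuple[float, float]
    Q: float
    Q_p: float
    I2: float  # percent
    tau2: float
    re_mean: float
    re_se: float  # Knapp–Hartung adjusted
    re_ci95: tuple[float, float]
    kh_q: float
    degenerate: bool = False  # k == 1

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "common_effects": {
                "mean": self.ce_mean,
                "se": self.ce_se,
                "ci95": list(self.ce_ci95),
            },
            "heterogeneity": {"Q": self.Q, "p": self.Q_p, "I2_percent": self.I2},
            "random_effects": {
                "tau2": self.tau2,
                "mean": self.re_mean,
                "se": self.re_se,
                "ci95": list(self.re_ci95),
                "knapp_hartung_q": self.kh_q,
            },
            "degenerate": self.degenerate,
        }


def _reml_tau2(y: np.ndarray, v: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> float:
    """REML between-site variance via fixed-point iteration, projected to >= 0."""
    tau2 = max(_dersimonian_laird(y, v), 0.0)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = float((w * y).sum() / w.sum())
        new = float(
            ((w**2) * ((y - mu) ** 2 - v)).sum() / (w**2).sum() + 1.0 / w.sum()
        )
        new = max(new, 0.0)
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    return tau2


def _dersimonian_laird(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu = (w * y).sum() / w.sum()
    Q = (w * (y - mu) ** 2).sum()
    k = y.size
    c = w.sum() - (w**2).sum() / w.sum()
    return float((Q - (k - 1)) / c) if c > 0 else 0.0


def inverse_variance_meta(
    sites: list[SiteSummary], kh_floor: bool = True
) -> MetaResult:
    """Pool site means by generic inverse variance (CE + REML/KH RE models)."""
    for s in sites:
        if s.sd == 0.0:
            raise ValueError(f"site {s.site!r} has sd = 0 (infinite weight)")
    y = np.array([s.mean for s in sites])
    v = np.array([s.se**2 for s in sites])
    k = y.size
    if k == 0:
        raise ValueError("no sites")
    w = 1.0 / v
    ce_mean = float((w * y).sum() / w.sum())
    ce_se = float(1.0 / math.sqrt(w.sum()))
    z = sst.norm.ppf(0.975)
    ce_ci = (ce_mean - z * ce_se, ce_mean + z * ce_se)
    if k == 1:
        return MetaResult(
            1, ce_mean, ce_se, ce_ci, 0.0, 1.0, 0.0, 0.0, ce_mean, ce_se,
            ce_ci, 1.0, degenerate=True,
        )
    Q = float((w * (y - ce_mean) ** 2).sum())
    df = k - 1
    Q_p = float(sst.chi2.sf(Q, df))
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    tau2 = _reml_tau2(y, v)
    ws = 1.0 / (v + tau2)
    re_mean = float((ws * y).sum() / ws.sum())
    re_var = 1.0 / ws.sum()
    kh_q = float((ws * (y - re_mean) ** 2).sum() / df)
    if kh_floor:
        kh_q = max(kh_q, 1.0)
    re_se = math.sqrt(kh_q * re_var)
    tq = sst.t.ppf(0.975, df)
    re_ci = (re_mean - tq * re_se, re_mean + tq * re_se)
    return MetaResult(
        k, ce_mean, ce_se, ce_ci, Q, Q_p, I2, tau2, re_mean, re_se, re_ci, kh_q
    )


def forest_table(sites: list[SiteSummary], result: MetaResult):
    """Per-site forest-plot rows: mean, 95% CI and CE/RE weights (percent)."""
    import pandas as pd

    z = sst.norm.ppf(0.975)
    w_ce = np.array([1.0 / s.se**2 for s in sites])
    w_re = np.array([1.0 / (s.se**2 + result.tau2) for s in sites])
    return pd.DataFrame(
        {
            "site": [s.site for s in sites],
            "mean": [s.mean for s in sites],
            "lower": [s.mean - z * s.se for s in sites],
            "upper": [s.mean + z * s.se for s in sites],
            "weight_CE_pct": 100.0 * w_ce / w_ce.sum(),
            "weight_RE_pct": 100.0 * w_re / w_re.sum(),
        }
    )


# ---------------------------------------------------------------- power --

def _paired_t_power(n: int, d: float, alpha: float, tail: str) -> float:
    df = n - 1
    nc = d * math.sqrt(n)
    if tail == "one":
        tc = sst.t.ppf(1.0 - alpha, df)
        return float(sst.nct.sf(tc, df, nc))
    tc = sst.t.ppf(1.0 - alpha / 2.0, df)
    return float(sst.nct.sf(tc, df, nc) + sst.nct.cdf(-tc, df, nc))


def power_paired_t(
    d: float, alpha: float = 0.02, power: float = 0.90, tail: str = "one"
) -> int:
    """Smallest n for a matched-pairs t-test at standardised effect size d."""
    if d <= 0:
        raise ValueError("effect size must be positive")
    for n in range(2, _MAX_N):
        if _paired_t_power(n, d, alpha, tail) >= power:
            return n
    raise ValueError("power unattainable within search range")


def _pearson_r_pdf(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Exact sampling density of Pearson r under bivariate normality."""
    r = np.asarray(r, dtype=float)
    lg = (
        special.gammaln(n - 1)
        - special.gammaln(n - 0.5)
        + (n - 1) / 2.0 * np.log1p(-(rho**2))
        + (n - 4) / 2.0 * np.log1p(-(r**2))
        - (n - 1.5) * np.log1p(-rho * r)
    )
    h = special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
    return (n - 2) / math.sqrt(2.0 * math.pi) * np.exp(lg) * h


def correlation_power(
    n: int, rho: float, alpha: float = 0.02, method: str = "exact"
) -> float:
    """Power of the one-tailed test of rho = 0 at true correlation ``rho``.

    "exact" integrates the exact density of r beyond the null critical value
    (the null critical value itself comes from the exact t transform);
    "fisher" uses the Fisher-z normal approximation.
    """
    if n < 4:
        return 0.0
    if method == "fisher":
        zc = sst.norm.ppf(1.0 - alpha)
        return float(
            sst.norm.sf(zc - math.atanh(rho) * math.sqrt(n - 3))
        )
    tc = sst.t.ppf(1.0 - alpha, n - 2)
    r_crit = tc / math.sqrt(n - 2 + tc**2)
    val, err = integrate.quad(
        _pearson_r_pdf, r_crit, 1.0, args=(rho, n), limit=200
    )
    if not np.isfinite(val) or err > 1e-6:
        raise RuntimeError("power integration did not converge")
    return float(val)


def power_correlation_exact(
    rho: float, alpha: float = 0.02, power: float = 0.90, method: str = "exact"
) -> int:
    """Smallest n for the one-tailed exact Pearson correlation test."""
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must be in (0, 1)")
    for n in range(4, _MAX_N):
        if correlation_power(n, rho, alpha, method) >= power:
            return n
    raise ValueError("power unattainable within search range")


def _aipe_width(n: int, sd: float, level: float) -> float:
    return 2.0 * sst.t.ppf((1.0 + level) / 2.0, n - 1) * sd / math.sqrt(n)


def aipe_mean_n(
    sd: float,
    target_width: float,
    level: float = 0.90,
    assurance: float | None = None,
) -> int:
    """Smallest n whose expected full CI width for a mean is <= the target.

    With ``assurance`` γ, the sd is replaced by the γ-quantile of its
    sampling distribution (chi-squared based) before the same solve, giving
    probability γ that the realised interval is narrow enough.
    """
    if sd <= 0 or target_width <= 0:
        raise ValueError("sd and target width must be positive")
    for n in range(2, _MAX_N):
        s = sd
        if assurance is not None:
            s = sd * math.sqrt(sst.chi2.ppf(assurance, n - 1) / (n - 1))
        if _aipe_width(n, s, level) <= target_width:
            return n
    raise ValueError("width unattainable within search range")


def tost_power(
    n: int,
    sd: float,
    bounds: tuple[float, float] = (0.8, 1.2),
    true_mean: float = 1.0,
    alpha: float = 0.05,
) -> float:
    """Exact power of the two one-sided tests (TOST) equivalence procedure.

    Both one-sided level-α t-tests must reject: x̄ must land between
    L + t·s/√n and U − t·s/√n.  The probability is integrated exactly over
    the sampling distribution of s (x̄ and s are independent under
    normality).
    """
    lo, hi = bounds
    tc = sst.t.ppf(1.0 - alpha, n - 1)
    se_true = sd / math.sqrt(n)

    def integrand(u: float) -> float:
        # u ~ chi2(n-1); s = sd * sqrt(u / (n-1))
        s = sd * math.sqrt(u / (n - 1))
        upper = (hi - tc * s / math.sqrt(n) - true_mean) / se_true
        lower = (lo + tc * s / math.sqrt(n) - true_mean) / se_true
        if upper <= lower:
            return 0.0
        return float(
            (sst.norm.cdf(upper) - sst.norm.cdf(lower)) * sst.chi2.pdf(u, n - 1)
        )

    val, _ = integrate.quad(integrand, 0.0, sst.chi2.ppf(1.0 - 1e-12, n - 1), limit=200)
    return float(val)


def tost_equivalence_n(
    sd: float,
    bounds: tuple[float, float] = (0.8, 1.2),
    true_mean: float = 1.0,
    alpha: float = 0.05,
    power: float = 0.90,
) -> int:
    """Smallest n for which the TOST procedure attains the target power."""
    lo, hi = bounds
    if not lo < true_mean < hi:
        raise ValueError("true mean must lie strictly inside the bounds")
    for n in range(2, _MAX_N):
        if tost_power(n, sd, bounds, true_mean, alpha) >= power:
            return n
    raise ValueError("power unattainable within search range")


def inflate(n: int, fraction: float = 0.10) -> int:
    """Recruitment target: ceiling of n × (1 + fraction).

    Pure ceiling with a float-noise guard (so 40 × 1.1 → 44, not 45).
    Published protocols sometimes round further up to a convenient
    recruitment figure; that convention is not modelled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.ceil(n * (1.0 + fraction) - 1e-9)
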