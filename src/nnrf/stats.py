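"""Pre-registered hypothesis tests on n-NRF magnitude tables.

Three analyses:

* discrimination — a paired one-tailed t-test that heel-lance magnitudes
  exceed control-lance magnitudes within participants;
* equivalence — whether the mean lance magnitude is equivalent to 1.0, read
  off a 90% BCa bootstrap confidence interval against the pre-registered
  bounds (0.8, 1.2);
* age correlation — a one-sided Pearson correlation between postmenstrual
  age and lance magnitude in preterm infants, partialled on study site, with
  a participant-resampling bootstrap interval.

The bootstrap resampling unit is the participant throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "PairedTestResult",
    "EquivalenceResult",
    "PartialCorrelationResult",
    "paired_one_tailed_t",
    "bca_bootstrap_ci",
    "equivalence_test",
    "equivalence_verdict",
    "partial_pearson_site",
]

EQUIVALENCE_BOUNDS = (0.8, 1.2)


@dataclass(frozen=True)
class PairedTestResult:
    n: int
    mean_difference: float
    ci95: tuple[float, float]
    t: float
    p_one_sided: float
    n_dropped: int = 0  # participants lacking one of the two stimuli

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_difference": self.mean_difference,
            "ci95": list(self.ci95),
            "t": self.t,
            "p_one_sided": self.p_one_sided,
            "n_dropped": self.n_dropped,
        }


@dataclass(frozen=True)
class EquivalenceResult:
    n: int
    mean: float
    ci_level: float
    ci: tuple[float, float]
    bounds: tuple[float, float]
    verdict: str  # "equivalent" | "not demonstrated"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "ci_level": self.ci_level,
            "ci": list(self.ci),
            "bounds": list(self.bounds),
            "verdict": self.verdict,
        }


@dataclass(frozen=True)
class PartialCorrelationResult:
    n: int
    r: float
    p_one_sided: float
    ci_level: float
    ci: tuple[float, float]  # one-sided: (lower quantile, 1.0)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r": self.r,
            "p_one_sided": self.p_one_sided,
            "ci_level": self.ci_level,
            "ci": list(self.ci),
        }


def paired_one_tailed_t(
    lance: Sequence[float],
    control: Sequence[float],
    pairing: Sequence | None = None,
) -> PairedTestResult:
    """Paired one-tailed t-test that lance > control.

    With ``pairing`` ids, values are matched by id and participants lacking
    either stimulus are dropped (their count is reported); otherwise the two
    sequences are assumed aligned.  A two-sided 95% CI of the mean difference
    is reported alongside the one-sided p.
    """
    dropped = 0
    if pairing is not None:
        ids_l, ids_c = pairing
        sl = pd.Series(np.asarray(lance, float), index=list(ids_l))
        sc = pd.Series(np.asarray(control, float), index=list(ids_c))
        common = sl.index.intersection(sc.index)
        dropped = len(sl.index.union(sc.index)) - len(common)
        lance, control = sl.loc[common].to_numpy(), sc.loc[common].to_numpy()
    x = np.asarray(lance, float)
    y = np.asarray(control, float)
    if x.size != y.size:
        raise ValueError("lance and control must pair one-to-one")
    if x.size < 2:
        raise ValueError("need at least 2 complete pairs")
    d = x - y
    n = d.size
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    if se == 0.0:
        t = np.inf * np.sign(md) if md != 0 else 0.0
        p = 0.0 if md > 0 else (0.5 if md == 0 else 1.0)
        return PairedTestResult(n, md, (md, md), float(t), float(p), dropped)
    t = md / se
    p = float(sst.t.sf(t, n - 1))
    half = sst.t.ppf(0.975, n - 1) * se
    return PairedTestResult(n, md, (md - half, md + half), float(t), p, dropped)


def bca_bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    level: float = 0.90,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Bias-corrected and accelerated (BCa) bootstrap confidence interval.

    z0 comes from the fraction of bootstrap statistics below the observed
    statistic; the acceleration comes from the jackknife skewness formula;
    the adjusted percentiles are mapped through the normal quantile/CDF.
    Degenerate data (all values equal) returns the point interval.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values")
    obs = float(statistic(x))
    if np.ptp(x) == 0.0:
        return (obs, obs)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, n, size=(n_boot, n))
    if statistic is np.mean:
        boot = x[idx].mean(axis=1)
    else:
        boot = np.array([statistic(x[row]) for row in idx])
    if np.ptp(boot) == 0.0:
        raise ValueError("all bootstrap statistics identical; BCa undefined")
    prop = np.mean(boot < obs) + 0.5 * np.mean(boot == obs)
    if prop <= 0.0 or prop >= 1.0:
        raise ValueError("observed statistic outside the bootstrap support")
    z0 = sst.norm.ppf(prop)
    # jackknife acceleration
    jack = np.array([statistic(np.delete(x, i)) for i in range(n)])
    dev = jack.mean() - jack
    denom = (dev**2).sum() ** 1.5
    a = (dev**3).sum() / (6.0 * denom) if denom > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    out = []
    for q in (alpha, 1.0 - alpha):
        z = sst.norm.ppf(q)
        adj = sst.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        out.append(float(np.quantile(boot, adj)))
    return (out[0], out[1])


def equivalence_verdict(
    ci: tuple[float, float], bounds: tuple[float, float] = EQUIVALENCE_BOUNDS
) -> str:
    """"equivalent" iff the whole CI lies within the bounds."""
    return (
        "equivalent"
        if ci[0] >= bounds[0] and ci[1] <= bounds[1]
        else "not demonstrated"
    )


def equivalence_test(
    magnitudes: Sequence[float],
    bounds: tuple[float, float] = EQUIVALENCE_BOUNDS,
    level: float = 0.90,
    n_boot: int = 10_000,
    seed: int = 0,
) -> EquivalenceResult:
    """Equivalence of the mean magnitude to 1.0 via the BCa bootstrap CI.

    The verdict is "equivalent" only when the full CI sits inside the
    bounds; otherwise equivalence is "not demonstrated" (which is not a
    demonstration of non-equivalence).
    """
    x = np.asarray(magnitudes, dtype=float)
    ci = bca_bootstrap_ci(x, np.mean, level=level, n_boot=n_boot, seed=seed)
    return EquivalenceResult(
        x.size, float(x.mean()), level, ci, bounds, equivalence_verdict(ci, bounds)
    )


def _site_residuals(y: np.ndarray, site: np.ndarray) -> np.ndarray:
    """Residualise y on site indicator variables (with intercept)."""
    labels, codes = np.unique(site, return_inverse=True)
    X = np.ones((y.size, 1))
    if labels.size > 1:
        dummies = (codes[:, None] == np.arange(1, labels.size)[None, :]).astype(float)
        X = np.hstack([X, dummies])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _partial_r(mag: np.ndarray, pma: np.ndarray, site: np.ndarray) -> float:
    rm = _site_residuals(mag, site)
    rp = _site_residuals(pma, site)
    # residuals at numerical-noise scale mean the confound absorbed the
    # variable entirely: the partial correlation is 0, not noise/noise
    tol = 1e-10
    if (
        np.linalg.norm(rm) <= tol * max(np.linalg.norm(mag), 1.0)
        or np.linalg.norm(rp) <= tol * max(np.linalg.norm(pma), 1.0)
    ):
        return 0.0
    return float((rm * rp).sum() / np.sqrt((rm**2).sum() * (rp**2).sum()))


def partial_pearson_site(
    magnitude: Sequence[float],
    pma: Sequence[float],
    site: Sequence,
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_method: str = "percentile",
) -> PartialCorrelationResult:
    """One-sided site-adjusted Pearson correlation of magnitude with PMA.

    Magnitude and PMA are residualised on site indicators (least squares
    with intercept); the Pearson R of the residual pair is tested one-sided
    (upper tail) via the t transform with df = n − 2 − (number of site
    indicators).  The CI resamples participants with replacement and is
    reported one-sided as [lower quantile at (1 − level), 1.0].
    ``ci_method`` is "percentile" (default) or "bca".
    """
    mag = np.asarray(magnitude, dtype=float)
    pma_a = np.asarray(pma, dtype=float)
    site_a = np.asarray(site)
    n = mag.size
    labels, counts = np.unique(site_a, return_counts=True)
    if (counts < 2).any():
        bad = labels[counts < 2][0]
        raise ValueError(f"site {bad!r} has fewer than 2 participants")
    k_ind = labels.size - 1
    if n <= k_ind + 3:
        raise ValueError("too few participants for site adjustment")
    r = _partial_r(mag, pma_a, site_a)
    df = n - 2 - k_ind
    t = r * np.sqrt(df / max(1.0 - r**2, np.finfo(float).tiny))
    p = float(sst.t.sf(t, df))

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        # a resample may drop a site level entirely; residualisation then
        # simply uses the sites present
        boot[b] = _partial_r(mag[idx], pma_a[idx], site_a[idx])
    if ci_method == "percentile":
        lower = float(np.quantile(boot, 1.0 - level))
    elif ci_method == "bca":
        prop = np.mean(boot < r) + 0.5 * np.mean(boot == r)
        prop = min(max(prop, 1e-12), 1 - 1e-12)
        z0 = sst.norm.ppf(prop)
        jack = np.array(
            [
                _partial_r(np.delete(mag, i), np.delete(pma_a, i), np.delete(site_a, i))
                for i in range(n)
            ]
        )
        dev = jack.mean() - jack
        denom = (dev**2).sum() ** 1.5
        a = (dev**3).sum() / (6.0 * denom) if denom > 0 else 0.0
        z = sst.norm.ppf(1.0 - level)
        adj = sst.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        lower = float(np.quantile(boot, adj))
    else:
        raise ValueError("ci_method must be 'percentile' or 'bca'")
    return PartialCorrelationResult(n, r, p, level, (lower, 1.0))
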