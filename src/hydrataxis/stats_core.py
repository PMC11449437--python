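"""Statistical machinery for the phototaxis analysis.

Four ingredients, and only those the analysis needs:

* a circular median and Fisher's common-median test -- the circular analogue
  of the Kruskal-Wallis test -- for comparing head-orientation samples;
* the Mann-Whitney U test (exact for small tie-free samples) for jump
  distances and jump counts;
* a truncated Student-t location-scale family for the heading-noise terms of
  the random-walk model, with maximum-likelihood fitting and seeded sampling;
* a Gaussian kernel density estimate with boundary reflection at zero for the
  (strictly positive) jump-distance distribution, with seeded sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from ._angles import circular_mean_deg, wrap_deg
from .exceptions import DegenerateDataError, FitError

__all__ = [
    "circ_median",
    "circ_cm_test",
    "common_median_statistic",
    "CMTestResult",
    "mann_whitney_u",
    "MWUResult",
    "NoiseDistribution",
    "fit_truncated_tls",
    "sample_noise",
    "JumpDistanceKDE",
    "fit_kde",
    "sample_kde",
    "silverman_bandwidth",
]


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def _mean_abs_dev(b_sorted: np.ndarray, prefix: np.ndarray, cands: np.ndarray) -> np.ndarray:
    """Mean absolute circular distance (deg) of the sample to each candidate.

    ``b_sorted`` holds the sample in [0, 360), sorted; ``prefix`` its prefix
    sums with prefix[k] = sum of the first k elements. Evaluated for every
    candidate with two binary searches, so the whole call is O((n+m) log n).
    """
    n = b_sorted.size
    total = prefix[-1]
    c = np.mod(cands, 360.0)
    out = np.empty_like(c)

    low = c <= 180.0
    # --- candidates in [0, 180] ---
    cl = c[low]
    i1 = np.searchsorted(b_sorted, cl, side="left")
    i2 = np.searchsorted(b_sorted, cl + 180.0, side="right")
    s_mid = (prefix[i2] - prefix[i1]) - cl * (i2 - i1)          # b in [c, c+180]
    s_hi = (360.0 + cl) * (n - i2) - (total - prefix[i2])       # b in (c+180, 360)
    s_lo = cl * i1 - prefix[i1]                                  # b in [0, c)
    out[low] = (s_mid + s_hi + s_lo) / n
    # --- candidates in (180, 360) ---
    ch = c[~low]
    j1 = np.searchsorted(b_sorted, ch, side="left")
    j0 = np.searchsorted(b_sorted, ch - 180.0, side="left")
    s_hi = (total - prefix[j1]) - ch * (n - j1)                  # b in [c, 360)
    s_lo = prefix[j0] + (360.0 - ch) * j0                        # b in [0, c-180)
    s_mid = ch * (j1 - j0) - (prefix[j1] - prefix[j0])           # b in [c-180, c)
    out[~low] = (s_hi + s_lo + s_mid) / n
    return out


def circ_median(angles) -> float:
    """Circular median: an angle minimising the mean absolute circular distance.

    The objective is piecewise linear with breakpoints at the data points and
    their antipodes, so the minimum is attained on that candidate set. Exact
    ties are broken by the circular mean of the tied candidates. Result in
    (-180, 180] degrees.
    """
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("circ_median requires at least one angle")
    if a.size == 1:
        return float(wrap_deg(a[0]))
    b = np.sort(np.mod(a, 360.0))
    prefix = np.concatenate([[0.0], np.cumsum(b)])
    cands = np.unique(np.concatenate([b, np.mod(b + 180.0, 360.0)]))
    f = _mean_abs_dev(b, prefix, cands)
    fmin = f.min()
    tied = cands[f <= fmin + 1e-9]
    if tied.size == 1:
        return float(wrap_deg(tied[0]))
    return circular_mean_deg(tied)


class CMTestResult(NamedTuple):
    statistic: float
    pvalue: float
    m: tuple[int, ...]
    n: tuple[int, ...]


def common_median_statistic(m: Sequence[int], n: Sequence[int]) -> float:
    """Fisher's common-median chi-square statistic from side counts.

    ``m[i]`` is the number of group-i angles on the negative side of the
    pooled circular median and ``n[i]`` the group size.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    N = n.sum()
    M = m.sum()
    if M <= 0 or M >= N:
        raise DegenerateDataError("all angles lie on one side of the pooled median")
    return float(N * N / (M * (N - M)) * np.sum(m * m / n) - N * M / (N - M))


def circ_cm_test(groups: Sequence[Sequence[float]]) -> CMTestResult:
    """Common-median test for k samples of angles (degrees).

    The circular analogue of the Kruskal-Wallis test: under the null of a
    common circular median, the statistic is asymptotically chi-square with
    k - 1 degrees of freedom. Groups smaller than 5 trigger a warning because
    the chi-square approximation becomes unreliable.
    """
    arrs = [np.atleast_1d(np.asarray(g, dtype=float)) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in arrs):
        raise ValueError("all groups must be non-empty")
    if any(g.size < 5 for g in arrs):
        warnings.warn(
            "group with fewer than 5 angles: chi-square approximation unreliable",
            stacklevel=2,
        )
    pooled_median = circ_median(np.concatenate(arrs))
    # Negative side: signed circular distance to the median < 0; angles exactly
    # at the median count as non-negative.
    m = tuple(int(np.sum(wrap_deg(g - pooled_median) < 0)) for g in arrs)
    n = tuple(int(g.size) for g in arrs)
    statistic = common_median_statistic(m, n)
    pvalue = float(stats.chi2.sf(statistic, df=len(arrs) - 1))
    return CMTestResult(statistic=statistic, pvalue=pvalue, m=m, n=n)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

class MWUResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str


#: largest combined sample size for which the exact null distribution is used
EXACT_MWU_LIMIT = 16


def mann_whitney_u(x, y, mode: str = "auto") -> MWUResult:
    """Two-sided Mann-Whitney U test; U is reported as min(U_x, U_y).

    ``mode='auto'`` uses the exact null distribution when the combined sample
    size is at most 16 and there are no ties, and otherwise the normal
    approximation with tie and continuity corrections. ``'exact'`` and
    ``'normal'`` force the respective method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (x.size + y.size <= EXACT_MWU_LIMIT and not has_ties) else "asymptotic"
    elif mode == "exact":
        if has_ties:
            warnings.warn("ties present: exact Mann-Whitney p ignores ties", stacklevel=2)
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u = min(u_x, x.size * y.size - u_x)
    return MWUResult(statistic=u, pvalue=float(min(res.pvalue, 1.0)), method=method)


# ---------------------------------------------------------------------------
# Truncated t location-scale noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseDistribution:
    """Student-t location-scale density truncated and renormalised to [lower, upper].

    Parameters are in degrees: location ``mu``, scale ``sigma`` > 0 and
    degrees of freedom ``nu`` > 0, truncated to the interval
    [``lower``, ``upper``] (default the full signed circle).
    """

    mu: float
    sigma: float
    nu: float
    lower: float = -180.0
    upper: float = 180.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.nu > 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")

    @property
    def _mass(self) -> float:
        lo = (self.lower - self.mu) / self.sigma
        hi = (self.upper - self.mu) / self.sigma
        return float(stats.t.cdf(hi, self.nu) - stats.t.cdf(lo, self.nu))

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x - self.mu) / self.sigma
        out = stats.t.pdf(z, self.nu) / (self.sigma * self._mass)
        return np.where((x >= self.lower) & (x <= self.upper), out, 0.0)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        lo = stats.t.cdf((self.lower - self.mu) / self.sigma, self.nu)
        raw = (stats.t.cdf((x - self.mu) / self.sigma, self.nu) - lo) / self._mass
        return np.clip(raw, 0.0, 1.0)

    def as_dict(self) -> dict:
        return {"mu": self.mu, "sigma": self.sigma, "nu": self.nu,
                "lower": self.lower, "upper": self.upper}


def fit_truncated_tls(
    samples, lower: float = -180.0, upper: float = 180.0, *, fix_nu: float | None = None
) -> NoiseDistribution:
    """Maximum-likelihood truncated t location-scale fit.

    Optimises (mu, log sigma, log nu) by Nelder-Mead from several start
    points; ``fix_nu`` pins the degrees of freedom. Raises :class:`FitError`
    on degenerate data or if no start converges (the attempted starts are
    reported in the message).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 samples, got {x.size}")
    if x.min() < lower or x.max() > upper:
        raise ValueError("samples outside the truncation bounds")
    if np.ptp(x) == 0.0:
        raise FitError("degenerate sample: all values equal, scale is not identifiable")

    def nll(p: np.ndarray) -> float:
        if fix_nu is None:
            mu, log_sigma, log_nu = p
            nu = np.exp(np.clip(log_nu, -2.0, 15.0))
        else:
            mu, log_sigma = p
            nu = fix_nu
        sigma = np.exp(np.clip(log_sigma, -20.0, 20.0))
        mass = stats.t.cdf((upper - mu) / sigma, nu) - stats.t.cdf((lower - mu) / sigma, nu)
        if not np.isfinite(mass) or mass <= 1e-300:
            return 1e12
        ll = stats.t.logpdf((x - mu) / sigma, nu).sum() - x.size * (np.log(sigma) + np.log(mass))
        return -float(ll) if np.isfinite(ll) else 1e12

    mad = np.median(np.abs(x - np.median(x)))
    scale0 = 1.4826 * mad if mad > 0 else float(np.std(x))
    starts = []
    for nu0 in (5.0, 2.0, 30.0):
        p0 = [float(np.median(x)), float(np.log(scale0))]
        if fix_nu is None:
            p0.append(float(np.log(nu0)))
        starts.append(np.asarray(p0))
    best = None
    for p0 in starts:
        res = optimize.minimize(nll, p0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"truncated t fit did not converge from starts {[list(s) for s in starts]}")
    if fix_nu is None:
        mu, log_sigma, log_nu = best.x
        nu = float(np.exp(np.clip(log_nu, -2.0, 15.0)))
    else:
        mu, log_sigma = best.x
        nu = float(fix_nu)
    return NoiseDistribution(mu=float(mu), sigma=float(np.exp(log_sigma)), nu=nu,
                             lower=float(lower), upper=float(upper))


def sample_noise(dist: NoiseDistribution, n: int, rng) -> np.ndarray:
    """Draw n i.i.d. values by rejection from the untruncated t location-scale.

    ``rng`` is a seed or :class:`numpy.random.Generator`; a fixed seed yields
    an identical sequence.
    """
    rng = np.random.default_rng(rng)
    out = np.empty(n, dtype=float)
    filled = 0
    while filled < n:
        batch = max(2 * (n - filled), 64)
        draws = dist.mu + dist.sigma * rng.standard_t(dist.nu, size=batch)
        keep = draws[(draws >= dist.lower) & (draws <= dist.upper)]
        take = min(keep.size, n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# Jump-distance KDE
# ---------------------------------------------------------------------------

def silverman_bandwidth(data: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n**(-1/5)."""
    data = np.asarray(data, dtype=float)
    sd = float(np.std(data, ddof=1))
    q75, q25 = np.percentile(data, [75.0, 25.0])
    iqr = float(q75 - q25)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        raise FitError("degenerate data: zero spread, cannot choose a bandwidth")
    return 0.9 * scale * data.size ** (-0.2)


@dataclass(frozen=True)
class JumpDistanceKDE:
    """Gaussian-kernel density on [0, inf) with boundary reflection at zero.

    The density at x >= 0 is the average over data points x_i of
    N(x; x_i, h) + N(x; -x_i, h), which integrates to one on the half line.
    """

    data: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.size < 1 or np.any(data <= 0):
            raise ValueError("KDE data must be positive")
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be > 0")
        object.__setattr__(self, "data", data)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        xi = self.data[:, None]
        h = self.bandwidth
        val = (stats.norm.pdf((x[None, :] - xi) / h) + stats.norm.pdf((x[None, :] + xi) / h)).mean(axis=0) / h
        return np.where(x >= 0, val, 0.0)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        xi = self.data[:, None]
        h = self.bandwidth
        val = (stats.norm.cdf((x[None, :] - xi) / h) - stats.norm.cdf((-x[None, :] - xi) / h)).mean(axis=0)
        return np.clip(np.where(x >= 0, val, 0.0), 0.0, 1.0)

    def mean(self) -> float:
        """Analytic mean: average of folded-normal means over the data."""
        m = self.data
        h = self.bandwidth
        return float(np.mean(m * (1.0 - 2.0 * stats.norm.cdf(-m / h)) + 2.0 * h * stats.norm.pdf(m / h)))

    def as_dict(self) -> dict:
        return {"data": [float(v) for v in self.data], "bandwidth": float(self.bandwidth)}


def fit_kde(data, bandwidth: float | None = None) -> JumpDistanceKDE:
    """Fit the reflected Gaussian KDE; Silverman's rule if no bandwidth given."""
    data = np.asarray(data, dtype=float)
    if data.size < 2:
        raise ValueError(f"need at least 2 jump distances, got {data.size}")
    if np.any(data <= 0):
        raise ValueError("jump distances must be positive")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(data)
    return JumpDistanceKDE(data=data, bandwidth=float(bandwidth))


def sample_kde(kde: JumpDistanceKDE, n: int, rng) -> np.ndarray:
    """Sample the reflected KDE: |uniformly chosen datum + N(0, h)|."""
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, kde.data.size, size=n)
    return np.abs(kde.data[idx] + kde.bandwidth * rng.standard_normal(n))
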