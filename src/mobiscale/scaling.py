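"""Heavy-tail distribution analysis.

Three complementary fits are provided for displacement and staying-time
samples:

* a two-regime power law fitted on the log-binned density — a broken line
  in log-log space with the break chosen by grid search over bin edges;
* a continuous maximum-likelihood power-law tail fit with a
  Kolmogorov–Smirnov-optimal lower bound and a semiparametric bootstrap
  confidence probability p (Clauset–Shalizi–Newman procedure);
* the Pearson correlation R of the log-binned points in log-log space,
  a direct linear-fit quality measure (R → −1 for a clean decaying law).

The MLE for a continuous power law p(x) ∝ x^(−α) above x_min is
α̂ = 1 + n / Σ ln(x_i / x_min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BinnedDistribution", "TwoRegimeFit", "PowerLawFit", "FitQuality",
           "log_bin", "fit_two_regime", "fit_powerlaw_ks", "loglog_pearson"]


@dataclass
class BinnedDistribution:
    """Log-binned probability density: geometric bin edges, densities, counts."""

    bin_edges: np.ndarray
    densities: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)


@dataclass
class TwoRegimeFit:
    break_point: float
    alpha_low: float
    alpha_high: float
    sse: float
    intercept_low: float = float("nan")
    intercept_high: float = float("nan")


@dataclass
class PowerLawFit:
    x_min: float
    alpha: float
    ks_stat: float
    p: float | None = None
    n_tail: int = 0


@dataclass
class FitQuality:
    R: float
    slope: float
    intercept: float
    n_points: int


class FitError(ValueError):
    """Raised when a distribution fit has too little usable data."""


def log_bin(samples, bins_per_decade: int = 10) -> BinnedDistribution:
    """Histogram positive samples into geometric bins.

    Densities are per-unit (linear) probability density: count / (N · bin
    width), so they integrate to 1 over the binned range.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise FitError("no samples to bin")
    if np.any(x <= 0):
        raise ValueError("log_bin requires strictly positive samples")
    lo, hi = np.log10(x.min()), np.log10(x.max())
    if hi == lo:
        hi = lo + 1.0 / bins_per_decade
    n_bins = max(1, int(np.ceil((hi - lo) * bins_per_decade)))
    edges = np.logspace(lo, hi, n_bins + 1)
    edges[0] *= 1 - 1e-12  # include the minimum sample
    counts, _ = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    densities = counts / (x.size * widths)
    return BinnedDistribution(bin_edges=edges, densities=densities, counts=counts)


def _ols_line(lx: np.ndarray, ly: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line: returns (slope, intercept, sse)."""
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    return float(slope), float(intercept), float(resid @ resid)


def fit_two_regime(dist: BinnedDistribution) -> TwoRegimeFit:
    """Fit a broken power law to a log-binned density.

    Every interior nonzero-bin edge is a candidate break; an OLS line is
    fitted on each side in log-log space and the break minimizing the total
    squared error is returned.  Slopes are reported as power-law exponents
    of the density (the log-log slopes themselves; decaying laws give
    negative values).
    """
    mask = dist.densities > 0
    if mask.sum() < 6:
        raise FitError("need >= 6 nonzero bins for a two-regime fit")
    lx = np.log10(dist.centers[mask])
    ly = np.log10(dist.densities[mask])
    m = len(lx)
    best = None
    # each side needs >= 2 points to define a line; >=3 keeps it a fit
    for k in range(3, m - 2):
        s1, b1, e1 = _ols_line(lx[:k], ly[:k])
        s2, b2, e2 = _ols_line(lx[k:], ly[k:])
        sse = e1 + e2
        if best is None or sse < best[0]:
            break_point = 10 ** ((lx[k - 1] + lx[k]) / 2.0)
            best = (sse, break_point, s1, s2, b1, b2)
    sse, bp, s1, s2, b1, b2 = best
    return TwoRegimeFit(break_point=bp, alpha_low=s1, alpha_high=s2, sse=sse,
                        intercept_low=b1, intercept_high=b2)


# ---------------------------------------------------------------------------
# Clauset-style KS power-law fit


def _alpha_mle(tail: np.ndarray, x_min: float) -> float:
    s = np.sum(np.log(tail / x_min))
    if s <= 0:  # every tail sample tied at x_min
        raise FitError("degenerate tail: all samples at x_min")
    return 1.0 + tail.size / s


def _ks_distance(tail_sorted: np.ndarray, x_min: float, alpha: float) -> float:
    n = tail_sorted.size
    cdf = 1.0 - (tail_sorted / x_min) ** (1.0 - alpha)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(ecdf_hi - cdf)), np.max(np.abs(cdf - ecdf_lo))))


def _fit_tail(x_sorted: np.ndarray, x_min) -> tuple[float, float, float, int]:
    """Fit above a fixed or KS-optimal x_min; returns (x_min, alpha, D, n_tail)."""
    if x_min != "estimate":
        x_min = float(x_min)
        tail = x_sorted[x_sorted >= x_min]
        if tail.size < 2:
            raise FitError("insufficient tail above x_min")
        alpha = _alpha_mle(tail, x_min)
        return x_min, alpha, _ks_distance(tail, x_min, alpha), tail.size

    candidates = np.unique(x_sorted[:-1])
    if candidates.size > 100:
        # decimate to ~100 quantile-spaced candidates to bound the scan
        idx = np.unique(np.linspace(0, candidates.size - 1, 100).astype(int))
        candidates = candidates[idx]
    best = None
    for xm in candidates:
        tail = x_sorted[x_sorted >= xm]
        if tail.size < 10:
            break
        try:
            alpha = _alpha_mle(tail, xm)
        except FitError:
            continue
        d = _ks_distance(tail, xm, alpha)
        if best is None or d < best[2]:
            best = (float(xm), alpha, d, tail.size)
    if best is None:
        raise FitError("no viable x_min candidate")
    return best


def fit_powerlaw_ks(samples, x_min="estimate", n_bootstrap: int = 1000,
                    seed: int | None = None, min_tail: int = 50) -> PowerLawFit:
    """Maximum-likelihood power-law tail fit with KS bootstrap p-value.

    Parameters
    ----------
    samples : array-like
        Positive observations.
    x_min : float or "estimate"
        Fixed lower bound, or ``"estimate"`` to choose the bound minimizing
        the KS distance between the tail ECDF and the fitted law.
    n_bootstrap : int
        Semiparametric bootstrap replicates for the confidence probability
        p (fraction of synthetic data sets, drawn from the fitted model
        above x_min and resampled empirically below it, whose refitted KS
        distance is at least the observed one).  ``0`` skips the bootstrap
        and leaves ``p`` as None.
    seed : int
        Seed for the bootstrap generator.
    min_tail : int
        Minimum number of samples at or above x_min.

    Notes
    -----
    p well above a small threshold (0.1 by convention) means the power law
    is a plausible generating family; p near 0 rejects it.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    if np.any(x <= 0):
        x = x[x > 0]
    if x.size < min_tail:
        raise FitError(f"need >= {min_tail} positive samples")
    xm, alpha, d_obs, n_tail = _fit_tail(x, x_min)
    if n_tail < min_tail:
        raise FitError(f"only {n_tail} samples above x_min={xm:g}")
    p = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        body = x[x < xm]
        p_tail = n_tail / x.size
        exceed = 0
        for _ in range(n_bootstrap):
            take_tail = rng.random(x.size) < p_tail
            k = int(take_tail.sum())
            synth = np.empty(x.size)
            # tail: inverse-CDF draws from the fitted Pareto
            synth[:k] = xm * (1.0 - rng.random(k)) ** (-1.0 / (alpha - 1.0))
            if x.size - k:
                if body.size:
                    synth[k:] = rng.choice(body, size=x.size - k, replace=True)
                else:
                    synth[k:] = xm
            synth.sort()
            try:
                _, _, d_s, _ = _fit_tail(synth, x_min)
            except FitError:
                continue
            if d_s >= d_obs:
                exceed += 1
        p = exceed / n_bootstrap
    return PowerLawFit(x_min=xm, alpha=float(alpha), ks_stat=d_obs, p=p,
                       n_tail=n_tail)


def loglog_pearson(dist: BinnedDistribution, fit_range=None) -> FitQuality:
    """Pearson R of the log-binned points in log-log coordinates.

    ``fit_range = (lo, hi)`` restricts to bins whose centers fall in the
    range.  For a decaying law R is negative, −1 for an exact power law.
    """
    centers = dist.centers
    mask = dist.densities > 0
    if fit_range is not None:
        lo, hi = fit_range
        mask &= (centers >= lo) & (centers <= hi)
    if mask.sum() < 3:
        raise FitError("need >= 3 nonzero bins in range")
    lx = np.log10(centers[mask])
    ly = np.log10(dist.densities[mask])
    slope, intercept, _ = _ols_line(lx, ly)
    sx, sy = lx.std(), ly.std()
    r = 0.0 if sx == 0 or sy == 0 else float(np.corrcoef(lx, ly)[0, 1])
    return FitQuality(R=r, slope=slope, intercept=intercept, n_points=int(mask.sum()))
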