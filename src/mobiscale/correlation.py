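"""Rank and linear correlation analysis of displacement series.

The central statistic is Kendall's Tau in its untied ("tau-a") form

    τ = 2 / (n(n−1)) · Σ_{i<j} sgn(x_i − x_j) · sgn(y_i − y_j),

with sgn(0) = 0, so tied pairs contribute zero.  τ is invariant under any
strictly monotone transform of both series, which makes it the right tool
for displacement data spanning several orders of magnitude.

Lagged correlations τ(Δn) pair Δr_n with Δr_{n+Δn}; index pairs are formed
inside each trajectory file only and pooled across files before τ is
applied, since displacements from different files share no temporal
ordering.

The linear counterpart r_Δ is the Pearson correlation of consecutive
log-displacement pairs computed with the series' own mean and variance of
log-displacements:

    r_Δ = Σ_{n=1}^{N−1} (ln Δr_n − μ)(ln Δr_{n+1} − μ) / ((N−1) σ²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sstats

__all__ = ["TauResult", "LagDecay", "LogPearson", "kendall_tau", "lagged_tau",
           "tau_decay", "fit_tau_decay", "tau_ci", "log_pearson",
           "scatter_correlation_pattern"]

#: n below which τ uses exact chunked O(n²) sign counting.
_EXACT_N = 4000


@dataclass
class TauResult:
    tau: float
    n_pairs: int
    lag: int = 1
    ci_halfwidth: float = float("nan")

    @property
    def significant(self) -> bool:
        return abs(self.tau) > self.ci_halfwidth


@dataclass
class LagDecay:
    lags: np.ndarray
    taus: list[TauResult]
    pearson_lags: np.ndarray = field(default_factory=lambda: np.empty(0))
    decay_exponent: float = float("nan")
    hurst_from_decay: float = float("nan")

    @property
    def tau_values(self) -> np.ndarray:
        return np.array([t.tau for t in self.taus])


@dataclass
class LogPearson:
    r_delta: float
    mean_log: float
    var_log: float
    n: int


class CorrelationError(ValueError):
    pass


def _cmd_exact(x: np.ndarray, y: np.ndarray) -> int:
    """Concordant-minus-discordant count by chunked pairwise sign products."""
    n = x.size
    total = 0
    chunk = max(1, 2_000_000 // max(n, 1))
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        sx = np.sign(x[i0:i1, None] - x[None, :])
        sy = np.sign(y[i0:i1, None] - y[None, :])
        # restrict to j > i to count each unordered pair once
        prod = (sx * sy).astype(np.int64)
        cols = np.arange(n)[None, :]
        rows = np.arange(i0, i1)[:, None]
        total += int(prod[cols > rows].sum())
    return total


def _cmd_fast(x: np.ndarray, y: np.ndarray) -> int:
    """Concordant-minus-discordant via scipy's tie-corrected tau-b.

    tau_b = (P−Q) / sqrt((n0−n1)(n0−n2)) with n0 = n(n−1)/2 and n1, n2 the
    tied-pair counts of x and y; P−Q is recovered and rounded back to the
    exact integer.
    """
    n = x.size
    n0 = n * (n - 1) // 2
    n1 = sum(c * (c - 1) // 2 for c in np.unique(x, return_counts=True)[1])
    n2 = sum(c * (c - 1) // 2 for c in np.unique(y, return_counts=True)[1])
    if n0 == n1 or n0 == n2:
        return 0  # a constant series: every pair tied
    tau_b = sstats.kendalltau(x, y, variant="b").statistic
    return int(round(tau_b * np.sqrt(float(n0 - n1) * float(n0 - n2))))


def kendall_tau(x, y, lag: int = 1, ci: bool = True) -> TauResult:
    """Kendall's tau-a between two equal-length series.

    Ties contribute 0 (sgn(0) = 0); the denominator is always n(n−1)/2.
    The attached ``ci_halfwidth`` is the normal-approximation 95% null
    interval for the pair count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("series must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise CorrelationError("need at least two elements")
    cmd = _cmd_exact(x, y) if n <= _EXACT_N else _cmd_fast(x, y)
    tau = 2.0 * cmd / (n * (n - 1))
    hw = tau_ci(n) if ci and n >= 10 else float("nan")
    return TauResult(tau=float(tau), n_pairs=n, lag=lag, ci_halfwidth=hw)


def _lag_pairs(per_file: Sequence[np.ndarray], lag: int):
    heads, tails = [], []
    for d in per_file:
        d = np.asarray(d, dtype=float)
        if d.size > lag:
            heads.append(d[:-lag])
            tails.append(d[lag:])
    if not heads:
        raise CorrelationError(f"no file is longer than lag {lag}")
    return np.concatenate(heads), np.concatenate(tails)


def lagged_tau(per_file: Sequence[np.ndarray], lag: int = 1) -> TauResult:
    """τ(Δn): tau between Δr_n and Δr_{n+Δn}, pairs pooled across files.

    ``per_file`` is a sequence of per-file displacement arrays (pairs never
    span file boundaries).  A single bare array is accepted.
    """
    if lag < 1:
        raise CorrelationError("lag must be >= 1")
    if isinstance(per_file, np.ndarray) and per_file.ndim == 1:
        per_file = [per_file]
    xs, ys = _lag_pairs(per_file, lag)
    res = kendall_tau(xs, ys, lag=lag)
    return res


def tau_decay(per_file: Sequence[np.ndarray], max_lag: int = 50,
              lags: Sequence[int] | None = None) -> LagDecay:
    """τ(Δn) over a range of lags plus the lagged log-Pearson curve.

    ``pearson_lags[k]`` is the ordinary Pearson correlation of the pooled
    (ln Δr_n, ln Δr_{n+Δn}) pairs at ``lags[k]``; its power-law decay
    exponent γ maps to a Hurst-type exponent H = 1 − γ/2, recorded as
    ``hurst_from_decay``.
    """
    if isinstance(per_file, np.ndarray) and per_file.ndim == 1:
        per_file = [per_file]
    if lags is None:
        lags = np.arange(1, max_lag + 1)
    lags = np.asarray(lags, dtype=int)
    taus, pear = [], []
    kept = []
    for lag in lags:
        try:
            taus.append(lagged_tau(per_file, lag=int(lag)))
        except CorrelationError:
            continue
        kept.append(lag)
        xs, ys = _lag_pairs(per_file, int(lag))
        ok = (xs > 0) & (ys > 0)
        if ok.sum() >= 3 and np.ptp(xs[ok]) > 0 and np.ptp(ys[ok]) > 0:
            pear.append(float(np.corrcoef(np.log(xs[ok]), np.log(ys[ok]))[0, 1]))
        else:
            pear.append(float("nan"))
    ld = LagDecay(lags=np.asarray(kept), taus=taus, pearson_lags=np.asarray(pear))
    try:
        ld.decay_exponent = fit_tau_decay(ld)
    except CorrelationError:
        pass
    ld.hurst_from_decay = _hurst_from_pearson_decay(ld)
    return ld


def fit_tau_decay(lag_decay: LagDecay) -> float:
    """OLS slope of log τ vs log Δn, restricted to positive τ values."""
    tv = lag_decay.tau_values
    mask = tv > 0
    if mask.sum() < 4:
        raise CorrelationError("need >= 4 positive tau values")
    slope = np.polyfit(np.log(lag_decay.lags[mask]), np.log(tv[mask]), 1)[0]
    return float(slope)


def _hurst_from_pearson_decay(ld: LagDecay) -> float:
    r = ld.pearson_lags
    mask = np.isfinite(r) & (r > 0)
    if mask.sum() < 4:
        return float("nan")
    gamma = -np.polyfit(np.log(ld.lags[mask]), np.log(r[mask]), 1)[0]
    return float(1.0 - gamma / 2.0)


def tau_ci(n_pairs: int, level: float = 0.95, method: str = "normal",
           n_shuffles: int = 2000, seed: int | None = None,
           x=None, y=None) -> float:
    """Half-width of the null confidence interval for τ.

    ``method="normal"`` uses the large-sample null variance of tau-a,
    var τ = 2(2n+5) / (9n(n−1)); ``method="permutation"`` shuffles ``y``
    against ``x`` and takes the |τ| quantile at ``level``.
    """
    if n_pairs < 2:
        raise CorrelationError("need n_pairs >= 2")
    if method == "normal":
        z = sstats.norm.ppf(0.5 + level / 2.0)
        return float(z * np.sqrt(2.0 * (2 * n_pairs + 5) /
                                 (9.0 * n_pairs * (n_pairs - 1))))
    if method == "permutation":
        if x is None or y is None:
            raise CorrelationError("permutation CI needs the two series")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float).copy()
        rng = np.random.default_rng(seed)
        taus = np.empty(n_shuffles)
        for k in range(n_shuffles):
            perm = rng.permutation(y.size)
            taus[k] = sstats.kendalltau(x, y[perm], variant="b").statistic
        return float(np.quantile(np.abs(taus), level))
    raise ValueError(f"unknown method {method!r}")


def log_pearson(displacements) -> LogPearson:
    """Consecutive log-displacement Pearson correlation r_Δ of one series.

    Uses the series' own mean μ and variance σ² of ln Δr:
    r_Δ = Σ (ln Δr_n − μ)(ln Δr_{n+1} − μ) / ((N−1) σ²).
    """
    d = np.asarray(displacements, dtype=float)
    if np.any(d <= 0):
        raise CorrelationError("log-Pearson requires positive displacements")
    if d.size < 3:
        raise CorrelationError("need at least 3 displacements")
    ld = np.log(d)
    mu = ld.mean()
    var = ld.var()  # population variance of the series itself
    # constant series: var is zero up to summation round-off
    if var <= 1e-15 * max(1.0, mu * mu):
        raise CorrelationError("zero variance: r_delta undefined")
    r = float(np.sum((ld[:-1] - mu) * (ld[1:] - mu)) / ((d.size - 1) * var))
    return LogPearson(r_delta=r, mean_log=float(mu), var_log=float(var),
                      n=int(d.size))


def scatter_correlation_pattern(per_file: Sequence[np.ndarray],
                                relative: bool = False,
                                user_means: Sequence[float] | None = None,
                                n_bins: int = 40) -> dict:
    """2-D log-log density of consecutive displacement pairs (Δr_n, Δr_{n+1}).

    With ``relative=True`` each file's displacements are divided by the
    corresponding entry of ``user_means`` first.  Returns the histogram,
    its edges, and ``diagonal_mass`` — the fraction of pairs within a
    factor 2 of the diagonal, the quantitative version of the visual
    "points accumulate near Δr_{n+1} = Δr_n" pattern.
    """
    if isinstance(per_file, np.ndarray) and per_file.ndim == 1:
        per_file = [per_file]
    if relative:
        if user_means is None:
            raise CorrelationError("relative mode needs per-file user means")
        per_file = [np.asarray(d, float) / m for d, m in zip(per_file, user_means)]
    xs, ys = _lag_pairs(per_file, 1)
    ok = (xs > 0) & (ys > 0)
    lx, ly = np.log10(xs[ok]), np.log10(ys[ok])
    lo = min(lx.min(), ly.min())
    hi = max(lx.max(), ly.max())
    hist, ex, ey = np.histogram2d(lx, ly, bins=n_bins, range=[[lo, hi], [lo, hi]])
    diag = np.mean(np.abs(lx - ly) <= np.log10(2.0))
    return {"hist": hist, "x_edges": ex, "y_edges": ey,
            "diagonal_mass": float(diag), "n_pairs": int(ok.sum())}
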