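"""Detrended fluctuation analysis (DFA).

Estimates the Hurst exponent H of a series z_t:

1. integrate the mean-subtracted series, y(t) = Σ_{u≤t} (z_u − ⟨z⟩);
2. cut y into ⌊N/l⌋ disjoint boxes of size l (trailing remainder
   discarded, or averaged with a reversed pass in ``both_ends`` mode);
3. remove a k-order least-squares polynomial trend inside each box;
4. F²(l) = mean squared residual per box, averaged over boxes;
5. F(l) = RMS fluctuation;
6. H = OLS slope of log F(l) vs log l.

H = 0.5 for an uncorrelated series; H > 0.5 indicates long-term
persistence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DFAResult", "dfa", "default_box_sizes"]


@dataclass
class DFAResult:
    box_sizes: np.ndarray
    fluctuations: np.ndarray
    hurst: float
    fit_range: tuple[float, float]
    detrend_order: int
    degenerate: bool = False


class DFAError(ValueError):
    pass


def default_box_sizes(n: int, n_sizes: int = 20, min_box: int = 4) -> np.ndarray:
    """~20 log-spaced box sizes between ``min_box`` and N/4."""
    max_box = n // 4
    if max_box < min_box:
        raise DFAError(f"series of length {n} too short for DFA")
    sizes = np.unique(np.round(np.logspace(
        np.log10(min_box), np.log10(max_box), n_sizes)).astype(int))
    return sizes


def _box_fluctuation(y: np.ndarray, l: int, order: int, reverse: bool) -> float:
    n = y.size
    n_boxes = n // l
    seg = y[n - n_boxes * l:][::-1] if reverse else y[:n_boxes * l]
    boxes = seg.reshape(n_boxes, l)
    t = np.arange(l, dtype=float)
    # Vandermonde LS fit per box, all boxes at once
    V = np.vander(t, order + 1)
    coef, *_ = np.linalg.lstsq(V, boxes.T, rcond=None)
    resid = boxes.T - V @ coef
    return float(np.mean(resid ** 2))


def dfa(series, box_sizes=None, order: int = 1,
        both_ends: bool = False) -> DFAResult:
    """Run DFA on a series and estimate the Hurst exponent.

    Parameters
    ----------
    series : array-like
        The raw series z_t (e.g. displacements); it is mean-subtracted and
        integrated internally.
    box_sizes : array-like of int, optional
        Strictly increasing box sizes; default log-spaced in [4, N/4].
    order : int
        Polynomial detrending order k (default 1, linear).
    both_ends : bool
        Average each F²(l) with a pass anchored at the series end, so the
        trailing remainder is not simply discarded.
    """
    z = np.asarray(series, dtype=float)
    n = z.size
    if box_sizes is None:
        box_sizes = default_box_sizes(n)
    box_sizes = np.asarray(sorted(set(int(b) for b in np.asarray(box_sizes))))
    if np.any(box_sizes < order + 2):
        raise DFAError(f"box sizes must be >= order+2 = {order + 2}")
    if n < 4 * box_sizes.min():
        raise DFAError("series too short for the requested box sizes")
    box_sizes = box_sizes[box_sizes <= n // 2]
    if box_sizes.size < 2:
        raise DFAError("need at least two usable box sizes")

    y = np.cumsum(z - z.mean())
    f2 = []
    for l in box_sizes:
        v = _box_fluctuation(y, int(l), order, reverse=False)
        if both_ends:
            v = 0.5 * (v + _box_fluctuation(y, int(l), order, reverse=True))
        f2.append(v)
    fluct = np.sqrt(np.asarray(f2))

    if np.all(fluct == 0):
        return DFAResult(box_sizes=box_sizes, fluctuations=fluct,
                         hurst=float("nan"),
                         fit_range=(float(box_sizes[0]), float(box_sizes[-1])),
                         detrend_order=order, degenerate=True)
    pos = fluct > 0
    hurst = float(np.polyfit(np.log(box_sizes[pos]), np.log(fluct[pos]), 1)[0])
    return DFAResult(box_sizes=box_sizes, fluctuations=fluct, hurst=hurst,
                     fit_range=(float(box_sizes[0]), float(box_sizes[-1])),
                     detrend_order=order)
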