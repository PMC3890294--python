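"""Synthetic inputs: GPS trajectories with planted dwells and displacement
series with controlled correlation structure.

Trajectory generation emulates the structure of handheld-GPS data the
pipeline assumes: multi-hour tracks sampled every few seconds, containing
dwell clusters (meter-scale jitter, minutes-long duration) separated by
travel segments whose consecutive points are spaced farther apart than
the staypoint distance resolution, so travel never pollutes dwells.

Series generation provides four canonical correlation structures for the
displacement magnitudes:

* ``iid_lognormal`` — no correlation (null case);
* ``log_ar1`` — log-displacements follow an AR(1) with coefficient φ;
  consecutive Kendall's Tau is (2/π)·arcsin(φ) under the Gaussian copula;
* ``fgn`` — log-displacements are fractional Gaussian noise with Hurst H
  (long-term persistence without a dominant lag-1 structure);
* ``cascade`` — dyadic multiplicative cascade: heavy tails and long-range
  persistence jointly, the "cascading-like" structure.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .series import DisplacementSeries
from .staypoint import EARTH_RADIUS_M, StayPoint
from .trajectory_io import TrackPoint, Trajectory

__all__ = ["ItineraryPlan", "SeriesPlan", "generate_trajectory",
           "generate_series", "generate_cohort", "fractional_gaussian_noise",
           "random_itinerary"]

_M_PER_DEG = np.pi * EARTH_RADIUS_M / 180.0  # meters per degree latitude


@dataclass
class ItineraryPlan:
    """Planted staypoint centers, dwell durations and travel behavior.

    ``jitter`` bounds the distance between *consecutive* dwell samples
    (offsets are drawn in a disc of radius jitter/2), so any jitter below
    the staypoint distance resolution keeps a dwell cluster intact.
    """

    centers: list   # (lat, lon) pairs, degrees
    dwell_durations: list  # seconds, one per center, each > t_min
    sampling_interval: float = 3.0   # s; handheld GPS records every 2-5 s
    jitter: float = 5.0              # m, must stay below d_max
    travel_speed: float = 20.0       # m/s; spaces travel points > d_max apart

    def __post_init__(self):
        if len(self.centers) != len(self.dwell_durations):
            raise ValueError("one dwell duration per center required")
        if self.travel_speed * self.sampling_interval <= 10.0:
            raise ValueError("travel points would fall within the dwell "
                             "distance resolution")


def random_itinerary(n_staypoints: int = 5, seed: int = 0,
                     origin=(40.0, 116.3), leg_scale: float = 2000.0,
                     dwell_range=(300.0, 1800.0), **kwargs) -> ItineraryPlan:
    """A random itinerary: heavy-tailed leg lengths, uniform dwells."""
    rng = np.random.default_rng(seed)
    lat, lon = origin
    centers = [(lat, lon)]
    for _ in range(n_staypoints - 1):
        length = leg_scale * (1.0 - rng.random()) ** (-1.0 / 1.5)  # Pareto-ish
        length = min(length, 50 * leg_scale)
        theta = rng.random() * 2 * np.pi
        lat += length * np.sin(theta) / _M_PER_DEG
        lon += length * np.cos(theta) / (_M_PER_DEG * np.cos(np.radians(lat)))
        centers.append((lat, lon))
    dwells = list(rng.uniform(*dwell_range, size=n_staypoints))
    return ItineraryPlan(centers=centers, dwell_durations=dwells, **kwargs)


def generate_trajectory(plan: ItineraryPlan, seed: int = 0,
                        start_time: float = 1.2e9
                        ) -> tuple[Trajectory, list[StayPoint]]:
    """Realize an itinerary as GPS records plus its ground-truth staypoints.

    Dwell clusters are jittered around each planted center for the planned
    duration; travel legs are linearly interpolated at the sampling
    interval with point spacing above the dwell distance resolution.
    Ground-truth staypoints carry the exact mean coordinates and
    arrival/departure times of the generated dwell samples.
    """
    rng = np.random.default_rng(seed)
    points: list[TrackPoint] = []
    truth: list[StayPoint] = []
    t = start_time
    prev = None
    for (lat, lon), dwell in zip(plan.centers, plan.dwell_durations):
        if prev is not None:
            # travel leg: straight-line interpolation, arrival sets new t
            dist = np.hypot((lat - prev[0]) * _M_PER_DEG,
                            (lon - prev[1]) * _M_PER_DEG * np.cos(np.radians(lat)))
            duration = max(dist / plan.travel_speed, plan.sampling_interval)
            n_leg = int(duration // plan.sampling_interval)
            for k in range(1, n_leg):
                f = k / n_leg
                points.append(TrackPoint(
                    latitude=prev[0] + f * (lat - prev[0]),
                    longitude=prev[1] + f * (lon - prev[1]),
                    timestamp=t + k * plan.sampling_interval))
            t += n_leg * plan.sampling_interval
        n_dwell = max(2, int(dwell // plan.sampling_interval) + 1)
        lat_pts, lon_pts, ts_pts = [], [], []
        for k in range(n_dwell):
            r = 0.5 * plan.jitter * np.sqrt(rng.random())
            th = rng.random() * 2 * np.pi
            lat_pts.append(lat + r * np.sin(th) / _M_PER_DEG)
            lon_pts.append(lon + r * np.cos(th) /
                           (_M_PER_DEG * np.cos(np.radians(lat))))
            ts_pts.append(t + k * plan.sampling_interval)
        points.extend(TrackPoint(latitude=a, longitude=o, timestamp=s)
                      for a, o, s in zip(lat_pts, lon_pts, ts_pts))
        truth.append(StayPoint(center_latitude=float(np.mean(lat_pts)),
                               center_longitude=float(np.mean(lon_pts)),
                               arrival=ts_pts[0], departure=ts_pts[-1],
                               n_members=n_dwell))
        t = ts_pts[-1] + plan.sampling_interval
        prev = (lat, lon)
    traj = Trajectory(user_id="synthetic", file_id=f"seed{seed}", points=points)
    return traj, truth


# ---------------------------------------------------------------------------
# Series generators


def fractional_gaussian_noise(n: int, hurst: float,
                              seed: int | np.random.Generator = 0) -> np.ndarray:
    """Unit-variance fractional Gaussian noise via circulant embedding.

    The autocovariance γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) is
    embedded in a circulant matrix whose eigenvalues are obtained by FFT
    (Davies–Harte); negative eigenvalues from numerical round-off are
    clipped.
    """
    if not (0 < hurst < 1):
        raise ValueError("hurst must be in (0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    k = np.arange(n, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, [0.0], gamma[1:][::-1]])
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(np.sqrt(lam / (2.0 * m)) * z)
    return np.sqrt(2.0) * w.real[:n]


@dataclass
class SeriesPlan:
    """Recipe for one synthetic displacement series."""

    kind: str = "log_ar1"       # iid_lognormal | log_ar1 | fgn | cascade
    length: int = 2000
    phi: float = 0.7            # AR(1) coefficient (log_ar1)
    hurst: float = 0.8          # fgn
    sigma: float = 1.0          # scale of log-displacements
    mu: float = np.log(500.0)   # location of log-displacements (≈ 500 m)
    cascade_levels: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("iid_lognormal", "log_ar1", "fgn", "cascade"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if not (-1 < self.phi < 1):
            raise ValueError("phi must be in (-1, 1)")
        if not (0 < self.hurst < 1):
            raise ValueError("hurst must be in (0, 1)")

    @property
    def expected_tau1(self) -> float:
        """Exact consecutive τ under the Gaussian copula, where defined."""
        if self.kind == "log_ar1":
            return float(2.0 / np.pi * np.arcsin(self.phi))
        if self.kind == "iid_lognormal":
            return 0.0
        return float("nan")


def _log_values(plan: SeriesPlan, rng: np.random.Generator) -> np.ndarray:
    n = plan.length
    if plan.kind == "iid_lognormal":
        return rng.standard_normal(n)
    if plan.kind == "log_ar1":
        x = np.empty(n)
        x[0] = rng.standard_normal() / np.sqrt(1 - plan.phi ** 2)
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = plan.phi * x[t - 1] + eps[t]
        return x * np.sqrt(1 - plan.phi ** 2)  # unit marginal variance
    if plan.kind == "fgn":
        return fractional_gaussian_noise(n, plan.hurst, rng)
    # cascade: sum of per-scale block noises over dyadic levels
    levels = plan.cascade_levels
    x = np.zeros(n)
    for j in range(levels):
        block = 2 ** j
        n_blocks = -(-n // block)
        vals = rng.standard_normal(n_blocks)
        x += np.repeat(vals, block)[:n]
    return x / np.sqrt(levels)


def generate_series(plan: SeriesPlan) -> DisplacementSeries:
    """Positive displacement series with the planned correlation structure."""
    rng = np.random.default_rng(plan.seed)
    x = _log_values(plan, rng)
    d = np.exp(plan.mu + plan.sigma * x)
    return DisplacementSeries.from_displacements(
        d, user_id=f"synth-{plan.kind}", file_id=f"seed{plan.seed}")


# ---------------------------------------------------------------------------
# Cohorts


def _pareto_icdf(u: np.ndarray, alpha: float = 2.0,
                 x_min: float = 10.0) -> np.ndarray:
    return x_min * (1.0 - u) ** (-1.0 / (alpha - 1.0))


def _bimodal_icdf(u: np.ndarray) -> np.ndarray:
    """Quantile function of an equal-weight two-lognormal mixture.

    A bimodal, light-tailed marginal whose log-binned density is far from
    any power law.  Computed by numerical inversion of the mixture CDF on
    a log grid.
    """
    from scipy import stats as sstats
    x = np.logspace(0, 6.5, 4000)
    cdf = 0.5 * sstats.lognorm.cdf(x, 0.35, scale=80.0) \
        + 0.5 * sstats.lognorm.cdf(x, 0.35, scale=8000.0)
    return np.interp(u, cdf, x, left=x[0], right=x[-1])


def generate_cohort(n_users: int = 10, length: int = 600, seed: int = 0,
                    coupled: bool = True, n_files: int = 2,
                    min_phi: float = 0.1, max_phi: float = 0.8
                    ) -> tuple[list[DisplacementSeries], pd.DataFrame]:
    """Per-user series spanning weak-to-strong correlation.

    Each user's rank structure is a Gaussian AR(1) copula with coefficient
    φ_i spread over [min_phi, max_phi]; the displacement marginal is a
    *strictly monotone* quantile map — the geometric blend, with clean-tail
    weight w_i, of a clean Pareto quantile function and a bimodal
    two-lognormal one.  Because the map is monotone, each user's Kendall's
    Tau is exactly the copula value (2/π)·arcsin(φ_i) in expectation,
    independent of the marginal; the marginal alone controls how
    power-law-like the displacement distribution is.

    ``coupled=True`` ties w_i to φ_i (stronger correlation ⇒ cleaner
    power-law tail); ``coupled=False`` assigns the weights in a seeded
    random permutation instead, breaking the coupling while keeping both
    margins of the cohort identical.

    Returns the series list (``n_files`` files per user) and an expected
    summary table with each user's φ, clean-tail weight and copula τ₁.
    """
    from scipy import stats as sstats

    rng = np.random.default_rng(seed)
    phis = np.linspace(min_phi, max_phi, n_users)
    weights = np.linspace(0.0, 1.0, n_users)
    if not coupled:
        weights = weights[rng.permutation(n_users)]
    series_list: list[DisplacementSeries] = []
    rows = []
    for i in range(n_users):
        uid = f"user{i:03d}"
        for f in range(n_files):
            plan = SeriesPlan(kind="log_ar1", length=length, phi=float(phis[i]),
                              seed=int(rng.integers(2 ** 31)))
            x = _log_values(plan, np.random.default_rng(plan.seed))
            u = np.clip(sstats.norm.cdf(x), 1e-12, 1 - 1e-12)
            w = weights[i]
            d = np.exp(w * np.log(_pareto_icdf(u))
                       + (1.0 - w) * np.log(_bimodal_icdf(u)))
            series_list.append(DisplacementSeries.from_displacements(
                d, user_id=uid, file_id=f"f{f}"))
        rows.append({"user_id": uid, "phi": float(phis[i]),
                     "clean_weight": float(weights[i]),
                     "expected_tau1": float(2 / np.pi * np.arcsin(phis[i]))})
    return series_list, pd.DataFrame(rows)
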