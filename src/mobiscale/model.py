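"""Top-level modelling interface.

:class:`MobilityModel` bundles a collection of per-file displacement
series (read from GPS trajectories or produced by simulators) and its
:meth:`~MobilityModel.fit` runs the two analysis tracks:

* **population level** — pool every file: log-binned displacement,
  staying-time and elapsed-time distributions with their power-law fits,
  the speed–displacement pattern, consecutive and lagged Kendall's Tau
  (raw and relative displacements), the lagged log-Pearson decay, DFA
  Hurst exponent, and the staytime–displacement independence check;
* **individual level** — per-user aggregation over that user's files for
  users with more than ``min_staypoints`` staypoints, yielding a summary
  table (staypoint/displacement counts, mean and max displacement, τ₁,
  r_Δ, H, KS power-law fit, log-log fit qualities) and the six cross-user
  Kendall's Taus between the correlation statistics {τ₁, r_Δ, H} and the
  fit-quality statistics {p, R_Δr}.

The result object prints a text summary and exposes plotting helpers.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import correlation as corr
from . import dfa as dfa_mod
from . import scaling
from .series import (DisplacementSeries, build_series, pool_population,
                     relative_displacements, speed_displacement_points,
                     user_mean_displacements)
from .staypoint import extract_staypoints
from .trajectory_io import filter_files, read_directory

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "MobilityModel", "MobilityResults"]


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the pipeline (defaults follow the analysis
    conventions: 10 m / 120 s staypoint resolutions, 6 h file filter,
    >200 staypoints for individual-level analysis)."""

    d_max: float = 10.0
    t_min: float = 120.0
    min_file_duration: float = 6 * 3600.0
    staypoint_criterion: str = "consecutive"
    min_staypoints: int = 200
    bins_per_decade: int = 10
    n_bootstrap: int = 200
    max_lag: int = 50
    split_point: float = 1000.0
    dfa_order: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


class MobilityModel:
    """A population of per-file movement series, ready to be analyzed."""

    def __init__(self, series_list: Sequence[DisplacementSeries],
                 staypoint_counts: dict | None = None,
                 config: AnalysisConfig | None = None):
        self.series_list = list(series_list)
        self.config = config or AnalysisConfig()
        #: staypoints per (user_id, file_id); reconstructed as record
        #: count + 1 per file when the model is built from bare series.
        self.staypoint_counts = staypoint_counts or {
            (s.user_id, s.file_id): len(s) + 1 for s in self.series_list}
        self.funnel: dict[str, int] = {}

    # -- constructors -------------------------------------------------

    @classmethod
    def from_directory(cls, indir: str | os.PathLike,
                       config: AnalysisConfig | None = None) -> "MobilityModel":
        """Read a Geolife-style PLT tree and build the series population."""
        config = config or AnalysisConfig()
        trajectories = read_directory(indir)
        if not trajectories:
            raise FileNotFoundError(f"no PLT trajectories under {indir}")
        kept = filter_files(trajectories, config.min_file_duration)
        series_list, sp_counts = [], {}
        n_staypoints = 0
        for traj in kept:
            sps = extract_staypoints(traj, d_max=config.d_max,
                                     t_min=config.t_min,
                                     criterion=config.staypoint_criterion)
            n_staypoints += len(sps)
            sp_counts[(traj.user_id, traj.file_id)] = len(sps)
            if len(sps) >= 2:
                series_list.append(build_series(sps, user_id=traj.user_id,
                                                file_id=traj.file_id))
        model = cls(series_list, staypoint_counts=sp_counts, config=config)
        model.funnel = {"files_read": len(trajectories),
                        "files_kept": len(kept),
                        "staypoints": n_staypoints,
                        "movement_records": sum(len(s) for s in series_list)}
        logger.info("funnel: %s", model.funnel)
        return model

    @classmethod
    def from_series(cls, series_list, config=None) -> "MobilityModel":
        if isinstance(series_list, DisplacementSeries):
            series_list = [series_list]
        return cls(series_list, config=config)

    # -- fitting ------------------------------------------------------

    def fit(self, population: bool = True,
            individual: bool = True) -> "MobilityResults":
        cfg = self.config
        res = MobilityResults(model=self, config=cfg)
        if population:
            res.population = self._fit_population()
        if individual:
            res.user_summaries = self._fit_individual()
            res.cross_user = cross_user_correlations(res.user_summaries)
        return res

    def _fit_population(self) -> dict:
        cfg = self.config
        pool = pool_population(self.series_list)
        per_file = pool["per_file"]
        out: dict = {"n_files": len(self.series_list),
                     "n_records": int(pool["displacements"].size)}

        d = pool["displacements"]
        d_pos = d[d > 0]
        if d_pos.size:
            dist = scaling.log_bin(d_pos, cfg.bins_per_decade)
            out["displacement_distribution"] = dist
            try:
                out["two_regime"] = scaling.fit_two_regime(dist)
            except scaling.FitError:
                out["two_regime"] = None
            try:
                out["loglog_R"] = scaling.loglog_pearson(dist).R
            except scaling.FitError:
                out["loglog_R"] = float("nan")

        st = pool["staytimes"]
        st = st[np.isfinite(st) & (st > 0)]
        if st.size:
            out["staytime_distribution"] = scaling.log_bin(st, cfg.bins_per_decade)
            try:
                out["staytime_fit"] = scaling.fit_powerlaw_ks(
                    st, n_bootstrap=0, min_tail=20)
            except scaling.FitError:
                out["staytime_fit"] = None
        te = pool["elapsed_times"]
        te = te[np.isfinite(te) & (te > 0)]
        if te.size:
            out["elapsed_distribution"] = scaling.log_bin(te, cfg.bins_per_decade)

        try:
            out["speed_displacement"] = speed_displacement_points(
                self.series_list, bins_per_decade=cfg.bins_per_decade,
                split_point=cfg.split_point)
        except Exception:  # noqa: BLE001 - optional pattern
            out["speed_displacement"] = None

        # correlations (pairs never cross file boundaries)
        try:
            out["tau1"] = corr.lagged_tau(per_file, 1)
        except corr.CorrelationError:
            out["tau1"] = None
        rel = relative_displacements(self.series_list)
        try:
            out["tau1_relative"] = corr.lagged_tau(rel, 1)
        except corr.CorrelationError:
            out["tau1_relative"] = None
        out["tau_decay"] = corr.tau_decay(per_file, max_lag=cfg.max_lag)

        # staytime-series correlation and staytime-displacement independence
        st_files = [s.staytimes for s in self.series_list]
        st_files = [x[np.isfinite(x)] for x in st_files]
        try:
            out["tau1_staytime"] = corr.lagged_tau(
                [x for x in st_files if x.size], 1)
        except corr.CorrelationError:
            out["tau1_staytime"] = None
        out["tau_staytime_displacement"] = run_staytime_independence(
            self.series_list)

        cat = np.concatenate([x for x in per_file if x.size]) \
            if per_file else np.empty(0)
        if cat.size >= 64:
            out["dfa"] = dfa_mod.dfa(cat, order=cfg.dfa_order)
        else:
            out["dfa"] = None
        return out

    def _fit_individual(self) -> pd.DataFrame:
        cfg = self.config
        by_user: dict[str, list[DisplacementSeries]] = {}
        for s in self.series_list:
            by_user.setdefault(s.user_id, []).append(s)
        sp_by_user: dict[str, int] = {}
        for (uid, _fid), n in self.staypoint_counts.items():
            sp_by_user[uid] = sp_by_user.get(uid, 0) + n
        rows = []
        for uid in sorted(by_user):
            if sp_by_user.get(uid, 0) <= cfg.min_staypoints:
                continue
            rows.append(self._user_summary(uid, by_user[uid],
                                           sp_by_user.get(uid, 0)))
        return pd.DataFrame(rows)

    def _user_summary(self, uid: str, series: list[DisplacementSeries],
                      n_staypoints: int) -> dict:
        cfg = self.config
        per_file = [s.displacements for s in series]
        d = np.concatenate(per_file) if per_file else np.empty(0)
        row = {"user_id": uid, "N_s": int(n_staypoints), "N_d": int(d.size),
               "mean_displacement": float(d.mean()) if d.size else np.nan,
               "max_displacement": float(d.max()) if d.size else np.nan}
        try:
            t = corr.lagged_tau(per_file, 1)
            row["tau1"], row["tau1_ci"] = t.tau, t.ci_halfwidth
        except corr.CorrelationError:
            row["tau1"] = row["tau1_ci"] = np.nan
        try:
            row["r_delta"] = corr.log_pearson(d[d > 0]).r_delta
        except corr.CorrelationError:
            row["r_delta"] = np.nan
        try:
            row["hurst"] = dfa_mod.dfa(d, order=cfg.dfa_order).hurst
        except dfa_mod.DFAError:
            row["hurst"] = np.nan
        try:
            fit = scaling.fit_powerlaw_ks(d[d > 0],
                                          n_bootstrap=cfg.n_bootstrap,
                                          seed=cfg.seed, min_tail=30)
            row["ks_xmin"], row["ks_alpha"], row["ks_p"] = \
                fit.x_min, fit.alpha, fit.p
        except scaling.FitError:
            row["ks_xmin"] = row["ks_alpha"] = row["ks_p"] = np.nan
        for key, samples in (("R_displacement", d[d > 0]),
                             ("R_staytime", _finite_positive(
                                 np.concatenate([s.staytimes for s in series])
                                 if series else np.empty(0)))):
            try:
                dist = scaling.log_bin(samples, cfg.bins_per_decade)
                row[key] = scaling.loglog_pearson(dist).R
            except (scaling.FitError, ValueError):
                row[key] = np.nan
        return row


def _finite_positive(x: np.ndarray) -> np.ndarray:
    return x[np.isfinite(x) & (x > 0)]


_CROSS_PAIRS = [("tau1", "ks_p"), ("tau1", "R_displacement"),
                ("r_delta", "ks_p"), ("r_delta", "R_displacement"),
                ("hurst", "ks_p"), ("hurst", "R_displacement")]


def cross_user_correlations(user_summaries: pd.DataFrame) -> dict | None:
    """Six cross-user Kendall's Taus between correlation strength
    {τ₁, r_Δ, H} and power-law fit quality {p, R_Δr}.

    Returns None when fewer than two users are available (flagged
    not-computable).
    """
    if user_summaries is None or len(user_summaries) < 2:
        return None
    out: dict = {"n_users": int(len(user_summaries))}
    n = len(user_summaries)
    out["ci_halfwidth"] = corr.tau_ci(n) if n >= 10 else float("nan")
    for a, b in _CROSS_PAIRS:
        sub = user_summaries[[a, b]].dropna()
        key = f"tau({a},{b})"
        if len(sub) < 2:
            out[key] = None
            continue
        out[key] = corr.kendall_tau(sub[a].to_numpy(), sub[b].to_numpy()).tau
    return out


def run_staytime_independence(series_list) -> corr.TauResult | None:
    """Kendall's Tau between paired staying times and displacements.

    Each movement record pairs the staying time of the origin staypoint
    with the displacement that follows it; pairs are pooled across files.
    """
    xs, ys = [], []
    for s in series_list:
        st, d = s.staytimes, s.displacements
        ok = np.isfinite(st)
        xs.append(st[ok])
        ys.append(d[ok])
    if not xs:
        return None
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 2:
        return None
    return corr.kendall_tau(x, y)


@dataclass
class MobilityResults:
    """Fitted population and per-user mobility statistics."""

    model: MobilityModel
    config: AnalysisConfig
    population: dict | None = None
    user_summaries: pd.DataFrame | None = None
    cross_user: dict | None = None

    # -- reporting ----------------------------------------------------

    def summary(self) -> str:
        lines = ["Mobility analysis summary", "=" * 60]
        if self.model.funnel:
            f = self.model.funnel
            lines.append(f"files read {f['files_read']}, kept "
                         f"{f['files_kept']}, staypoints {f['staypoints']}, "
                         f"movement records {f['movement_records']}")
        p = self.population
        if p:
            lines.append(f"files analyzed: {p['n_files']}, pooled movement "
                         f"records: {p['n_records']}")
            if p.get("two_regime"):
                tr = p["two_regime"]
                lines.append(f"displacement density: two-regime power law, "
                             f"exponents {tr.alpha_low:.2f} / "
                             f"{tr.alpha_high:.2f}, break "
                             f"{tr.break_point:.0f} m")
            if p.get("loglog_R") is not None:
                lines.append(f"displacement log-log fit R = {p['loglog_R']:.3f}")
            if p.get("speed_displacement"):
                sd = p["speed_displacement"]
                lines.append(f"speed-displacement slopes: "
                             f"{sd['slope_low']:.2f} (< {sd['split_point']:.0f} m) / "
                             f"{sd['slope_high']:.2f} (above)")
            for key, label in (("tau1", "tau1 (raw dr)"),
                               ("tau1_relative", "tau1 (relative dr')"),
                               ("tau1_staytime", "tau1 (staying times)"),
                               ("tau_staytime_displacement",
                                "tau (staytime vs displacement)")):
                t = p.get(key)
                if t is not None:
                    lines.append(f"{label} = {t.tau:.3f} "
                                 f"(95% null CI +-{t.ci_halfwidth:.3f})")
            td = p.get("tau_decay")
            if td is not None and np.isfinite(td.decay_exponent):
                lines.append(f"tau(dn) decay exponent {td.decay_exponent:.3f}")
            if p.get("dfa") is not None and not p["dfa"].degenerate:
                lines.append(f"DFA Hurst H = {p['dfa'].hurst:.3f}")
        if self.user_summaries is not None:
            lines.append("-" * 60)
            lines.append(f"individual level: {len(self.user_summaries)} users "
                         f"above {self.config.min_staypoints} staypoints")
            if len(self.user_summaries):
                with pd.option_context("display.width", 120,
                                       "display.max_columns", 20):
                    lines.append(self.user_summaries.round(3).to_string(index=False))
        if self.cross_user:
            lines.append("-" * 60)
            hw = self.cross_user["ci_halfwidth"]
            hw_txt = f"+-{hw:.3f}" if np.isfinite(hw) else "n/a (n < 10)"
            lines.append("cross-user correlations "
                         f"(n = {self.cross_user['n_users']}, 95% null CI "
                         f"{hw_txt}):")
            for (a, b) in _CROSS_PAIRS:
                v = self.cross_user.get(f"tau({a},{b})")
                if v is not None:
                    lines.append(f"  tau({a}, {b}) = {v:.3f}")
        elif self.user_summaries is not None:
            lines.append("cross-user correlations: not computable (<2 users)")
        return "\n".join(lines)

    def to_json(self) -> dict:
        """JSON-serializable report of the scalar statistics."""
        def tau_dict(t):
            return None if t is None else {"tau": t.tau, "n_pairs": t.n_pairs,
                                           "ci_halfwidth": t.ci_halfwidth}
        out: dict = {}
        p = self.population or {}
        pop: dict = {k: tau_dict(p.get(k)) for k in
                     ("tau1", "tau1_relative", "tau1_staytime",
                      "tau_staytime_displacement")}
        if p.get("two_regime"):
            tr = p["two_regime"]
            pop["two_regime"] = {"break_point": tr.break_point,
                                 "alpha_low": tr.alpha_low,
                                 "alpha_high": tr.alpha_high}
        if p.get("tau_decay") is not None:
            td = p["tau_decay"]
            pop["tau_decay"] = {"lags": td.lags.tolist(),
                                "taus": td.tau_values.tolist(),
                                "decay_exponent": td.decay_exponent,
                                "hurst_from_decay": td.hurst_from_decay}
        if p.get("dfa") is not None:
            pop["dfa_hurst"] = p["dfa"].hurst
        if p.get("speed_displacement"):
            sd = p["speed_displacement"]
            pop["speed_slopes"] = [sd["slope_low"], sd["slope_high"]]
        out["population"] = pop
        if self.user_summaries is not None:
            out["users"] = self.user_summaries.to_dict(orient="records")
        if self.cross_user is not None:
            out["cross_user"] = self.cross_user
        return out

    # -- plotting -----------------------------------------------------

    def plot_distributions(self, ax=None):
        """Log-log displacement/staytime/elapsed-time densities."""
        import matplotlib.pyplot as plt
        p = self.population or {}
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for ax_, key, label in zip(
                axes, ("displacement_distribution", "staytime_distribution",
                       "elapsed_distribution"),
                ("dr (m)", "dt (s)", "dt_e (s)")):
            dist = p.get(key)
            if dist is not None:
                m = dist.densities > 0
                ax_.loglog(dist.centers[m], dist.densities[m], "o", ms=4)
            ax_.set_xlabel(label)
            ax_.set_ylabel("P")
        fig.tight_layout()
        return fig

    def plot_tau_decay(self):
        import matplotlib.pyplot as plt
        td = (self.population or {}).get("tau_decay")
        fig, ax = plt.subplots(figsize=(5, 4))
        if td is not None:
            m = td.tau_values > 0
            ax.loglog(td.lags[m], td.tau_values[m], "o-", ms=4)
        ax.set_xlabel("lag dn")
        ax.set_ylabel("tau(dn)")
        fig.tight_layout()
        return fig

    def plot_speed_displacement(self):
        import matplotlib.pyplot as plt
        sd = (self.population or {}).get("speed_displacement")
        fig, ax = plt.subplots(figsize=(5, 4))
        if sd is not None:
            pts = sd["points"]
            ok = (pts[:, 0] > 0) & (pts[:, 1] > 0)
            ax.loglog(pts[ok, 0], pts[ok, 1], ".", ms=2, alpha=0.3)
            cx, cy = sd["curve"]
            if cx.size:
                ax.loglog(cx, cy, "r-", lw=2)
        ax.set_xlabel("dr (m)")
        ax.set_ylabel("v (m/s)")
        fig.tight_layout()
        return fig


# -- pipeline entry points (thin wrappers used by the CLI) -----------------


def run_population(indir, config: AnalysisConfig | None = None) -> MobilityResults:
    """Population-level track: pool all qualifying files under ``indir``."""
    model = MobilityModel.from_directory(indir, config=config)
    return model.fit(individual=False)


def run_individual(indir, config: AnalysisConfig | None = None,
                   min_staypoints: int | None = None) -> MobilityResults:
    """Individual-level track: per-user summaries + cross-user correlations."""
    config = config or AnalysisConfig()
    if min_staypoints is not None:
        config.min_staypoints = min_staypoints
    model = MobilityModel.from_directory(indir, config=config)
    return model.fit(population=False)
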