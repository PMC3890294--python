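"""End-to-end model interface: directory pipeline, summaries, thresholds."""

import json
import os

import numpy as np
import pandas as pd
import pytest

from mobiscale.model import (AnalysisConfig, MobilityModel,
                             cross_user_correlations, run_individual,
                             run_population, run_staytime_independence)
from mobiscale.series import DisplacementSeries
from mobiscale.synthetic_data import (generate_cohort, generate_trajectory,
                                      random_itinerary)
from mobiscale.trajectory_io import read_series, write_plt, write_series


@pytest.fixture(scope="module")
def plt_tree(tmp_path_factory):
    """Two users x two files of synthetic GPS data in Geolife layout."""
    root = tmp_path_factory.mktemp("geolife")
    seed = 0
    for user in ("000", "001"):
        d = root / user / "Trajectory"
        d.mkdir(parents=True)
        for f in range(2):
            plan = random_itinerary(n_staypoints=6, seed=seed,
                                    dwell_range=(300.0, 900.0))
            traj, _ = generate_trajectory(plan, seed=seed)
            write_plt(traj, d / f"2008{seed:02d}.plt")
            seed += 1
    return root


class TestDirectoryPipeline:
    def test_funnel_counts(self, plt_tree):
        cfg = AnalysisConfig(min_file_duration=0.0, min_staypoints=0,
                             n_bootstrap=0, max_lag=3)
        model = MobilityModel.from_directory(plt_tree, config=cfg)
        assert model.funnel["files_read"] == 4
        assert model.funnel["files_kept"] == 4
        assert model.funnel["staypoints"] == 24
        assert model.funnel["movement_records"] == 20

    def test_duration_filter_drops_short_files(self, plt_tree):
        cfg = AnalysisConfig(min_file_duration=1e9)
        with_all = MobilityModel.from_directory(
            plt_tree, config=AnalysisConfig(min_file_duration=0.0))
        model = MobilityModel.from_directory(plt_tree, config=cfg)
        assert len(model.series_list) == 0
        assert len(with_all.series_list) == 4

    def test_empty_directory_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            MobilityModel.from_directory(tmp_path)

    def test_summary_and_json(self, plt_tree):
        cfg = AnalysisConfig(min_file_duration=0.0, min_staypoints=0,
                             n_bootstrap=0, max_lag=3)
        res = MobilityModel.from_directory(plt_tree, config=cfg).fit()
        text = res.summary()
        assert "files analyzed: 4" in text
        assert "individual level: 2 users" in text
        blob = json.loads(json.dumps(res.to_json(), default=float))
        assert set(blob) >= {"population", "users"}
        assert len(blob["users"]) == 2


def _cohort_model(n_users=10, length=600, seed=0, coupled=True, **cfg):
    series, expected = generate_cohort(n_users=n_users, length=length,
                                       seed=seed, coupled=coupled)
    config = AnalysisConfig(min_staypoints=0, n_bootstrap=0, max_lag=5, **cfg)
    return MobilityModel.from_series(series, config=config), expected


class TestIndividualTrack:
    def test_threshold_excludes_short_users(self):
        big, _ = generate_cohort(n_users=6, length=300, seed=1)
        small, _ = generate_cohort(n_users=4, length=50, seed=2)
        for s in small:
            s.user_id = "small-" + s.user_id
        cfg = AnalysisConfig(min_staypoints=200, n_bootstrap=0, max_lag=3)
        model = MobilityModel.from_series(big + small, config=cfg)
        res = model.fit(population=False)
        # 300-record users have 2*(301) staypoints; 50-record users 2*51
        assert len(res.user_summaries) == 6

    def test_threshold_monotone(self):
        model, _ = _cohort_model(n_users=5, length=100)
        counts = []
        for thr in (0, 100, 150, 10_000):
            model.config.min_staypoints = thr
            counts.append(len(model.fit(population=False).user_summaries))
        assert counts[0] == 5
        assert sorted(counts, reverse=True) == counts

    def test_summary_statistics_in_range(self):
        model, expected = _cohort_model(n_users=6)
        df = model.fit(population=False).user_summaries
        assert (df["N_d"] == 1200).all()
        assert (df["tau1"].abs() <= 1).all()
        assert (df["r_delta"].abs() <= 1).all()
        assert df["hurst"].between(0, 1.2).all()
        assert df["R_displacement"].between(-1, 0).all()
        # measured tau tracks the planted copula ordering
        assert (df.sort_values("user_id")["tau1"].to_numpy().argsort()
                == np.arange(6)).all()

    def test_single_user_cross_correlations_not_computable(self):
        model, _ = _cohort_model(n_users=1)
        res = model.fit(population=False)
        assert res.cross_user is None
        assert "not computable" in res.summary()

    def test_pipeline_reentrant_from_series_files(self, tmp_path):
        model, _ = _cohort_model(n_users=3, length=200)
        res1 = model.fit(individual=False)
        path = tmp_path / "series.tsv"
        write_series(model.series_list, path)
        model2 = MobilityModel.from_series(read_series(path),
                                           config=model.config)
        res2 = model2.fit(individual=False)
        assert res1.population["tau1"].tau == \
            pytest.approx(res2.population["tau1"].tau, abs=1e-12)


class TestPlotting:
    def test_plot_helpers_return_figures(self):
        import matplotlib.pyplot as plt
        model, _ = _cohort_model(n_users=3, length=100)
        res = model.fit(individual=False)
        for fig in (res.plot_distributions(), res.plot_tau_decay(),
                    res.plot_speed_displacement()):
            assert fig.axes
            plt.close(fig)


class TestStaytimeIndependence:
    def test_independent_pairs_null(self, rng):
        s = DisplacementSeries.from_displacements(
            rng.lognormal(5, 1, 2000), staytimes=rng.lognormal(6, 1, 2000))
        res = run_staytime_independence([s])
        assert abs(res.tau) < res.ci_halfwidth

    def test_coupled_pairs_near_one(self, rng):
        d = rng.lognormal(5, 1, 500)
        s = DisplacementSeries.from_displacements(d, staytimes=3.0 * d)
        assert run_staytime_independence([s]).tau == 1.0

    def test_no_staytimes_gives_none(self):
        s = DisplacementSeries.from_displacements(np.ones(10) * 5)
        assert run_staytime_independence([s]) is None


class TestCrossUserCorrelations:
    def test_coupled_cohort_positive(self):
        model, _ = _cohort_model(n_users=10, length=600, seed=3)
        res = model.fit(population=False)
        cu = res.cross_user
        assert cu["n_users"] == 10
        # stronger correlation <-> more negative R (better power-law fit)
        assert cu["tau(tau1,R_displacement)"] < -cu["ci_halfwidth"]

    def test_fewer_than_two_users_none(self):
        assert cross_user_correlations(pd.DataFrame()) is None
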