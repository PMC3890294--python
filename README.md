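# mobiscale

Scaling laws and displacement correlations in GPS-based human mobility.

`mobiscale` is a tested, reusable pipeline for the movement-analysis
workflow that starts from raw GPS trajectories and ends at the statistics
that characterize human (or animal) mobility:

1. **Staypoint extraction** — find the *effective staying positions* in a
   GPS track: maximal sub-sequences of records confined within a 10 m
   spatial resolution for longer than 120 s, summarized by their mean
   coordinates, arrival/departure times and staying time Δt.
2. **Movement series** — for consecutive staypoints, the displacement Δr
   (great-circle distance between centers), the elapsed travel time Δt_e,
   the speed v = Δr/Δt_e, and the relative displacement Δr′ = Δr/⟨Δr⟩
   normalized by the user's mean.
3. **Scaling analysis** — log-binned densities of Δr, Δt and Δt_e; a
   two-regime power-law fit P(Δr) ∝ Δr^(−β₁) below a break scale and
   ∝ Δr^(−β₂) above it; a Clauset-style maximum-likelihood power-law tail
   fit α̂ = 1 + n/Σln(xᵢ/x_min) with a KS-optimal lower bound and a
   semiparametric-bootstrap confidence probability p; and the log-log
   Pearson R of the binned points as a direct fit-quality measure.
4. **Correlation analysis** — Kendall's tau-a between Δr_n and Δr_{n+Δn}
   (τ = 2/(n(n−1)) Σ_{i<j} sgn(xᵢ−xⱼ)sgn(yᵢ−yⱼ), pairs never spanning
   file boundaries), the power-law decay of τ(Δn), the consecutive
   log-displacement Pearson r_Δ, and the Hurst exponent H from detrended
   fluctuation analysis (DFA).
5. **Mobility models** — seeded simulators of five reference processes
   (Lévy flight, CTRW, exploration/preferential-return, SLAW on a
   self-similar landscape, and a hierarchical-traffic-system random walk)
   whose displacement series run through exactly the same analysis,
   so their correlation signatures can be compared with data.
6. **Synthetic data** — generators for GPS tracks with planted dwell
   clusters and for displacement series with controlled consecutive
   correlation (Gaussian-copula AR(1)), long-term persistence (fractional
   Gaussian noise, multiplicative cascades), and whole cohorts in which
   correlation strength and power-law tail cleanliness are coupled or
   decoupled by construction.

The package is aimed at researchers in human mobility, movement ecology
and epidemic modelling who need these statistics with explicit,
reproducible conventions rather than one-off notebook code.

## Worked example

The central interface is a statsmodels-style pair of objects: a
`MobilityModel` built from per-file displacement series (read from PLT
trajectory trees with `MobilityModel.from_directory`, or from simulator /
generator output with `from_series`), whose `fit()` returns a
`MobilityResults` with the population statistics, the per-user summary
table and the cross-user correlations.

```python
from mobiscale.synthetic_data import generate_cohort
from mobiscale.model import MobilityModel, AnalysisConfig

# 10 synthetic users whose displacement-correlation strength and
# power-law tail cleanliness are coupled by construction
series, expected = generate_cohort(n_users=10, length=600, seed=42,
                                   coupled=True)
cfg = AnalysisConfig(min_staypoints=0, n_bootstrap=100, max_lag=20, seed=0)
results = MobilityModel.from_series(series, config=cfg).fit()
print(results.summary())
```

prints (abridged):

```
files analyzed: 20, pooled movement records: 12000
displacement density: two-regime power law, exponents -1.20 / -3.27, break 13841 m
tau1 (raw dr) = 0.434 (95% null CI +-0.012)
tau1 (relative dr') = 0.237 (95% null CI +-0.012)
tau(dn) decay exponent -0.191
DFA Hurst H = 0.720
------------------------------------------------------------
individual level: 10 users above 0 staypoints
user_id  N_s  N_d  mean_displacement  ...  tau1  r_delta  hurst  ks_alpha  ks_p  R_displacement
user000 1202 1200           4319.990  ... 0.062    0.100  0.541     7.017  0.38          -0.843
...
user009 1202 1200             70.899  ... 0.576    0.762  0.644     1.997  0.76          -0.995
------------------------------------------------------------
cross-user correlations (n = 10, 95% null CI +-0.487):
  tau(tau1, R_displacement) = -0.911
```

Reading the output: the pooled series has a significant consecutive
rank correlation (τ₁ = 0.434, far outside the ±0.012 null band) that
decays slowly with lag, and long-term persistence (H = 0.72 > 0.5).  At
the individual level the users span weak (τ₁ ≈ 0.06) to strong
(τ₁ ≈ 0.58) correlation, and the cross-user Kendall's Tau between τ₁ and
the log-log fit quality R is −0.91: users with stronger displacement
correlation have displacement distributions closer to a power law (R
closer to −1).  On this cohort that coupling is planted, so the pipeline
must — and does — detect it.

## Command line

Every stage is also a shell command operating on Geolife-style PLT trees
and tab-separated series tables:

```bash
mobiscale synth trajectory --seed 3 --out data        # synthetic GPS data
mobiscale extract data out --dmax 10 --tmin 120       # staypoints -> series
mobiscale report data --out report.json --plots figs  # both analysis tracks
mobiscale simulate hts --seed 2 --steps 10000 --out hts.tsv
```

`mobiscale report` logs the processing funnel (files read → files above
the 6 h recording-time filter → staypoints → movement records) so counts
are auditable at every stage.

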