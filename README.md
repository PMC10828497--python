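# hrvnoise

Monte Carlo sensitivity analysis of heart-rate-variability (HRV) parameters
to beat-timing noise.

## The problem

HRV parameters are computed from the beat-to-beat (RR) interval tachogram,
usually derived from ECG R-peak detections or PPG pulse arrivals. Beat
detection is never exact: finite sampling rate, signal noise and detector
jitter all perturb the beat times, and these timing errors propagate —
often nonlinearly — into every downstream HRV parameter. Researchers
choosing which parameters to report (and engineers validating wearable
sensors) need to know *which parameters tolerate timing noise and which are
systematically biased by it*.

`hrvnoise` answers that question by simulation. It provides:

* **noise models** — zero-mean beat-time noise from four families, each
  parameterized to a target standard deviation σ (ms):
  Gaussian `N(0, σ)`, uniform on `[−√3σ, +√3σ]`, triangular on
  `[−√6σ, 0, +√6σ]`, and a heavy-tailed scaled Student *t* (ν = 3);
* **a 34-parameter HRV suite** for 5-min segments — time domain (MeanRR,
  MeanHR, SDNN, RMSSD, NN50, pNN50, HRVti, TINN, SI, PRSA DC/AC and their
  modified variants), frequency domain (LF/HF/total power, relative and
  normalized powers, LF/HF ratio from a 4 Hz spline-resampled Welch
  spectrum), and nonlinear (Poincaré SD1/SD2, ApEn, SampEn, DFA α₁/α₂,
  correlation dimension D2, and recurrence-plot REC/DET/Lmean/Lmax/ShanEn);
* **a synthetic cohort generator** — integral pulse frequency modulation
  (IPFM) tachograms with band-limited LF and HF rate modulation, calibrated
  to a resting healthy adult population (69 ± 9.6 bpm, ~344 beats per 5-min
  window);
* **the evaluation pipeline** — per-segment errors `e = x̂ − x`, aggregated
  into bias Δ = mean(e), MAE = mean|e|, RMSE = √mean(e²) and 5th/95th error
  percentiles per (parameter, noise family, σ); Kolmogorov–Smirnov
  comparisons of error distributions between noise families; Bland–Altman
  agreement statistics; and the normalized linear sensitivity

  ```
  Δ_p(σ)    = α_bias / 100% · σ · x̄_p
  MAE_p(σ)  = α_MAE  / 100% · σ · |x̄_p|
  RMSE_p(σ) = α_RMSE / 100% · σ · |x̄_p|
  ```

  fitted through the origin across the σ grid, where x̄_p is the group mean
  of the ground truth. α is in %/ms: "each extra millisecond of timing
  noise costs this many percent of the typical parameter value".

## Worked example

```
hrv-noise simulate-cohort --n-recordings 20 --seed 1 --out cohort_demo
hrv-noise run-sensitivity --cohort cohort_demo --n-segments 200 \
    --sigma-grid 1:10:10 --noise gaussian --seed 2 --out results_demo
hrv-noise report --results results_demo --top 5
```

prints

```
Most noise-tolerant parameters (smallest alpha_RMSE):
 parameter   family      x_bar  alpha_bias  alpha_mae  alpha_rmse
    MeanHR gaussian  65.592884   -0.000022   0.000383    0.000485
    MeanRR gaussian 935.582072    0.000022   0.000384    0.000490
       DET gaussian  95.717242   -0.086853   0.092383    0.104637
       SD2 gaussian  58.698123    0.113257   0.126046    0.151912
DFA_alpha2 gaussian   0.105191   -0.071893   0.191102    0.243370

Least noise-tolerant parameters (largest alpha_RMSE):
parameter   family      x_bar  alpha_bias  alpha_mae  alpha_rmse
       AC gaussian -12.845084   -1.073749   1.399869    1.698403
    pNN50 gaussian  31.637526    1.416885   1.522469    1.736988
     NN50 gaussian 101.590000    1.458102   1.563056    1.801557
       DC gaussian  12.428365   -1.260567   1.557811    1.895910
     Lmax gaussian  62.250000   -1.703145   2.091775    3.404595
```

Reading the table: the mean heart rate and mean RR interval are essentially
immune to zero-mean timing noise (α ≈ 0 %/ms), whereas the threshold-count
parameters NN50/pNN50 are *overestimated* by ~1.4–1.5 % of their typical
value per millisecond of noise (positive α_bias) and their RMSE grows by
~1.7–1.8 %/ms. The recurrence-plot maximum line length (Lmax) is the least
tolerant parameter of all. `run-sensitivity` also writes `summary.csv`
(bias/MAE/RMSE/percentiles per parameter × σ), `ks.csv` (family-pair KS
tests, when several `--noise` families are given), `ba_summary.csv` and
per-parameter `ba_<param>.csv` Bland–Altman tables, and `convergence.csv`
(the 2%-normalized-standard-error sample-size check).

The same pipeline is available as a library:

```python
from hrvnoise import CohortSpec, RunConfig, generate_cohort, run_monte_carlo

cohort = generate_cohort(CohortSpec(seed=1))
result = run_monte_carlo(cohort, RunConfig(n_segments=500, seed=2))
print(result.alpha.sort_values("alpha_rmse"))
```

Real recordings can be analyzed instead of synthetic ones by pointing
`--cohort` at a directory of RR CSV files (`t_sec,rr_ms` or a single
`rr_ms` column).

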