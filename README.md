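# phenoacoustics

Inferring **insect acoustic phenology** — diel and seasonal cycles of
insect sound activity — from passive acoustic monitoring (PAM) of
tropical-forest soundscapes.

Long-duration recorders produce far more audio than anyone can listen
to. The standard workaround is *acoustic indices*: scalar summaries of a
recording's time–frequency energy. This package implements, as a fully
tested pipeline, the chain that turns banks of 1-minute recordings into
calibrated activity curves with propagated uncertainty:

1. **Acoustic indices** restricted to the insect band (3–10 kHz, where
   cricket and katydid biophony concentrates): ACI (acoustic
   complexity), ADI (acoustic diversity), BI (bioacoustic index), H
   (acoustic entropy) and NP (number of spectral peaks), min–max scaled
   to [0.0001, 0.9999].
2. **Quality control**: a two-band rain classifier (band power and band
   signal-to-noise in 0.6–1.2 and 4.4–5.6 kHz), then removal of clips
   whose five-index vector has squared Mahalanobis distance > 12 from
   the corpus mean.
3. **Calibration** of manual activity labels against the scaled indices:
   beta regression with logit link for *spectrogram coverage* (fraction
   of the 3–10 kHz spectrogram occupied by insect sound per 15 s,
   quantized to 5%) and Poisson regression for *sonotype counts*
   (distinct insect sound types per 15 s). All 2¹² submodels over
   {5 linear + 5 quadratic index terms, site, year} are ranked by AICc
   (−2ℓ + 2k + 2k(k+1)/(n−k−1)); models with ΔAICc < 2 are combined by
   Akaike-weighted full averaging; predictive error is measured by
   5-fold cross-validation repeated 100 times (RMSE, MAE).
4. **Cyclic smoothing**: a Gaussian GAM per index with cyclic cubic
   regression splines (k = 4) over hour (period 24) and day of year
   (period 365) plus a site × year factor, fitted by penalized least
   squares with GCV-selected smoothing parameters.
5. **Uncertainty propagation**: 1000 Monte Carlo iterations drawing each
   index from Normal(GAM mean, GAM se), pushing the draws through the
   calibration model, then drawing activity from Normal(calibration
   mean, calibration se) — yielding a distribution of predicted
   activity at every (hour, day-of-year, site, year) grid point.

Because suitable labelled field data are rarely at hand, the package
ships a **synthetic soundscape generator** (`phenoacoustics.synth`):
insect sonotypes confined to 3–10 kHz with nocturnal and dry-season
activation cycles, a 1-min-per-10-min recording schedule, rain and
recorder-fault contamination, and ground-truth labels computed exactly
as a manual annotator would quantize them. Every pipeline stage is
verified against this known truth.

## Worked example

Run a reduced synthetic study (2 sites, 2018–2019 sampled every 15th
day, one 15-s clip every 3 h, 5% missing files, 8% rain, 2% faults) and
produce activity curves:

```python
from phenoacoustics.pipeline import PipelineConfig, run_all

cfg = PipelineConfig(
    output_dir="study", seed=1,
    sites=["T1", "T2"], start_date="2018-01-01", end_date="2019-12-31",
    cadence_minutes=180, day_stride=15, write_audio=False,
    clip_duration=15.0, sample_rate=22050.0,
    missing_fraction=0.05, rain_rate=0.08, fault_rate=0.02,
)
report = run_all(cfg)
```

The QC stage logs

```
[qc] retained 646/740 clips (87.3%)
```

and the final report (also written to `study/report.json`) contains the
propagated median activity by hour and day of year. For this run:

| quantity | night (20–05 h) | day (07–15 h) |
|---|---|---|
| spectrogram coverage (median) | 0.448 | 0.200 |
| sonotypes per 15 s (median) | 11.73 | 4.80 |

| quantity | dry season (doy 182–334) | wet season (doy 60–151) |
|---|---|---|
| spectrogram coverage (median) | 0.201 | 0.072 |
| sonotypes per 15 s (median) | 4.79 | 1.73 |

i.e. the pipeline recovers the nocturnal and dry-season activity peaks
that the generator injected, after rain/fault screening retained 87.3%
of clips. Cross-validated calibration error for this run: coverage
RMSE 0.033 / MAE 0.026; sonotypes RMSE 1.05 / MAE 0.80.

The same pipeline is available from the shell:

```bash
phenoacoustics all --config study.yaml --seed 1
phenoacoustics indices --config study.yaml --jobs 4   # per-stage reruns
```

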