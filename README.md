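# dyadsync

Interpersonal motion-synchrony analysis and diagnostic classification for
dyadic interaction videos.

Autism diagnostics lean on semi-structured observation interviews
(ADOS-2). A scalable, rater-independent screening signal can be extracted
from ordinary interview videos: the degree to which patient and clinician
move *in sync*. `dyadsync` implements that full analysis chain for
researchers in digital phenotyping and psychiatric machine learning:

1. **Motion energy analysis (MEA)** — per region of interest (head/body of
   participant and administrator), count the pixels whose gray value
   changes by more than a threshold (τ = 8) between frames.
2. **Windowed cross-lagged synchrony** — SD-scale and smooth each series
   (0.5 s moving average), then correlate 60-s windows at lags up to ±5 s
   in 30-s steps; each correlation r becomes |atanh(r)| (absolute Fisher
   Z). Intrapersonal head–body coordination uses 30-s windows and 15-s
   steps. Pseudodyads (participants paired with foreign administrators)
   give the chance-level baseline.
3. **Feature engineering** — each synchrony matrix collapses to
   {min, max, mean, median, SD, skew, kurtosis}; with four movement
   quantities this yields 25 features per dyad (27 with IQ and sex).
4. **Classification** — a class-weighted linear SVM in a repeated nested
   stratified CV (10 outer folds × 10 repetitions, 10 inner folds tuning
   C ∈ {0.0156 … 16} by balanced accuracy BAC = (sensitivity +
   specificity)/2), with all preprocessing (0–1 scaling, pruning, kNN
   imputation, age residualization) fit strictly in-fold. Each dyad's 100
   held-out decision scores pool by their median. Inference by label
   permutation; feature stability by cross-validation ratio and
   sign-based consistency with FDR control.
5. **Post-hoc statistics** — Welch group comparisons from summary
   statistics, Cohen's d, Yates-corrected chi-square, and FDR-corrected
   Pearson correlations of decision scores with ADOS-2 calibrated
   severity scores and ADI-R domains.

Because clinical videos cannot be distributed, the package ships a
**synthetic dyad generator**: coupled AR(1) latents with a configurable
lag and group-specific coupling strength, observed through a shot-noise
model that yields nonnegative motion-energy-like counts with exact zeros,
plus group-shifted clinical scores and demographics. Every pipeline stage
is exercised end to end on generated cohorts.

## Worked example

Run the numbered analysis scripts (each is a thin driver over the
library; all outputs land under `results/run/`):

```bash
python analysis/01_simulate_cohort.py      # 40 dyads, 5-min series
python analysis/02_extract_motion_energy.py
python analysis/03_compute_synchrony.py
python analysis/04_build_features.py
python analysis/05_classify.py
python analysis/06_feature_stability.py
python analysis/07_posthoc_stats.py
```

With the default seed the pseudodyad comparison and classification print:

```
real vs 500 pseudodyads (head): t = 3.15, df = 43.1, p = 0.0029, d = 0.56
feature table: 40 dyads x 25 features
confusion tn/tp/fn/fp = 9/6/14/11
BAC = 37.5%  sensitivity = 30.0%  specificity = 45.0%  AUC = 0.35
```

Read this the way a power analysis would: the real dyads are reliably
above the pseudodyad chance baseline (t = 3.15, p = .003) because the
generated administrator truly follows the participant. The classifier,
however, sees only a *weak* group contrast (coupling 0.2 vs 0.4 at
n = 40), and a single-cohort BAC estimate scatters roughly between 0.38
and 0.70 across seeds (mean ≈ 0.58) — this particular seed lands below
chance. That is the realistic operating regime of proof-of-concept
clinical classifiers; with a strong contrast (coupling 0.1 vs 0.5,
n = 80) the same pipeline reaches BAC ≈ 0.70 consistently (see the test
suite's power checks).

The stability output ranks features by |CVR|; in coupled cohorts the
body/head synchrony means and higher moments dominate, with sign-based
consistency −log10 p far above the 1.3 (p = .05) line.

The same stages are available as one CLI:

```bash
dyadsync run-all --outdir results/run --seed 11
dyadsync classify --outdir results/run --labeling ndd-cc   # relabeled variant
```

or from YAML (`dyadsync simulate --config cfg.yaml`); every stage writes a
JSON provenance sidecar (config hash, seed, package version) and reruns
byte-identically under a fixed seed.

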