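# ncreann

Linear and non-linear directed connectivity between source-level EEG time
courses, estimated with a neural-network nonlinear multivariate
autoregressive (nMVAR) model, plus the surrounding analysis stack: band
filtering and epoching, time-shifted surrogate significance testing,
source-cluster extraction from beamformer-style activity volumes, and the
group statistics layer (repeated-measures ANOVA, normality-routed paired
tests, Spearman matrices, Benjamini–Hochberg FDR).

## The method in brief

Source activity `x(n) ∈ R^M` at 256 Hz is modelled as

    x(n) = f(x_p) + σ(n),

where `x_p` stacks the `p` past samples of all `M` channels and `f` is a
single-hidden-layer perceptron (10 tanh units) trained by incremental
error back-propagation with momentum, an adaptive learning rate and early
stopping, under a permuted n-fold scheme (80/10/10 at 10 folds).  The
fitted `f` splits into a linear part — its first-order Taylor expansion at
the standardized mean — and a non-linear remainder:

- `lC_{i→j}`: mean absolute Taylor coefficient of channel *i* on output
  *j* across lags (linear directed connectivity);
- `NC_{i→j}`: mean absolute deviation of the instantaneous Jacobian from
  that Taylor coefficient across samples and lags (non-linear directed
  connectivity).

Both are unitless.  Per-edge significance comes from retraining on
time-shifted surrogates (channels independently circularly shifted) and
comparing the observed strength against the 95th percentile of its null.
Source clusters are extracted from Neural Activity Index volumes
(power/noise per voxel) by top-1% thresholding and density clustering
(eps = 1.5 × grid spacing, ≥ 5 voxels per cluster).  A synthetic-data
module generates coupled nMVAR series with known ground-truth edges,
blob-shaped activity volumes and prime–probe behavioral tables, so the
whole pipeline is testable end to end without any recordings.

See `docs/methods.md` for the full model description, parameter defaults
and design rationale.

## Worked example

Run the bundled synthetic scenario — two alpha-band regions with one true
directed edge `region0 → region1` — through the full pipeline:

```bash
ncreann run --seed 3 -o runs/demo
```

```
pipeline finished; manifest at runs/demo/manifest.json
```

The edge table `runs/demo/connectivity_alpha_post_s1.csv` then contains
(off-diagonal lC rows):

```
source  target  measure  value      significant
ch0     ch1     lC       0.347364   True
ch1     ch0     lC                  False
```

The true edge `ch0 → ch1` is significant against its 30-surrogate null
(fold-averaged lC ≈ 0.35 versus a null 95th percentile ≈ 0.25 on this
seed), the reverse edge is reported missing (non-significant), and
`clusters_alpha.json` records the two activity clusters recovered from
the synthetic NAI volume.  `behavior_stats.json` holds the 2×2
repeated-measures ANOVA of the simulated behavioral table; the
response × overlap interaction (the behavioral binding effect) is
significant with a large partial eta squared.

The same stages are available individually (`ncreann simulate / prep /
fit / connectivity / surrogates / clusters / stats`) and as library
functions:

```python
import ncreann as nc

series  = nc.simulate_nmvar(spec)                 # ground-truth nMVAR
samples = nc.build_regression_samples(series, p=5)
models, metrics = nc.fit_ncreann(samples, nc.NMVARConfig())
result  = nc.connectivity_from_fit(models, samples)   # lC and NC matrices
```

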