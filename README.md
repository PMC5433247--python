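# pcorrnet

Directed effective-connectivity estimation for multivariate ROI timeseries
via **prediction correlation** (p-correlation), with the common-driver
validation simulator, thresholding calculus, and directionality scoring.

## The problem and the method

Functional-connectivity studies of resting-state fMRI usually correlate the
BOLD timeseries of two regions of interest (ROIs). Correlation is symmetric:
it detects that two regions covary but says nothing about the direction of
information flow, and it is famously fooled by a *common driver* — when
region 1 drives regions 2 and 3, the driven pair 2–3 shows a strong spurious
correlation although they never interact.

p-correlation replaces the correlation between `x_i` and `x_j` with the
correlation between `x_j` and a *causal prediction* of `x_j` computed from
`x_i`:

```
x̂_{j|i}[n] = Σ_{m=0}^{N_h-1} h_{j|i}[m] · x_i[n-m]          (causal FIR)
J(h)       = Σ_n (x_j[n] - x̂_{j|i}[n])²                      (least squares)
ρ_{j|i}    = corr(x_j, x̂_{j|i})                              (p-correlation)
```

The filter coefficients minimize `J`, optionally under `h[m] ≥ 0`
(non-negative least squares) when interactions are known to be positive.
The filter length `N_h` — the memory duration, in samples — is chosen by
minimizing an Akaike information criterion

```
AIC = N_x log(2π J / (N_x - N_h)) + N_x + N_h     (+ AICc correction when N_x/N_h < 40)
```

over `N_h = 1..max_taps`. Because the system predicting j from i differs
from the one predicting i from j, the matrix `ρ_{j|i}` is asymmetric and
yields a directed graph; with `N_h = 1` and a nonnegative coefficient the
method reduces exactly to standard correlation.

Downstream, three thresholding operators (zero-clipping, a top-`s`-percent
sparsity threshold with `s` derived from the ground-truth *connections of
interest*, and a unidirectional projection) produce the network estimate
`d_{j|i}`, scored against a ground truth `a_{j|i}` by the directionality
accuracy `A = Σ 1{a>0}·1{d>0} / Σ 1{a>0}`.

## Worked example

Simulate the three-ROI common-driver network
`x1 → x2, x1 → x3` with weak driving (a21 = a31 = 0.1), estimate each
subject's directed network, and score it:

```sh
pcorr experiment common-driver --case 2 --n-samples 1000 --n-subjects 5 --seed 0
```

prints (abridged):

```json
{
 "case": 2,
 "s_percent": 44.44444444444444,
 "per_subject_accuracy": [1.0, 1.0, 1.0, 1.0, 1.0],
 "accuracy_mean": 1.0,
 "accuracy_std": 0.0,
 "mean_selected_taps": 2.1333333333333333,
 "mean_nonzero_rho": 0.22640251819914056
}
```

Every subject recovers both true directed connections (accuracy 1.0). The
percentile threshold retained the top 44.4% of entries — 4 COIs (both
directions of the two connected pairs) out of 3² possible connections. The
AIC chose ~2.1 taps on average: it detects the one-sample lag through which
ROI 1 drives ROIs 2 and 3, which is exactly what breaks the symmetry and
orients the edges. The mean nonzero p-correlation strength was 0.23.

The same tools are available as a library:

```python
from pcorrnet import (CommonDriverSpec, simulate_common_driver,
                      pcorr_matrix, corr_matrix)

spec = CommonDriverSpec.from_case(3, n_samples=5000, base_seed=0)  # strong driving
ts = simulate_common_driver(spec, 0)
corr_matrix(ts).values    # 2-3 entry is the largest: the common-driver confound
pcorr_matrix(ts, max_taps=3, constrained=True).values  # 2-3 pair ranks lowest
```

File-based workflows (`pcorr simulate`, `pcorr compute`, `pcorr threshold`,
`pcorr accuracy`, `pcorr average`, `pcorr pipeline-sim`, `pcorr cohort-split`)
read and write tab-delimited matrices with JSON sidecars; see `pcorr --help`.

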