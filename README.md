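# aispls

Baseline correction for Raman-type spectra by penalized least squares,
centered on **aisPLS** — an adaptive-smoothing-vector corrector with
trimmed-statistics logistic weights, a curvature discriminant for weak
broad peaks, and physically constrained non-negative output — together
with the classic correctors it is benchmarked against (AsLS, airPLS,
arPLS, asPLS), a synthetic-spectrum simulator with known ground truth,
and an RMSE benchmark harness.

## The problem

Raman spectra sit on a slowly varying background (fluorescence,
instrument response, dark current) that distorts peak heights and
areas. Baseline correction estimates this background `b` from the
measured spectrum `y` and reports the corrected signal `y - b`.

The penalized least-squares (Whittaker) family estimates the baseline
as the minimizer of

    Q(z) = Σᵢ wᵢ (yᵢ - zᵢ)² + Σₖ λₖ (Δᵈ z)ₖ²,

a weighted fidelity term plus a roughness penalty on order-`d`
differences (here `d = 2` by default). The normal equations
`(W + DᵀΛD) z = W y` are banded and solved by a banded Cholesky
factorization. The art is in the weights: they must vanish over peaks
(so the baseline passes underneath) while staying near 1 over
background.

**aisPLS** iterates the solve with three refinements over arPLS:

1. the mean `m` and deviation `σ` of the negative residuals — which
   drive the peak/background threshold `-m + 2σ` — are computed after
   one pass of 3σ outlier trimming;
2. points between 0 and the threshold get a logistic weight whose
   scale is multiplied by `q = |D²z| / |D²y|`: jagged (noise-like)
   points keep weight ≈ 1 as background anchors, while smooth
   deviations — weak broad peaks — are down-weighted;
3. each point carries its own smoothing parameter λᵢ, multiplied by an
   adaptation rate β in peak-classified regions (exponentially
   stiffening the baseline under peaks) and relaxed back toward the
   initial value λ₀ elsewhere.

After convergence the corrected spectrum is post-processed for
physical non-negativity: Raman intensities are scattering energies,
so negative points are zeroed and small non-monotone blips emerging
from a zeroed run are zeroed as well.

## Worked example

```python
import numpy as np
from aispls import simulate_dataset, aispls_correct, rmse

sim = simulate_dataset(snr_db=20, seed=42)     # 0..1600 cm^-1, known truth
result = aispls_correct(sim.composite)
print(f"points: {len(sim.grid)}, achieved SNR: {sim.achieved_snr_db():.2f} dB")
print(f"iterations: {result.n_iterations}, converged: {result.converged}")
print(f"baseline RMSE vs truth: {rmse(result.baseline, sim.baseline):.3f}")
print(f"corrected minimum: {result.corrected.min():.3f}")
print(f"points zeroed by post-processing: {int(result.zeroed.sum())}")
```

prints

```
points: 1601, achieved SNR: 20.00 dB
iterations: 200, converged: False
baseline RMSE vs truth: 6.192
corrected minimum: 0.000
points zeroed by post-processing: 676
```

The simulated spectrum is built from 14 Gaussian/Lorentzian peaks on
an analytic baseline (linear drift + slow sinusoid + broad bump) plus
white Gaussian noise scaled so the energy ratio of the noiseless
composite to the noise is exactly 20 dB. Because the true baseline is
known, the RMSE of the estimate (here ≈ 6.2 intensity units at the
noisiest setting; ≈ 2.3 at 40–60 dB) measures correction quality
directly. At 20 dB the iteration cap (T = 200) is reached before the
negative-residual criterion can fire — expected, since the noise norm
itself is 10% of the signal norm. The corrected spectrum is
non-negative everywhere; the zeroed points are noise excursions below
the baseline.

## Command line

```sh
aispls simulate --snr-db 20 --seed 1 --out spectrum.csv
aispls correct --method aispls --lam0 1e7 --in spectrum.csv --out corrected.csv
aispls benchmark --n-seeds 20 --out report.csv
```

`simulate` writes the composite spectrum with its pure/baseline/noise
decomposition and a JSON sidecar of the generating configuration;
`correct` writes `wavenumber,raw,baseline,corrected`; `benchmark`
writes the per-method, per-SNR RMSE table and prints a markdown
summary.

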