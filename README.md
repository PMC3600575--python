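# stcorr — single-trial linear correlation analysis for EEG

`stcorr` extracts EEG components whose single-trial band power is maximally
correlated with a continuous behavioral variable — typically the manual
reaction time (RT) of each trial.  It is aimed at cognitive-neuroscience
studies where no meaningful categorical trial split exists (so discriminant
single-trial methods do not apply) and the question is *which* latencies,
frequency bands, and scalp topographies carry behaviorally relevant signal.

## The method

Let x_n(t) ∈ ℝ^D be the instantaneous band power of D channels at epoch
latency t on trial n, and y_n the trial's RT.  A spatial filter w ∈ ℝ^D
projects the channels to a one-dimensional component z_n(t) = wᵀx_n(t).
The filter is chosen to maximize the Pearson correlation between the
projected component and the response across trials:

    ŵ = argmax_w  (wᵀX y) / ( sqrt(wᵀ X Xᵀ w) · ‖y‖ ),

whose closed form is ŵ ∝ R⁻¹ X y with R = X Xᵀ / N.  Two regularizers make
this practical on real EEG:

* **temporal** — the data matrix is augmented with the Δt consecutive
  samples of a short latency window, X̃ = [X^t, X^{t+1}, …], and the
  response replicated per sample (1 ⊗ y), pooling the covariance estimate
  over N·Δt columns and tying the fit to the whole window;
* **spatial** — an L2 (ridge) prior, ŵ ∝ (R + λI)⁻¹ X̃ ỹ, with λ chosen by
  nested cross-validation.

From a fitted filter the package derives the single-trial correlated
component (SCC) z_n(t), the component correlation trace (CCT)
c(t) = corr_n(z_n(t), y_n), the trials × latency component map sorted by
RT, and the forward model a = X z / (zᵀz) — the per-channel coupling of the
component, which (unlike w itself) is topographically interpretable.

The training latency τ is found by scanning 60 ms windows in 10 ms steps
across the epoch: each window's merit is the pooled k-fold cross-validated
correlation r_cv between held-out component amplitude and RT; significance
comes from a permutation null (the response is shuffled and the full
cross-validation rerun), Benjamini–Hochberg FDR controls for the multiple
windows, and τ is the significant window at the largest local maximum of
r_cv.

Band power is obtained by convolution with unit-L2-norm complex Morlet
kernels (power = |coefficient|²), collapsed over each standard band
(θ 5–7, α 8–12, β1 16–22, β2 23–30, γ 31–40 Hz) by a per-bin maximum, with
the mean over a baseline trial set subtracted.

Because real recordings of this kind are rarely shareable, the package
ships a first-class synthetic-data generator (`stcorr.synthetic`) that
plants a band-limited source with known topography, latency window, and
power–RT correlation ρ inside realistic spatially correlated 1/f noise —
every claim the package makes about itself is validated against this ground
truth.

## Worked example

```python
import numpy as np
from stcorr import (Band, ResponseVector, SyntheticSpec, WindowSpec,
                    band_power, build_augmented, forward_model, generate,
                    scan_windows, scc, solve_weights, split_train_test)

# a 32-channel dataset: alpha source at 240-300 ms, corr(power, RT) = 0.5
epochs, events, truth = generate(SyntheticSpec(seed=7))
data = band_power(epochs, Band.named("alpha"))
response = ResponseVector(events.rt_ms)

train, test = split_train_test(data, response, 0.8, seed=7)
result = scan_windows(train.data, train.response,
                      WindowSpec(0.0, 1000.0, 60.0, 10.0),
                      n_perm=200, seed=7)
tau = result.selected
i = result.windows.index(tau)
print(f"tau = {tau.start_ms:.0f}-{tau.stop_ms:.0f} ms, "
      f"r_cv = {result.r_cv[i]:.2f}, p = {result.p_values[i]:.4f}")

filt = solve_weights(build_augmented(train.data, tau, train.response),
                     float(result.lam[i]))
fm = forward_model(test.data, scc(filt, test.data))
cos = abs(fm.coupling @ truth.power_topography) / np.linalg.norm(fm.coupling)
print(f"forward-model cosine vs planted pattern = {cos:.3f}")
```

Output:

```
tau = 230-290 ms, r_cv = 0.48, p = 0.0050
forward-model cosine vs planted pattern = 0.998
```

The scan finds the planted 240–300 ms window to within one grid step, the
held-out correlation is close to the planted ρ = 0.5, and the forward model
recovers the planted channel-power pattern almost exactly.  (The pattern
compared against is the *power-space* topography — the elementwise square
of the amplitude mixing vector — because the analysis operates on band
power, where a source mixed with amplitude topography a appears with
channel-power profile a².)

A command-line interface wraps the same pipeline:

```bash
stcorr simulate --out sim/ --seed 7
stcorr scan --epochs sim/epochs.h5 --events sim/events.tsv --out scan/ \
       --band alpha --epoch 0:1000 --window 60 --step 10 --perms 1000 --seed 7
```

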