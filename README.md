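# hemexpand

Hematoma-expansion risk prediction for hemorrhagic stroke, built on a
non-stationary Gaussian volume process and a multi-scale kernel Transformer.

After an intracerebral hemorrhage, the hematoma volume `V(t)` can keep
growing during the first hours; growth beyond a clinical threshold
("hematoma expansion") predicts neurological deterioration. `hemexpand`
models the volume marginally as

    V(t) ~ N(M(t), Σ(t))

with time-varying mean `M(t)` (ml) and variance `Σ(t)` (ml²), learns the
personalized maps from a patient's hourly ICU record to `M(t)` and `Σ(t)`
with a multi-scale kernel Transformer (embedding → linear/polynomial/RBF/
Matérn Gram-matrix bank → Transformer encoder → Gaussian-process
parameterization head), and converts the predictive distribution into the
probability of crossing the expansion threshold

    c = max(v0 + 12.5 ml, 1.33 · v0),     P = 1 − exp(−Σᵢ β(tᵢ) Δt),

where `β(t) = P(V(t) ≥ c)` acts as a per-hour hazard. The package is aimed
at methods researchers in clinical time-series prediction: it ships a
seeded synthetic ICU cohort generator (long-format event tables with tiered
missingness and physiologic outliers), a split-aware cleaning pipeline
(hourly resampling, one-hot encoding, winsorization, tiered imputation),
likelihood-based training on a small NumPy autodiff core, and an
uncertainty-focused evaluation suite (interval coverage and width,
noise-robustness RNH, confusion-matrix rates, rank-based AUC). Real
credentialed ICU data is deliberately not required anywhere.

## Worked example: from a predicted volume process to an expansion risk

```python
import numpy as np
from hemexpand import (TimeGrid, VolumeProcess, expansion_threshold,
                       crossing_probability, monte_carlo_crossing)

th = expansion_threshold(18.0)                      # baseline volume 18 ml
grid = TimeGrid(t0=0.0, horizon=24.0, n_points=24)  # hourly, 24 h window
mean = 18.0 + 8.0 * (1 - np.exp(-grid.points / 12.0))  # growing hematoma
process = VolumeProcess(grid, mean, np.full(24, 9.0))  # SD 3 ml throughout

result = crossing_probability(process, th)
print(f"threshold c = {th.c:.1f} ml ({th.branch} branch)")
print(f"cumulative hazard = {result.cumulative_hazard:.4f}")
print(f"P(expansion within 24 h) = {result.probability:.4f}")
est, se = monte_carlo_crossing(process, th, n_paths=100_000, seed=0)
print(f"Monte-Carlo check: {est:.4f} +/- {se:.4f}")
```

prints

```
threshold c = 30.5 ml (absolute branch)
cumulative hazard = 0.2256
P(expansion within 24 h) = 0.2020
Monte-Carlo check: 0.2021 +/- 0.0013
```

The threshold took the absolute branch (18 + 12.5 = 30.5 ml beats
1.33 × 18 ≈ 23.9 ml). The mean path climbs toward 26 ml, so with a 3 ml
predictive SD the volume has a per-hour tail probability above 30.5 ml that
integrates to a cumulative hazard of 0.23 — a 20% expansion risk over the
day, confirmed by the independent Bernoulli-interval Monte-Carlo oracle.

In the full pipeline those mean/variance paths come from the fitted model
rather than a formula; `hemexpand.model.predict_expansion_probability`
composes the Gaussian-process head with exactly this crossing computation.

## Command line

```bash
hemexpand simulate --out runs/cohort --config config.yaml   # synthetic cohort
hemexpand train runs/cohort --out runs/fit --config config.yaml
hemexpand predict runs/cohort --checkpoint runs/fit/checkpoint.mskt --out runs/pred
hemexpand evaluate runs/cohort --checkpoint runs/fit/checkpoint.mskt \
    --out runs/eval --noise-sd 0.5    # adds the RNH robustness run
```

Every command writes its resolved configuration and seed next to its
outputs; a cohort directory can always be regenerated bitwise from its
manifest.

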