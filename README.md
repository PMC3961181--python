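# scfc — structure–function connectivity modelling testbed

`scfc` quantifies how much of resting-state functional connectivity (FC) is
explained by structural connectivity (SC) alone, how much is added when SC
is filtered through stationary generative dynamics, and what role the
homotopic interhemispheric connections play in both. It is aimed at
computational neuroscientists studying structure–function coupling in
whole-brain network models, and at anyone who needs a fully synthetic,
reproducible testbed for such analyses: every input a real study would take
from diffusion tractography and fMRI (weight matrix, fiber lengths, region
metadata, empirical FC or BOLD) is emulated by a generator with known
ground truth.

## The models

**SC as predictor.** The baseline is the Pearson correlation *r* between
the vectorized SC weights and empirical FC over a connection class
(all / direct / indirect / intra- / interhemispheric pairs); *r²* is the
variance explained. By definition SC has zero predictive power on indirect
pairs (pairs with zero weight).

**Spatial autoregressive (SAR) model.** Each region's BOLD fluctuation is a
linear mixture of the others',

    x = k C x + e,   e ~ N(0, sigma^2 I),

with `C` the spectrally normalized SC (largest eigenvalue 1) and `k < 1`
the coupling strength. The covariance is closed form,
`Sigma = sigma^2 (I − kC)^{-1} (I − kC)^{-T}`, so the model's FC is exact,
strictly stationary, and costs one matrix inverse.

**Stochastic simulators.** Delay-coupled Euler–Maruyama integrators for the
rate model (with or without conduction delays), Wilson–Cowan, Kuramoto and
FitzHugh–Nagumo systems, followed by Balloon–Windkessel hemodynamics,
global-signal regression, TR sampling and Pearson FC — the classic
simulation protocol (three 8-minute runs, FCs averaged).

**Evaluation.** Predictive power per connection class with permutation
tests (structure-preserving region-relabeling null) and paired sign-flip
tests; network partitions by Ward-criterion agglomerative clustering on
`1 − r`, compared with the adjusted Rand index; sliding-window FC and
window-length / run-duration curves; SC manipulation experiments
(homotopic addition, homotopic shuffling, random removal / addition /
permutation curves).

## Worked example: the homotopic-connection effect

Homotopic (mirror-pair, callosal) connections are systematically
underestimated by tractography. The testbed generates a ground-truth
connectome with intact homotopic links, an "empirical" FC session from it,
and an observed SC with those links fully degraded — then restores them at
the constant value 0.5 and refits the SAR model:

```python
import numpy as np
from scfc import (SyntheticConfig, make_sc, make_empirical_like_fc,
                  connection_masks, sar_fc, predictive_power_report,
                  add_homotopic, optimize_coupling)

truth = make_sc(SyntheticConfig(n_regions=60, homotopic_weight=0.5,
                                homotopic_degradation=0.0, seed=42))
observed = make_sc(SyntheticConfig(n_regions=60, homotopic_weight=0.5,
                                   homotopic_degradation=1.0, seed=42))
emp_fc, _ = make_empirical_like_fc(truth, k_true=0.6, t_samples=240,
                                   noise_sd=0.05, seed=7)
masks = connection_masks(observed)

for label, sc in [("observed SC", observed),
                  ("with homotopic links restored", add_homotopic(observed, 0.5).sc)]:
    k_opt, _ = optimize_coupling("sar", sc, emp_fc)
    report = predictive_power_report(sar_fc(sc, k_opt), emp_fc, masks)
    print(f"{label} (k* = {k_opt:.2f}):")
    for mask, r in report.r.items():
        print(f"  {mask:17s} r = {r:+.3f}  (R^2 = {r*r:.3f})")
```

prints

```
observed SC (k* = 0.15):
  all               r = +0.092  (R^2 = 0.008)
  direct            r = +0.411  (R^2 = 0.169)
  indirect          r = +0.023  (R^2 = 0.001)
  intrahemispheric  r = +0.292  (R^2 = 0.086)
  interhemispheric  r = +0.005  (R^2 = 0.000)
with homotopic links restored (k* = 0.55):
  all               r = +0.850  (R^2 = 0.722)
  direct            r = +0.419  (R^2 = 0.176)
  indirect          r = +0.872  (R^2 = 0.760)
  intrahemispheric  r = +0.308  (R^2 = 0.095)
  interhemispheric  r = +0.912  (R^2 = 0.832)
```

With the homotopic links missing, the SAR model predicts essentially
nothing interhemispheric or indirect; restoring the 30 homotopic entries
raises interhemispheric *r* from 0.005 to 0.912 and — although those pairs
carry no direct connection themselves — indirect *r* from 0.023 to 0.872.
Shuffling *which* left–right pairs carry the restored weights
(`shuffle_homotopic`) destroys the gain, so the effect is specific to the
homotopic topography, not to interhemispheric weight mass as such.

## Command line

`scfc` exposes the pipeline as subcommands over delimited-text artifacts:

```sh
scfc synthesize --n-regions 60 --seed 1 --out-dir data/
scfc manipulate --sc-dir data/ --mode add_homotopic --value 0.5 --out-dir data_h/
scfc evaluate   --sc-dir data_h/ --emp-fc data/fc_empirical.tsv --out report
scfc simulate   --sc-dir data/ --model rate --k 0.6 --out bold.tsv
scfc windowed   --sc-dir data/ --sim-bold bold.tsv --emp-bold data/bold.tsv --out win.tsv
scfc sweep      --sc-dir data/ --emp-fc data/fc_empirical.tsv --model fitzhugh_nagumo \
                --grid alpha=0.7,0.85,1.0 --grid beta=0.1,0.2 --out sweep.tsv
scfc run        --sc-dir data/ --emp-fc data/fc_empirical.tsv --out-dir results/
```

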