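# Methods

## Problem setting

The package treats a resting-state session as the output of a generative
process on a structural connectome: an N×N nonnegative symmetric weight
matrix `C` (proportion of white-matter fibers linking each region pair,
zero diagonal) together with a fiber-length matrix `L` (mm) over a
parcellation with hemisphere labels and a homotopic (mirror-pair) perfect
matching. Functional connectivity (FC) is the N×N Pearson-correlation
matrix of regional time courses. The scientific questions are (i) how much
of FC the anatomy explains directly, (ii) how much a *stationary*
generative process driven by that anatomy adds, and (iii) how specifically
the homotopic interhemispheric connections shape the answer. Every
analysis runs on synthetic connectomes with known ground truth.

## Generative models

### Spatial autoregressive (SAR) model

Each region's fluctuation is a linear mixture of the others':
`x = kCx + e` with `e ~ N(0, σ²I)`, giving
`Σ = σ² A⁻¹A⁻ᵀ`, `A = I − kC`. FC is the correlation matrix of `Σ` and is
independent of σ. `C` is first spectrally normalized (divided by its
largest eigenvalue), so stability is exactly `k < 1`; violating it raises
an error that reports the bound. The model has no temporal dynamics: it
asserts a strictly stationary FC. Two analytic consequences are used as
test oracles: the 2-region connectome with a unit edge at `k = 0.5` has
off-diagonal FC exactly 0.8, and the sample correlation of independent
draws `x = A⁻¹ε` converges to the analytic FC.

### Stochastic simulators

All simulators integrate Euler–Maruyama on a fixed grid `dt` (default
1 ms; 0.1 ms is advisable for FitzHugh–Nagumo), with independent
per-region noise of amplitude σ, spectrally normalized `C` scaled by the
coupling strength `k`, and a discarded initial transient (default 2 s).
Conduction delays are `round((L/1000)/v/dt)` grid steps for velocity `v`
(m/s); `v = ∞` disables them. Delay buffers hold the coupled state
variable; the plain rate model is delay-free by definition, its `rate_delay`
variant and the oscillator models use delays when `v` is finite.

- **Rate model** (reduced Wilson–Cowan, excitatory population only):
  `dx_i = (−x_i + k Σ_j C_ij x_j(t−τ_ij))/τ · dt + σ dW_i`, with
  τ = 20 ms. Leak and coupling share the 1/τ timescale so the stability
  bound is `k < 1`, directly comparable with the SAR bound; at `k = 0`
  each node is an Ornstein–Uhlenbeck process with stationary variance
  σ²τ/2 (used as a closed-form check). Its stationary covariance
  `(σ²τ/2)(I − kC)⁻¹` has one factor of the SAR's two, which is why it
  tracks, but never beats, the SAR prediction on SAR-generated data.
- **Kuramoto**: `dθ_i = (ω_i + k Σ_j C_ij sin(θ_j(t−τ_ij) − θ_i)) dt +
  σ dW_i`, emitted activity `sin θ_i`. Natural frequencies are
  `2π(f̄ + s·z_i + spread·linspace(−½,½))` with mean f̄ = 60 Hz, Gaussian
  scatter s = 1 Hz, and an optional deterministic `freq_spread` (Hz
  end-to-end) for controlled detuning: two oscillators lock iff
  `|Δω| ≤ 2kC₁₂`, which the tests verify on both sides of the boundary.
- **FitzHugh–Nagumo**: `dx_i = c(x_i − x_i³/3 + y_i + k Σ C_ij x_j(t−τ_ij))dt
  + σ dW_i`, `dy_i = −(x_i − α + β y_i)/c · dt`, with α = 0.85, β = 0.2,
  c = 10 — inside the oscillatory regime swept by the α×β facility.
- **Wilson–Cowan**: `τ_e dE_i = (−E_i + S(c₁E_i − c₂I_i + k Σ C_ij
  E_j(t−τ_ij) + P))dt + σ dW_i`, `τ_i dI_i = (−I_i + S(c₃E_i − c₄I_i))dt +
  σ dW_i`, logistic S, c₁…c₄ = 16, 12, 15, 3, P = 1.25,
  τ_e = τ_i = 10 ms; emitted activity E.

Divergence (non-finite state) aborts with the blow-up time. Simulations
are bit-reproducible given (seed, dt, duration).

### Hemodynamics

The Balloon–Windkessel system converts neuronal activity to BOLD per
region: vasodilatory signal `ds/dt = z − κs − γ(f−1)`, inflow `df/dt = s`,
volume `τ v̇ = f − v^{1/α}`, deoxyhemoglobin
`τ q̇ = f(1−(1−ρ)^{1/f})/ρ − v^{1/α} q/v`, from rest (0,1,1,1), with
`BOLD = V₀(k₁(1−q) + k₂(1−q/v) + k₃(1−v))`. Defaults are the canonical
resting-state set κ = 0.65 s⁻¹, γ = 0.41 s⁻¹, τ = 0.98 s, α = 0.32,
ρ = 0.34, V₀ = 0.02, k₁ = 7ρ, k₂ = 2, k₃ = 2ρ−0.2, all overridable.
Integration is explicit Euler at the input dt with v, q floored at 1e−6;
nonpositive flow aborts with diagnostics. Rest is a fixed point (zero
input gives identically zero BOLD) and the unit 1-s impulse peaks between
3 and 7 s.

Two pipeline conventions sit in front of this stage. The neural drive is
z-scored per region and scaled by `neural_gain` (default 0.1) — the
balloon model expects small zero-mean perturbations around rest, and slow
high-amplitude excursions (e.g. FitzHugh–Nagumo relaxation oscillations)
would otherwise drive the flow nonphysical; FC is insensitive to this
per-region affine rescaling. The drive is also block-averaged to
`hemo_dt` (default 10 ms) before integration, since the balloon states
evolve on ~1 s timescales. BOLD is then decimated to the scan TR
(default 2 s) by bin averaging, and the global mean series is regressed
out of each region (with an intercept; the operation is idempotent and
errors on an exactly constant global mean).

## The synthetic-data generator

`make_parcellation` draws mirror-symmetric coordinates in a brain-sized
box (left hemisphere uniform; right = x-mirror of the homotopic partner),
with the canonical ordering that pairs region i with region N−1−i.
`make_sc` builds a modular connectome: contiguous modules on the left
hemisphere mirrored to the right; edge presence Bernoulli with
intra-module density 0.6 (within a hemisphere) and background density 0.1;
log-normal weights scaled by `weight_scale` and decayed as
`exp(−d/50 mm)`; lengths = Euclidean distance × tortuosity (1.2).
Homotopic pairs are then set to `homotopic_weight × (1 − degradation)`
deterministically, so two configurations differing only in degradation
share every other entry. Weights are rescaled only if a row sum exceeds 1
(fiber-proportion semantics).

Two choices matter for the homotopic experiments and are deliberate.
Dense module wiring is *intra*-hemispheric: interhemispheric anatomy is
dominated by the homotopic links, as callosal wiring dominates real
interhemispheric tractography. And `weight_scale` defaults to 0.02, so
ordinary fiber proportions are small (≲0.03) compared with the homotopic
0.5 — on real tractography matrices a constant 0.5 is likewise among the
strongest entries. With either choice inverted, degrading homotopic links
barely moves interhemispheric predictive power and the testbed stops
emulating the phenomenon it exists to probe.

"Empirical" FC is generated from the SAR family at a known `k_true` with a
*finite* number of samples: `t_samples` columns of `A⁻¹ε` plus optional
i.i.d. observation noise, returned with the sample-correlation FC. The
finite sample matters: the sample covariance is then Wishart-distributed
around the analytic covariance with the same fluctuation a finite session
exhibits under a stationary generator (the tests check the Wishart mean
property at 200 replicates of 240 samples). Optional non-stationarity is
block-switching of the coupling strength (`n_states`, `dwell_time`,
per-state modulation factors); one state with factor 1 reproduces the
stationary path bit-for-bit at equal seed. The generator does **not**
attempt realistic weight distributions beyond log-normal × distance decay,
geometric white-matter modelling, spatially correlated noise, or
physiological confounds — so passing tests demonstrate internal
consistency of the pipeline and the *direction* of effects under a known
stationary ground truth, not quantitative agreement with any real dataset.

## SC manipulation

`add_homotopic(sc, value)` sets every homotopic pair to a constant weight
(both triangle entries); lengths for newly created edges come from
coordinates (distance × tortuosity) or, absent coordinates, the median
existing interhemispheric length. `shuffle_homotopic` replaces the
left–right matching carrying the homotopic weights by a uniformly random
perfect matching (identity included — no derangement restriction),
preserving the weight multiset. `perturb_sc` removes, adds, or permutes
`round(fraction·E)` connections, with the fraction relative to the number
of existing edges E in all three modes so the curves are comparable;
added edges draw weights from the existing weight distribution.

## Evaluation

Predictive power is Pearson r between masked FC vectors (row-major
upper-triangle pair order everywhere); SC-as-predictor on the indirect
class returns exactly 0 by definition. After homotopic addition, the
connection classes are still derived from the *original* SC, so the
effect on formerly indirect pairs is measurable. The permutation test
applies a random region relabeling to the simulated matrix before masking
(a structure-preserving null) with the add-one p-value rule; its type-I
error at nominal 0.05 calibrates to [0.03, 0.07] over 1000 null
simulations. The paired sign-flip test enumerates all 2ⁿ assignments for
n ≤ 20 (exact proportion, identity included — five all-positive
differences give one-sided p = 1/32) and samples 10⁵ flips with the
add-one rule otherwise. Multiple-testing correction across a declared
model × mask family is Bonferroni.

Partitions come from agglomerative clustering with the generalized Ward
criterion applied to the dissimilarity `d = 1 − r` (negative correlations
kept; d may exceed 1; no Euclidean embedding is assumed — the
Lance–Williams recurrence is applied to the condensed dissimilarity
directly via `scipy.cluster.hierarchy.linkage(method="ward")`).
Labels are renumbered by first appearance, making the partition
deterministic. Partition similarity is the Hubert–Arabie adjusted Rand
index (`sklearn.metrics.adjusted_rand_score`), cross-checked in the test
suite against a direct contingency-table evaluation; the worked 4-element
example {12|34} vs {13|24} gives −0.5.

## Windowed analysis

Sliding windows of length 20–420 s (step 20 s, increment 20 s) are cut at
scan resolution; each window's FC re-standardizes the series implicitly
(no session-level detrending). Windowed predictive power compares *every*
(simulated, empirical) pair of equal-length windows — never index-matched,
since the simulators cannot be phase-aligned with the data — and reports
mean (headline), sd and max. Predictors that are constant in time (SC
alone, the analytic SAR FC) have no windowed structure; their curve point
is the whole-session predictive power, replicated across lengths, hence an
exactly flat curve. The duration analysis computes FC on the first d
seconds of each of three runs, averages the FCs entrywise, and scores
against empirical FC per duration.

## Experiment protocol and problem sizes

The pipeline optimizes `k` per model on a sorted grid maximizing r over
all pairs (analytic for SAR; one shorter run — default 120 s — per grid
point with per-gridpoint seeds for the stochastic models; ties to the
smallest k), then simulates `n_runs = 3` runs of 480 s, averages the
per-run FCs entrywise (a Fisher-z averaging flag exists), and reports
predictive power per class plus the clustering ARI against the empirical
partition (10 networks, or N/2 if smaller). Per-cell seeds are derived
from a CRC of the parameter values, so grid order is irrelevant and the
whole pipeline is a pure function of (config, seeds).

The canned experiments run at desk scale: homotopic manipulation at
N = 60 over 20 seeds with 240-sample sessions; random-manipulation curves
at N = 60, 50 seeds, fractions 0–0.5; the window-length analysis at
N = 60 with 480 s sessions (21 window lengths) over 10 seeds in the test
suite and 4 in the reproduction script. GSR is left off in the windowed
experiment (both sides treated identically; the curve's direction does
not depend on it).

## Known limitations

- The SAR generator of "empirical" FC makes the SAR predictor the true
  model by construction; cross-model comparisons on this testbed measure
  fidelity to a stationary linear ground truth, not biological realism.
  A flag-level alternative is to generate with any simulator instead.
- Conductance-based neural-mass and spiking attractor models are not
  implemented; neither are finer parcellations as real data, NIfTI/DICOM
  handling, tractography, or fMRI preprocessing.
- Euler–Maruyama with delay buffers is exact on the grid but first-order;
  halving dt is the convergence check. The Wilson–Cowan sigmoid is the
  plain logistic; published variants differ in thresholds and gains.
- The exact TR, permutation scheme and correction method of the original
  protocol are unspecified in the available sources; the package's
  choices (TR 2 s, region-relabeling null, Bonferroni) are configurable
  and logged.
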