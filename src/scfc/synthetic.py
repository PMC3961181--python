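"""Synthetic connectomes and "empirical-like" functional connectivity.

Real structural connectomes (tractography fiber proportions) and empirical
resting-state FC are emulated here so that every downstream stage of the
pipeline is testable without any acquisition.  Structural matrices are
modular and hemispherically mirror-symmetric, with log-normal edge weights
decayed by inter-region distance, fiber lengths proportional to Euclidean
distance, and homotopic (mirror-pair) connections that can be degraded to
emulate how poorly diffusion tractography estimates callosal fibers.

"Empirical" FC is generated from the SAR family at a known coupling
strength with a *finite* number of samples, so the sample correlation
fluctuates around the analytic FC exactly as a Wishart-distributed sample
covariance fluctuates around its population value.  An optional
block-switching non-stationarity modulates the coupling strength over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .core import BoldTrace, FCMatrix, Parcellation, StructuralConnectome, compute_fc
from .dynamics import _sar_operator

__all__ = [
    "SyntheticConfig",
    "NonstationaritySpec",
    "make_parcellation",
    "make_sc",
    "make_empirical_like_fc",
]

# Exponential distance-decay constant for edge weights (1/mm).  Arbitrary but
# fixed: only the relative weight structure matters downstream.
DISTANCE_DECAY = 1.0 / 50.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic structural connectome generator.

    ``homotopic_weight`` is the ground-truth weight of mirror-pair
    connections (0.5 by convention, matching the value used in the
    homotopic-addition manipulation); ``homotopic_degradation`` scales it
    down by (1 - degradation), emulating tractography's systematic
    underestimation of callosal fibers. ``tortuosity`` (>= 1) converts
    Euclidean distance into fiber length.

    ``weight_scale`` sets the magnitude of ordinary (non-homotopic) edges.
    The default (0.02) keeps individual fiber proportions small — as
    tractography-derived proportions are — so the homotopic links at 0.5
    are the dominant interhemispheric anatomy, and typical row sums stay
    below 1 without rescaling.
    """

    n_regions: int = 160
    n_modules: int = 4
    intra_module_density: float = 0.6
    inter_module_density: float = 0.1
    weight_scale: float = 0.02
    homotopic_weight: float = 0.5
    homotopic_degradation: float = 0.0
    tortuosity: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 4 or self.n_regions % 2:
            raise ValueError("n_regions must be even and >= 4")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        for name in ("intra_module_density", "inter_module_density"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.homotopic_degradation <= 1.0:
            raise ValueError("homotopic_degradation must lie in [0, 1]")
        if self.homotopic_weight < 0 or self.weight_scale <= 0:
            raise ValueError("homotopic_weight >= 0 and weight_scale > 0 required")
        if self.tortuosity < 1.0:
            raise ValueError("tortuosity must be >= 1")


@dataclass(frozen=True)
class NonstationaritySpec:
    """Block-switching modulation of the generative coupling strength.

    The session is divided into blocks of ``dwell_time`` seconds; block b is
    generated at coupling k * state_modulation[b mod n_states].  With
    n_states = 1 and modulation 1 this reduces to the stationary generator.
    """

    n_states: int = 2
    dwell_time: float = 60.0
    state_modulation: tuple = (1.0, 0.5)

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if len(self.state_modulation) != self.n_states:
            raise ValueError("state_modulation must have one factor per state")
        if any(m < 0 for m in self.state_modulation):
            raise ValueError("state modulation factors must be nonnegative")


def make_parcellation(n_regions: int, seed: int = 0) -> Parcellation:
    """Mirror-symmetric parcellation with canonical homotopic ordering.

    Left-hemisphere coordinates are drawn uniformly in a brain-sized box
    (mm); each right-hemisphere region is the x-mirror of its homotopic
    partner ``n_regions - 1 - i``.
    """
    if n_regions < 4 or n_regions % 2:
        raise ValueError("n_regions must be even and >= 4")
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    left = np.column_stack([
        rng.uniform(-70.0, -5.0, size=half),
        rng.uniform(-90.0, 70.0, size=half),
        rng.uniform(-50.0, 70.0, size=half),
    ])
    coords = np.empty((n_regions, 3))
    coords[:half] = left
    coords[half:] = left[::-1] * np.array([-1.0, 1.0, 1.0])  # partner n-1-i mirrored
    return Parcellation.canonical(n_regions, coordinates=coords)


def _module_labels(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous modules on the left hemisphere, mirrored to the right."""
    half = n_regions // 2
    left = (np.arange(half) * n_modules) // half
    labels = np.empty(n_regions, dtype=int)
    labels[:half] = left
    labels[half:] = left[::-1]
    return labels


def make_sc(cfg: SyntheticConfig) -> StructuralConnectome:
    """Generate a modular, mirror-symmetric synthetic structural connectome.

    Edge presence is Bernoulli with intra/inter-module density; present
    edges get log-normal weights scaled by ``weight_scale`` and decayed
    exponentially with Euclidean distance.  Homotopic pairs are then set to
    ``homotopic_weight * (1 - homotopic_degradation)`` regardless of the
    Bernoulli draw, so two configs differing only in degradation share all
    other entries.  Weights are finally rescaled so every row sum is <= 1
    (fiber-proportion semantics); lengths are distance * tortuosity on
    present edges.
    """
    parc = make_parcellation(cfg.n_regions, cfg.seed)
    n = cfg.n_regions
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    dist = squareform(pdist(parc.coordinates))
    modules = _module_labels(n, cfg.n_modules)

    iu, ju = np.triu_indices(n, k=1)
    # Dense module wiring is intra-hemispheric; cross-hemisphere pairs get the
    # sparse background density regardless of (mirrored) module identity,
    # leaving the homotopic links as the dominant interhemispheric anatomy —
    # the callosal wiring pattern the generator emulates.
    hemi = parc.hemisphere
    same_module = (modules[iu] == modules[ju]) & (hemi[iu] == hemi[ju])
    density = np.where(same_module, cfg.intra_module_density, cfg.inter_module_density)
    present = rng.random(iu.size) < density
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=iu.size)
    w_pairs = np.where(present, raw, 0.0) * cfg.weight_scale \
        * np.exp(-DISTANCE_DECAY * dist[iu, ju])

    weights = np.zeros((n, n))
    weights[iu, ju] = w_pairs
    weights += weights.T

    # Homotopic overwrite is deterministic: no RNG consumption depends on it.
    h = cfg.homotopic_weight * (1.0 - cfg.homotopic_degradation)
    pairs = parc.homotopic_pairs()
    weights[pairs[:, 0], pairs[:, 1]] = h
    weights[pairs[:, 1], pairs[:, 0]] = h

    row_max = weights.sum(axis=1).max()
    if row_max > 1.0:
        weights = weights / row_max

    lengths = np.where(weights > 0, dist * cfg.tortuosity, 0.0)
    np.fill_diagonal(lengths, 0.0)
    return StructuralConnectome(parcellation=parc, weights=weights, lengths=lengths)


def make_empirical_like_fc(
    sc: StructuralConnectome,
    k_true: float,
    t_samples: int,
    noise_sd: float = 0.0,
    nonstat: Optional[NonstationaritySpec] = None,
    seed: int = 0,
    tr: float = 2.0,
) -> tuple[FCMatrix, BoldTrace]:
    """Finite-sample "empirical" FC from the SAR generative model.

    Draws ``t_samples`` independent samples x = (I - k C)^{-1} eps (blockwise
    state-modulated coupling when ``nonstat`` is given, dwell time converted
    to samples at TR), adds i.i.d. observation noise of sd ``noise_sd``, and
    returns the sample-correlation FC together with the sample trace.  With
    a finite t_samples the sample covariance is Wishart-distributed around
    the analytic SAR covariance, which is precisely the fluctuation a real
    finite-length session exhibits under a stationary generator.
    """
    n = sc.n_regions
    if t_samples < n + 2:
        raise ValueError(f"t_samples must be >= n_regions + 2 = {n + 2}")
    rng = np.random.default_rng(seed)

    if nonstat is None:
        k_blocks = [(k_true, t_samples)]
    else:
        dwell = max(1, int(round(nonstat.dwell_time / tr)))
        k_blocks = []
        t = 0
        b = 0
        while t < t_samples:
            m = min(dwell, t_samples - t)
            k_blocks.append((k_true * nonstat.state_modulation[b % nonstat.n_states], m))
            t += m
            b += 1

    # Noise is drawn in one block so a single-state NonstationaritySpec with
    # modulation 1 reproduces the stationary path bit-for-bit at equal seed.
    eps = rng.standard_normal((n, t_samples))
    solves: dict[float, np.ndarray] = {}
    x = np.empty_like(eps)
    t0 = 0
    for k_eff, m in k_blocks:
        if k_eff not in solves:
            solves[k_eff] = np.linalg.inv(_sar_operator(sc, k_eff))
        x[:, t0:t0 + m] = solves[k_eff] @ eps[:, t0:t0 + m]
        t0 += m
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    trace = BoldTrace(values=x, sampling_interval=tr)
    return compute_fc(trace), trace
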