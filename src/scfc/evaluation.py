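"""Model performance: predictive power, permutation tests, network partitions.

Predictive power is the Pearson correlation between simulated and empirical
FC over a chosen connection class; its square is the variance explained.
Partitions of the regions into functional networks are obtained by
agglomerative hierarchical clustering with the generalized Ward criterion
on the dissimilarity d = 1 - r, and compared with the chance-corrected
adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score

from .core import ConnectionMask, FCMatrix, StructuralConnectome, vectorize

__all__ = [
    "PredictivePowerReport",
    "Partition",
    "predictive_power",
    "predictive_power_report",
    "permutation_test",
    "paired_permutation_test",
    "cluster_fc",
    "adjusted_rand",
    "bonferroni",
]


@dataclass(frozen=True)
class Partition:
    """Per-region cluster labels, 1..K with every cluster non-empty."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        uniq = np.unique(lab)
        if lab.ndim != 1 or uniq.size == 0:
            raise ValueError("labels must be a non-empty 1-d integer array")
        if not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("labels must be 1..K with every cluster non-empty")
        object.__setattr__(self, "labels", lab)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    @property
    def n_elements(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class PredictivePowerReport:
    """Pearson r of simulated vs empirical FC per connection class."""

    r: dict[str, float]
    n_pairs: dict[str, int]

    @property
    def variance_explained(self) -> dict[str, float]:
        return {k: v ** 2 for k, v in self.r.items()}


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ValueError("empirical FC vector is constant on this mask")
    if na == 0:
        raise ValueError("simulated FC vector is constant on this mask")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def predictive_power(sim, emp: FCMatrix, mask: ConnectionMask) -> float:
    """Pearson r between masked simulated and empirical FC vectors.

    The predictor may be an FC matrix or the structural connectome itself
    (SC-as-predictor).  By definition SC has zero predictive power on the
    indirect class (its masked vector is identically zero there), so that
    case returns exactly 0.
    """
    if isinstance(sim, StructuralConnectome) and mask.label == "indirect":
        return 0.0
    if mask.n_pairs < 3:
        raise ValueError("mask must contain at least 3 pairs")
    return _pearson(vectorize(sim, mask), vectorize(emp, mask))


def predictive_power_report(sim, emp: FCMatrix,
                            masks: dict[str, ConnectionMask]) -> PredictivePowerReport:
    order = ["all", "direct", "indirect", "intrahemispheric", "interhemispheric"]
    r = {}
    n_pairs = {}
    for name in order:
        if name not in masks:
            continue
        r[name] = predictive_power(sim, emp, masks[name])
        n_pairs[name] = masks[name].n_pairs
    return PredictivePowerReport(r=r, n_pairs=n_pairs)


def permutation_test(sim: FCMatrix, emp: FCMatrix, mask: ConnectionMask,
                     n_perm: int = 1000, seed: int = 0) -> float:
    """One-sided permutation test of predictive power against a
    structure-preserving null.

    The null is built by applying a random region relabeling to the
    simulated matrix before masking and correlating, which preserves the
    simulated matrix's value distribution and symmetry while destroying its
    alignment with the empirical matrix.  p = (1 + #{r_null >= r_obs}) /
    (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    n = mask.n_regions
    emp_vec = vectorize(emp, mask)
    obs = _pearson(vectorize(sim, mask), emp_vec)
    rng = np.random.default_rng(seed)
    sim_m = sim.values if isinstance(sim, FCMatrix) else np.asarray(sim, dtype=float)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        null_m = sim_m[np.ix_(p, p)]
        r_null = _pearson(vectorize(null_m, mask), emp_vec)
        if r_null >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def paired_permutation_test(pp_model_a: np.ndarray, pp_model_b: np.ndarray,
                            alternative: str = "two-sided",
                            n_samples: int = 100_000, seed: int = 0) -> float:
    """Sign-flip test on per-subject predictive-power differences.

    The statistic is the mean difference.  For n <= 20 all 2^n sign
    assignments are enumerated and the p-value is the exact proportion of
    flips at least as extreme as the observed statistic (the identity flip
    included); for larger n, ``n_samples`` random flips are drawn and the
    add-one rule applied.
    """
    a = np.asarray(pp_model_a, dtype=float)
    b = np.asarray(pp_model_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    n = a.size
    if n < 5:
        raise ValueError("need at least 5 paired values")
    d = a - b
    obs = d.mean()
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative '{alternative}'")

    def extreme(stat):
        if alternative == "greater":
            return stat >= obs - 1e-15
        if alternative == "less":
            return stat <= obs + 1e-15
        return np.abs(stat) >= np.abs(obs) - 1e-15

    if n <= 20:
        count = 0
        total = 2 ** n
        # enumerate sign patterns in chunks to bound memory
        chunk = 1 << 14
        for start in range(0, total, chunk):
            idx = np.arange(start, min(start + chunk, total))[:, None]
            signs = 1.0 - 2.0 * ((idx >> np.arange(n)) & 1)
            stats = signs @ d / n
            count += int(np.count_nonzero(extreme(stats)))
        return count / total
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_samples, n))
    stats = signs @ d / n
    count = int(np.count_nonzero(extreme(stats)))
    return (1 + count) / (n_samples + 1)


def cluster_fc(fc: FCMatrix, k_clusters: int) -> Partition:
    """Agglomerative clustering of regions with the generalized Ward criterion.

    The dissimilarity is d = 1 - r (negative correlations kept as-is, so d
    may exceed 1); the Ward recurrence is applied directly to this
    dissimilarity without requiring a Euclidean embedding.  Deterministic
    given the FC matrix; labels are renumbered 1..K by first appearance.
    """
    n = fc.n_regions
    if not 2 <= k_clusters <= n:
        raise ValueError(f"k_clusters must lie in 2..{n}")
    iu, ju = np.triu_indices(n, k=1)
    d = 1.0 - fc.values[iu, ju]
    z = linkage(d, method="ward")
    raw = fcluster(z, t=k_clusters, criterion="maxclust")
    # renumber by first appearance for a stable labeling
    mapping: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels[i] = mapping[lab]
    part = Partition(labels=labels)
    if part.n_clusters != k_clusters:
        raise RuntimeError(f"requested {k_clusters} clusters, obtained {part.n_clusters}")
    return part


def adjusted_rand(p1: Partition, p2: Partition) -> float:
    """Hubert-Arabie adjusted Rand index between two region partitions.

    1 for identical partitions (up to relabeling), approximately 0 for
    independent random partitions.
    """
    if p1.n_elements != p2.n_elements:
        raise ValueError("partitions must cover the same region set")
    return float(adjusted_rand_score(p1.labels, p2.labels))


def bonferroni(p_values: dict[str, float]) -> dict[str, float]:
    """Bonferroni correction across a declared family of tests."""
    m = len(p_values)
    return {k: min(1.0, v * m) for k, v in p_values.items()}
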