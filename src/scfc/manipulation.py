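"""Structural-connectome editing experiments.

Three manipulations probe how specific anatomical features shape simulated
FC: setting every homotopic (mirror-pair interhemispheric) connection to a
constant weight, randomly re-wiring which left-right region pairs carry the
homotopic weights, and random removal / addition / permutation of a given
fraction of connections.  All edits preserve symmetry and return an edit
log alongside the edited connectome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .core import StructuralConnectome

__all__ = ["ManipulationResult", "add_homotopic", "shuffle_homotopic", "perturb_sc"]


@dataclass(frozen=True)
class ManipulationResult:
    sc: StructuralConnectome
    log: dict


def _fill_length(sc: StructuralConnectome, i: int, j: int,
                 dist: np.ndarray | None, inter_median: float,
                 tortuosity: float) -> float:
    """Length for a newly created edge: distance-derived if coordinates
    exist, else the median existing interhemispheric length."""
    if dist is not None:
        return float(dist[i, j]) * tortuosity
    return inter_median


def _inter_median_length(sc: StructuralConnectome) -> float:
    hemi = sc.parcellation.hemisphere
    iu, ju = np.triu_indices(sc.n_regions, k=1)
    inter = (hemi[iu] != hemi[ju]) & (sc.weights[iu, ju] > 0)
    vals = sc.lengths[iu, ju][inter]
    if vals.size == 0:
        vals = sc.lengths[sc.lengths > 0]
    return float(np.median(vals)) if vals.size else 50.0


def add_homotopic(sc: StructuralConnectome, value: float,
                  tortuosity: float = 1.0) -> ManipulationResult:
    """Set every homotopic pair's weight to a constant value.

    Lengths for newly created edges come from inter-region Euclidean
    distance (times ``tortuosity``) when coordinates are available, else
    the median existing interhemispheric length.  ``value = 0`` turns the
    homotopic pairs into indirect connections.
    """
    if value < 0:
        raise ValueError("homotopic weight must be nonnegative")
    w = sc.weights.copy()
    ln = sc.lengths.copy()
    coords = sc.parcellation.coordinates
    dist = squareform(pdist(coords)) if coords is not None else None
    inter_median = _inter_median_length(sc)
    n_changed = 0
    for i, j in sc.parcellation.homotopic_pairs():
        if w[i, j] != value:
            n_changed += 1
        w[i, j] = w[j, i] = value
        if value > 0 and ln[i, j] == 0:
            ln[i, j] = ln[j, i] = _fill_length(sc, i, j, dist, inter_median, tortuosity)
        elif value == 0:
            ln[i, j] = ln[j, i] = 0.0
    edited = sc.replace(weights=w, lengths=ln)
    return ManipulationResult(sc=edited, log={
        "mode": "add_homotopic", "value": value, "n_changed": n_changed})


def shuffle_homotopic(sc: StructuralConnectome, seed: int) -> ManipulationResult:
    """Re-wire the homotopic weights onto a random left-right perfect matching.

    The multiset of homotopic weights is preserved, but which region in the
    opposite hemisphere each region connects to is drawn uniformly over all
    perfect matchings (the identity included).  All other entries are
    untouched, except where a new edge lands on an existing one, whose
    weight is overwritten.
    """
    pairs = sc.parcellation.homotopic_pairs()
    weights_on_pairs = sc.weights[pairs[:, 0], pairs[:, 1]]
    if not np.any(weights_on_pairs > 0):
        raise ValueError("no homotopic weights present; run add_homotopic first")
    rng = np.random.default_rng(seed)
    w = sc.weights.copy()
    ln = sc.lengths.copy()
    left = pairs[:, 0]
    right = pairs[:, 1]
    # Remove the current homotopic edges, then lay the same weights on a
    # random matching left[i] -- right[perm[i]].
    w[left, right] = w[right, left] = 0.0
    ln[left, right] = ln[right, left] = 0.0
    perm = rng.permutation(len(right))
    coords = sc.parcellation.coordinates
    dist = squareform(pdist(coords)) if coords is not None else None
    inter_median = _inter_median_length(sc)
    orig_len = sc.lengths[left, right]
    for idx, (a, wt, b) in enumerate(zip(left, weights_on_pairs, right[perm])):
        if wt > 0:
            w[a, b] = w[b, a] = wt
            if b == right[idx]:  # edge lands back on its original position
                ln[a, b] = ln[b, a] = orig_len[idx]
            else:
                ln[a, b] = ln[b, a] = _fill_length(sc, a, b, dist, inter_median, 1.0)
    edited = sc.replace(weights=w, lengths=ln)
    identity = bool(np.all(perm == np.arange(len(perm))))
    return ManipulationResult(sc=edited, log={
        "mode": "shuffle_homotopic", "seed": seed,
        "n_changed": 0 if identity else int(len(perm))})


def perturb_sc(sc: StructuralConnectome, mode: str, fraction: float,
               seed: int) -> ManipulationResult:
    """Randomly remove, add, or permute a fraction of structural connections.

    The fraction is relative to the number of existing edges E in all three
    modes.  ``remove`` zeroes round(fraction*E) uniformly chosen existing
    edges; ``add`` gives round(fraction*E) absent pairs weights resampled
    from the existing weight distribution (and plausible lengths);
    ``permute`` randomly reassigns round(fraction*E) existing edge weights
    among their positions.
    """
    if mode not in ("remove", "add", "permute"):
        raise ValueError(f"unknown perturbation mode '{mode}'")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = sc.n_regions
    iu, ju = np.triu_indices(n, k=1)
    pair_w = sc.weights[iu, ju]
    existing = np.flatnonzero(pair_w > 0)
    absent = np.flatnonzero(pair_w == 0)
    n_edit = int(round(fraction * existing.size))
    w = sc.weights.copy()
    ln = sc.lengths.copy()

    if n_edit > 0:
        if mode == "remove":
            chosen = rng.choice(existing, size=n_edit, replace=False)
            w[iu[chosen], ju[chosen]] = w[ju[chosen], iu[chosen]] = 0.0
            ln[iu[chosen], ju[chosen]] = ln[ju[chosen], iu[chosen]] = 0.0
        elif mode == "add":
            if n_edit > absent.size:
                raise ValueError("not enough absent pairs to add connections")
            chosen = rng.choice(absent, size=n_edit, replace=False)
            new_w = rng.choice(pair_w[existing], size=n_edit, replace=True)
            coords = sc.parcellation.coordinates
            dist = squareform(pdist(coords)) if coords is not None else None
            inter_median = _inter_median_length(sc)
            for idx, wt in zip(chosen, new_w):
                a, b = iu[idx], ju[idx]
                w[a, b] = w[b, a] = wt
                ln[a, b] = ln[b, a] = _fill_length(sc, a, b, dist, inter_median, 1.0)
        else:  # permute
            chosen = rng.choice(existing, size=n_edit, replace=False)
            shuffled = chosen[rng.permutation(n_edit)]
            vals = sc.weights[iu[chosen], ju[chosen]]
            w[iu[shuffled], ju[shuffled]] = vals
            w[ju[shuffled], iu[shuffled]] = vals

    edited = sc.replace(weights=w, lengths=ln)
    return ManipulationResult(sc=edited, log={
        "mode": mode, "fraction": fraction, "seed": seed, "n_changed": n_edit})
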