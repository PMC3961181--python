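"""Core data structures for structure-function connectome analysis.

The common currency of the package is a small set of containers: a
:class:`Parcellation` (regions, hemispheres and homotopic pairing), a
:class:`StructuralConnectome` (fiber-proportion weight matrix ``C`` and
fiber-length matrix ``L`` in mm), region-by-time activity traces at
simulation resolution (:class:`NeuralTrace`) or scan resolution
(:class:`BoldTrace`), and the :class:`FCMatrix` of Pearson correlations
between regional time courses.

Pair ordering convention used by *every* module: unordered region pairs are
flattened in row-major upper-triangle order (``np.triu_indices(n, 1)``),
0-based internally, 1-based in file headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "Parcellation",
    "StructuralConnectome",
    "FCMatrix",
    "BoldTrace",
    "NeuralTrace",
    "ConnectionMask",
    "connection_masks",
    "compute_fc",
    "global_signal_regression",
    "vectorize",
    "pair_indices",
]

LEFT = "L"
RIGHT = "R"


def pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle pair indices — the canonical flattening."""
    return np.triu_indices(n, k=1)


@dataclass(frozen=True)
class Parcellation:
    """A brain parcellation with hemisphere labels and homotopic pairing.

    ``homotopic_partner`` must be an involution without fixed points whose
    partners lie in opposite hemispheres (a perfect matching between the two
    hemispheres).  The canonical symmetric ordering pairs region ``i`` with
    region ``n - 1 - i`` (0-based), mirroring how homologous regions are
    arranged symmetrically with respect to the center of a connectivity
    matrix.
    """

    hemisphere: np.ndarray
    homotopic_partner: np.ndarray
    coordinates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        hemi = np.asarray(self.hemisphere, dtype=object)
        partner = np.asarray(self.homotopic_partner, dtype=np.intp)
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "homotopic_partner", partner)
        n = hemi.size
        if n < 2 or n % 2:
            raise ValueError(f"n_regions must be even and >= 2, got {n}")
        if partner.shape != (n,):
            raise ValueError("homotopic_partner must have one entry per region")
        if not set(np.unique(hemi)) <= {LEFT, RIGHT}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        if (hemi == LEFT).sum() != n // 2:
            raise ValueError("each hemisphere must contain exactly n/2 regions")
        idx = np.arange(n)
        if np.any(partner[partner] != idx):
            raise ValueError("homotopic_partner must be an involution")
        if np.any(partner == idx):
            raise ValueError("homotopic pairing cannot have fixed points")
        if np.any(hemi[partner] == hemi):
            raise ValueError("homotopic partners must lie in opposite hemispheres")
        if self.coordinates is not None:
            coords = np.asarray(self.coordinates, dtype=float)
            if coords.shape != (n, 3):
                raise ValueError("coordinates must be (n_regions, 3)")
            object.__setattr__(self, "coordinates", coords)

    @property
    def n_regions(self) -> int:
        return self.hemisphere.size

    @classmethod
    def canonical(cls, n_regions: int, coordinates: Optional[np.ndarray] = None) -> "Parcellation":
        """Canonical symmetric ordering: region i is homotopic to n-1-i."""
        if n_regions < 2 or n_regions % 2:
            raise ValueError(f"n_regions must be even and >= 2, got {n_regions}")
        half = n_regions // 2
        hemi = np.array([LEFT] * half + [RIGHT] * half, dtype=object)
        partner = n_regions - 1 - np.arange(n_regions)
        return cls(hemisphere=hemi, homotopic_partner=partner, coordinates=coordinates)

    def homotopic_pairs(self) -> np.ndarray:
        """The n/2 unordered homotopic pairs as an (n/2, 2) array, i < j."""
        idx = np.arange(self.n_regions)
        i = np.minimum(idx, self.homotopic_partner)
        j = np.maximum(idx, self.homotopic_partner)
        pairs = np.unique(np.column_stack([i, j]), axis=0)
        return pairs


@dataclass(frozen=True)
class StructuralConnectome:
    """Weights ``C`` (fiber proportion, unitless) and lengths ``L`` (mm)."""

    parcellation: Parcellation
    weights: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        n = self.parcellation.n_regions
        w = np.asarray(self.weights, dtype=float)
        ln = np.asarray(self.lengths, dtype=float)
        for name, m in (("weights", w), ("lengths", ln)):
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {m.shape}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} must have a zero diagonal")
            if np.any(m < 0):
                raise ValueError(f"{name} must be nonnegative")
        if np.any((w > 0) & (ln <= 0)):
            raise ValueError("lengths must be positive wherever weights are positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "lengths", ln)

    @property
    def n_regions(self) -> int:
        return self.parcellation.n_regions

    def replace(self, weights: np.ndarray, lengths: Optional[np.ndarray] = None) -> "StructuralConnectome":
        return StructuralConnectome(
            parcellation=self.parcellation,
            weights=weights,
            lengths=self.lengths if lengths is None else lengths,
        )


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric Pearson-correlation matrix with unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("FC matrix must have a unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BoldTrace:
    """Region x time BOLD activity sampled every ``sampling_interval`` s (TR)."""

    values: np.ndarray
    sampling_interval: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] < 2:
            raise ValueError("trace must be region x time with at least 2 time points")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.sampling_interval


@dataclass(frozen=True)
class NeuralTrace:
    """Region x time neuronal activity at the simulation step ``dt`` (s)."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("trace must be region x time")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ConnectionMask:
    """Boolean indicator over the N(N-1)/2 unordered off-diagonal pairs.

    ``label`` names the connection class: all, direct, indirect,
    intrahemispheric, interhemispheric or homotopic.
    """

    label: str
    pair_mask: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        m = np.asarray(self.pair_mask, dtype=bool)
        n_pairs = self.n_regions * (self.n_regions - 1) // 2
        if m.shape != (n_pairs,):
            raise ValueError(f"pair_mask must have {n_pairs} entries")
        object.__setattr__(self, "pair_mask", m)

    @property
    def n_pairs(self) -> int:
        return int(self.pair_mask.sum())


def connection_masks(sc: StructuralConnectome) -> dict[str, ConnectionMask]:
    """Connection-class masks for a structural connectome.

    ``direct`` are pairs with nonzero SC weight, ``indirect`` pairs with zero
    weight; intra/interhemispheric split by hemisphere co-membership, and
    ``homotopic`` is the n/2 interhemispheric partner pairs.  direct/indirect
    and intra/inter each partition ``all``; homotopic is a subset of inter.
    """
    n = sc.n_regions
    iu, ju = pair_indices(n)
    hemi = sc.parcellation.hemisphere
    partner = sc.parcellation.homotopic_partner
    w = sc.weights[iu, ju]
    direct = w > 0
    same_hemi = hemi[iu] == hemi[ju]
    homotopic = partner[iu] == ju
    full = np.ones_like(direct)
    return {
        "all": ConnectionMask("all", full, n),
        "direct": ConnectionMask("direct", direct, n),
        "indirect": ConnectionMask("indirect", ~direct, n),
        "intrahemispheric": ConnectionMask("intrahemispheric", same_hemi, n),
        "interhemispheric": ConnectionMask("interhemispheric", ~same_hemi, n),
        "homotopic": ConnectionMask("homotopic", homotopic, n),
    }


def global_signal_regression(trace: BoldTrace) -> BoldTrace:
    """Regress the across-region mean series out of each region's series.

    The regression includes an intercept, so the operation is well defined on
    raw (non-demeaned) simulated BOLD.  Residuals are orthogonal to the
    global mean series and the operation is idempotent.
    """
    x = trace.values
    g = x.mean(axis=0)
    # Only an exactly constant global mean is degenerate; a numerically tiny
    # residual mean (as after a previous GSR pass) still regresses cleanly,
    # which keeps the operation idempotent.
    if np.ptp(g) == 0.0:
        raise ValueError("global mean series is constant; GSR regressor is degenerate")
    design = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    resid = x.T - design @ beta
    return BoldTrace(values=resid.T, sampling_interval=trace.sampling_interval)


def compute_fc(trace: BoldTrace, apply_gsr: bool = False) -> FCMatrix:
    """Pairwise Pearson correlation of regional time courses.

    The diagonal is forced to exactly 1 and the matrix symmetrized to absorb
    floating-point drift.  Constant series are an error (undefined
    correlation), never silent NaN propagation.
    """
    if trace.n_samples < 3:
        raise ValueError("need at least 3 time points to estimate correlations")
    if apply_gsr:
        trace = global_signal_regression(trace)
    x = trace.values
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd < 1e-14 * max(1.0, np.abs(x).max()))
    if bad.size:
        raise ValueError(f"constant time series for region(s) {bad.tolist()}: correlation undefined")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(values=r)


def vectorize(fc, mask: ConnectionMask) -> np.ndarray:
    """Masked upper-triangle values in the canonical row-major pair order.

    Accepts an :class:`FCMatrix`, a :class:`StructuralConnectome` (its weight
    matrix) or a plain square array.
    """
    if isinstance(fc, FCMatrix):
        m = fc.values
    elif isinstance(fc, StructuralConnectome):
        m = fc.weights
    else:
        m = np.asarray(fc, dtype=float)
    n = mask.n_regions
    if m.shape != (n, n):
        raise ValueError(f"matrix shape {m.shape} does not match mask on {n} regions")
    if mask.n_pairs == 0:
        raise ValueError("empty connection mask")
    iu, ju = pair_indices(n)
    return m[iu, ju][mask.pair_mask]
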