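"""Balloon-Windkessel hemodynamic model: neuronal activity to BOLD.

Each region is converted independently through the four-state nonlinear ODE
system (vasodilatory signal s, inflow f, blood volume v, deoxyhemoglobin q)

    ds/dt = z - kappa*s - gamma*(f - 1)
    df/dt = s
    tau * dv/dt = f - v^(1/alpha)
    tau * dq/dt = f * (1 - (1 - rho)^(1/f)) / rho - v^(1/alpha) * q / v

integrated from the resting fixed point (s, f, v, q) = (0, 1, 1, 1), with
BOLD = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)).  Explicit Euler at
the neural time step is adequate at millisecond resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoldTrace, NeuralTrace

__all__ = ["HemodynamicParams", "balloon_windkessel", "downsample"]

_RHO_DEFAULT = 0.34


@dataclass(frozen=True)
class HemodynamicParams:
    """Balloon-Windkessel parameters (canonical resting defaults).

    kappa: vasodilatory signal decay rate (1/s); gamma: flow-dependent
    elimination (1/s); tau: hemodynamic transit time (s); alpha: Grubb's
    vessel stiffness exponent; rho: resting oxygen extraction fraction;
    v0: resting blood-volume fraction; k1..k3: BOLD output weights
    (k1 = 7*rho, k2 = 2, k3 = 2*rho - 0.2 at 1.5 T conventions).
    """

    kappa: float = 0.65
    gamma: float = 0.41
    tau: float = 0.98
    alpha: float = 0.32
    rho: float = _RHO_DEFAULT
    v0: float = 0.02
    k1: float = 7.0 * _RHO_DEFAULT
    k2: float = 2.0
    k3: float = 2.0 * _RHO_DEFAULT - 0.2

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "rho", "v0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def balloon_windkessel(neural: NeuralTrace,
                       params: HemodynamicParams = HemodynamicParams()) -> BoldTrace:
    """Integrate the Balloon-Windkessel system per region at the neural dt.

    Raises :class:`FloatingPointError` with the failure time if flow or
    volume become nonpositive (numerical failure); v and q are floored at
    1e-6 to keep the divisions defined near that boundary.
    """
    z = neural.values
    n, t_len = z.shape
    dt = neural.dt
    inv_alpha = 1.0 / params.alpha

    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    bold = np.empty_like(z)
    floor = 1e-6

    for t in range(t_len):
        zt = z[:, t]
        fv = v ** inv_alpha  # outflow
        extraction = (1.0 - (1.0 - params.rho) ** (1.0 / f)) / params.rho
        ds = zt - params.kappa * s - params.gamma * (f - 1.0)
        df = s
        dv = (f - fv) / params.tau
        dq = (f * extraction - fv * q / v) / params.tau
        s = s + dt * ds
        f = f + dt * df
        v = np.maximum(v + dt * dv, floor)
        q = np.maximum(q + dt * dq, floor)
        if not np.all(np.isfinite(s)) or np.any(f <= 0.0):
            raise FloatingPointError(
                f"Balloon-Windkessel integration failed at t = {t * dt:.3f} s "
                f"(min f = {f.min():.3g}, min v = {v.min():.3g})")
        bold[:, t] = params.v0 * (params.k1 * (1.0 - q)
                                  + params.k2 * (1.0 - q / v)
                                  + params.k3 * (1.0 - v))
    return BoldTrace(values=bold, sampling_interval=dt)


def downsample(trace: BoldTrace, tr: float) -> BoldTrace:
    """Decimate to scan resolution by averaging consecutive TR-length bins."""
    dt = trace.sampling_interval
    if tr < dt - 1e-12:
        raise ValueError(f"TR ({tr}) must be at least the sampling interval ({dt})")
    m = int(round(tr / dt))
    if abs(m * dt - tr) > 1e-9 * tr:
        raise ValueError("TR must be an integer multiple of the sampling interval")
    if m == 1:
        return BoldTrace(values=trace.values.copy(), sampling_interval=tr)
    t_len = (trace.n_samples // m) * m
    binned = trace.values[:, :t_len].reshape(trace.n_regions, -1, m).mean(axis=2)
    return BoldTrace(values=binned, sampling_interval=tr)
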