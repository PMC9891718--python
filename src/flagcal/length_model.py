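"""Ion-current model of flagellar length control.

The model closes a negative feedback loop through four relations:

1. Flagellar Ca²⁺ at the base is proportional to length, ``Ca = α·L``
   (length-proportional influx through uniformly distributed channels).
2. The calcium-dependent kinase CDPK1 equilibrates fast, so its active
   fraction follows a saturable binding curve,
   ``F = αL / (αL + K_D)``.
3. CDPK1 phosphorylates the IFT kinesin (and phosphatases reverse it) on a
   fast timescale, so the phosphorylated kinesin fraction is the
   Michaelis-Menten quasi-steady-state ``F / (F + K_M)``; the fraction of
   kinesin competent to enter the flagellum is the complement
   ``K = 1 − F / (F + K_M)``.
4. Assembly is carried by active kinesins loaded with unsaturated precursor
   from a shared pool feeding both flagella, while disassembly proceeds at
   a constant rate:  ``dL/dt = A·K·(P − 2L) − D``.

Lengthening raises Ca²⁺, which activates CDPK1, phosphorylates kinesin and
throttles IFT injection — a length sensor.  Integration is forward Euler
with a 0.02 s step, with states stored every 50 steps (1 s of simulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LengthModelParams",
    "LengthState",
    "LengthTrajectory",
    "phospho_state",
    "net_growth_rate",
    "simulate",
    "steady_state",
]


@dataclass(frozen=True)
class LengthModelParams:
    """Parameters of the length-control model.

    Attributes
    ----------
    alpha
        Ca²⁺ concentration per unit length (concentration·µm⁻¹).  ``alpha=0``
        switches the feedback off and makes the model a linear ODE, which is
        used as the analytic reference case.
    K_D
        Dissociation constant of Ca²⁺ binding by CDPK1, in the same
        concentration units as ``alpha·L``.
    K_M
        Michaelis constant of the CDPK1–kinesin interaction (dimensionless,
        expressed relative to the active-CDPK1 fraction).
    A
        Assembly proportionality constant (µm·s⁻¹ per µm of available
        precursor); also absorbs the size of the kinesin pool.
    P
        Total precursor (tubulin) pool in µm-equivalents, shared by the two
        flagella; the available pool at length L is ``P − 2L``.
    D
        Constant disassembly rate (µm/s).
    L0
        Initial length of each flagellum (µm).
    dt
        Euler timestep in seconds.
    record_every
        Number of Euler steps between stored outputs; the recording interval
        is ``dt·record_every`` seconds.

    The defaults are illustrative, not fitted: they give a stable set-point
    near 12 µm and regeneration from zero on the scale of tens of minutes,
    matching the qualitative behaviour of wild-type flagella.
    """

    alpha: float = 1.0
    K_D: float = 10.0
    K_M: float = 0.48
    A: float = 4.0e-4
    P: float = 40.0
    D: float = 3.0e-3
    L0: float = 0.0
    dt: float = 0.02
    record_every: int = 50

    def __post_init__(self) -> None:
        for name in ("K_D", "K_M", "A", "P", "D", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.L0 < 0:
            raise ValueError("L0 must be non-negative")
        if self.record_every < 1:
            raise ValueError("record_every must be at least 1")


@dataclass(frozen=True)
class LengthState:
    """Model state at one time point."""

    t: float
    L: float
    F: float
    K: float

    @property
    def phospho_ratio(self) -> float:
        return 1.0 - self.K


@dataclass
class LengthTrajectory:
    """Recorded time series of a simulation run."""

    params: LengthModelParams
    t: np.ndarray
    L: np.ndarray
    F: np.ndarray
    K: np.ndarray
    amputations: list = field(default_factory=list)

    @property
    def phospho_ratio(self) -> np.ndarray:
        return 1.0 - self.K

    def state(self, i: int) -> LengthState:
        return LengthState(t=self.t[i], L=self.L[i], F=self.F[i], K=self.K[i])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.t,
                "L_um": self.L,
                "F": self.F,
                "K": self.K,
                "phospho_ratio": self.phospho_ratio,
            }
        )


def phospho_state(L, p: LengthModelParams):
    """Active-CDPK1 fraction, competent-kinesin fraction, phospho fraction.

    Returns ``(F, K, phospho_ratio)`` where ``F = αL/(αL + K_D)`` is the
    fraction of CDPK1 activated by length-proportional Ca²⁺,
    ``phospho_ratio = F/(F + K_M)`` is the phosphorylated (IFT-incompetent)
    kinesin fraction and ``K = 1 − phospho_ratio``.

    Accepts scalar or array ``L``; all outputs share the input shape.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("length must be non-negative")
    ca = p.alpha * L
    with np.errstate(invalid="ignore"):
        F = np.where(ca > 0, ca / (ca + p.K_D), 0.0)
    phospho = F / (F + p.K_M)
    K = 1.0 - phospho
    if L.ndim == 0:
        return float(F), float(K), float(phospho)
    return F, K, phospho


def net_growth_rate(L, p: LengthModelParams):
    """Net elongation rate dL/dt = A·K(L)·(P − 2L) − D in µm/s."""
    L = np.asarray(L, dtype=float)
    _, K, _ = phospho_state(L, p)
    rate = p.A * K * (p.P - 2.0 * L) - p.D
    if L.ndim == 0:
        return float(rate)
    return rate


def simulate(
    p: LengthModelParams,
    T: float,
    amputations: list | tuple = (),
) -> LengthTrajectory:
    """Integrate the model for ``T`` seconds by forward Euler.

    Amputation events reset the length to zero at the given times (severing
    removes the flagellum but leaves the precursor pool intact, so the
    flagellum regrows).  Length is clamped at zero from below after each
    step.  The returned trajectory is sampled every
    ``p.dt * p.record_every`` seconds, starting at t=0.
    """
    if T <= 0:
        raise ValueError("duration T must be positive")
    amputations = sorted(float(a) for a in amputations)
    if amputations and (amputations[0] < 0 or amputations[-1] > T):
        raise ValueError("amputation times must lie within [0, T]")

    n_steps = int(round(T / p.dt))
    amp_steps = {int(round(a / p.dt)) for a in amputations}
    n_rec = n_steps // p.record_every + 1

    t_out = np.empty(n_rec)
    L_out = np.empty(n_rec)
    F_out = np.empty(n_rec)
    K_out = np.empty(n_rec)

    # plain-float inner loop: forward Euler is sequential, so array ops
    # would only add per-step overhead
    alpha, K_D, K_M, A, P, D, dt = p.alpha, p.K_D, p.K_M, p.A, p.P, p.D, p.dt
    L = float(p.L0)
    j = 0
    for step in range(n_steps + 1):
        if step in amp_steps:
            L = 0.0
        ca = alpha * L
        F = ca / (ca + K_D) if ca > 0 else 0.0
        K = 1.0 - F / (F + K_M)
        if step % p.record_every == 0:
            t_out[j] = step * dt
            L_out[j] = L
            F_out[j] = F
            K_out[j] = K
            j += 1
        if step == n_steps:
            break
        L = L + dt * (A * K * (P - 2.0 * L) - D)
        if L < 0.0:
            L = 0.0
        if not math.isfinite(L):
            raise FloatingPointError(
                f"length became non-finite at step {step + 1} "
                f"(t={(step + 1) * dt:.2f} s); check parameter magnitudes"
            )

    return LengthTrajectory(
        params=p,
        t=t_out[:j],
        L=L_out[:j],
        F=F_out[:j],
        K=K_out[:j],
        amputations=list(amputations),
    )


def steady_state(p: LengthModelParams) -> float:
    """Stable fixed point L* of the length dynamics on (0, P/2).

    Found by bracketing root search; ``|net_growth_rate(L*)| < 1e-10``.
    Raises ``ValueError`` when growth from zero is impossible or no sign
    change exists on the interval (no stable length).
    """
    lo, hi = 0.0, p.P / 2.0
    r_lo = net_growth_rate(lo, p)
    if r_lo <= 0:
        raise ValueError("no stable length: net growth rate at L=0 is not positive")
    r_hi = net_growth_rate(hi, p)
    if r_hi >= 0:
        raise ValueError("no stable length: no sign change on (0, P/2)")
    L_star = brentq(lambda L: net_growth_rate(L, p), lo, hi, xtol=1e-13, rtol=1e-15)
    # brentq meets xtol on L; polish with a few Newton steps on the rate
    for _ in range(3):
        r = net_growth_rate(L_star, p)
        if abs(r) < 1e-12:
            break
        h = 1e-6
        dr = (net_growth_rate(L_star + h, p) - net_growth_rate(L_star - h, p)) / (2 * h)
        L_star -= r / dr
    return float(L_star)
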