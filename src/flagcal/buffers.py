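"""Free-Ca²⁺ calculation in EGTA-buffered media.

Single-site 1:1 Ca:EGTA binding.  Writing x for free Ca²⁺ and
b = Ca_t − x for the CaEGTA complex, mass action gives

    x · (E_t − b) = Kd_app · b

whose physical root is solved in closed form (stable quadratic formula).
The apparent dissociation constant folds EGTA protonation at the working
pH into a single constant:

    Kd_app = Kd_abs · (1 + 10^(pKa1−pH) + 10^(pKa1+pKa2−2·pH))

Mg²⁺ competition and ionic-strength/temperature corrections are out of
scope; pass the apparent Kd appropriate for your conditions (≈150 nM at
pH 7.2, 0.1 M ionic strength, 20–25 °C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["BufferSpec", "apparent_kd", "free_ca", "free_ca_bisect"]

# EGTA absolute Kd and the two high pKa values of the free ligand.
EGTA_KD_ABS = 1.07e-11  # M
EGTA_PKA1 = 9.40
EGTA_PKA2 = 8.79


def apparent_kd(
    pH: float,
    kd_abs: float = EGTA_KD_ABS,
    pKa1: float = EGTA_PKA1,
    pKa2: float = EGTA_PKA2,
) -> float:
    """pH-corrected apparent Ca–chelator dissociation constant (molar)."""
    if not 0.0 < pH < 14.0:
        raise ValueError("pH must lie in (0, 14)")
    if kd_abs <= 0 or pKa1 <= 0 or pKa2 <= 0:
        raise ValueError("constants must be positive")
    return kd_abs * (1.0 + 10.0 ** (pKa1 - pH) + 10.0 ** (pKa1 + pKa2 - 2.0 * pH))


@dataclass(frozen=True)
class BufferSpec:
    """Total concentrations and binding constant of a Ca/EGTA buffer.

    Either give ``kd_app`` directly, or give ``pH`` (plus optionally the
    absolute constants) and the apparent Kd is derived.
    """

    ca_total: float
    chelator_total: float = 0.0
    kd_app: float | None = None
    pH: float | None = None
    kd_abs: float = EGTA_KD_ABS
    pKa1: float = EGTA_PKA1
    pKa2: float = EGTA_PKA2

    def __post_init__(self) -> None:
        if self.ca_total < 0 or self.chelator_total < 0:
            raise ValueError("concentrations must be non-negative")
        if self.chelator_total > 0 and self.kd_app is None and self.pH is None:
            raise ValueError("provide kd_app or pH when a chelator is present")
        if self.kd_app is not None and self.kd_app <= 0:
            raise ValueError("kd_app must be positive")

    def resolved_kd(self) -> float:
        if self.kd_app is not None:
            return self.kd_app
        return apparent_kd(self.pH, self.kd_abs, self.pKa1, self.pKa2)


def free_ca(spec: BufferSpec) -> float:
    """Free Ca²⁺ concentration (molar) of a Ca/EGTA mixture.

    Solves the 1:1 binding quadratic
    ``x² + (E_t − Ca_t + Kd)·x − Kd·Ca_t = 0`` for its unique non-negative
    root, using the numerically stable form that avoids cancellation when
    the chelator is in large excess.  ``chelator_total = 0`` returns
    ``ca_total`` (no buffering).
    """
    ca_t = spec.ca_total
    e_t = spec.chelator_total
    if ca_t == 0.0:
        return 0.0
    if e_t == 0.0:
        return ca_t
    kd = spec.resolved_kd()
    b = e_t - ca_t + kd
    c = -kd * ca_t
    disc = math.sqrt(b * b - 4.0 * c)
    if b >= 0:
        # root via  x = 2c / (−b − √disc): stable when b > 0
        x = -2.0 * c / (b + disc)
    else:
        x = (-b + disc) / 2.0
    return float(min(max(x, 0.0), ca_t))


def free_ca_bisect(spec: BufferSpec, rtol: float = 1e-14, max_iter: int = 300) -> float:
    """Bisection solution of the same equilibrium (independent cross-check).

    Brackets free Ca on [0, ca_total] and bisects the mass-action residual
    ``x·(E_t − Ca_t + x) − Kd·(Ca_t − x)``, which is increasing in x.
    Terminates on the *relative* bracket width, so heavily buffered roots
    many orders below ca_total converge fully.
    """
    ca_t = spec.ca_total
    e_t = spec.chelator_total
    if ca_t == 0.0:
        return 0.0
    if e_t == 0.0:
        return ca_t
    kd = spec.resolved_kd()

    def residual(x: float) -> float:
        return x * (e_t - ca_t + x) - kd * (ca_t - x)

    lo, hi = 0.0, ca_t
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < rtol * hi:
            break
    return 0.5 * (lo + hi)
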