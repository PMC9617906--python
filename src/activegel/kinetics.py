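"""Enzyme-kinetics map from molecular composition to sheet mechanics.

The network is built from microtubules (mean length ``mt_length``, um),
kinesin motor clusters (nM), the passive crosslinker PRC1 (nM) and ATP (uM).
Michaelis-Menten kinetics splits the motor pool into a stepping (force
generating) fraction ``f = [ATP] / (K_M + [ATP])`` and a dwelling fraction
``1 - f`` that passively crosslinks; only a fraction ``p0`` of PRC1 is
functionally active.  This yields

* activity          ``zeta  = zeta0 * [motors] * f``           (Pa)
* crosslinker pool  ``[XL]  = p0*[PRC1] + [motors]*(1 - f)``   (nM)
* shear modulus     ``mu    = mu0 * [XL]^2``                   (Pa)
* bending modulus   ``kappa = kappa0 * [XL]^2``                (Pa*um^2)
* nematic elasticity ``K    = K0 * mt_length^a``               (Pa*um^2)

so motors play a dual antagonistic role: at saturating ATP they fluidise the
gel (all stepping), at limiting ATP they stiffen it (most crosslinking),
producing a re-entrant out/in/out instability sequence as the motor
concentration increases.  Downstream instability *directions* depend only on
the ratios zeta0/mu0, K0/kappa0, kappa0/zeta0 and on p0 — a global rescaling
of all four prefactors drops out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanics import ElastomerParams

__all__ = [
    "Composition",
    "KineticConstants",
    "michaelis_menten_fraction",
    "activity",
    "crosslinker_concentration",
    "moduli",
    "nematic_elasticity",
    "composition_to_mechanics",
]


@dataclass(frozen=True)
class Composition:
    """Molecular composition of one sample.

    atp : uM, motors : nM (kinesin clusters), prc1 : nM, mt_length : um.
    """

    atp: float
    motors: float
    prc1: float
    mt_length: float = 1.5

    def __post_init__(self) -> None:
        for name in ("atp", "motors", "prc1", "mt_length"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.mt_length <= 0:
            raise ValueError("mt_length must be > 0")


@dataclass(frozen=True)
class KineticConstants:
    """Microscopic-to-mesoscopic map parameters.

    zeta0 : Pa/nM — efficiency of turning ATP hydrolysis into active stress.
    mu0 : Pa/nM^2, kappa0 : Pa*um^2/nM^2 — crosslinker-squared prefactors.
    K0 : Pa*um^2 per um^length_exponent — nematic elasticity prefactor.
    p0 : active PRC1 fraction, in [0, 1].
    km : Michaelis constant (k_h + k_-)/k_b, uM.
    length_exponent : power of the mean filament length in K (default 2;
        the proper scaling is ambiguous, so it is exposed as a parameter).
    """

    zeta0: float
    mu0: float
    kappa0: float
    K0: float
    p0: float
    km: float = 30.0
    length_exponent: float = 2.0

    def __post_init__(self) -> None:
        for name in ("zeta0", "mu0", "kappa0", "K0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if not np.isfinite(self.km) or self.km <= 0:
            raise ValueError("km must be finite and > 0")
        if not np.isfinite(self.length_exponent):
            raise ValueError("length_exponent must be finite")

    def rescaled(self, c: float) -> "KineticConstants":
        """All four prefactors multiplied by ``c`` (direction-neutral)."""
        return KineticConstants(
            zeta0=c * self.zeta0, mu0=c * self.mu0, kappa0=c * self.kappa0,
            K0=c * self.K0, p0=self.p0, km=self.km,
            length_exponent=self.length_exponent,
        )


def michaelis_menten_fraction(atp, km):
    """Stepping (ATP-bound) fraction ``[ATP] / (K_M + [ATP])`` in [0, 1)."""
    atp = np.asarray(atp, dtype=float)
    if np.any(atp < 0):
        raise ValueError("atp must be >= 0")
    if np.any(np.asarray(km) <= 0):
        raise ValueError("km must be > 0")
    out = atp / (km + atp)
    return float(out) if out.ndim == 0 else out


def activity(c: Composition, k: KineticConstants) -> float:
    """Active stress zeta = zeta0 * [motors] * f(ATP), Pa.

    Linear in the motor concentration, saturating at zeta0*[motors] for
    abundant ATP (the elongation rate of a bundle follows Michaelis-Menten
    kinetics of the motors sliding it apart).
    """
    return k.zeta0 * c.motors * michaelis_menten_fraction(c.atp, k.km)


def crosslinker_concentration(c: Composition, k: KineticConstants) -> float:
    """Effective crosslinker pool [XL] = p0*[PRC1] + [motors]*(1 - f), nM.

    Non-stepping motors dwell on filament pairs and count as crosslinkers;
    with no ATP every motor crosslinks, with saturating ATP none do.
    """
    f = michaelis_menten_fraction(c.atp, k.km)
    return k.p0 * c.prc1 + c.motors * (1.0 - f)


def moduli(c: Composition, k: KineticConstants) -> tuple[float, float]:
    """(mu, kappa): crosslinked-gel moduli, quadratic in the pool [XL]."""
    xl = crosslinker_concentration(c, k)
    return k.mu0 * xl * xl, k.kappa0 * xl * xl


def nematic_elasticity(c: Composition, k: KineticConstants) -> float:
    """K = K0 * mt_length**length_exponent, Pa*um^2."""
    return k.K0 * c.mt_length ** k.length_exponent


def composition_to_mechanics(c: Composition, k: KineticConstants,
                             gamma: float = 1.0) -> ElastomerParams:
    """Assemble the full coarse-grained parameter set for one composition."""
    mu, kappa = moduli(c, k)
    return ElastomerParams(
        zeta=activity(c, k), mu=mu, kappa=kappa,
        K=nematic_elasticity(c, k), gamma=gamma,
    )


def _mechanics_arrays(atp, motors, prc1, mt_length, k: KineticConstants):
    """Vectorised (zeta, mu, kappa, K) for broadcastable composition arrays.

    Used by the phase-diagram and inference layers; validation is the
    caller's job.
    """
    atp = np.asarray(atp, dtype=float)
    motors = np.asarray(motors, dtype=float)
    prc1 = np.asarray(prc1, dtype=float)
    mt_length = np.asarray(mt_length, dtype=float)
    f = atp / (k.km + atp)
    zeta = k.zeta0 * motors * f
    xl = k.p0 * prc1 + motors * (1.0 - f)
    xl2 = xl * xl
    mu = k.mu0 * xl2
    kappa = k.kappa0 * xl2
    K = k.K0 * mt_length ** k.length_exponent
    return zeta, mu, kappa, K
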