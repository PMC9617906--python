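"""Linear stability of a thin active nematic elastomer sheet.

An aligned, crosslinked extensile network (microtubule bundles driven by
kinesin motor clusters) is modelled as a thin elastic sheet lying in the
``xy`` plane with nematic order along ``x``.  Small deformations
``u = (u_x, u_y, h)`` varying along ``x`` feel a destabilising active force
``zeta * d2u/dx2`` (extensile dipolar stress), elastic restoring forces from
the deformation free energy, and friction ``gamma``.  The overdamped force
balance gives one dispersion relation per branch:

* in-plane bend:      ``sigma_y(q) = [(zeta - mu) q^2 - K q^4] / gamma``
* out-of-plane height: ``sigma_h(q) = [zeta q^2 - (K + kappa) q^4] / gamma``

The in-plane branch is unstable only above the critical activity
``zeta* = mu`` (the shear modulus), while the out-of-plane branch is
unstable at any non-zero activity.  Which branch *wins* (grows faster at its
own most-unstable wavenumber) defines three regimes; the ii/iii boundary is
the closed form ``zeta/mu = 1 / (1 - (1 + kappa/K)**-0.5)``.

Units are fixed package-wide: stresses/moduli (zeta, mu, nu) in Pa, the
quartic stiffnesses (kappa, K) in Pa*um^2, lengths in um, time in s, and the
friction coefficient gamma in Pa*s/um^2.  Growth rates come out in 1/s and
wavenumbers in 1/um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElastomerParams",
    "ModeResult",
    "RegimeLabel",
    "FluidLimitError",
    "UnboundedGrowthError",
    "growth_rate_in_plane",
    "growth_rate_out_of_plane",
    "most_unstable_mode",
    "numeric_most_unstable_mode",
    "critical_activity_ratio",
    "classify_regime",
    "free_energy",
]

IN_PLANE = "in_plane"
OUT_OF_PLANE = "out_of_plane"


class FluidLimitError(ValueError):
    """Raised when mu = 0: the elastomer description degenerates to a fluid."""


class UnboundedGrowthError(ValueError):
    """Raised when an unstable branch has no quartic stiffness.

    Without the q^4 cutoff the growth rate increases without bound as
    q -> infinity and no finite most-unstable wavelength exists.
    """


def _require_finite(**values: float) -> None:
    for name, value in values.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ElastomerParams:
    """Coarse-grained mechanical state of the active sheet.

    Parameters
    ----------
    zeta : float
        Activity (extensile convention, >= 0), Pa.
    mu : float
        Shear modulus, Pa.
    kappa : float
        Effective bending modulus, Pa*um^2.
    K : float
        Nematic elasticity, Pa*um^2.
    gamma : float
        Friction coefficient, Pa*s/um^2.  Sets the timescale only.
    nu : float
        Effective bulk modulus, Pa.  Enters the free energy through the
        (passive, always stable) u_x mode; it never enters the unstable
        branches.
    """

    zeta: float
    mu: float
    kappa: float
    K: float
    gamma: float = 1.0
    nu: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(
            zeta=self.zeta, mu=self.mu, kappa=self.kappa,
            K=self.K, gamma=self.gamma, nu=self.nu,
        )
        if self.zeta < 0:
            raise ValueError("zeta must be >= 0 (extensile convention)")
        for name in ("mu", "kappa", "K", "nu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass(frozen=True)
class ModeResult:
    """Most unstable mode of one branch.

    ``lambda_star * q_star == 2*pi`` whenever the branch is unstable; for a
    stable branch ``q_star`` and ``lambda_star`` are NaN and ``sigma_star``
    is 0 (the flat state is marginal at q = 0).
    """

    branch: str
    q_star: float
    lambda_star: float
    sigma_star: float
    unstable: bool


@dataclass(frozen=True)
class RegimeLabel:
    """Phase-diagram regime and the direction of the winning instability.

    ``i_out_only``   : 0 <= zeta/mu < 1, only out-of-plane modes unstable.
    ``ii_out_faster``: in-plane unstable too, but out-of-plane grows faster.
    ``iii_in_faster``: in-plane grows faster; the sheet bends in-plane.
    """

    regime: str
    direction: str


def growth_rate_in_plane(p: ElastomerParams, q):
    """Growth rate sigma_y(q) of the in-plane bend branch, 1/s.

    ``sigma_y(q) = [(zeta - mu) q^2 - K q^4] / gamma`` for a perturbation
    ``u_y ~ exp(i q x)``.  Accepts scalar or array ``q >= 0``.
    """
    q = np.asarray(q, dtype=float)
    _require_finite(q=q)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    q2 = q * q
    return ((p.zeta - p.mu) * q2 - p.K * q2 * q2) / p.gamma


def growth_rate_out_of_plane(p: ElastomerParams, q):
    """Growth rate sigma_h(q) of the out-of-plane buckling branch, 1/s.

    ``sigma_h(q) = [zeta q^2 - (K + kappa) q^4] / gamma``.
    """
    q = np.asarray(q, dtype=float)
    _require_finite(q=q)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    q2 = q * q
    return (p.zeta * q2 - (p.K + p.kappa) * q2 * q2) / p.gamma


def _stable(branch: str) -> ModeResult:
    return ModeResult(branch=branch, q_star=math.nan, lambda_star=math.nan,
                      sigma_star=0.0, unstable=False)


def most_unstable_mode(p: ElastomerParams, branch: str) -> ModeResult:
    """Closed-form fastest-growing mode of one branch.

    Maximising the quadratic-in-q^2 dispersion gives, when unstable,

    * in-plane:      ``q* = sqrt((zeta - mu) / (2 K))``,
      ``sigma* = (zeta - mu)^2 / (4 gamma K)``  (requires zeta > mu);
    * out-of-plane:  ``q* = sqrt(zeta / (2 (K + kappa)))``,
      ``sigma* = zeta^2 / (4 gamma (K + kappa))``  (requires zeta > 0).

    Raises :class:`UnboundedGrowthError` if the branch is unstable but its
    quartic stiffness vanishes.
    """
    if branch == IN_PLANE:
        drive = p.zeta - p.mu
        stiff = p.K
    elif branch == OUT_OF_PLANE:
        drive = p.zeta
        stiff = p.K + p.kappa
    else:
        raise ValueError(f"unknown branch {branch!r}")
    if drive <= 0:
        return _stable(branch)
    if stiff == 0:
        raise UnboundedGrowthError(
            f"{branch} branch with vanishing quartic stiffness: "
            "unbounded growth at q -> infinity, no finite wavelength exists"
        )
    q_star = math.sqrt(drive / (2.0 * stiff))
    sigma_star = drive * drive / (4.0 * p.gamma * stiff)
    return ModeResult(branch=branch, q_star=q_star,
                      lambda_star=2.0 * math.pi / q_star,
                      sigma_star=sigma_star, unstable=True)


def numeric_most_unstable_mode(p: ElastomerParams, branch: str,
                               n: int = 10_000) -> ModeResult:
    """Brute-force grid argmax of the dispersion relation.

    Cross-check for :func:`most_unstable_mode` that never uses the closed
    forms.  The search grid is a composite of a logarithmic and a linear grid
    spanning ``[1e-4, 1] * q_upper`` where ``q_upper`` is the neutral
    wavenumber (the positive root of sigma = 0), which brackets the maximum
    for any unstable quadratic-in-q^2 dispersion.
    """
    if branch == IN_PLANE:
        drive, stiff = p.zeta - p.mu, p.K
        rate = growth_rate_in_plane
    elif branch == OUT_OF_PLANE:
        drive, stiff = p.zeta, p.K + p.kappa
        rate = growth_rate_out_of_plane
    else:
        raise ValueError(f"unknown branch {branch!r}")
    if drive <= 0:
        return _stable(branch)
    if stiff == 0:
        raise UnboundedGrowthError("no finite wavelength: quartic stiffness is 0")
    q_upper = math.sqrt(drive / stiff)  # sigma crosses zero here
    grid = np.concatenate([
        np.geomspace(1e-4 * q_upper, q_upper, n // 2),
        np.linspace(1e-4 * q_upper, q_upper, n - n // 2),
    ])
    sigma = rate(p, grid)
    k = int(np.argmax(sigma))
    q_star = float(grid[k])
    return ModeResult(branch=branch, q_star=q_star,
                      lambda_star=2.0 * math.pi / q_star,
                      sigma_star=float(sigma[k]), unstable=True)


def critical_activity_ratio(kappa_over_K: float) -> float:
    """Regime ii/iii boundary value of zeta/mu as a function of kappa/K.

    ``1 / (1 - (1 + kappa/K)**-0.5)``: above it the fastest in-plane mode
    outgrows the fastest out-of-plane mode.  Strictly decreasing in kappa/K,
    diverging as kappa/K -> 0+ and approaching 1 from above as
    kappa/K -> infinity (``inf`` input returns the limit 1.0).
    """
    x = float(kappa_over_K)
    if math.isnan(x) or x <= 0:
        raise ValueError("kappa_over_K must be > 0 (boundary diverges at 0+)")
    if math.isinf(x):
        return 1.0
    return 1.0 / (1.0 - (1.0 + x) ** -0.5)


def classify_regime(p: ElastomerParams) -> RegimeLabel:
    """Assign the three-regime phase-diagram label.

    regime i  : zeta/mu <= 1 (in-plane branch stable or marginal);
    regime ii : in-plane unstable but out-of-plane faster (ties included);
    regime iii: zeta/mu strictly above the critical ratio -> in-plane wins.

    The label depends only on zeta/mu and kappa/K; it is invariant under
    gamma -> c*gamma (friction rescales time, not the competition).
    """
    if p.mu == 0:
        raise FluidLimitError(
            "mu = 0: fluid limit, the elastomer regime classification "
            "does not apply"
        )
    if p.K <= 0:
        raise ValueError("classify_regime requires K > 0")
    ratio = p.zeta / p.mu
    if ratio <= 1.0:
        return RegimeLabel(regime="i_out_only", direction=OUT_OF_PLANE)
    if p.kappa == 0:
        # kappa/K -> 0: boundary diverges, in-plane can never win.
        return RegimeLabel(regime="ii_out_faster", direction=OUT_OF_PLANE)
    boundary = critical_activity_ratio(p.kappa / p.K)
    if ratio > boundary:
        return RegimeLabel(regime="iii_in_faster", direction=IN_PLANE)
    return RegimeLabel(regime="ii_out_faster", direction=OUT_OF_PLANE)


def free_energy(field, p: ElastomerParams) -> float:
    """Deformation free energy per unit width, Pa*um^3 / um = Pa*um^2... in
    practice reported in Pa*um^3 per unit width of the sheet.

    Discretises

    ``F = 1/2 * Int dx [ nu (dx u_x)^2 + mu (dx u_y)^2 + kappa (dxx h)^2
    + K ((dxx u_y)^2 + (dxx h)^2) ]``

    with spectral (FFT) derivatives on the periodic grid.  Non-negative by
    construction; zero for the flat state.
    """
    x = np.asarray(field.x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("free_energy needs a grid with at least 4 points")
    dx = x[1] - x[0]
    q = 2.0 * np.pi * np.fft.rfftfreq(n, d=dx)

    def d1(f):
        return np.fft.irfft(1j * q * np.fft.rfft(f), n=n)

    def d2(f):
        return np.fft.irfft(-(q * q) * np.fft.rfft(f), n=n)

    u_x = np.asarray(field.u_x, dtype=float)
    u_y = np.asarray(field.u_y, dtype=float)
    h = np.asarray(field.h, dtype=float)
    density = (
        p.nu * d1(u_x) ** 2
        + p.mu * d1(u_y) ** 2
        + p.kappa * d2(h) ** 2
        + p.K * (d2(u_y) ** 2 + d2(h) ** 2)
    )
    return 0.5 * float(np.sum(density)) * dx
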