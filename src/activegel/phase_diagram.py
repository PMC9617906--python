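"""Composition-space phase diagrams of the instability direction.

Forward-predicts, for every cell of a 2D grid over molecular composition
(any two of ATP, motor clusters, PRC1, filament length), which instability
branch wins, its regime label, the activity/shear-modulus ratio and the
winning wavelength — the computational twin of an experimental
blurriness phase diagram.  Boundaries between the in-plane and out-of-plane
regions are located by per-scan-line bisection on the sign of
``sigma_y* - sigma_h*`` (the difference of the two maximal growth rates),
which is robust for re-entrant (multi-crossing) diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import KineticConstants, _mechanics_arrays
from .mechanics import IN_PLANE, OUT_OF_PLANE, critical_activity_ratio

__all__ = ["PhaseGrid", "AXES", "predict_grid", "boundary_trace",
           "wavelength_map", "DEFAULT_AXES"]

AXES = ("atp", "motors", "prc1", "mt_length")

#: Default axis ranges mirroring typical experimental phase-diagram panels:
#: (min, max, n, scale).  ATP in uM, proteins in nM, length in um.
DEFAULT_AXES = {
    "atp": (1.0, 1500.0, 40, "log"),
    "motors": (5.0, 200.0, 40, "lin"),
    "prc1": (10.0, 500.0, 40, "lin"),
    "mt_length": (0.5, 10.0, 40, "lin"),
}

STABLE = "stable"


def axis_values(name: str, spec=None) -> np.ndarray:
    """Materialise an axis: ``spec`` is an array, a (min, max, n, scale)
    tuple, or None for the default range."""
    if spec is None:
        spec = DEFAULT_AXES[name]
    if isinstance(spec, tuple):
        lo, hi, n, scale = spec
        if scale == "log":
            return np.geomspace(lo, hi, int(n))
        return np.linspace(lo, hi, int(n))
    return np.asarray(spec, dtype=float)


@dataclass
class PhaseGrid:
    """Predicted instability direction over a composition grid.

    2D arrays are indexed ``[i1, i2]`` with ``i1`` along ``axis1``.
    ``direction`` holds 'in_plane' / 'out_of_plane' / 'stable'.
    """

    axis1: str
    axis1_values: np.ndarray
    axis2: str
    axis2_values: np.ndarray
    fixed: dict = field(default_factory=dict)
    direction: np.ndarray = None
    regime: np.ndarray = None
    lambda_star: np.ndarray = None
    zeta_over_mu: np.ndarray = None

    def to_dataframe(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.axis1_values, self.axis2_values,
                             indexing="ij")
        df = pd.DataFrame({
            self.axis1: a1.ravel(),
            self.axis2: a2.ravel(),
            "direction": self.direction.ravel(),
            "regime": self.regime.ravel(),
            "lambda_star_um": self.lambda_star.ravel(),
            "zeta_over_mu": self.zeta_over_mu.ravel(),
        })
        for name, value in self.fixed.items():
            df[name] = value
        return df


def _composition_fields(axis1, a1, axis2, a2, fixed):
    comp = dict(fixed)
    comp[axis1] = a1
    comp[axis2] = a2
    missing = [n for n in AXES if n not in comp]
    if missing:
        raise ValueError(f"composition fields not specified: {missing}")
    return comp["atp"], comp["motors"], comp["prc1"], comp["mt_length"]


def _max_growth_rates(atp, motors, prc1, mt_length, k, gamma):
    """Vectorised (sigma_y*, sigma_h*, extras) from composition arrays."""
    zeta, mu, kappa, K = _mechanics_arrays(atp, motors, prc1, mt_length, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        sig_y = np.where(zeta > mu, (zeta - mu) ** 2 / (4.0 * gamma * K), 0.0)
        sig_h = np.where(zeta > 0, zeta ** 2 / (4.0 * gamma * (K + kappa)), 0.0)
    return sig_y, sig_h, zeta, mu, kappa, K


def predict_grid(axes, fixed, k: KineticConstants,
                 gamma: float = 1.0) -> PhaseGrid:
    """Classify every cell of the Cartesian product of two composition axes.

    Parameters
    ----------
    axes : dict
        Two entries ``{name: spec}`` with name in ``AXES`` and spec an
        array or (min, max, n, scale) tuple.  Insertion order fixes which
        is axis1.
    fixed : dict
        The remaining composition fields (scalars).
    """
    if len(axes) != 2:
        raise ValueError("axes must specify exactly two composition axes")
    (n1, s1), (n2, s2) = axes.items()
    if n1 not in AXES or n2 not in AXES:
        raise ValueError(f"axes must be among {AXES}")
    v1 = axis_values(n1, s1)
    v2 = axis_values(n2, s2)
    if v1.size == 0 or v2.size == 0:
        raise ValueError("empty axis")
    a1, a2 = np.meshgrid(v1, v2, indexing="ij")
    atp, motors, prc1, L = _composition_fields(n1, a1, n2, a2, fixed)
    sig_y, sig_h, zeta, mu, kappa, K = _max_growth_rates(
        atp, motors, prc1, L, k, gamma)

    direction = np.where(sig_y > sig_h, IN_PLANE, OUT_OF_PLANE)
    direction = np.where((sig_y <= 0) & (sig_h <= 0), STABLE, direction)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mu > 0, zeta / mu, np.inf)
        regime = np.where(ratio <= 1.0, "i_out_only",
                          np.where(direction == IN_PLANE, "iii_in_faster",
                                   "ii_out_faster"))
        regime = np.where(direction == STABLE, STABLE, regime)
        lam_in = 2.0 * np.pi * np.sqrt(2.0 * K / (zeta - mu))
        lam_out = 2.0 * np.pi * np.sqrt(2.0 * (K + kappa) / zeta)
    lam = np.where(direction == IN_PLANE, lam_in, lam_out)
    lam = np.where(direction == STABLE, np.nan, lam)

    return PhaseGrid(axis1=n1, axis1_values=v1, axis2=n2, axis2_values=v2,
                     fixed=dict(fixed), direction=direction, regime=regime,
                     lambda_star=lam, zeta_over_mu=ratio)


def boundary_trace(axis1, axis1_values, axis2, axis2_values, fixed,
                   k: KineticConstants, gamma: float = 1.0,
                   tol: float = 1e-9, max_crossings: int = 2) -> pd.DataFrame:
    """Locate in/out phase-boundary points by per-scan-line bisection.

    For every value of ``axis2`` the sign of
    ``g = sigma_y* - sigma_h*`` is sampled along ``axis1_values``; each of
    the first ``max_crossings`` sign changes is refined with Brent's method
    until ``|g| <= tol * max(sigma_h*, tiny)``.  Re-entrant lines yield two
    crossings; lines with no sign change contribute nothing.

    Returns a DataFrame with columns (axis1, axis2, crossing).
    """
    v1 = axis_values(axis1, axis1_values)
    v2 = axis_values(axis2, axis2_values)

    def g_of(x, a2):
        atp, motors, prc1, L = _composition_fields(axis1, x, axis2, a2, fixed)
        sig_y, sig_h, *_ = _max_growth_rates(atp, motors, prc1, L, k, gamma)
        return sig_y - sig_h, sig_h

    rows = []
    for a2 in v2:
        g, _ = g_of(v1, a2)
        signs = np.sign(g)
        changes = np.nonzero(np.diff(signs) != 0)[0]
        for ci, idx in enumerate(changes[:max_crossings]):
            lo, hi = v1[idx], v1[idx + 1]
            root = brentq(lambda x: g_of(x, a2)[0], lo, hi,
                          xtol=1e-14, rtol=1e-15)
            gval, sh = g_of(root, a2)
            if abs(gval) <= tol * max(sh, 1e-300):
                rows.append((float(root), float(a2), ci))
    return pd.DataFrame(rows, columns=[axis1, axis2, "crossing"])


def wavelength_map(grid: PhaseGrid) -> np.ndarray:
    """Wavelength (um) of the winning branch per cell; NaN where stable.

    ``lambda = 2*pi/q*`` of the faster-growing unstable branch: in regime
    iii the in-plane wavelength ``2*pi*sqrt(2K/(zeta-mu))``, elsewhere the
    out-of-plane wavelength ``2*pi*sqrt(2(K+kappa)/zeta)``.
    """
    if grid.lambda_star is None:
        raise ValueError("grid has not been predicted")
    return grid.lambda_star


def boundary_satisfies_closed_form(df: pd.DataFrame, fixed, k,
                                   axis1: str, axis2: str) -> np.ndarray:
    """Relative mismatch |zeta/mu - R(kappa/K)| / R at each boundary point.

    Convenience diagnostic: every traced point must satisfy the closed-form
    regime boundary ``zeta/mu = 1/(1-(1+kappa/K)^-0.5)``.
    """
    out = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        a1 = getattr(row, axis1)
        a2 = getattr(row, axis2)
        atp, motors, prc1, L = _composition_fields(axis1, a1, axis2, a2, fixed)
        zeta, mu, kappa, K = _mechanics_arrays(atp, motors, prc1, L, k)
        r = critical_activity_ratio(float(kappa) / float(K))
        out[i] = abs(float(zeta) / float(mu) - r) / r
    return out
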