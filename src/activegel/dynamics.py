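"""Spectral integration of the linearised overdamped sheet dynamics.

The in-plane and out-of-plane deformation equations are linear and diagonal
in Fourier space, so each spatial mode can be advanced *exactly*:
``u_hat(q, t + dt) = u_hat(q, t) * exp(sigma(q) * dt)`` with sigma(q) the
matching dispersion relation (in-plane bend for u_y, height for h, and the
always-stable passive relaxation ``-nu q^2 / gamma`` for u_x).  There is no
time-discretisation error, which makes this simulator a trustworthy numeric
oracle for the closed-form mode selection: white noise evolved long enough
develops a spectral peak at the analytic most-unstable wavenumber, and the
branch with the larger maximal growth rate dominates the RMS amplitude.

Periodic boundary conditions on a uniform 1D grid (positions in um, time in
s).  Growth is unbounded in the linear theory; runs are capped by an
overflow guard rather than any ad-hoc saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mechanics import ElastomerParams

__all__ = ["DeformationField", "init_noise_field", "evolve",
           "dominant_wavelength", "rms"]


@dataclass(frozen=True)
class DeformationField:
    """Discretised deformation state on a periodic uniform grid.

    x : grid positions (um); u_y : in-plane displacement; h : height;
    u_x : axial displacement (passive); t : time stamp (s).
    """

    x: np.ndarray
    u_y: np.ndarray
    h: np.ndarray
    u_x: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.u_y) == len(self.h) == len(self.u_x) == n):
            raise ValueError("all field arrays must share the grid length")
        if n >= 2:
            dx = np.diff(self.x)
            if not np.allclose(dx, dx[0]):
                raise ValueError("grid must be uniform")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def domain_length(self) -> float:
        return self.n * self.dx


def init_noise_field(n_points: int = 1024, domain_length: float = 512.0,
                     amplitude: float = 1e-4,
                     seed: int | None = None) -> DeformationField:
    """Independent Gaussian white noise per grid point, per field.

    Emulates the small random fluctuations that seed the instability in an
    experiment.  Deterministic for a given seed; the expected power spectrum
    is flat.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    if domain_length <= 0 or amplitude < 0:
        raise ValueError("domain_length must be > 0 and amplitude >= 0")
    rng = np.random.default_rng(seed)
    x = np.arange(n_points) * (domain_length / n_points)
    noise = rng.normal(0.0, 1.0, size=(3, n_points)) * amplitude
    return DeformationField(x=x, u_y=noise[0], h=noise[1], u_x=noise[2],
                            t=0.0)


def _wavenumbers(field: DeformationField) -> np.ndarray:
    return 2.0 * np.pi * np.fft.rfftfreq(field.n, d=field.dx)


def evolve(field: DeformationField, p: ElastomerParams,
           t_final: float) -> DeformationField:
    """Advance the field to ``t_final`` with the exact mode propagator.

    Raises if any ``sigma(q) * dt`` exceeds 700 (the linear theory would
    overflow double precision; reduce ``t_final``).  Composition is exact:
    ``evolve(evolve(f, t1), t2) == evolve(f, t2)`` up to rounding.
    """
    dt = t_final - field.t
    if dt < 0:
        raise ValueError("t_final must be >= field.t")
    if dt == 0:
        return field
    q = _wavenumbers(field)
    q2 = q * q
    sig_y = ((p.zeta - p.mu) * q2 - p.K * q2 * q2) / p.gamma
    sig_h = (p.zeta * q2 - (p.K + p.kappa) * q2 * q2) / p.gamma
    sig_x = -(p.nu * q2) / p.gamma
    biggest = max(sig_y.max(), sig_h.max(), sig_x.max()) * dt
    if biggest > 700.0:
        raise OverflowError(
            f"growth overflow (max sigma*dt = {biggest:.1f} > 700); "
            "reduce t_final"
        )

    def push(f, sig):
        return np.fft.irfft(np.fft.rfft(f) * np.exp(sig * dt), n=field.n)

    return replace(field, u_y=push(field.u_y, sig_y),
                   h=push(field.h, sig_h), u_x=push(field.u_x, sig_x),
                   t=t_final)


def rms(values: np.ndarray) -> float:
    """Root-mean-square amplitude of a field array.

    Scaled by the peak magnitude before squaring so that strongly
    amplified (linear-theory) fields do not overflow.
    """
    values = np.asarray(values, dtype=float)
    peak = np.max(np.abs(values))
    if peak == 0 or not np.isfinite(peak):
        return float(peak)
    return float(peak * np.sqrt(np.mean(np.square(values / peak))))


def dominant_wavelength(field: DeformationField, which: str = "u_y") -> float:
    """Wavelength (um) of the power-spectrum peak of one field.

    The q = 0 (uniform translation) mode is excluded; the discrete peak is
    refined by parabolic interpolation on log-power over its two
    neighbours.  Raises for a flat field (no dominant mode).
    """
    try:
        values = getattr(field, which)
    except AttributeError:
        raise ValueError(f"unknown field {which!r}") from None
    values = np.asarray(values, dtype=float)
    if np.allclose(values, values[0]):
        raise ValueError("flat field: no dominant mode")
    # amplitudes, not power: strongly amplified fields would overflow the
    # square while |F| still fits in double precision
    power = np.abs(np.fft.rfft(values - values.mean()))
    power[0] = 0.0
    k = int(np.argmax(power))
    dq = _wavenumbers(field)[1]
    if 1 <= k < len(power) - 1 and power[k - 1] > 0 and power[k + 1] > 0:
        lm, l0, lp = np.log(power[k - 1: k + 2])
        denom = lm - 2.0 * l0 + lp
        shift = 0.0 if denom == 0 else 0.5 * (lm - lp) / denom
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    q_peak = (k + shift) * dq
    return 2.0 * np.pi / q_peak
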