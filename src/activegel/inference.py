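"""Bayesian estimation of the four kinetic parameters from phase diagrams.

The instability *direction* and *wavelength* predicted by the multiscale
model depend on the molecular composition only through four quantities:
the ratios zeta0/mu0, K0/kappa0, kappa0/zeta0 and the active PRC1 fraction
p0 (a common rescaling of all four prefactors drops out of the direction
competition).  This module fits those four from tables of phase-diagram
observations (composition, blurriness B, optional wavelength) by MCMC.

Likelihood (the published analysis states the data channels — directions of
four phase diagrams plus wavelengths — but not a likelihood; this one is
this package's own construction):

* direction channel: each observation is reduced to a Bernoulli outcome
  (out-of-plane if B > 0.5, in-plane if B <= 0.05, mixed rows down-weighted
  to 1/2 with the label of the nearest threshold) with success probability
  ``P(out) = logistic(s * log(sigma_h*/sigma_y*))`` — the softer the
  growth-rate contrast, the less certain the readout.  When the in-plane
  branch is stable, P(out) = 1 - eps.
* wavelength channel: Gaussian on log(lambda) around the model wavelength
  of the branch indicated by the observed direction, sd ``sigma_lambda``.

Sampling: per-chain adaptive random-walk Metropolis (Haario-style empirical
covariance adaptation, frozen after burn-in = the first half), on the
transformed parameters (log ratios, logit p0).  Priors are log-uniform over
six decades for each ratio and uniform(0, 1) for p0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticConstants

__all__ = [
    "PhaseObservation", "LikelihoodConfig", "Priors", "ObservationData",
    "PosteriorSummary", "prepare_observations", "log_likelihood",
    "log_prior", "run_mcmc", "theta_to_constants",
    "posterior_predictive_boundary",
]

PARAM_NAMES = ("zeta0_over_mu0", "K0_over_kappa0", "kappa0_over_zeta0", "p0")


@dataclass(frozen=True)
class PhaseObservation:
    """One phase-diagram point: composition, blurriness, optional lambda."""

    atp: float
    motors: float
    prc1: float
    mt_length: float
    B: float
    lambda_obs: float | None = None
    replicate: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.B <= 1.0:
            raise ValueError("B must lie in [0, 1]")
        if self.lambda_obs is not None and not self.lambda_obs > 0:
            raise ValueError("lambda_obs must be > 0 when present")


@dataclass(frozen=True)
class LikelihoodConfig:
    """Fixed hyperparameters of the likelihood (not sampled, keeping the
    four-parameter structure of the theory).

    s : softness of the logistic link on the log growth-rate ratio.
    sigma_lambda : sd of the Gaussian on log wavelength.
    km, length_exponent : kinetics constants held fixed during fitting.
    """

    s: float = 5.0
    sigma_lambda: float = 0.2
    eps: float = 1e-6
    b_in: float = 0.05
    b_out: float = 0.5
    mixed_weight: float = 0.5
    km: float = 30.0
    length_exponent: float = 2.0
    use_wavelength: bool = True


@dataclass(frozen=True)
class Priors:
    """Per-ratio log-uniform boxes (six decades) and uniform p0."""

    r_zeta_mu: tuple = (1e-1, 1e5)
    r_K_kappa: tuple = (1e-1, 1e5)
    r_kappa_zeta: tuple = (1e-3, 1e3)

    @property
    def log_bounds(self) -> np.ndarray:
        return np.log(np.array([self.r_zeta_mu, self.r_K_kappa,
                                self.r_kappa_zeta]))


@dataclass
class ObservationData:
    """Vectorised observation table ready for likelihood evaluation."""

    atp: np.ndarray
    motors: np.ndarray
    prc1: np.ndarray
    mt_length: np.ndarray
    y: np.ndarray          # 1 = out-of-plane, 0 = in-plane
    weight: np.ndarray     # 1 clear, mixed_weight mixed
    lam: np.ndarray        # observed wavelength, NaN when absent
    has_lam: np.ndarray

    @property
    def n(self) -> int:
        return self.atp.size


_COLUMN_ALIASES = {
    "atp": ("atp", "atp_uM"), "motors": ("motors", "motors_nM"),
    "prc1": ("prc1", "prc1_nM"), "mt_length": ("mt_length", "mt_length_um"),
    "lam": ("lambda_obs", "lambda_um"),
}


def _col(df: pd.DataFrame, key: str):
    for name in _COLUMN_ALIASES[key]:
        if name in df.columns:
            return df[name].to_numpy(dtype=float)
    return None


def prepare_observations(data, config: LikelihoodConfig = LikelihoodConfig(),
                         ) -> ObservationData:
    """Reduce a table (DataFrame or PhaseObservation list) to arrays.

    Blurriness is collapsed to the Bernoulli direction outcome; mixed rows
    (b_in < B <= b_out) get weight ``mixed_weight`` and the label of the
    nearer threshold.  Wavelengths are kept only for clearly-classified
    rows (near the boundary the branch identity of a measured wavelength is
    ambiguous).
    """
    if isinstance(data, pd.DataFrame):
        df = data
    else:
        df = pd.DataFrame([{
            "atp": o.atp, "motors": o.motors, "prc1": o.prc1,
            "mt_length": o.mt_length, "B": o.B,
            "lambda_obs": np.nan if o.lambda_obs is None else o.lambda_obs,
        } for o in data])
    if len(df) == 0:
        raise ValueError("empty observation table")
    b = df["B"].to_numpy(dtype=float)
    out = b > config.b_out
    clear_in = b <= config.b_in
    mixed = ~(out | clear_in)
    y = np.where(out, 1.0, 0.0)
    # mixed: label of the nearest threshold
    y[mixed] = np.where((config.b_out - b[mixed]) < (b[mixed] - config.b_in),
                        1.0, 0.0)
    weight = np.where(mixed, config.mixed_weight, 1.0)
    lam = _col(df, "lam")
    if lam is None:
        lam = np.full(len(df), np.nan)
    lam = np.where(mixed, np.nan, lam)
    return ObservationData(
        atp=_col(df, "atp"), motors=_col(df, "motors"),
        prc1=_col(df, "prc1"), mt_length=_col(df, "mt_length"),
        y=y, weight=weight, lam=lam, has_lam=np.isfinite(lam),
    )


def theta_to_constants(theta, config: LikelihoodConfig = LikelihoodConfig(),
                       zeta0: float = 1.0) -> KineticConstants:
    """Kinetic constants for a transformed parameter vector.

    theta = (log zeta0/mu0, log K0/kappa0, log kappa0/zeta0, logit p0); the
    overall stress scale is not identifiable from directions/wavelengths and
    is fixed by ``zeta0``.
    """
    r_zm, r_kk, r_kz = np.exp(theta[:3])
    p0 = 1.0 / (1.0 + math.exp(-theta[3]))
    kappa0 = r_kz * zeta0
    return KineticConstants(zeta0=zeta0, mu0=zeta0 / r_zm, kappa0=kappa0,
                            K0=r_kk * kappa0, p0=p0, km=config.km,
                            length_exponent=config.length_exponent)


def _model_arrays(theta, obs: ObservationData, config: LikelihoodConfig):
    """sigma_y*, sigma_h*, and per-row labelled-branch wavelength."""
    r_zm = math.exp(theta[0])
    r_kk = math.exp(theta[1])
    r_kz = math.exp(theta[2])
    p0 = 1.0 / (1.0 + math.exp(-theta[3]))
    f = obs.atp / (config.km + obs.atp)
    zeta = obs.motors * f                       # zeta0 = 1 scale
    xl = p0 * obs.prc1 + obs.motors * (1.0 - f)
    xl2 = xl * xl
    mu = xl2 / r_zm
    kappa = r_kz * xl2
    K = r_kk * r_kz * obs.mt_length ** config.length_exponent
    drive = zeta - mu
    unstable_in = drive > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sig_y = np.where(unstable_in, drive * drive / (4.0 * K), 0.0)
        sig_h = zeta * zeta / (4.0 * (K + kappa))
        lam_in = 2.0 * np.pi * np.sqrt(
            2.0 * K / np.maximum(drive, 1e-12 * np.maximum(mu, 1e-300)))
        lam_out = 2.0 * np.pi * np.sqrt(2.0 * (K + kappa) / zeta)
    lam_model = np.where(obs.y > 0.5, lam_out, lam_in)
    return sig_y, sig_h, lam_model, unstable_in


def log_likelihood(theta, obs: ObservationData,
                   config: LikelihoodConfig = LikelihoodConfig()) -> float:
    """Log-likelihood of the direction (+ optional wavelength) channels."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    if obs.n == 0:
        raise ValueError("no observations")
    sig_y, sig_h, lam_model, unstable_in = _model_arrays(theta, obs, config)
    with np.errstate(divide="ignore", over="ignore"):
        log_ratio = np.where(sig_y > 0, np.log(sig_h) -
                             np.log(np.where(sig_y > 0, sig_y, 1.0)), np.inf)
        p_out = np.where(np.isinf(log_ratio), 1.0 - config.eps,
                         1.0 / (1.0 + np.exp(-config.s * log_ratio)))
    p_out = np.clip(p_out, config.eps, 1.0 - config.eps)
    ll = float(np.sum(obs.weight * (obs.y * np.log(p_out) +
                                    (1.0 - obs.y) * np.log1p(-p_out))))
    if config.use_wavelength and obs.has_lam.any():
        sel = obs.has_lam
        resid = (np.log(obs.lam[sel]) - np.log(lam_model[sel]))
        sl = config.sigma_lambda
        ll += float(np.sum(-0.5 * (resid / sl) ** 2
                           - math.log(sl) - 0.5 * math.log(2.0 * math.pi)))
    return ll


def log_prior(theta, priors: Priors = Priors()) -> float:
    """Log-density of the prior in transformed space.

    Flat in log inside each ratio box; the logit-p0 coordinate carries the
    Jacobian of the uniform(0,1) prior, log[p0 (1 - p0)].
    """
    theta = np.asarray(theta, dtype=float)
    lb = priors.log_bounds
    if np.any(theta[:3] < lb[:, 0]) or np.any(theta[:3] > lb[:, 1]):
        return -np.inf
    if not np.isfinite(theta[3]):
        return -np.inf
    # log sigmoid(x) + log sigmoid(-x), numerically stable
    ax = abs(theta[3])
    return -ax - 2.0 * math.log1p(math.exp(-ax))


def sample_prior(rng: np.random.Generator, priors: Priors = Priors()):
    lb = priors.log_bounds
    logs = rng.uniform(lb[:, 0], lb[:, 1])
    p0 = rng.uniform(0.0, 1.0)
    p0 = min(max(p0, 1e-9), 1.0 - 1e-9)
    return np.concatenate([logs, [math.log(p0 / (1.0 - p0))]])


@dataclass
class PosteriorSummary:
    """Posterior table plus sampler diagnostics.

    ``table`` has one row per natural-space parameter (the three ratios and
    p0) with mean / median / 2.5% / 97.5% columns; ``chains`` keeps the
    post-burn-in transformed draws, shape (n_chains, n_kept, 4).
    """

    table: pd.DataFrame
    acceptance_rate: float
    rhat: dict
    chains: np.ndarray
    warnings: list = field(default_factory=list)

    def credible_interval(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["q2.5"]), float(row["q97.5"])


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Gelman-Rubin split R-hat per parameter, chains (C, N, D)."""
    c, n, d = chains.shape
    half = n // 2
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, length = segs.shape[0], half
    means = segs.mean(axis=1)
    variances = segs.var(axis=1, ddof=1)
    w = variances.mean(axis=0)
    b = length * means.var(axis=0, ddof=1)
    var_plus = (length - 1) / length * w + b / length
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_plus / w)


def _natural(draws: np.ndarray) -> np.ndarray:
    out = np.empty_like(draws)
    out[..., :3] = np.exp(draws[..., :3])
    out[..., 3] = 1.0 / (1.0 + np.exp(-draws[..., 3]))
    return out


def run_mcmc(data, priors: Priors = Priors(), n_chains: int = 4,
             n_steps: int = 5000, seed: int = 0,
             config: LikelihoodConfig = LikelihoodConfig(),
             prior_only: bool = False) -> PosteriorSummary:
    """Adaptive random-walk Metropolis over the four transformed parameters.

    Each chain starts at an independent prior draw; the proposal covariance
    is adapted to 2.38^2/d times the running empirical covariance (with a
    small regulariser) and a global log-scale tuned towards 30% acceptance
    during the burn-in (first half), then frozen.  Fully reproducible for a
    given ``seed``.  ``prior_only`` ignores the data (posterior = prior),
    used for prior-recovery checks.
    """
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2 (needed for R-hat)")
    if n_steps < 10:
        raise ValueError("n_steps too small")
    obs = None if prior_only else (
        data if isinstance(data, ObservationData)
        else prepare_observations(data, config))

    def log_post(theta):
        lp = log_prior(theta, priors)
        if not np.isfinite(lp):
            return -np.inf
        if obs is None:
            return lp
        return lp + log_likelihood(theta, obs, config)

    d = 4
    n_burn = n_steps // 2
    chains = np.empty((n_chains, n_steps - n_burn, d))
    accepted_post = 0
    proposals_post = 0
    for c in range(n_chains):
        rng = np.random.default_rng([int(seed), c])
        # start each chain at the best of a batch of its own prior draws:
        # the six-decade prior box is mostly likelihood plateau, and a
        # random-walk chain started deep in it may not reach the mode
        # within the burn-in
        starts = [sample_prior(rng, priors) for _ in range(128)]
        lps = [log_post(t) for t in starts]
        theta = starts[int(np.argmax(lps))]
        lp = log_post(theta)
        mean = theta.copy()
        cov = np.eye(d) * 0.25
        m2 = np.zeros((d, d))
        log_scale = 0.0
        chol = np.linalg.cholesky(cov * math.exp(2 * log_scale) +
                                  1e-9 * np.eye(d))
        for i in range(n_steps):
            prop = theta + chol @ rng.normal(size=d)
            lp_prop = log_post(prop)
            accept = math.log(rng.uniform()) < lp_prop - lp
            if accept:
                theta, lp = prop, lp_prop
            if i < n_burn:
                # running covariance (Welford) + acceptance-rate tuning
                delta = theta - mean
                mean += delta / (i + 1)
                m2 += np.outer(delta, theta - mean)
                log_scale += ((1.0 if accept else 0.0) - 0.3) \
                    / max(20.0, (i + 1) ** 0.6)
                if i >= 50:
                    cov = m2 / i * (2.38 ** 2 / d)
                chol = np.linalg.cholesky(
                    cov * math.exp(2.0 * log_scale) + 1e-9 * np.eye(d))
            else:
                proposals_post += 1
                accepted_post += int(accept)
                chains[c, i - n_burn] = theta
    acc = accepted_post / max(proposals_post, 1)
    warns = []
    if not 0.05 <= acc <= 0.8:
        warns.append(f"acceptance rate {acc:.3f} outside [0.05, 0.8]")
        warnings.warn(warns[-1])
    rhat_vals = _split_rhat(chains)
    rhat = dict(zip(PARAM_NAMES, rhat_vals))
    if np.any(rhat_vals > 1.1):
        warns.append(f"R-hat above 1.1: {rhat}")
        warnings.warn(warns[-1])
    nat = _natural(chains.reshape(-1, d))
    table = pd.DataFrame({
        "mean": nat.mean(axis=0),
        "median": np.median(nat, axis=0),
        "q2.5": np.percentile(nat, 2.5, axis=0),
        "q97.5": np.percentile(nat, 97.5, axis=0),
        "rhat": rhat_vals,
    }, index=list(PARAM_NAMES))
    return PosteriorSummary(table=table, acceptance_rate=acc, rhat=rhat,
                            chains=chains, warnings=warns)


def posterior_predictive_boundary(summary: PosteriorSummary, axis1: str,
                                  axis1_values, axis2: str, axis2_values,
                                  fixed: dict,
                                  config: LikelihoodConfig = LikelihoodConfig(),
                                  n_draws: int = 50, seed: int = 0,
                                  gamma: float = 1.0) -> pd.DataFrame:
    """Pointwise credible band of the phase boundary over posterior draws.

    For each of ``n_draws`` posterior draws the boundary is traced per
    scan line; per (axis2 value, crossing index) the 2.5/50/97.5 percentiles
    of the axis1 boundary coordinate are reported.
    """
    from .phase_diagram import axis_values as _axvals, boundary_trace

    rng = np.random.default_rng(seed)
    flat = summary.chains.reshape(-1, summary.chains.shape[-1])
    idx = rng.choice(flat.shape[0], size=min(n_draws, flat.shape[0]),
                     replace=False)
    v2 = _axvals(axis2, axis2_values)
    collected = {}
    for i in idx:
        k = theta_to_constants(flat[i], config)
        df = boundary_trace(axis1, axis1_values, axis2, v2, fixed, k,
                            gamma=gamma)
        for row in df.itertuples(index=False):
            key = (getattr(row, axis2), int(row.crossing))
            collected.setdefault(key, []).append(getattr(row, axis1))
    rows = []
    for (a2, crossing), vals in sorted(collected.items()):
        vals = np.asarray(vals)
        rows.append({
            axis2: a2, "crossing": crossing, "n_draws": len(vals),
            "q2.5": np.percentile(vals, 2.5),
            "median": np.percentile(vals, 50.0),
            "q97.5": np.percentile(vals, 97.5),
        })
    return pd.DataFrame(rows)
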