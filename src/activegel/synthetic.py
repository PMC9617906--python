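"""Synthetic data with known ground truth for every pipeline stage.

Three generators, all seed-deterministic:

* phase-diagram observation tables shaped like the four experimental panels
  (ATP x PRC1, motors x PRC1, ATP x motors, length x motors) with noisy
  blurriness readouts and wavelengths drawn around the model prediction of
  a known ("planted") kinetic parameter set;
* widefield-microscopy-like images of aligned filament bundles with a
  patch of known area fraction rendered out of focus, plus the exact
  binary ground-truth mask;
* image time series whose out-of-focus area follows logistic growth,
  emulating the rise of the blurriness coefficient during an instability.

The planted kinetic constants reproduce the qualitative experimental
anchors (re-entrant motor dependence at limiting ATP, crosslinker-dependent
softening threshold, activities of tens of Pa, wavelengths of tens of um);
see the methods note for how they were chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .kinetics import KineticConstants, _mechanics_arrays
from .mechanics import IN_PLANE, OUT_OF_PLANE

__all__ = [
    "TRUE_CONSTANTS", "GeneratorConfig", "default_panels",
    "generate_phase_observations", "generate_bundle_image",
    "generate_growth_series",
]

#: Planted ground-truth kinetic constants (zeta0/mu0 = 1600, K0/kappa0 =
#: 1000, kappa0/zeta0 = 0.3, p0 = 0.6; overall stress scale zeta0 = 1 Pa/nM).
TRUE_CONSTANTS = KineticConstants(
    zeta0=1.0, mu0=6.25e-4, kappa0=0.3, K0=300.0, p0=0.6,
    km=30.0, length_exponent=2.0,
)


def default_panels(n: int = 10) -> list[dict]:
    """The four experimental-style panels as (axes, fixed) grid specs.

    Fixed concentrations follow the published panel captions: motors 60 nM
    for the ATP x PRC1 panel, ATP 1 mM for motors x PRC1, PRC1 100 nM for
    ATP x motors, and ATP 8 uM / PRC1 100 nM for the length x motors panel.
    """
    return [
        {"axes": {"atp": (1.0, 1500.0, n, "log"),
                  "prc1": (10.0, 500.0, n, "lin")},
         "fixed": {"motors": 60.0, "mt_length": 1.5}},
        {"axes": {"motors": (5.0, 200.0, n, "lin"),
                  "prc1": (10.0, 500.0, n, "lin")},
         "fixed": {"atp": 1000.0, "mt_length": 1.5}},
        {"axes": {"atp": (1.0, 1500.0, n, "log"),
                  "motors": (5.0, 200.0, n, "lin")},
         "fixed": {"prc1": 100.0, "mt_length": 1.5}},
        {"axes": {"mt_length": (0.5, 10.0, n, "lin"),
                  "motors": (5.0, 200.0, n, "lin")},
         "fixed": {"atp": 8.0, "prc1": 100.0}},
    ]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-data generators (defaults = study conditions).

    ``b_in_mean``/``b_out_mean`` centre the Beta-distributed blurriness
    readouts of clearly in-plane / out-of-plane cells; ``mixed_band`` is the
    half-width in |log sigma-ratio| inside which cells read out in the mixed
    band; ``softness`` is the logistic steepness tying the mixed-band mean
    to the growth-rate contrast; ``sigma_lambda`` is the lognormal noise on
    observed wavelengths.
    """

    constants: KineticConstants = field(default_factory=lambda: TRUE_CONSTANTS)
    panels: list = field(default_factory=default_panels)
    b_in_mean: float = 0.02
    b_out_mean: float = 0.65
    b_concentration: float = 80.0
    mixed_band: float = 0.5
    softness: float = 5.0
    sigma_lambda: float = 0.2
    noise_scale: float = 1.0
    image_size: int = 512
    stripe_period: float = 12.0
    defocus_sigma: float = 8.0
    photons: float = 500.0
    seed: int = 0


def _beta_ab(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


def generate_phase_observations(cfg: GeneratorConfig | None = None,
                                seed: int | None = None,
                                n_replicates: int = 1) -> pd.DataFrame:
    """Observation table for all panels with planted-truth labels attached.

    Per cell and replicate the growth-rate contrast
    ``lr = log(sigma_h*/sigma_y*)`` under the planted constants decides the
    readout: clearly out-of-plane cells (lr > mixed_band) draw B from a Beta
    around ``b_out_mean``, clearly in-plane cells from a Beta around
    ``b_in_mean``, and near-boundary cells (|lr| < mixed_band) from the
    mixed band (0.05, 0.5] with mean sliding with the logistic of
    ``softness * lr`` — the "superposition" readout of a deformation with
    both components.  Wavelengths (winning-branch prediction with lognormal
    noise) are attached to clearly-classified cells.  With
    ``noise_scale = 0`` the readouts collapse onto the regime-typical means
    and every label matches the forward prediction exactly.

    Ground-truth columns: true_direction, true_log_ratio, true_lambda_um.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k = cfg.constants
    frames = []
    for panel_id, panel in enumerate(cfg.panels):
        from .phase_diagram import axis_values, _composition_fields

        (n1, s1), (n2, s2) = panel["axes"].items()
        v1 = axis_values(n1, s1)
        v2 = axis_values(n2, s2)
        a1, a2 = np.meshgrid(v1, v2, indexing="ij")
        atp, motors, prc1, L = _composition_fields(
            n1, a1.ravel(), n2, a2.ravel(), panel["fixed"])
        atp, motors, prc1, L = np.broadcast_arrays(atp, motors, prc1, L)
        zeta, mu, kappa, K = _mechanics_arrays(atp, motors, prc1, L, k)
        with np.errstate(divide="ignore", invalid="ignore"):
            sig_y = np.where(zeta > mu, (zeta - mu) ** 2 / (4.0 * K), 0.0)
            sig_h = zeta ** 2 / (4.0 * (K + kappa))
            lr = np.where(sig_y > 0, np.log(sig_h / np.where(sig_y > 0,
                                                             sig_y, 1.0)),
                          np.inf)
            lam_in = 2.0 * np.pi * np.sqrt(2.0 * K /
                                           np.where(zeta > mu, zeta - mu, 1.0))
            lam_out = 2.0 * np.pi * np.sqrt(2.0 * (K + kappa) / zeta)
        direction = np.where(sig_h >= sig_y, OUT_OF_PLANE, IN_PLANE)
        lam_true = np.where(direction == IN_PLANE, lam_in, lam_out)

        for rep in range(n_replicates):
            b = np.empty(lr.shape)
            mixed = np.abs(lr) < cfg.mixed_band
            out_clear = (~mixed) & (lr > 0)
            in_clear = (~mixed) & (lr <= 0)
            if cfg.noise_scale == 0:
                b[out_clear] = cfg.b_out_mean
                b[in_clear] = cfg.b_in_mean
                b[mixed] = np.where(lr[mixed] > 0, cfg.b_out_mean,
                                    cfg.b_in_mean)
            else:
                conc = cfg.b_concentration / cfg.noise_scale
                a_o, b_o = _beta_ab(cfg.b_out_mean, conc)
                b[out_clear] = rng.beta(a_o, b_o, size=out_clear.sum())
                a_i, b_i = _beta_ab(cfg.b_in_mean, conc)
                b[in_clear] = rng.beta(a_i, b_i, size=in_clear.sum())
                # mixed band (0.05, 0.5]: mean slides with the logistic of
                # the growth-rate contrast, matching the direction channel
                # the fitter assumes.
                pos = 1.0 / (1.0 + np.exp(-cfg.softness * lr[mixed]))
                pos = np.clip(pos, 0.05, 0.95)
                mb = rng.beta(pos * 12.0, (1.0 - pos) * 12.0)
                b[mixed] = 0.05 + 0.45 * mb
            lam_obs = np.where(
                mixed, np.nan,
                lam_true * np.exp(rng.normal(0.0, cfg.sigma_lambda,
                                             size=lam_true.shape)
                                  * (cfg.noise_scale > 0)))
            frames.append(pd.DataFrame({
                "panel": panel_id, "replicate": rep,
                "atp_uM": atp, "motors_nM": motors, "prc1_nM": prc1,
                "mt_length_um": L, "B": np.clip(b, 0.0, 1.0),
                "lambda_um": lam_obs,
                "true_direction": direction, "true_log_ratio": lr,
                "true_lambda_um": lam_true,
            }))
    return pd.concat(frames, ignore_index=True)


def _ellipse_mask(shape, fraction, rng) -> np.ndarray:
    """Random smooth region of exactly the requested area fraction.

    A randomly placed/oriented ellipse of analytic area fraction*H*W (or the
    complement of one of area (1-fraction)*H*W when fraction > 0.5), kept
    fully inside the frame so the rasterised area matches the request to
    well under 1%.
    """
    H, W = shape
    if fraction <= 0.0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1.0:
        return np.ones(shape, dtype=bool)
    invert = fraction > 0.5
    area = (1.0 - fraction if invert else fraction) * H * W
    r = np.sqrt(area / np.pi)
    s = rng.uniform(0.85, 1.18)
    a, b = r * s, r / s
    theta = rng.uniform(0.0, np.pi)
    # bounding half-widths of the rotated ellipse
    bx = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    by = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    cx = rng.uniform(bx, W - bx) if W > 2 * bx else W / 2.0
    cy = rng.uniform(by, H - by) if H > 2 * by else H / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    return ~inside if invert else inside


def _bundle_texture(size: int, stripe_period: float,
                    rng) -> np.ndarray:
    """Aligned-bundle texture: wavy stripes plus multi-scale cloud noise."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    warp = ndimage.gaussian_filter(rng.normal(size=(size, size)), 25.0)
    warp *= 8.0 / max(warp.std(), 1e-12)
    phase = 2.0 * np.pi * (yy + warp) / stripe_period
    stripes = np.sin(phase + rng.uniform(0, 2 * np.pi))
    cloud = ndimage.gaussian_filter(rng.normal(size=(size, size)), 20.0)
    cloud /= max(cloud.std(), 1e-12)
    fine = ndimage.gaussian_filter(rng.normal(size=(size, size)), 2.0)
    fine /= max(fine.std(), 1e-12)
    img = 0.55 + 0.22 * stripes + 0.12 * cloud + 0.06 * fine
    return np.clip(img, 0.02, None)


def generate_bundle_image(blurred_fraction: float, seed: int,
                          size: int = 512, stripe_period: float = 12.0,
                          defocus_sigma: float = 8.0,
                          photons: float = 500.0):
    """Microscopy-like image with a defocused patch of known area fraction.

    Returns ``(image, mask)`` where ``mask`` is the exact binary
    ground-truth out-of-focus region (area fraction within 0.01 of the
    request).  The patch is the image convolved with a Gaussian defocus
    kernel, composited with a feathered edge; Poisson shot noise at the
    given photon budget is applied to the whole frame.
    """
    if not 0.0 <= blurred_fraction <= 1.0:
        raise ValueError("blurred_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sharp = _bundle_texture(size, stripe_period, rng)
    mask = _ellipse_mask((size, size), blurred_fraction, rng)
    blurred = ndimage.gaussian_filter(sharp, defocus_sigma)
    feather = ndimage.gaussian_filter(mask.astype(float), 2.0)
    img = feather * blurred + (1.0 - feather) * sharp
    if photons > 0:
        img = rng.poisson(img * photons) / photons
    return img, mask


def generate_growth_series(n_frames: int = 8, a_max: float = 0.6,
                           t0: float = 4.0, tau: float = 1.5,
                           seed: int = 0, size: int = 256,
                           stripe_period: float = 12.0,
                           defocus_sigma: float = 8.0,
                           photons: float = 500.0):
    """Image stack whose out-of-focus area grows logistically in time.

    ``a(t) = a_max / (1 + exp(-(t - t0)/tau))`` with frames at t = 0..n-1.
    All frames share one texture and one (nested, growing) defocus region,
    so the ground-truth blurred fraction is monotone non-decreasing.
    Returns ``(stack, times, fractions)``.
    """
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    times = np.arange(n_frames, dtype=float)
    fractions = a_max / (1.0 + np.exp(-(times - t0) / tau))
    rng = np.random.default_rng(seed)
    sharp = _bundle_texture(size, stripe_period, rng)
    blurred = ndimage.gaussian_filter(sharp, defocus_sigma)
    # one fixed centre/orientation; the area grows => nested masks
    s = rng.uniform(0.85, 1.18)
    theta = rng.uniform(0.0, np.pi)
    cy, cx = size / 2.0 + rng.uniform(-size / 8, size / 8, size=2)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    ellipse_r2 = (xr / s) ** 2 + (yr * s) ** 2
    frames = []
    noise_rng = np.random.default_rng(seed + 1)
    for frac in fractions:
        if frac <= 0:
            mask = np.zeros((size, size), dtype=bool)
        else:
            # quantile cut of the elliptic distance gives the exact area
            # fraction even when the region hits the frame edge
            mask = ellipse_r2 <= np.quantile(ellipse_r2, frac)
        feather = ndimage.gaussian_filter(mask.astype(float), 2.0)
        img = feather * blurred + (1.0 - feather) * sharp
        if photons > 0:
            img = noise_rng.poisson(img * photons) / photons
        frames.append(img)
    return np.stack(frames), times, fractions
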