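"""Synthetic 450k-style beta matrices with known purity and DMC truth.

The generator emulates the data-generating model the estimators
assume.  On the arcsine scale each site has a baseline mean m_i drawn
from a bimodal distribution (real methylomes concentrate near beta 0.1
and 0.9); a fraction of sites are true DMCs carrying a cancer-normal
effect delta_is ~ N(mu_i, tau^2), with the sign of mu_i negatively
correlated with the baseline (hyper-methylated sites tend to start
low, hypo-methylated sites high).  Each tumor sample has a purity
lambda_s; its observed signal is the cell mixture
Y'_is = (1 - lambda_s) X_is + lambda_s (X_is + delta_is).  By default
the mixing happens on the beta scale (the physically literal reading:
fluorescence fractions average over cells); a flag switches to mixing
on the transformed scale, under which the downstream linear model is
exact.  Normal samples are X_is alone.  All emitted beta values are
clamped to [0, 1] (clamp events are logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dm import arcsine_transform, inverse_arcsine
from .io import BetaMatrix, SampleGroups

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "SynthTruth", "generate", "idmc_grade_config"]

_HALF_PI = np.pi / 2


@dataclass
class SynthConfig:
    """Parameters of the synthetic methylome generator.

    Scales: ``effect_mean``, ``effect_sample_sd`` and ``noise_sd`` are
    on the arcsine-transformed scale (radians); purities and beta
    values are fractions.

    - ``n_sites`` / ``n_tumor`` / ``n_normal``: matrix dimensions.
    - ``frac_dmc``: fraction of sites carrying a true effect.
    - ``effect_mean``: magnitude of the per-site mean effect mu_i at
      DMC sites (signed by the drawn direction).
    - ``effect_sample_sd``: tau, the per-sample spread of delta_is
      around mu_i (biological effect heterogeneity at DMC sites).
    - ``purity_low`` / ``purity_high``: lambda ~ Uniform bounds.
    - ``noise_sd``: technical noise on the transformed scale.
    - ``x_delta_corr``: target correlation between baseline and effect
      sign; negative by default (lowly methylated sites gain, highly
      methylated sites lose methylation).
    - ``baseline_shapes``: Beta-distribution shape pairs of the two
      baseline components (modes near beta 0.1 and 0.9 by default).
    - ``mixing``: 'beta' (mixture of beta values over cells) or
      'transformed' (mixture on the arcsine scale).
    """

    n_sites: int = 2000
    n_tumor: int = 50
    n_normal: int = 20
    frac_dmc: float = 0.1
    effect_mean: float = 0.5
    effect_sample_sd: float = 0.2
    purity_low: float = 0.3
    purity_high: float = 0.9
    noise_sd: float = 0.25
    x_delta_corr: float = -0.3
    baseline_shapes: tuple = ((3.0, 20.0), (20.0, 3.0))
    mixing: str = "beta"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_dmc <= 1.0:
            raise ValueError(f"frac_dmc must be in [0, 1], got {self.frac_dmc}")
        if not (0.0 < self.purity_low <= self.purity_high <= 1.0):
            raise ValueError("need 0 < purity_low <= purity_high <= 1")
        if self.noise_sd < 0 or self.effect_sample_sd < 0:
            raise ValueError("noise_sd and effect_sample_sd must be >= 0")
        if not -1.0 <= self.x_delta_corr <= 1.0:
            raise ValueError("x_delta_corr must be in [-1, 1]")
        if self.mixing not in ("beta", "transformed"):
            raise ValueError(f"mixing must be 'beta' or 'transformed', got {self.mixing!r}")
        if min(self.n_sites, self.n_tumor, self.n_normal) < 0:
            raise ValueError("dimensions must be nonnegative")


@dataclass
class SynthTruth:
    """Ground truth emitted alongside a synthetic matrix.

    ``purity``: Series over tumor sample ids with the true lambda_s.
    ``sites``: DataFrame (site_id, is_dmc, mu, direction) with mu on
    the transformed scale and direction in {hyper, hypo, ''}.
    """

    purity: pd.Series
    sites: pd.DataFrame


def idmc_grade_config(**overrides) -> SynthConfig:
    """Config whose DMC sites look like selected purity markers.

    Real iDMCs are the extreme tail of the differential signal: normal
    beta near 0.1 (or 0.9) and near-complete methylation change in the
    pure tumor, so the observed tumor beta tracks the purity almost
    directly.  ``effect_mean`` = 2.2 on the arcsine scale moves a
    baseline at beta 0.1 to about 0.97 in the pure cancer methylome.
    The direction is almost deterministic given the baseline
    (``x_delta_corr`` = -0.9): marker-grade sites gain methylation from
    a low baseline or lose it from a high one, which keeps the pure
    cancer value away from the baseline's own boundary.
    """
    defaults = dict(effect_mean=2.2, effect_sample_sd=0.2, x_delta_corr=-0.9)
    defaults.update(overrides)
    return SynthConfig(**defaults)


def _draw_baseline(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    comp = rng.integers(0, len(cfg.baseline_shapes), size=cfg.n_sites)
    b = np.empty(cfg.n_sites)
    for k, (a, bb) in enumerate(cfg.baseline_shapes):
        mask = comp == k
        b[mask] = rng.beta(a, bb, size=int(mask.sum()))
    return arcsine_transform(b)


def _draw_directions(rng: np.random.Generator, m_dmc: np.ndarray, corr: float) -> np.ndarray:
    """Signs of mu_i with baseline-dependent probabilities.

    P(hyper) = clip(0.5 + corr * z_i / 2, 0.02, 0.98) with z_i the
    standardized baseline: a negative ``corr`` makes high-baseline
    sites lean hypo, reproducing the negative baseline-effect
    correlation seen in tumor methylomes.
    """
    if m_dmc.size == 0:
        return np.empty(0)
    sd = m_dmc.std()
    z = (m_dmc - m_dmc.mean()) / sd if sd > 0 else np.zeros_like(m_dmc)
    p_hyper = np.clip(0.5 + corr * z / 2.0, 0.02, 0.98)
    return np.where(rng.random(m_dmc.size) < p_hyper, 1.0, -1.0)


def _clamp_transformed(t: np.ndarray, what: str) -> np.ndarray:
    n_clamped = int(np.sum((t < -_HALF_PI) | (t > _HALF_PI)))
    if n_clamped:
        logger.info("generate: clamped %d %s value(s) to the transformed range", n_clamped, what)
    return np.clip(t, -_HALF_PI, _HALF_PI)


def generate(config: SynthConfig) -> tuple[BetaMatrix, SampleGroups, SynthTruth]:
    """Draw one synthetic dataset; bit-identical for a fixed config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    site_ids = [f"cg{i:06d}" for i in range(cfg.n_sites)]
    tumor_ids = [f"T{i:03d}" for i in range(cfg.n_tumor)]
    normal_ids = [f"N{i:03d}" for i in range(cfg.n_normal)]

    m = _draw_baseline(rng, cfg)

    n_dmc = int(round(cfg.frac_dmc * cfg.n_sites))
    dmc_idx = rng.choice(cfg.n_sites, size=n_dmc, replace=False)
    is_dmc = np.zeros(cfg.n_sites, dtype=bool)
    is_dmc[dmc_idx] = True
    sign = np.zeros(cfg.n_sites)
    sign[dmc_idx] = _draw_directions(rng, m[dmc_idx], cfg.x_delta_corr)
    mu = sign * cfg.effect_mean

    lam = rng.uniform(cfg.purity_low, cfg.purity_high, size=cfg.n_tumor)

    # normal samples: X_is = m_i + technical noise (rng.normal with sd=0 is exact zero)
    eps_n = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_sites, cfg.n_normal))
    x_normal = _clamp_transformed(m[:, None] + eps_n, "normal")

    # tumor samples: shared normal-cell realization X_is plus delta_is at DMC sites
    eps_t = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_sites, cfg.n_tumor))
    t_x = m[:, None] + eps_t
    delta = np.zeros((cfg.n_sites, cfg.n_tumor))
    if n_dmc:
        jitter = rng.normal(0.0, cfg.effect_sample_sd, size=(n_dmc, cfg.n_tumor))
        delta[dmc_idx] = mu[dmc_idx, None] + jitter

    if cfg.mixing == "beta":
        x_beta = inverse_arcsine(_clamp_transformed(t_x, "tumor baseline"))
        y_beta = inverse_arcsine(_clamp_transformed(t_x + delta, "pure tumor"))
        tumor_beta = (1.0 - lam[None, :]) * x_beta + lam[None, :] * y_beta
    else:
        tumor_beta = inverse_arcsine(_clamp_transformed(t_x + lam[None, :] * delta, "tumor"))

    values = np.concatenate([tumor_beta, inverse_arcsine(x_normal)], axis=1)
    df = pd.DataFrame(values, index=site_ids, columns=tumor_ids + normal_ids)
    beta = BetaMatrix(df)
    groups = SampleGroups(tumor_ids=tumor_ids, normal_ids=normal_ids)
    truth = SynthTruth(
        purity=pd.Series(lam, index=tumor_ids, name="purity"),
        sites=pd.DataFrame(
            {
                "site_id": site_ids,
                "is_dmc": is_dmc,
                "mu": mu,
                "direction": np.where(~is_dmc, "", np.where(sign > 0, "hyper", "hypo")),
            }
        ),
    )
    return beta, groups, truth
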