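"""Control-free differential methylation detection.

Without normal controls the purity itself carries the contrast: on the
arcsine scale an observed tumor value at site i is
Y'_is ~ N(m_i + lambda_s mu_i, sigma'^2), so across tumor samples the
cancer-normal difference mu_i is the slope of a simple linear
regression of Y'_is on the purities lambda_s.  The slope t statistic
is algebraically identical to the Pearson-correlation test statistic
r sqrt((n1 - 2) / (1 - r^2)).

Sites are ranked by the posterior probability Pr(|mu_i| > c) under the
plug-in posterior mu_i ~ N(mu-hat, se^2); the threshold c (default
0.1, on the transformed scale) demotes sites whose statistic is large
only because the standard error is tiny.  c = 0 makes the probability
1 everywhere and the ranking falls back to |t| — equivalently |r|.
This mode needs dispersed purities and a reasonable number of tumor
samples (> 20 recommended).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dm import arcsine_transform
from .io import BetaMatrix, PurityTable

logger = logging.getLogger(__name__)

__all__ = ["regress_on_purity", "posterior_prob", "call_dm_control_free"]

DEFAULT_EFFECT_THRESHOLD = 0.1
DEFAULT_DISPERSION_FLOOR = 0.05
RECOMMENDED_MIN_SAMPLES = 20
MIN_SAMPLES = 4


def regress_on_purity(y: np.ndarray, lambdas: np.ndarray):
    """Per-site OLS of transformed tumor values on (1, lambda).

    ``y`` is (n1,) or (M, n1).  Returns ``(mu_hat, se_mu, t_stat,
    pearson_r)`` arrays: slope, its standard error on n1 - 2 residual
    df, the slope t statistic, and the Pearson correlation of y with
    the purities.  Constant y gives t = 0, r = 0; an exactly linear y
    gives zero residuals and an infinite t (guarded, r = +/-1).
    """
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    y = np.atleast_2d(y)
    lam = np.asarray(lambdas, dtype=float)
    n = lam.size
    if y.shape[1] != n:
        raise ValueError(f"y has {y.shape[1]} values but {n} purities given")
    if n < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} tumor samples, got {n}")
    sxx = np.sum((lam - lam.mean()) ** 2)
    if sxx == 0:
        raise ValueError("purity dispersion insufficient: all purities equal")
    lc = lam - lam.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    mu_hat = (yc @ lc) / sxx
    resid = yc - mu_hat[:, None] * lc[None, :]
    rss = (resid**2).sum(axis=1)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mu_hat / np.where(se > 0, se, 1.0), np.sign(mu_hat) * np.inf)
        t = np.where((se <= 0) & (mu_hat == 0), 0.0, t)
        syy = (yc**2).sum(axis=1)
        r = np.where(syy > 0, (yc @ lc) / np.sqrt(sxx * np.where(syy > 0, syy, 1.0)), 0.0)
    if squeeze:
        return float(mu_hat[0]), float(se[0]), float(t[0]), float(r[0])
    return mu_hat, se, t, r


def posterior_prob(mu_hat, se_mu, c: float = DEFAULT_EFFECT_THRESHOLD) -> np.ndarray:
    """Pr(|mu| > c) under the plug-in posterior mu ~ N(mu-hat, se^2).

    Equals Phi((-c - mu-hat)/se) + 1 - Phi((c - mu-hat)/se).  At c = 0
    this is identically 1, so rankings at c = 0 must fall back to the
    test statistic.
    """
    mu_hat = np.asarray(mu_hat, dtype=float)
    se_mu = np.asarray(se_mu, dtype=float)
    if c < 0:
        raise ValueError(f"effect threshold c must be >= 0, got {c}")
    if np.any(se_mu <= 0):
        raise ValueError("posterior_prob requires se_mu > 0")
    if c == 0:
        # Phi(-x) + 1 - Phi(-x) is identically 1; return it exactly so
        # rankings at c = 0 degrade cleanly to the tie-break statistic
        return np.ones_like(mu_hat)
    return stats.norm.cdf((-c - mu_hat) / se_mu) + stats.norm.sf((c - mu_hat) / se_mu)


def call_dm_control_free(
    beta: BetaMatrix,
    tumor_ids,
    purity: PurityTable,
    c: float = DEFAULT_EFFECT_THRESHOLD,
    dispersion_floor: float = DEFAULT_DISPERSION_FLOOR,
    emit_p: bool = False,
) -> pd.DataFrame:
    """Rank CpG sites by evidence of differential methylation, tumors only.

    Tumor columns are arcsine-transformed, each site regressed on the
    purities, and sites ranked descending by Pr(|mu| > c) with |t| as
    tie-break.  Errors below 4 samples or when sd(lambda) is under
    ``dispersion_floor``; warns below 20 samples.  ``emit_p`` adds a
    two-sided t(n1 - 2) p-value column.

    Returns a DataFrame with columns site_id, mu_hat, se, t, pearson_r,
    post_prob, rank (and p if requested).
    """
    tumor_ids = list(tumor_ids)
    n1 = len(tumor_ids)
    if n1 < MIN_SAMPLES:
        raise ValueError(f"control-free calling needs >= {MIN_SAMPLES} tumor samples, got {n1}")
    if n1 < RECOMMENDED_MIN_SAMPLES:
        warnings.warn(
            f"only {n1} tumor samples; control-free calling is recommended "
            f"with more than {RECOMMENDED_MIN_SAMPLES}",
            stacklevel=2,
        )
    lam = purity.for_samples(tumor_ids)
    if lam.std(ddof=1) < dispersion_floor:
        raise ValueError(
            f"purity dispersion insufficient: sd(lambda) = {lam.std(ddof=1):.4f} "
            f"< floor {dispersion_floor}"
        )
    data = beta.subset_samples(tumor_ids)
    complete = data.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("call_dm_control_free: dropped %d site(s) with missing values", n_dropped)
    data = data.loc[complete]
    if data.empty:
        raise ValueError("no complete-case sites to test")

    z = arcsine_transform(data.to_numpy())
    mu_hat, se, t, r = regress_on_purity(z, lam)
    # zero-residual sites have se = 0; give them probability 1 (effect known exactly
    # up to the model) when |mu| > c, else 0
    ok = se > 0
    post = np.empty_like(mu_hat)
    post[ok] = posterior_prob(mu_hat[ok], se[ok], c)
    post[~ok] = (np.abs(mu_hat[~ok]) > c).astype(float)

    out = pd.DataFrame(
        {
            "site_id": data.index,
            "mu_hat": mu_hat,
            "se": se,
            "t": t,
            "pearson_r": r,
            "post_prob": post,
        }
    )
    if emit_p:
        finite_t = np.where(np.isfinite(t), t, np.sign(t) * 1e308)
        out["p"] = 2.0 * stats.t.sf(np.abs(finite_t), n1 - 2)
    out = out.sort_values(
        by=["post_prob", "t", "site_id"],
        key=lambda s: -s if s.name == "post_prob" else (-s.abs() if s.name == "t" else s),
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
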