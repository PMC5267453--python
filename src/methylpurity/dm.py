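"""Purity-aware differential methylation calling with normal controls.

Model.  Beta values are mapped through the variance-stabilizing
arcsine transform f(x) = arcsin(2x - 1).  On that scale a normal
sample at site i is X_i ~ N(m_i, sigma_i^2) and a *pure* cancer sample
would be Y_i = X_i + delta_i with E[delta_i] = mu_i.  An observed
tumor sample s with purity lambda_s is the mixture
Y'_is = (1 - lambda_s) X_is + lambda_s Y_is = X_is + lambda_s delta_is,
so the purity acts multiplicatively on the cancer-normal difference:
E[Y'_is] = m_i + lambda_s mu_i.  Stacking normals first, the site-wise
linear model is Z = W beta + eps with W a (n0 + n1) x 2 design whose
first column is all ones and second column is 0 for normals and
lambda_s for tumors, beta = (m_i, mu_i).

Estimation is by the normal equation beta-hat = (W'W)^-1 W'Z = HZ with
a group-heteroscedastic covariance var(beta-hat) = H1 Sigma H1' +
H2 Sigma' H2', Sigma = sigma^2 I_{n0}, Sigma' = sigma'^2 I_{n1}.
Residual variances use the denominators n0 - 2 and n1 - 2 and are
stabilized across sites by log-scale shrinkage toward their geometric
mean.  H0: mu_i = 0 is tested by the Wald statistic
t = mu-hat / se(mu-hat) against a t distribution with n0 + n1 - 2
degrees of freedom, followed by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, PurityTable, SampleGroups

logger = logging.getLogger(__name__)

__all__ = [
    "DMModelFit",
    "arcsine_transform",
    "build_design",
    "fit_site",
    "shrink_variances",
    "wald_test",
    "call_dm",
]

DEFAULT_SHRINK_WEIGHT = 0.2
_VAR_FLOOR = np.finfo(float).tiny


def arcsine_transform(beta) -> np.ndarray:
    """Elementwise arcsin(2v - 1); maps [0, 1] to [-pi/2, pi/2]."""
    if isinstance(beta, BetaMatrix):
        v = beta.values.to_numpy()
    else:
        v = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.arcsin(2.0 * v - 1.0)
    bad = np.isnan(out) & ~np.isnan(v)
    if np.any(bad):
        raise ValueError("values outside [0, 1] cannot be arcsine-transformed")
    return out


def inverse_arcsine(t) -> np.ndarray:
    """Inverse of the arcsine transform: (sin(t) + 1) / 2."""
    return (np.sin(np.asarray(t, dtype=float)) + 1.0) / 2.0


def build_design(groups: SampleGroups, purity: PurityTable) -> tuple[np.ndarray, list]:
    """Design matrix W and the stacked sample order (normals, tumors).

    W has a leading all-ones column; the second column is 0 for the n0
    normal samples and lambda_s for the n1 tumor samples.
    """
    lam = purity.for_samples(groups.tumor_ids)
    n0, n1 = groups.n_normal, groups.n_tumor
    w = np.zeros((n0 + n1, 2))
    w[:, 0] = 1.0
    w[n0:, 1] = lam
    order = list(groups.normal_ids) + list(groups.tumor_ids)
    if n0 == 0 and np.ptp(lam) == 0:
        raise ValueError("design is rank deficient: no normals and constant purity")
    return w, order


@dataclass
class DMModelFit:
    """Per-site fit of the purity design (arrays over sites)."""

    m_hat: np.ndarray
    mu_hat: np.ndarray
    sigma2: np.ndarray
    sigma2_prime: np.ndarray
    q_normal: float  # (H1 H1')[mu, mu]: normal-variance multiplier of var(mu-hat)
    q_tumor: float  # (H2 H2')[mu, mu]
    n0: int
    n1: int

    def se_mu(self, sigma2=None, sigma2_prime=None) -> np.ndarray:
        """Standard error of mu-hat, optionally from shrunken variances."""
        s2 = self.sigma2 if sigma2 is None else sigma2
        s2p = self.sigma2_prime if sigma2_prime is None else sigma2_prime
        return np.sqrt(self.q_normal * s2 + self.q_tumor * s2p)


def _hat_matrix(w: np.ndarray) -> np.ndarray:
    wtw = w.T @ w
    if np.linalg.matrix_rank(wtw) < 2:
        raise ValueError("design matrix is rank deficient")
    return np.linalg.solve(wtw, w.T)


def fit_site(z: np.ndarray, w: np.ndarray, n0: int, n1: int) -> DMModelFit:
    """Fit the purity linear model for one or many sites.

    ``z`` is (n0 + n1,) or (M, n0 + n1) in design order (normals
    first).  Returns pre-shrinkage estimates; the group residual
    variances use denominators n0 - 2 and n1 - 2, hence both groups
    need more than 2 samples.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != n0 + n1:
        raise ValueError(f"z has {z.shape[1]} values, expected n0 + n1 = {n0 + n1}")
    if n0 <= 2 or n1 <= 2:
        raise ValueError("fit requires n0 > 2 and n1 > 2 (variance denominators n0-2, n1-2)")
    h = _hat_matrix(w)
    beta = z @ h.T  # (M, 2)
    resid = z - beta @ w.T
    sigma2 = (resid[:, :n0] ** 2).sum(axis=1) / (n0 - 2)
    sigma2_prime = (resid[:, n0:] ** 2).sum(axis=1) / (n1 - 2)
    h1, h2 = h[:, :n0], h[:, n0:]
    q_normal = float((h1 @ h1.T)[1, 1])
    q_tumor = float((h2 @ h2.T)[1, 1])
    return DMModelFit(
        m_hat=beta[:, 0],
        mu_hat=beta[:, 1],
        sigma2=sigma2,
        sigma2_prime=sigma2_prime,
        q_normal=q_normal,
        q_tumor=q_tumor,
        n0=n0,
        n1=n1,
    )


def shrink_variances(variances: np.ndarray, weight: float = DEFAULT_SHRINK_WEIGHT) -> np.ndarray:
    """Shrink a vector of variances toward their geometric mean.

    On the log scale: sigma-tilde^2 = exp((1 - w) log sigma-hat^2 + w g)
    with g the mean log variance.  w = 0 is the identity, w = 1
    collapses every entry to the geometric mean.  Zero variances are
    floored at machine-scale epsilon before taking logs.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"shrinkage weight must be in [0, 1], got {weight}")
    v = np.asarray(variances, dtype=float)
    if np.any(v < 0):
        raise ValueError("variances must be nonnegative")
    n_floored = int((v < _VAR_FLOOR).sum())
    if n_floored:
        logger.info("shrink_variances: floored %d zero variance(s)", n_floored)
    logv = np.log(np.maximum(v, _VAR_FLOOR))
    g = logv.mean()
    return np.exp((1.0 - weight) * logv + weight * g)


def wald_test(mu_hat: np.ndarray, se_mu: np.ndarray, n0: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Wald statistic t = mu-hat / se and two-sided t(n0+n1-2) p-value.

    Degenerate sites (se = 0) get p = 1 when mu-hat = 0 and p = 0
    otherwise, with a log warning.
    """
    mu_hat = np.asarray(mu_hat, dtype=float)
    se_mu = np.asarray(se_mu, dtype=float)
    df = n0 + n1 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_mu > 0, mu_hat / np.where(se_mu > 0, se_mu, 1.0), np.where(mu_hat == 0, 0.0, np.inf * np.sign(mu_hat)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degen = se_mu <= 0
    if np.any(degen):
        logger.warning("wald_test: %d degenerate site(s) with zero standard error", int(degen.sum()))
        p = np.where(degen, np.where(mu_hat == 0, 1.0, 0.0), p)
    return t, p


def call_dm(
    beta: BetaMatrix,
    groups: SampleGroups,
    purity: PurityTable,
    shrink_weight: float = DEFAULT_SHRINK_WEIGHT,
) -> pd.DataFrame:
    """Genome-wide purity-aware DM calling against normal controls.

    Pipeline per site: arcsine transform -> normal-equation fit ->
    log-scale variance shrinkage (separately for the normal and tumor
    pools) -> Wald t test with n0 + n1 - 2 df -> Benjamini-Hochberg
    FDR over all tested sites.  Sites with missing values among the
    used samples are dropped (complete case) and reported in the log.

    Returns a DataFrame with columns site_id, m_hat, mu_hat, se, t,
    df, p, fdr, flag ('' or 'degenerate').
    """
    groups.validate_against(beta)
    w, order = build_design(groups, purity)
    data = beta.subset_samples(order)
    complete = data.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("call_dm: dropped %d site(s) with missing values", n_dropped)
    data = data.loc[complete]
    if data.empty:
        raise ValueError("no complete-case sites to test")

    z = arcsine_transform(data.to_numpy())
    n0, n1 = groups.n_normal, groups.n_tumor
    fit = fit_site(z, w, n0, n1)
    s2 = shrink_variances(fit.sigma2, shrink_weight)
    s2p = shrink_variances(fit.sigma2_prime, shrink_weight)
    se = fit.se_mu(s2, s2p)
    t, p = wald_test(fit.mu_hat, se, n0, n1)
    fdr = multipletests(p, method="fdr_bh")[1]
    flag = np.where(se <= 0, "degenerate", "")
    return pd.DataFrame(
        {
            "site_id": data.index,
            "m_hat": fit.m_hat,
            "mu_hat": fit.mu_hat,
            "se": se,
            "t": t,
            "df": n0 + n1 - 2,
            "p": p,
            "fdr": fdr,
            "flag": flag,
        }
    ).reset_index(drop=True)
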