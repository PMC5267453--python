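"""Selection of informative differentially methylated CpGs (iDMCs).

iDMCs are the purity markers: CpG sites with a large, reliable
tumor-vs-normal methylation difference.  They are found by a two-sided
Wilcoxon rank-sum test per site, a tumor-variance filter (var > 0.005
by default, so that the site actually responds to varying tumor
content), and keeping the ``n_top`` sites with smallest p-values
(1000 by default).  Each retained site is labelled *hyper* when its
mean tumor beta exceeds the mean control beta, else *hypo*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, SampleGroups

logger = logging.getLogger(__name__)

__all__ = ["IDMCSet", "rank_sum_test", "select_idmcs"]

DEFAULT_N_TOP = 1000
DEFAULT_VAR_MIN = 0.005


@dataclass
class IDMCSet:
    """Selected iDMCs, ranked by ascending rank-sum p-value.

    ``table`` columns: site_id, direction ('hyper'/'hypo'), statistic
    (signed z of group A vs B), rank_sum_p, tumor_var, rank (1..N).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"site_id", "direction", "statistic", "rank_sum_p", "tumor_var", "rank"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"IDMCSet table missing column(s): {sorted(missing)}")
        if self.table["site_id"].duplicated().any():
            raise ValueError("duplicate site ids in iDMC set")
        bad_dir = set(self.table["direction"]) - {"hyper", "hypo"}
        if bad_dir:
            raise ValueError(f"invalid direction(s): {sorted(bad_dir)}")
        ranks = np.sort(self.table["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.table) + 1)):
            raise ValueError("ranks must be a permutation of 1..N")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def site_ids(self) -> pd.Index:
        return pd.Index(self.table["site_id"])

    @property
    def directions(self) -> pd.Series:
        return self.table.set_index("site_id")["direction"]

    @classmethod
    def from_directions(cls, site_ids, directions) -> "IDMCSet":
        """Build a set from a user-supplied (site, direction) list.

        Statistic/p columns are filled with NaN; ranks follow input order.
        """
        n = len(site_ids)
        return cls(
            pd.DataFrame(
                {
                    "site_id": list(site_ids),
                    "direction": list(directions),
                    "statistic": np.full(n, np.nan),
                    "rank_sum_p": np.full(n, np.nan),
                    "tumor_var": np.full(n, np.nan),
                    "rank": np.arange(1, n + 1),
                }
            )
        )


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided rank-sum z and p for row-wise groups.

    ``x``: (M, nx), ``y``: (M, ny).  Normal approximation with tie
    correction and a 0.5 continuity correction; rows where all values
    tie across both groups get z = 0, p = 1.
    """
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    nx, ny = x.shape[1], y.shape[1]
    n = nx + ny
    pooled = np.concatenate([x, y], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    w = ranks[:, :nx].sum(axis=1)  # rank sum of group A
    mean_w = nx * (n + 1) / 2.0

    # tie correction: sum over tie groups of (t^3 - t)
    srt = np.sort(pooled, axis=1)
    new_group = np.ones_like(srt, dtype=bool)
    new_group[:, 1:] = srt[:, 1:] != srt[:, :-1]
    run_id = np.cumsum(new_group, axis=1)
    tie_sum = np.zeros(pooled.shape[0])
    for r in range(pooled.shape[0]):
        _, counts = np.unique(run_id[r], return_counts=True)
        t = counts.astype(float)
        tie_sum[r] = np.sum(t**3 - t)
    var_w = nx * ny / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))

    d = w - mean_w
    cc = np.sign(d) * 0.5  # continuity correction toward the mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var_w > 0, (d - cc) / np.sqrt(var_w), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(var_w > 0, np.minimum(p, 1.0), 1.0)
    return z, p


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of group A (``x``) vs B (``y``).

    Returns ``(statistic, p_value)`` where the statistic is the signed
    normal-approximation z (tie-corrected, continuity-corrected) of the
    rank sum of ``x``.  Degenerate input (all values tied across both
    groups) yields p = 1 with a log message.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("rank_sum_test requires at least 2 values per group")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("rank_sum_test does not accept missing values")
    z, p = _ranksum_z(x[None, :], y[None, :])
    if np.all(np.concatenate([x, y]) == x[0]):
        logger.info("rank_sum_test: all values tied; degenerate p = 1")
    return float(z[0]), float(p[0])


def select_idmcs(
    beta: BetaMatrix,
    groups: SampleGroups,
    n_top: int = DEFAULT_N_TOP,
    var_min: float = DEFAULT_VAR_MIN,
) -> IDMCSet:
    """Select iDMCs between tumor samples and a control panel.

    Sites with any missing value among the used samples are dropped
    (complete-case per site).  Survivors are filtered to tumor beta
    variance > ``var_min``, ranked by ascending rank-sum p (ties broken
    by larger \\|statistic\\|, then site id), and truncated to ``n_top``.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    groups.validate_against(beta)
    if groups.n_tumor < 2 or groups.n_normal < 2:
        raise ValueError("need >= 2 tumor and >= 2 control samples for iDMC selection")

    tumor = beta.subset_samples(groups.tumor_ids)
    normal = beta.subset_samples(groups.normal_ids)
    complete = ~(tumor.isna().any(axis=1) | normal.isna().any(axis=1))
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("select_idmcs: dropped %d site(s) with missing values", n_dropped)
    tumor = tumor.loc[complete]
    normal = normal.loc[complete]
    if tumor.empty:
        raise ValueError("no complete-case sites available for iDMC selection")

    tv = tumor.to_numpy()
    nv = normal.to_numpy()
    tumor_var = tv.var(axis=1, ddof=1)
    keep = tumor_var > var_min
    if not keep.any():
        raise ValueError(f"no site passes the tumor variance filter (> {var_min})")

    tv, nv = tv[keep], nv[keep]
    sites = tumor.index[keep]
    tumor_var = tumor_var[keep]
    z, p = _ranksum_z(tv, nv)
    if np.all(p > 0.5):
        warnings.warn(
            "no site shows tumor-vs-control separation (all rank-sum p > 0.5); "
            "the selected iDMC set is unlikely to be informative",
            stacklevel=2,
        )
    direction = np.where(tv.mean(axis=1) >= nv.mean(axis=1), "hyper", "hypo")

    out = pd.DataFrame(
        {
            "site_id": sites,
            "direction": direction,
            "statistic": z,
            "rank_sum_p": p,
            "tumor_var": tumor_var,
        }
    )
    out = out.sort_values(
        by=["rank_sum_p", "statistic", "site_id"],
        key=lambda s: -s.abs() if s.name == "statistic" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    if len(out) < n_top:
        warnings.warn(
            f"only {len(out)} site(s) survive the variance filter; "
            f"returning all of them (n_top={n_top})",
            stacklevel=2,
        )
    out = out.head(n_top).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return IDMCSet(out)
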