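"""Tumor purity estimation from iDMC beta values.

A solid tumor sample is a mixture of cancer and normal cells with
mixing proportion lambda (the purity).  At a hyper-methylated iDMC the
normal methylome contributes beta near 0 and the cancer methylome beta
near 1, so the observed beta is approximately lambda; hypo sites show
1 - lambda and are flipped (v -> 1 - v) before pooling.  Pooling all
iDMCs of one tumor sample therefore gives a cloud of values whose
dominant density peak sits at the purity: lambda-hat is the mode of a
Gaussian kernel density over the transformed values.  Estimation is
strictly per-sample and needs no external purity caller for
calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .idmc import IDMCSet, select_idmcs
from .io import BetaMatrix, PurityTable, SampleGroups

logger = logging.getLogger(__name__)

__all__ = [
    "PurityEstimate",
    "transform_idmc_betas",
    "density_mode",
    "estimate_purity",
]

MIN_IDMC_VALUES = 10
BANDWIDTH_FLOOR = 0.01
GRID_POINTS = 1001


@dataclass
class PurityEstimate:
    sample_id: str
    lambda_hat: float
    n_idmc_used: int
    density_peak_height: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_hat <= 1.0:
            raise ValueError(f"lambda_hat out of [0, 1]: {self.lambda_hat}")


def transform_idmc_betas(beta_column: pd.Series, idmc: IDMCSet) -> np.ndarray:
    """Direction-transform one tumor sample's iDMC beta values.

    Hyper sites pass through unchanged; hypo sites are flipped to
    1 - beta.  The flip is applied regardless of the value itself (a
    hypo site with beta > 0.5 still flips).  iDMC sites missing from
    the column are dropped with a logged count; more than 50% missing
    is an error.
    """
    directions = idmc.directions
    present = directions.index.intersection(beta_column.index)
    values = beta_column.reindex(present)
    present = values.index[values.notna()]
    n_dropped = len(directions) - len(present)
    if n_dropped:
        logger.info("transform_idmc_betas: %d iDMC value(s) unavailable", n_dropped)
    if len(directions) and n_dropped > 0.5 * len(directions):
        raise ValueError(
            f"{n_dropped}/{len(directions)} iDMC values missing for this sample (> 50%)"
        )
    v = beta_column[present].to_numpy(dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("beta values outside [0, 1]")
    hypo = (directions[present] == "hypo").to_numpy()
    out = v.copy()
    out[hypo] = 1.0 - out[hypo]
    return out


def _silverman_bandwidth(values: np.ndarray) -> float:
    # 0.9 * min(sd, IQR/1.34) * n^(-1/5), floored so point masses stay finite
    n = values.size
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * n ** (-0.2)
    return max(bw, BANDWIDTH_FLOOR)


def density_mode(values: np.ndarray) -> tuple[float, float]:
    """Mode of a Gaussian KDE over ``values``, evaluated on [0, 1].

    The density is evaluated on a fixed grid of 1001 equispaced points;
    the returned location is the grid point of global maximum density
    (smallest grid point on ties), together with the density height
    there.  Bandwidth is Silverman's rule with a floor of 0.01.
    """
    values = np.asarray(values, dtype=float)
    if values.size < MIN_IDMC_VALUES:
        raise ValueError(
            f"need >= {MIN_IDMC_VALUES} values for density estimation, got {values.size}"
        )
    bw = _silverman_bandwidth(values)
    grid = np.linspace(0.0, 1.0, GRID_POINTS)
    # Gaussian KDE by direct evaluation; no boundary correction.
    z = (grid[:, None] - values[None, :]) / bw
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (values.size * bw * np.sqrt(2 * np.pi))
    peaks = np.flatnonzero(dens == dens.max())
    if len(peaks) > 1:
        logger.info("density_mode: %d tied maxima; taking smallest grid point", len(peaks))
    imax = int(peaks[0])
    # secondary-peak diagnostic: local maxima within 5% of the global peak
    local = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])) + 1
    rivals = [i for i in local if i != imax and dens[i] > 0.95 * dens[imax]]
    if rivals:
        logger.warning(
            "density_mode: near-tied secondary peak(s) at %s (mode %.3f); "
            "consider varying the iDMC count to check stability",
            [round(grid[i], 3) for i in rivals[:3]],
            grid[imax],
        )
    return float(grid[imax]), float(dens[imax])


def estimate_purity(
    beta: BetaMatrix,
    groups: SampleGroups,
    idmc: IDMCSet | None = None,
    n_top: int | None = None,
    var_min: float | None = None,
) -> PurityTable:
    """Estimate purity for every tumor sample in ``groups``.

    When ``idmc`` is None an iDMC set is first selected against the
    normal samples in ``groups`` (using defaults unless ``n_top`` /
    ``var_min`` are given).  Each tumor column is direction-transformed
    and its KDE mode taken as lambda-hat.  A failing sample is reported
    and skipped; the others are still estimated.
    """
    groups.validate_against(beta)
    if idmc is None:
        kwargs = {}
        if n_top is not None:
            kwargs["n_top"] = n_top
        if var_min is not None:
            kwargs["var_min"] = var_min
        idmc = select_idmcs(beta, groups, **kwargs)

    estimates: dict[str, float] = {}
    failures: dict[str, str] = {}
    for sample in groups.tumor_ids:
        try:
            vals = transform_idmc_betas(beta.values[sample], idmc)
            mode, height = density_mode(vals)
            est = PurityEstimate(sample, mode, len(vals), height)
            estimates[sample] = est.lambda_hat
        except ValueError as exc:  # pragma: no cover - exercised via API tests
            failures[sample] = str(exc)
            logger.error("purity estimation failed for %s: %s", sample, exc)
    if failures and not estimates:
        raise ValueError(f"purity estimation failed for all samples: {failures}")
    if failures:
        logger.warning("purity estimation failed for %d sample(s): %s", len(failures), list(failures))
    series = pd.Series(estimates, name="purity")
    # mode can legitimately land on 0.0; PurityTable requires lambda > 0
    series = series.clip(lower=1e-6)
    return PurityTable(series)
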