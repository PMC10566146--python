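"""Classical isolation-by-distance dispersal estimation (Rousset's method).

Under limited dispersal in two dimensions, the expected genetic
differentiation between pairs of individuals increases linearly with the
logarithm of their separation, with slope 1 / (4 pi D sigma^2) where D is the
effective density.  Regressing a pairwise differentiation statistic on
log-distance therefore yields a dispersal estimate once density is known:

    sigma_hat = sqrt(1 / (4 pi D slope))

A non-positive fitted slope makes the inversion impossible; such runs are
reported as UNDEFINED rather than silently dropped, and batch evaluation
tracks the undefined fraction.

The pairwise statistic used here is the individual-level analogue of
F_ST / (1 - F_ST): with per-individual allele frequencies p_il (half the
minor-allele dosage), per-locus probabilities of allelic identity are

    Q_ij,l = p_il p_jl + (1 - p_il)(1 - p_jl)        (between individuals)
    Q_w,l  = mean_i [ 1 - H_il ]                     (within individuals,
                                                      H_il = heterozygosity)

and the multilocus ratio estimator is

    a_hat_ij = sum_l (Q_w,l - Q_ij,l) / sum_l (1 - Q_w,l).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    InvalidParameterError,
    SingularFitError,
    UndefinedStatisticError,
)
from .io import GenotypeMatrix, LocationsTable, pairwise_distances
from .network import enumerate_pairs

logger = logging.getLogger(__name__)

#: sentinel for an impossible sigma inversion (non-positive slope)
UNDEFINED = None


@dataclass
class IBDRegression:
    """Fitted isolation-by-distance regression and the derived sigma."""

    pair_stats: np.ndarray
    distances: np.ndarray
    slope: float
    intercept: float
    density: float
    sigma_hat: float | None
    n_excluded_zero_distance: int = 0

    @property
    def defined(self) -> bool:
        return self.sigma_hat is not None

    def summary(self) -> str:
        sig = "UNDEFINED" if self.sigma_hat is None else f"{self.sigma_hat:.4f}"
        return "\n".join([
            "Rousset isolation-by-distance regression",
            "=" * 44,
            f"pairs used:                {len(self.pair_stats)}",
            f"zero-distance pairs dropped: {self.n_excluded_zero_distance}",
            f"slope (per log map unit):  {self.slope:.6g}",
            f"intercept:                 {self.intercept:.6g}",
            f"density (per map unit^2):  {self.density:.4g}",
            f"sigma_hat (map units):     {sig}",
        ])


def _per_locus_identities(g: GenotypeMatrix):
    """(Q_w per locus, per-individual allele frequencies)."""
    if g.phased:
        dosage = g.counts.reshape(g.n, 2, g.m).sum(axis=1)
    else:
        dosage = g.counts
    dosage = dosage.astype(np.float64)
    p = dosage / 2.0
    het = dosage == 1
    q_within = 1.0 - het.mean(axis=0)  # homozygote fraction per locus
    return q_within, p


def pairwise_stat(g: GenotypeMatrix, i: int, j: int) -> float:
    """Rousset-style differentiation statistic for one pair of individuals."""
    return float(pairwise_stat_matrix(g, np.array([[i, j]]))[0])


def pairwise_stat_matrix(g: GenotypeMatrix, pairs: np.ndarray) -> np.ndarray:
    """Vectorized a_hat for an array of (i, j) pairs."""
    if g.m < 2:
        raise UndefinedStatisticError("need at least 2 polymorphic sites")
    q_within, p = _per_locus_identities(g)
    denom = float(np.sum(1.0 - q_within))
    if denom <= 0:
        raise UndefinedStatisticError(
            "all individuals homozygous at every site; statistic undefined"
        )
    pi = p[pairs[:, 0]]
    pj = p[pairs[:, 1]]
    q_between = pi * pj + (1.0 - pi) * (1.0 - pj)  # (P, m)
    num = np.sum(q_within[None, :] - q_between, axis=1)
    return num / denom


def fit_ibd(pair_stats, distances, dimension: str = "2D"):
    """Least-squares fit of the pair statistic against geographic distance.

    In two dimensions the regressor is log distance (Rousset's result); in one
    dimension raw distance.  Pairs at exactly zero distance are excluded (with
    a logged count) since log(0) is undefined.
    Returns (slope, intercept, n_excluded).
    """
    stats_arr = np.asarray(pair_stats, dtype=float)
    d = np.asarray(distances, dtype=float)
    if stats_arr.shape != d.shape:
        raise InvalidParameterError("pair_stats and distances must align")
    if dimension not in ("1D", "2D"):
        raise InvalidParameterError(f"dimension must be '1D' or '2D', got {dimension!r}")
    keep = d > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluding %d zero-distance pairs from the IBD fit", n_excluded)
    x = np.log(d[keep]) if dimension == "2D" else d[keep]
    y = stats_arr[keep]
    if len(x) < 2 or np.ptp(x) == 0:
        raise SingularFitError("need >= 2 distinct distances for the IBD fit")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), n_excluded


def sigma_from_slope(slope: float, density: float) -> float | None:
    """Invert the IBD slope to sigma; UNDEFINED (None) for slope <= 0."""
    if density <= 0:
        raise InvalidParameterError(f"density must be > 0, got {density}")
    if slope <= 0:
        return UNDEFINED
    return math.sqrt(1.0 / (4.0 * math.pi * density * slope))


def estimate(g: GenotypeMatrix, loc: LocationsTable, density: float,
             dimension: str = "2D") -> IBDRegression:
    """Full Rousset pipeline: pair statistics -> IBD fit -> sigma inversion."""
    if g.n != loc.n:
        raise InvalidParameterError("genotypes and locations misaligned")
    if g.n < 3:
        raise SingularFitError(f"need at least 3 individuals, got {g.n}")
    pairs = enumerate_pairs(g.n)
    stats_arr = pairwise_stat_matrix(g, pairs)
    d = pairwise_distances(loc, pairs)
    slope, intercept, n_excl = fit_ibd(stats_arr, d, dimension)
    sigma_hat = sigma_from_slope(slope, density)
    return IBDRegression(
        pair_stats=stats_arr, distances=d, slope=slope, intercept=intercept,
        density=density, sigma_hat=sigma_hat, n_excluded_zero_distance=n_excl,
    )


class RoussetIBD:
    """Model-style wrapper: ``RoussetIBD(g, loc, density).fit()``."""

    def __init__(self, genotypes: GenotypeMatrix, locations: LocationsTable,
                 density: float, dimension: str = "2D"):
        self.genotypes = genotypes
        self.locations = locations
        self.density = density
        self.dimension = dimension

    def fit(self) -> IBDRegression:
        return estimate(self.genotypes, self.locations, self.density, self.dimension)


def batch_estimate(datasets, density) -> dict:
    """Rousset estimates over (genotypes, locations) datasets.

    ``density`` may be a scalar or a per-dataset sequence.  Returns a dict
    with per-dataset sigma estimates (NaN where undefined) and the undefined
    fraction — undefined runs are excluded from downstream error metrics, the
    same accounting used in published comparisons.
    """
    datasets = list(datasets)
    dens = np.broadcast_to(np.asarray(density, dtype=float), (len(datasets),))
    out = np.full(len(datasets), np.nan)
    for k, (g, loc) in enumerate(datasets):
        reg = estimate(g, loc, float(dens[k]))
        if reg.defined:
            out[k] = reg.sigma_hat
    n_undef = int(np.isnan(out).sum())
    return {
        "sigma_hat": out,
        "undefined_fraction": n_undef / len(datasets) if datasets else 0.0,
        "n": len(datasets),
    }
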