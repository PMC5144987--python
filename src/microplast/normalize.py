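"""Median-of-ratios normalization and empirical low-expression filtering.

Size factors place samples on a common count scale: for sample k,

    s_k = median_i counts[i, k] / geomean_i(counts[i, :])

over genes whose geometric mean across samples is strictly positive.  The
low-expression threshold is derived empirically as the crossing point of
the (log-scale) densities of per-gene mean normalized counts for genic
versus intergenic regions; when no intergenic table is available the
published default of 3.486 normalized counts is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

#: published empirical low-expression threshold (normalized read counts)
DEFAULT_THRESHOLD = 3.486

_KDE_GRID_SIZE = 512
_LOG_EPS = 1e-8


class NormalizationError(ValueError):
    """Normalization is impossible for the given counts."""


class ThresholdError(ValueError):
    """Genic and intergenic densities do not cross usably."""


@dataclass
class NormalizedMatrix:
    """Normalized expression values plus the size factors that produced them."""

    values: pd.DataFrame  # genes x samples, counts / size factor
    size_factors: pd.Series  # per-sample, strictly positive

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FilterReport:
    n_input_genes: int
    n_all_zero: int
    n_below_threshold: int
    n_expressed: int
    threshold: float

    def __post_init__(self) -> None:
        if self.n_input_genes != self.n_all_zero + self.n_below_threshold + self.n_expressed:
            raise ValueError("filter report does not partition the input genes")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Genes with a zero in any sample have zero geometric mean and are
    excluded from the median (the standard convention: their ratios are
    undefined).  Raises :class:`NormalizationError` when no gene is
    positive in every sample.
    """
    x = counts.to_numpy(dtype=float)
    if x.size == 0:
        raise NormalizationError("empty count matrix")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    eligible = (x > 0).all(axis=1)
    if not eligible.any():
        raise NormalizationError(
            "no gene has strictly positive counts in every sample; "
            "median-of-ratios reference is undefined"
        )
    log_x = np.log(x[eligible])
    log_geomean = log_x.mean(axis=1)
    ratios = np.exp(log_x - log_geomean[:, None])
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | np.ndarray) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor."""
    s = np.asarray(factors, dtype=float)
    if s.shape[0] != counts.shape[1]:
        raise ValueError(
            f"{s.shape[0]} size factors for {counts.shape[1]} samples"
        )
    if (s <= 0).any():
        raise ValueError("size factors must be strictly positive")
    values = counts.astype(float) / s
    return NormalizedMatrix(
        values=values, size_factors=pd.Series(s, index=counts.columns, name="size_factor")
    )


def _log_mean_density(norm: NormalizedMatrix) -> tuple[gaussian_kde, np.ndarray]:
    means = norm.values.to_numpy().mean(axis=1)
    logm = np.log(means + _LOG_EPS)
    if np.ptp(logm) == 0:
        raise ThresholdError("degenerate (constant) mean distribution")
    return gaussian_kde(logm, bw_method="silverman"), logm


def derive_threshold(genic: NormalizedMatrix, intergenic: NormalizedMatrix) -> float:
    """Low-expression threshold from the genic/intergenic density crossing.

    Both per-gene (per-region) mean normalized counts are kernel-smoothed on
    the log scale (Gaussian KDE, Silverman bandwidth, 512-point grid); the
    threshold is the smallest grid value above the intergenic mode at which
    the genic density exceeds the intergenic density, mapped back to the
    count scale.
    """
    if list(genic.sample_ids) != list(intergenic.sample_ids):
        raise ValueError("genic and intergenic matrices must share samples")
    kde_g, logm_g = _log_mean_density(genic)
    kde_i, logm_i = _log_mean_density(intergenic)

    lo = min(logm_g.min(), logm_i.min()) - 1.0
    hi = max(logm_g.max(), logm_i.max()) + 1.0
    grid = np.linspace(lo, hi, _KDE_GRID_SIZE)
    dens_g = kde_g(grid)
    dens_i = kde_i(grid)

    mode_i = grid[np.argmax(dens_i)]
    above = grid > mode_i
    crossing = above & (dens_g > dens_i)
    if not crossing.any():
        mode_g = grid[np.argmax(dens_g)]
        raise ThresholdError(
            "genic density never exceeds the intergenic density above the "
            f"intergenic mode (modes: intergenic={np.exp(mode_i):.4g}, "
            f"genic={np.exp(mode_g):.4g})"
        )
    log_threshold = grid[np.argmax(crossing)]
    return float(np.exp(log_threshold) - _LOG_EPS)


def filter_expressed(
    norm: NormalizedMatrix, threshold: float = DEFAULT_THRESHOLD
) -> tuple[NormalizedMatrix, FilterReport]:
    """Drop all-zero genes, then genes below ``threshold`` in every sample.

    A gene at or above the threshold in even a single sample is kept.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    v = norm.values.to_numpy()
    all_zero = (v == 0).all(axis=1)
    below = (~all_zero) & (v < threshold).all(axis=1)
    expressed = ~(all_zero | below)
    if not expressed.any():
        raise ValueError("all genes removed by the expression filter")
    report = FilterReport(
        n_input_genes=v.shape[0],
        n_all_zero=int(all_zero.sum()),
        n_below_threshold=int(below.sum()),
        n_expressed=int(expressed.sum()),
        threshold=float(threshold),
    )
    kept = NormalizedMatrix(
        values=norm.values.loc[expressed], size_factors=norm.size_factors
    )
    return kept, report
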