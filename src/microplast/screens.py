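"""Covariate screens: infection status, residual heterozygosity, rRNA level.

The infection screen follows the line-level model log(mu_ik) = b0 + I
literally: infection is the only term, so individual flies of the same
line are treated as independent.  Because infection is a genotype-level
covariate, any genotype structure in expression inflates this screen's
test statistic (p-values are anti-conservative under line effects); the
screen is a deliberate, documented reproduction of that model rather than
a mixed-model alternative.

The heterozygosity / rRNA screens correlate the per-line SD of normalized
expression with a per-line covariate by Spearman rank correlation: exact
permutation p-values for n <= 8 lines, t-approximation otherwise.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, spearmanr

from .nbglm import _fit_cells, _irls, bh_fdr, moment_dispersion, nb_loglik


def infection_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB-GLM LRT of log(mu) = b0 + I vs log(mu) = b0 (df = 1)."""
    if design["infected"].nunique() < 2:
        raise ValueError("both infection classes must be present")
    s = (
        np.ones(counts.shape[1])
        if size_factors is None
        else np.asarray(size_factors, dtype=float)
    )
    offset = np.log(s)
    X1 = np.column_stack(
        [np.ones(len(design)), design["infected"].astype(int).to_numpy()]
    )
    X0 = X1[:, :1]
    inf_cells = design["infected"].astype(int).to_numpy()
    rows = []
    Y = counts.to_numpy(dtype=float)
    for gi, gene in enumerate(counts.index):
        y = Y[gi]
        # dispersion under the fuller (infection) model, shared by both fits
        phi = _infection_dispersion(y, inf_cells, s)
        _, mu1, dev1, _ = _irls(y, X1, offset, phi)
        _, mu0, dev0, _ = _irls(y, X0, offset, phi)
        stat = max(0.0, dev0 - dev1)
        stat = 0.0 if stat < 1e-8 else stat
        p = float(chi2.sf(stat, 1)) if stat > 0 else 1.0
        rows.append(
            {"gene_id": gene, "screen": "infection", "statistic": stat, "p_value": p}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out


def _infection_dispersion(y: np.ndarray, inf_cells: np.ndarray, s: np.ndarray) -> float:
    """Profile phi under the two-group (infected / uninfected) mean model."""
    if not (y > 0).any():
        return 0.0
    phi0 = moment_dispersion(y, inf_cells)
    def profile(phi: float) -> float:
        mu = _fit_cells(y, inf_cells, 2, s, phi)
        return nb_loglik(y, mu, phi)
    ll0 = profile(0.0)
    lo = np.log(max(phi0 / 50.0, 1e-6))
    hi = np.log(min(max(phi0 * 50.0, 1.0), 50.0))
    res = minimize_scalar(
        lambda t: -profile(np.exp(t)), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    phi_hat = float(np.exp(res.x))
    if -res.fun <= ll0 + 1e-9 or phi_hat < 1e-5:
        return 0.0
    return phi_hat


def line_sd(norm_values: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-genotype SD of normalized expression (all flies pooled).

    Singleton genotypes get NaN (flagged missing) rather than 0.
    """
    out = {}
    for g, sub in design.groupby("genotype", observed=True):
        cols = [c for c in sub["sample_id"] if c in norm_values.columns]
        x = norm_values[cols].to_numpy()
        out[g] = (
            x.std(axis=1, ddof=1) if x.shape[1] >= 2 else np.full(x.shape[0], np.nan)
        )
    return pd.DataFrame(out, index=norm_values.index)


@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> np.ndarray:
    """All n! Spearman rho values for one fixed ranking vs every permutation."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n**2 - 1)
    rhos = [
        1.0 - 6.0 * np.sum((base - np.array(perm, dtype=float)) ** 2) / denom
        for perm in permutations(base)
    ]
    return np.sort(np.array(rhos))


def spearman_screen_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p: exact permutation null when n <= 8
    (tie-free), t-approximation otherwise."""
    n = len(x)
    rho, p_t = spearmanr(x, y)
    if np.isnan(rho):
        raise ValueError("undefined correlation (constant input)")
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= 8 and not ties:
        null = _exact_rho_null(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return float(rho), p
    return float(rho), float(p_t)


def covariate_correlation(
    line_sd_table: pd.DataFrame,
    covariate: pd.Series,
    screen: str = "heterozygosity",
) -> pd.DataFrame:
    """Per-gene Spearman correlation of per-line expression SD vs covariate.

    ``covariate`` is indexed by genotype (one value per line).  Lines with
    undefined SD are dropped per gene; needs >= 4 informative lines.
    """
    if covariate.nunique() < 2:
        raise ValueError("constant covariate: correlation undefined")
    common = [g for g in line_sd_table.columns if g in covariate.index]
    if len(common) < 4:
        raise ValueError("need >= 4 genotypes with SD and covariate values")
    cov = covariate.loc[common].to_numpy(dtype=float)
    rows = []
    for gene, sds in line_sd_table[common].iterrows():
        s = sds.to_numpy(dtype=float)
        ok = ~np.isnan(s)
        if ok.sum() < 4 or len(np.unique(s[ok])) < 2:
            rows.append(
                {"gene_id": gene, "screen": screen, "statistic": np.nan, "p_value": np.nan}
            )
            continue
        rho, p = spearman_screen_p(s[ok], cov[ok])
        rows.append({"gene_id": gene, "screen": screen, "statistic": rho, "p_value": p})
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
    return out
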