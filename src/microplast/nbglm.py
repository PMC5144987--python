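"""Negative-binomial GLM core: IRLS fitting, dispersion profiling, LRTs.

Counts for one gene are modeled as x_k ~ NB(mu_k, mu_k + phi*mu_k^2) with
log link and log-size-factor offset:

    log(mu_k) = offset_k + X_k beta .

``phi`` (>= 0) is the overdispersion; phi = 0 recovers Poisson regression.
Fitting is iteratively reweighted least squares at fixed phi; the deviance
is 2*[loglik(saturated) - loglik(fitted)] at that phi, so a difference of
deviances between nested fits sharing one phi is a likelihood-ratio
statistic.  Dispersion is estimated per gene by profile likelihood under
the fullest model in use, initialized from a method-of-moments estimate
pooled over design cells.

The IRLS solver here is deliberately lean (dense normal equations, warm
starts) because the term-ladder refits each gene under ~8 nested models
for thousands of simulated genes; statsmodels' GLM agrees with it and
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy.linalg import qr as scipy_qr
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

_MU_FLOOR = 1e-10
_IRLS_TOL = 1e-8
_IRLS_MAXIT = 100
_PHI_FLOOR = 0.0  # reported when data are under-dispersed
_PHI_MAX = 50.0
_LRT_CLAMP = 1e-8

#: patsy formula fragment per design term
_TERM_FORMULA = {
    "S": "C(sex)",
    "G": "C(genotype)",
    "R": "C(replicate)",
    "GxR": "C(genotype):C(replicate)",
    "GxS": "C(genotype):C(sex)",
    "RxS": "C(replicate):C(sex)",
    "GxRxS": "C(genotype):C(replicate):C(sex)",
}
ALL_TERMS = tuple(_TERM_FORMULA)


@dataclass
class GeneFit:
    """One fitted NB GLM for one gene."""

    gene_id: str
    term_set: tuple[str, ...]
    coefficients: np.ndarray
    coef_names: list[str]
    fitted_means: np.ndarray
    deviance: float
    dispersion: float
    converged: bool
    n_params: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_params == 0:
            self.n_params = len(self.coefficients)


@dataclass
class TermTest:
    gene_id: str
    term: str
    lrt_stat: float
    df: int
    p_value: float
    fdr: float = np.nan


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Exact NB (or Poisson when phi == 0) log-likelihood."""
    mu = np.maximum(mu, _MU_FLOOR)
    if phi <= 0:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """2*[loglik(saturated) - loglik(mu)] at fixed phi; 0 at y == mu."""
    mu = np.maximum(mu, _MU_FLOOR)
    y_pos = np.maximum(y, _MU_FLOOR)  # y*log(y) -> 0 as y -> 0
    if phi <= 0:
        unit = y * np.log(y_pos / mu) - (y - mu)
    else:
        r = 1.0 / phi
        unit = y * np.log(y_pos / mu) - (y + r) * np.log((y + r) / (mu + r))
    return float(2.0 * np.sum(unit))


def moment_dispersion(y: np.ndarray, cells: np.ndarray) -> float:
    """Method-of-moments phi pooled over design cells.

    Per cell with n >= 2: phi_c = (s_c^2 - m_c) / m_c^2; pooled by
    (n_c - 1) weights and clamped at 0.
    """
    est, wts = [], []
    for c in np.unique(cells):
        yc = y[cells == c]
        if len(yc) < 2:
            continue
        m = yc.mean()
        if m <= 0:
            continue
        v = yc.var(ddof=1)
        est.append((v - m) / m**2)
        wts.append(len(yc) - 1)
    if not est:
        return 0.0
    return float(max(0.0, np.average(est, weights=wts)))


def build_design_matrix(
    design: pd.DataFrame, term_set: tuple[str, ...] | list[str]
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded model matrix for a subset of the seven design terms.

    Aliased (rank-deficient) columns are dropped with a warning so nested
    deviance comparisons use the effective parameter counts.
    """
    bad = [t for t in term_set if t not in _TERM_FORMULA]
    if bad:
        raise ValueError(f"unknown design terms: {bad}")
    rhs = " + ".join(["1"] + [_TERM_FORMULA[t] for t in term_set])
    dm = dmatrix(rhs, design, return_type="dataframe")
    X = np.asarray(dm, dtype=float)
    names = list(dm.columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # drop dependent columns via pivoted QR
        _, _, piv = scipy_qr(X, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        dropped = [names[j] for j in range(X.shape[1]) if j not in set(keep)]
        warnings.warn(f"dropping aliased design columns: {dropped}")
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """IRLS for the NB log-link GLM at fixed phi.

    Returns (beta, mu, deviance, converged).
    """
    n, p = X.shape
    if beta0 is None:
        z0 = np.log(np.maximum(y, 0) + 0.5) - offset
        beta = np.linalg.lstsq(X, z0, rcond=None)[0]
    else:
        beta = beta0.copy()
    eta = offset + X @ beta
    mu = np.maximum(np.exp(eta), _MU_FLOOR)
    dev = nb_deviance(y, mu, phi)
    converged = False
    for _ in range(_IRLS_MAXIT):
        w = mu / (1.0 + phi * mu)  # GLM working weights
        z = (eta - offset) + (y - mu) / mu  # working response (offset removed)
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        XtWz = Xw.T @ z
        try:
            beta_new = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(XtWX, XtWz, rcond=None)[0]
        eta_new = offset + X @ beta_new
        # step-halving keeps the deviance monotone on hard rows
        step = 1.0
        for _half in range(12):
            eta_try = eta + step * (eta_new - eta)
            mu_try = np.maximum(np.exp(np.clip(eta_try, -30, 30)), _MU_FLOOR)
            dev_try = nb_deviance(y, mu_try, phi)
            if np.isfinite(dev_try) and dev_try <= dev + 1e-10:
                break
            step *= 0.5
        beta = beta + step * (beta_new - beta)
        eta = eta + step * (eta_new - eta)
        mu = np.maximum(np.exp(np.clip(eta, -30, 30)), _MU_FLOOR)
        dev_new = nb_deviance(y, mu, phi)
        if abs(dev - dev_new) <= _IRLS_TOL * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    return beta, mu, dev, converged


def _fit_cells(
    y: np.ndarray, cells: np.ndarray, n_cells: int, s: np.ndarray, phi: float
) -> np.ndarray:
    """MLE fitted means for a cell-partition model (vectorized Newton).

    For each cell the score in eta is sum (y - mu)/(1 + phi*mu) with
    mu = s*exp(eta); a handful of Newton steps converge from the ratio
    start exp(eta) = sum(y)/sum(s).
    """
    sum_y = np.bincount(cells, weights=y, minlength=n_cells)
    sum_s = np.bincount(cells, weights=s, minlength=n_cells)
    eta = np.log(np.maximum(sum_y, 0.25) / sum_s)
    if phi <= 0:
        mu_cell = np.where(sum_y > 0, sum_y / sum_s, _MU_FLOOR / 1.0)
        return np.maximum(s * mu_cell[cells], _MU_FLOOR)
    for _ in range(50):
        mu = s * np.exp(eta[cells])
        denom = 1.0 + phi * mu
        score = np.bincount(cells, weights=(y - mu) / denom, minlength=n_cells)
        info = np.bincount(
            cells, weights=mu * (1.0 + phi * y) / denom**2, minlength=n_cells
        )
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.maximum(s * np.exp(eta[cells]), _MU_FLOOR)


def cell_codes(design: pd.DataFrame, factors=("genotype", "sex", "replicate")) -> tuple[np.ndarray, int]:
    """Integer codes for the finest design cells."""
    key = design[list(factors)].astype(str).agg("|".join, axis=1)
    codes = pd.Categorical(key).codes.astype(np.int64)
    return codes, int(codes.max()) + 1


def estimate_dispersion(
    counts_row: np.ndarray,
    design: pd.DataFrame,
    term_set: tuple[str, ...] = ALL_TERMS,
    size_factors: np.ndarray | None = None,
    cr_adjust: bool = True,
) -> float:
    """Per-gene profile-likelihood dispersion under the fullest model.

    Maximizes the NB likelihood over phi with the mean model refitted at
    each candidate phi, initialized from the pooled method-of-moments
    estimate and clamped at 0 for under-dispersed data.  By default the
    Cox-Reid adjustment (-1/2 log det X'WX) compensates the downward bias
    from estimating the mean model (without it, a cell of n flies biases
    phi by roughly the factor 1 - 1/n).
    """
    y = np.asarray(counts_row, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    if not (y > 0).any():
        raise ValueError("all-zero gene: dispersion undefined")
    s = np.ones_like(y) if size_factors is None else np.asarray(size_factors, float)
    cells, n_cells = cell_codes(design)
    phi0 = moment_dispersion(y, cells)

    # any term set containing the 3-way interaction spans the full cell
    # partition (patsy expands interaction codings to full span)
    full_is_partition = "GxRxS" in term_set
    if full_is_partition:
        def profile(phi: float) -> float:
            mu = _fit_cells(y, cells, n_cells, s, phi)
            ll = nb_loglik(y, mu, phi)
            if cr_adjust:
                w = mu / (1.0 + phi * mu)
                cell_w = np.bincount(cells, weights=w, minlength=n_cells)
                ll -= 0.5 * np.sum(np.log(np.maximum(cell_w, 1e-300)))
            return ll
    else:
        X, _ = build_design_matrix(design, term_set)
        offset = np.log(s)
        warm: dict[str, np.ndarray | None] = {"beta": None}

        def profile(phi: float) -> float:
            beta, mu, _, _ = _irls(y, X, offset, phi, beta0=warm["beta"])
            warm["beta"] = beta
            ll = nb_loglik(y, mu, phi)
            if cr_adjust:
                w = mu / (1.0 + phi * mu)
                _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
                ll -= 0.5 * logdet
            return ll

    ll0 = profile(0.0)
    # profile on log(phi) around the MoM start
    lo = np.log(max(phi0 / 50.0, 1e-6))
    hi = np.log(min(max(phi0 * 50.0, 1.0), _PHI_MAX))
    res = minimize_scalar(
        lambda t: -profile(np.exp(t)), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    phi_hat = float(np.exp(res.x))
    if -res.fun <= ll0 + 1e-9 or phi_hat < 1e-5:
        return _PHI_FLOOR
    return phi_hat


def fit_nb_glm(
    counts_row: np.ndarray,
    design: pd.DataFrame,
    term_set: tuple[str, ...] | list[str],
    size_factors: np.ndarray | None = None,
    phi: float = 0.0,
    gene_id: str = "",
    _X: np.ndarray | None = None,
    _names: list[str] | None = None,
) -> GeneFit:
    """Fit one NB GLM (log link, log-size-factor offset) at fixed phi.

    Non-convergence flags the fit rather than raising.  ``_X``/``_names``
    allow a prebuilt design matrix to be reused across genes.
    """
    y = np.asarray(counts_row, dtype=float)
    if phi < 0:
        raise ValueError("phi must be >= 0")
    s = np.ones_like(y) if size_factors is None else np.asarray(size_factors, float)
    if _X is None:
        _X, _names = build_design_matrix(design, tuple(term_set))
    offset = np.log(s)
    beta, mu, dev, converged = _irls(y, _X, offset, phi)
    return GeneFit(
        gene_id=gene_id,
        term_set=tuple(term_set),
        coefficients=beta,
        coef_names=list(_names),
        fitted_means=mu,
        deviance=max(dev, 0.0),
        dispersion=phi,
        converged=converged,
    )


def lrt_term(full: GeneFit, reduced: GeneFit, term: str | None = None) -> TermTest:
    """Likelihood-ratio test from the deviance gap of two nested fits.

    Both fits must share one dispersion; the statistic is
    max(0, deviance_reduced - deviance_full) on chi2 with df equal to the
    parameter-count difference.
    """
    if not set(reduced.term_set) <= set(full.term_set):
        raise ValueError(
            f"models are not nested: {reduced.term_set} vs {full.term_set}"
        )
    if abs(full.dispersion - reduced.dispersion) > 1e-12:
        raise ValueError("full and reduced fits must share the same dispersion")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    stat = reduced.deviance - full.deviance
    stat = 0.0 if stat < _LRT_CLAMP else float(stat)
    # identical models (df = 0) trivially give stat 0, p = 1
    p = float(chi2.sf(stat, df)) if stat > 0 and df > 0 else 1.0
    if term is None:
        term = "+".join(t for t in full.term_set if t not in reduced.term_set)
    return TermTest(gene_id=full.gene_id, term=term, lrt_stat=stat, df=df, p_value=p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
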