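"""The nested-model likelihood-ratio ladder over G, R, S and interactions.

Each gene is tested for every design term by comparing nested NB GLMs
fitted with a shared, gene-specific dispersion:

* main effects S, G, R — full model ``beta0 + S + G + R`` versus the same
  model with the tested main effect deleted;
* G x R — ``beta0 + S + G + R + GxR`` versus the main-effects model;
* G x S — adding GxS on top of GxR versus without it;
* R x S — adding RxS on top of GxS versus without it;
* G x R x S — the full three-way model versus the all-two-ways model.

The LRT statistic is the deviance difference between reduced and full fit;
dispersion is estimated once per gene under the full three-way model and
held fixed across the ladder so the deviance differences are valid LRTs.
Benjamini-Hochberg FDR is applied per term across genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .nbglm import (
    ALL_TERMS,
    _fit_cells,
    _irls,
    bh_fdr,
    build_design_matrix,
    cell_codes,
    estimate_dispersion,
    nb_deviance,
)

logger = logging.getLogger(__name__)

#: (term, full model terms, reduced model terms) for each rung of the ladder
LADDER: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = [
    ("S", ("S", "G", "R"), ("G", "R")),
    ("G", ("S", "G", "R"), ("S", "R")),
    ("R", ("S", "G", "R"), ("S", "G")),
    ("GxR", ("S", "G", "R", "GxR"), ("S", "G", "R")),
    ("GxS", ("S", "G", "R", "GxR", "GxS"), ("S", "G", "R", "GxR")),
    ("RxS", ("S", "G", "R", "GxR", "GxS", "RxS"), ("S", "G", "R", "GxR", "GxS")),
    ("GxRxS", ALL_TERMS, ("S", "G", "R", "GxR", "GxS", "RxS")),
]

_FACTOR_OF = {"S": "sex", "G": "genotype", "R": "replicate"}


def _testable_terms(design: pd.DataFrame) -> set[str]:
    ok = {f for f, col in _FACTOR_OF.items() if design[col].nunique() >= 2}
    terms = set()
    for term, _, _ in LADDER:
        parts = term.split("x")
        if all(p in ok for p in parts):
            terms.add(term)
    return terms


def test_all_terms(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: np.ndarray | pd.Series | None = None,
    dispersions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the full LRT ladder for every gene.

    Returns a long DataFrame with one row per gene x testable term:
    ``gene_id, term, lrt_stat, df, p_value, fdr`` (FDR per term across
    genes).  ``dispersions`` may supply precomputed per-gene phi values;
    otherwise each gene's phi is profiled under the full three-way model.
    """
    for f, col in _FACTOR_OF.items():
        if design[col].nunique() < 2 and f in {"S", "G", "R"}:
            logger.warning("factor %s has < 2 levels; its terms are skipped", col)
    testable = _testable_terms(design)
    if not testable:
        raise ValueError("no design term is testable (all factors constant)")

    s = (
        np.ones(counts.shape[1])
        if size_factors is None
        else np.asarray(size_factors, dtype=float)
    )
    offset = np.log(s)
    cells, n_cells = cell_codes(design)

    # distinct model matrices across the ladder, built once
    model_sets: list[tuple[str, ...]] = []
    for _, full_t, red_t in LADDER:
        for ts in (full_t, red_t):
            if ts not in model_sets and ts != ALL_TERMS:
                model_sets.append(ts)
    matrices = {ts: build_design_matrix(design, ts) for ts in model_sets}
    n_full_params = n_cells  # the three-way model is the cell-means model

    rows = []
    Y = counts.to_numpy(dtype=float)
    for gi, gene in enumerate(counts.index):
        y = Y[gi]
        if dispersions is not None:
            phi = float(dispersions[gi])
        else:
            phi = estimate_dispersion(y, design, ALL_TERMS, s)

        deviances: dict[tuple[str, ...], float] = {}
        nparams: dict[tuple[str, ...], int] = {}
        for ts, (X, names) in matrices.items():
            _, mu, dev, _ = _irls(y, X, offset, phi)
            deviances[ts] = dev
            nparams[ts] = X.shape[1]
        mu_full = _fit_cells(y, cells, n_cells, s, phi)
        deviances[ALL_TERMS] = nb_deviance(y, mu_full, phi)
        nparams[ALL_TERMS] = n_full_params

        for term, full_t, red_t in LADDER:
            if term not in testable:
                continue
            df = nparams[full_t] - nparams[red_t]
            stat = deviances[red_t] - deviances[full_t]
            stat = 0.0 if stat < 1e-8 else float(stat)
            p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
            rows.append(
                {
                    "gene_id": gene,
                    "term": term,
                    "lrt_stat": stat,
                    "df": df,
                    "p_value": p,
                    "dispersion": phi,
                }
            )

    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for term in out["term"].unique():
        mask = out["term"] == term
        out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p_value"].to_numpy())
    return out
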