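"""Microenvironmental plasticity: CV_E, variance heterogeneity, heritability.

Plasticity of a gene's expression is quantified as the coefficient of
environmental variation within each genotype x sex x replicate cell,

    CV_E = 100 * sd / mean        (normalized counts, n-1 denominator),

analyzed as a trait with the fixed-effects ANOVA  Y = mu + S + G + GxS + e
where replicate-level CV_E values form the error stratum.  Heterogeneity
of within-cell variance is screened with Levene's test (absolute
deviations from the group mean) and the Brown-Forsythe variant (from the
group median).  Broad-sense heritability is estimated from balanced-design
method-of-moments variance components:

    expression scheme:  H2 = (sG + sGR + sGS + sGRS) / (... + sE)
    CV_E scheme:        H2 = (sG + sGS) / (sG + sGS + sE)

with components from the expected mean squares of the random-effects
ANOVA (genotype and all genotype interactions random), negative solutions
truncated at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .nbglm import bh_fdr


# ---------------------------------------------------------------------------
# heterogeneity of variance


def levene_test(values, group_labels, center: str = "mean"):
    """Levene (center='mean') / Brown-Forsythe (center='median') test.

    One-way ANOVA F on Z_jk = |y_jk - center_j|; returns (F, df1, df2, p).
    """
    if center not in {"mean", "median"}:
        raise ValueError("center must be 'mean' or 'median'")
    y = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = [y[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    cent = np.mean if center == "mean" else np.median
    z = [np.abs(g - cent(g)) for g in groups]
    k = len(z)
    n_total = sum(len(g) for g in z)
    grand = np.concatenate(z).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in z)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in z)
    df1, df2 = k - 1, n_total - k
    if ss_within <= 0:
        if ss_between <= 0:
            raise ValueError("all absolute deviations identical: F undefined")
        return np.inf, df1, df2, 0.0
    F = (ss_between / df1) / (ss_within / df2)
    return float(F), df1, df2, float(f_dist.sf(F, df1, df2))


def hov_tests(
    norm_values: pd.DataFrame, design: pd.DataFrame, center: str = "median"
) -> pd.DataFrame:
    """Per-gene heterogeneity-of-variance test across G x S x R cells.

    Returns gene_id, F, df1, df2, p_value, fdr.  The default grouping is
    the finest design cell; pass a coarser label column via ``design`` if
    desired.
    """
    labels = (
        design[["genotype", "sex", "replicate"]].astype(str).agg("|".join, axis=1)
    ).to_numpy()
    rows = []
    for gene, y in norm_values.iterrows():
        try:
            F, df1, df2, p = levene_test(y.to_numpy(), labels, center=center)
        except ValueError:
            F, df1, df2, p = np.nan, 0, 0, np.nan
        rows.append({"gene_id": gene, "F": F, "df1": df1, "df2": df2, "p_value": p})
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# CV_E


def cve(values) -> float:
    """Coefficient of environmental variation, 100 * sd / mean."""
    y = np.asarray(values, dtype=float)
    if len(y) < 2:
        raise ValueError("CV_E needs at least 2 observations")
    m = y.mean()
    if m <= 0:
        raise ValueError("CV_E undefined for non-positive mean")
    return float(100.0 * y.std(ddof=1) / m)


def cve_table(norm_values: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """CV_E for every gene x (genotype, sex, replicate) cell.

    Cells with n < 2 or mean <= 0 are flagged (``defined = False``) with
    NaN CV_E rather than fabricated.
    """
    cells = design.groupby(["genotype", "sex", "replicate"], sort=True, observed=True)
    blocks = []
    V = norm_values.to_numpy()
    sample_pos = {sid: j for j, sid in enumerate(norm_values.columns)}
    for (g, s, r), sub in cells:
        cols = [sample_pos[sid] for sid in sub["sample_id"]]
        x = V[:, cols]
        n = x.shape[1]
        mean = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1) if n >= 2 else np.full(len(mean), np.nan)
        defined = (n >= 2) & (mean > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(defined, 100.0 * sd / np.where(mean > 0, mean, np.nan), np.nan)
        blocks.append(
            pd.DataFrame(
                {
                    "gene_id": norm_values.index,
                    "genotype": g,
                    "sex": s,
                    "replicate": r,
                    "n": n,
                    "mean": mean,
                    "sd": sd,
                    "cve": cv,
                    "defined": defined,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)


def _reshape_cells(
    table: pd.DataFrame, value_col: str
) -> tuple[np.ndarray, list, list, list, list]:
    """Pivot a long gene x (G, S, R) table to a (genes, G, S, R) array."""
    genes = list(pd.unique(table["gene_id"]))
    gl = sorted(table["genotype"].unique())
    sl = sorted(table["sex"].unique())
    rl = sorted(table["replicate"].unique())
    pivot = table.pivot_table(
        index="gene_id", columns=["genotype", "sex", "replicate"], values=value_col,
        sort=True, observed=True,
    ).reindex(genes)
    arr = pivot.to_numpy().reshape(len(genes), len(gl), len(sl), len(rl))
    return arr, genes, gl, sl, rl


def cve_anova(cve_tab: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene fixed-effects ANOVA of CV_E:  Y = mu + S + G + GxS + e.

    Replicate-level CV_E values are the error stratum (balanced design, so
    type I/II/III sums of squares coincide).  Returns a long DataFrame of
    gene_id, term in {G, S, GxS}, F, df1, df2, p_value, fdr (BH per term).
    Genes with any undefined cell are dropped.
    """
    tab = cve_tab[cve_tab.get("defined", True) != False]  # noqa: E712
    complete = tab.groupby("gene_id")["cve"].apply(lambda v: v.notna().all())
    tab = tab[tab["gene_id"].isin(complete[complete].index)]
    if tab.empty:
        raise ValueError("no gene has a complete CV_E table")
    arr, genes, gl, sl, rl = _reshape_cells(tab, "cve")
    a, c, r = len(gl), len(sl), len(rl)
    if r < 2:
        raise ValueError("need >= 2 replicate-level CV_E values per G x S cell")

    grand = arr.mean(axis=(1, 2, 3), keepdims=True)
    mg = arr.mean(axis=(2, 3), keepdims=True)
    ms = arr.mean(axis=(1, 3), keepdims=True)
    mgs = arr.mean(axis=3, keepdims=True)

    ss_g = (c * r) * ((mg - grand) ** 2).sum(axis=(1, 2, 3))
    ss_s = (a * r) * ((ms - grand) ** 2).sum(axis=(1, 2, 3))
    ss_gs = r * ((mgs - mg - ms + grand) ** 2).sum(axis=(1, 2, 3))
    ss_e = ((arr - mgs) ** 2).sum(axis=(1, 2, 3))
    df = {"G": a - 1, "S": c - 1, "GxS": (a - 1) * (c - 1)}
    df_e = a * c * (r - 1)
    mse = ss_e / df_e

    rows = []
    for term, ss in (("S", ss_s), ("G", ss_g), ("GxS", ss_gs)):
        if df[term] == 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(ss <= 1e-300, 0.0, (ss / df[term]) / mse)
        # zero between-cell signal: F = 0, p = 1 (even at zero residual);
        # signal with zero residual: F = inf, p = 0
        p = np.where(
            ss <= 1e-300,
            1.0,
            np.where(mse > 0, f_dist.sf(F, df[term], df_e), 0.0),
        )
        for gi, gene in enumerate(genes):
            rows.append(
                {
                    "gene_id": gene,
                    "term": term,
                    "F": float(F[gi]) if np.isfinite(F[gi]) else np.inf,
                    "df1": df[term],
                    "df2": df_e,
                    "p_value": float(p[gi]),
                }
            )
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for term in out["term"].unique():
        mask = out["term"] == term
        out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# variance components and broad-sense heritability


@dataclass
class VarianceComponents:
    gene_id: str
    scheme: str  # 'expression' | 'cve'
    sigma_g: float
    sigma_gr: float
    sigma_gs: float
    sigma_grs: float
    sigma_eps: float
    balanced: bool = True


@dataclass
class HeritabilityEstimate:
    gene_id: str
    h2: float
    scheme: str


def _balanced_cell_array(values: np.ndarray, design: pd.DataFrame):
    """Reshape per-fly values to (G, R, S, n); harmonic-mean fallback if
    unbalanced (flagged)."""
    df = design.copy()
    df["_y"] = values
    sizes = df.groupby(["genotype", "replicate", "sex"], observed=True)["_y"].size()
    balanced = sizes.nunique() == 1
    gl = sorted(df["genotype"].unique())
    rl = sorted(df["replicate"].unique())
    sl = sorted(df["sex"].unique())
    if balanced:
        n = int(sizes.iloc[0])
        arr = np.full((len(gl), len(rl), len(sl), n), np.nan)
        for (g, r, s), sub in df.groupby(["genotype", "replicate", "sex"], observed=True):
            arr[gl.index(g), rl.index(r), sl.index(s), :] = sub["_y"].to_numpy()
        return arr, n, balanced
    warnings.warn(
        "unbalanced design: variance components use an unweighted-means "
        "EMS solution with harmonic-mean cell size (flagged)"
    )
    n_h = len(sizes) / np.sum(1.0 / sizes.to_numpy())
    cm = df.groupby(["genotype", "replicate", "sex"], observed=True)["_y"].agg(["mean", "var", "size"])
    arr = np.full((len(gl), len(rl), len(sl), 1), np.nan)
    within_ss = 0.0
    within_df = 0
    for (g, r, s), row in cm.iterrows():
        arr[gl.index(g), rl.index(r), sl.index(s), 0] = row["mean"]
        if row["size"] >= 2:
            within_ss += row["var"] * (row["size"] - 1)
            within_df += int(row["size"] - 1)
    return (arr, n_h, balanced, within_ss, within_df)


def variance_components(
    values, design: pd.DataFrame, scheme: str = "expression", gene_id: str = ""
) -> VarianceComponents:
    """Method-of-moments variance components from balanced-design EMS.

    expression scheme
        ``values`` are per-fly quantities (log2(normalized + 1) in the
        pipeline) on the G x R x S x n design.  Random effects: G, GxR,
        GxS, GxRxS; residual = within-cell.  Unrestricted-model EMS give

            sGRS = (MS_GRS - MSE) / n
            sGR  = (MS_GR - MS_GRS) / (n c)
            sGS  = (MS_GS - MS_GRS) / (n b)
            sG   = (MS_G - MS_GR - MS_GS + MS_GRS) / (n b c)

        with b replicate and c sex levels; factors with one level drop out
        of the system.  Negative solutions are truncated at 0.

    cve scheme
        ``values`` are per-(G, S, R) CV_E values; random G and GxS,
        residual = replicate within G x S.
    """
    y = np.asarray(values, dtype=float)
    if scheme == "expression":
        res = _balanced_cell_array(y, design)
        if len(res) == 3:
            arr, n, balanced = res
            within_ss = ((arr - arr.mean(axis=3, keepdims=True)) ** 2).sum()
            within_df = arr.size - arr.shape[0] * arr.shape[1] * arr.shape[2]
        else:
            arr, n, balanced, within_ss, within_df = res
        a, b, c = arr.shape[0], arr.shape[1], arr.shape[2]
        cell = arr.mean(axis=3)  # (G, R, S)
        grand = cell.mean()
        mg = cell.mean(axis=(1, 2))
        mr = cell.mean(axis=(0, 2))
        ms = cell.mean(axis=(0, 1))
        mgr = cell.mean(axis=2)
        mgs = cell.mean(axis=1)
        mrs = cell.mean(axis=0)

        mse = within_ss / within_df if within_df > 0 else 0.0
        ms_g = n * b * c * np.sum((mg - grand) ** 2) / (a - 1) if a > 1 else 0.0

        s_g = s_gr = s_gs = s_grs = 0.0
        if a < 2:
            raise ValueError("need >= 2 genotypes for genetic components")
        if b > 1 and c > 1:
            ms_gr = (
                n * c * np.sum((mgr - mg[:, None] - mr[None, :] + grand) ** 2)
                / ((a - 1) * (b - 1))
            )
            ms_gs = (
                n * b * np.sum((mgs - mg[:, None] - ms[None, :] + grand) ** 2)
                / ((a - 1) * (c - 1))
            )
            resid3 = (
                cell
                - mgr[:, :, None]
                - mgs[:, None, :]
                - mrs[None, :, :]
                + mg[:, None, None]
                + mr[None, :, None]
                + ms[None, None, :]
                - grand
            )
            ms_grs = n * np.sum(resid3**2) / ((a - 1) * (b - 1) * (c - 1))
            s_grs = (ms_grs - mse) / n
            s_gr = (ms_gr - ms_grs) / (n * c)
            s_gs = (ms_gs - ms_grs) / (n * b)
            s_g = (ms_g - ms_gr - ms_gs + ms_grs) / (n * b * c)
        elif b > 1:  # no sex axis
            ms_gr = n * np.sum((mgr - mg[:, None] - mr[None, :] + grand) ** 2) / (
                (a - 1) * (b - 1)
            )
            s_gr = (ms_gr - mse) / n
            s_g = (ms_g - ms_gr) / (n * b)
        elif c > 1:  # no replicate axis
            ms_gs = n * np.sum((mgs - mg[:, None] - ms[None, :] + grand) ** 2) / (
                (a - 1) * (c - 1)
            )
            s_gs = (ms_gs - mse) / n
            s_g = (ms_g - ms_gs) / (n * c)
        else:  # one-way: G groups with n observations each
            s_g = (ms_g - mse) / n
        return VarianceComponents(
            gene_id=gene_id,
            scheme="expression",
            sigma_g=max(0.0, float(s_g)),
            sigma_gr=max(0.0, float(s_gr)),
            sigma_gs=max(0.0, float(s_gs)),
            sigma_grs=max(0.0, float(s_grs)),
            sigma_eps=max(0.0, float(mse)),
            balanced=bool(balanced),
        )

    if scheme == "cve":
        # values indexed like design rows carrying genotype, sex, replicate
        df = design.copy()
        df["_y"] = y
        sizes = df.groupby(["genotype", "sex"], observed=True)["_y"].size()
        if sizes.nunique() != 1:
            warnings.warn("unbalanced CV_E table; using unweighted means")
        gl = sorted(df["genotype"].unique())
        sl = sorted(df["sex"].unique())
        r = int(sizes.iloc[0])
        a, c = len(gl), len(sl)
        cell = (
            df.groupby(["genotype", "sex"], observed=True)["_y"]
            .mean()
            .unstack()
            .reindex(index=gl, columns=sl)
            .to_numpy()
        )
        within = df.groupby(["genotype", "sex"], observed=True)["_y"].var(ddof=1)
        mse = float(within.mean()) if r > 1 else 0.0
        grand = cell.mean()
        mg = cell.mean(axis=1)
        ms = cell.mean(axis=0)
        ms_g = r * c * np.sum((mg - grand) ** 2) / (a - 1) if a > 1 else 0.0
        s_g = s_gs = 0.0
        if c > 1:
            ms_gs = r * np.sum((cell - mg[:, None] - ms[None, :] + grand) ** 2) / (
                (a - 1) * (c - 1)
            )
            s_gs = (ms_gs - mse) / r
            s_g = (ms_g - ms_gs) / (r * c)
        else:
            s_g = (ms_g - mse) / r
        return VarianceComponents(
            gene_id=gene_id,
            scheme="cve",
            sigma_g=max(0.0, float(s_g)),
            sigma_gr=0.0,
            sigma_gs=max(0.0, float(s_gs)),
            sigma_grs=0.0,
            sigma_eps=max(0.0, float(mse)),
        )

    raise ValueError("scheme must be 'expression' or 'cve'")


def heritability(vc: VarianceComponents) -> HeritabilityEstimate:
    """Broad-sense heritability from (truncated) variance components."""
    if vc.scheme == "expression":
        genetic = vc.sigma_g + vc.sigma_gr + vc.sigma_gs + vc.sigma_grs
    else:
        genetic = vc.sigma_g + vc.sigma_gs
    total = genetic + vc.sigma_eps
    h2 = 0.0 if total <= 0 else genetic / total
    return HeritabilityEstimate(gene_id=vc.gene_id, h2=float(h2), scheme=vc.scheme)


def heritability_table(
    norm_values: pd.DataFrame,
    design: pd.DataFrame,
    scheme: str = "expression",
    cve_tab: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene variance components + H2.

    expression scheme works on log2(normalized + 1) per fly; cve scheme on
    the replicate-level CV_E table (computed here when not supplied).
    """
    rows = []
    if scheme == "expression":
        logv = np.log2(norm_values.to_numpy() + 1.0)
        for gi, gene in enumerate(norm_values.index):
            vc = variance_components(logv[gi], design, "expression", gene_id=gene)
            h = heritability(vc)
            rows.append({**vc.__dict__, "h2": h.h2})
    elif scheme == "cve":
        if cve_tab is None:
            cve_tab = cve_table(norm_values, design)
        ok = cve_tab[cve_tab["defined"]]
        for gene, sub in ok.groupby("gene_id", sort=False, observed=True):
            if sub["cve"].isna().any():
                continue
            vc = variance_components(
                sub["cve"].to_numpy(),
                sub[["genotype", "sex", "replicate"]],
                "cve",
                gene_id=gene,
            )
            h = heritability(vc)
            rows.append({**vc.__dict__, "h2": h.h2})
    else:
        raise ValueError("scheme must be 'expression' or 'cve'")
    return pd.DataFrame(rows)
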