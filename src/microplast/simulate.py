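"""Synthetic count-data generator for replicated inbred-line RNA-seq designs.

Emulates a fully crossed, balanced design — genotype (G) x replicate
environment (R) x sex (S), with several individually sequenced flies per
cell — and negative-binomial read counts

    x_ik ~ NB(mu_ik, sigma2_ik),   sigma2_ik = mu_ik + phi * mu_ik**2,

where ``phi`` is a per-gene overdispersion parameter (``phi = 0`` recovers
Poisson sampling).  Mean structure is planted on the log scale as
sum-to-zero effects for each of the seven design terms (G, R, S and their
interactions), so the intercept is interpretable as the grand log-mean.
Microenvironmental-plasticity differences are planted by inflating ``phi``
per (genotype, sex) with a multiplier >= 1, which perturbs within-cell
variance (hence CV_E) while leaving the mean model intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TERMS = ("G", "R", "S", "GxR", "GxS", "RxS", "GxRxS")

#: factor axes (in order) spanned by each design term
TERM_FACTORS = {
    "G": ("genotype",),
    "R": ("replicate",),
    "S": ("sex",),
    "GxR": ("genotype", "replicate"),
    "GxS": ("genotype", "sex"),
    "RxS": ("replicate", "sex"),
    "GxRxS": ("genotype", "replicate", "sex"),
}

SEXES = ("F", "M")


@dataclass
class SyntheticTruth:
    """Ground-truth generative parameters for a simulated gene panel.

    Attributes
    ----------
    gene_ids : list of str
    baseline : (n_genes,) log-scale intercepts (grand log-means).
    effects : dict mapping term -> ndarray of per-gene effect arrays; for a
        term spanning d factors the array has shape (n_genes, L1, ..., Ld)
        and sums to zero over every factor axis.
    dispersion : (n_genes,) NB overdispersion phi >= 0.
    cve_multiplier : (n_genes, n_genotypes, 2) variance-inflation factors
        >= 1 applied multiplicatively to phi per (genotype, sex).
    active_terms : dict term -> boolean mask of genes truly non-null.
    genotypes, replicates : level labels for the effect array axes.
    """

    gene_ids: list[str]
    baseline: np.ndarray
    effects: dict[str, np.ndarray]
    dispersion: np.ndarray
    cve_multiplier: np.ndarray
    active_terms: dict[str, np.ndarray]
    genotypes: list[str] = field(default_factory=list)
    replicates: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def generate_design(
    n_genotypes: int = 16,
    n_replicates: int = 3,
    n_flies_per_cell: int = 8,
    infected_fraction: float = 9 / 16,
    seed: int = 0,
    dropout_rate: float = 0.0,
) -> pd.DataFrame:
    """Build a balanced genotype x replicate x sex x fly design table.

    Infection status (e.g. Wolbachia) is a line-level covariate: a seeded
    random subset of ``round(infected_fraction * n_genotypes)`` genotypes is
    flagged infected, constant across all flies of that genotype.

    ``dropout_rate`` optionally removes a random fraction of flies after the
    balanced table is built (real studies lose samples to QC); the default
    keeps the design exactly balanced.

    Returns a DataFrame with columns
    ``sample_id, genotype, sex, replicate, fly_index, infected``.
    """
    if n_genotypes < 1 or n_replicates < 1 or n_flies_per_cell < 1:
        raise ValueError("design dimensions must all be >= 1")
    if not 0.0 <= infected_fraction <= 1.0:
        raise ValueError("infected_fraction must be in [0, 1]")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    genotypes = [f"G{i + 1:02d}" for i in range(n_genotypes)]
    replicates = [f"R{j + 1}" for j in range(n_replicates)]

    n_inf = int(round(infected_fraction * n_genotypes))
    infected_lines = set(rng.choice(genotypes, size=n_inf, replace=False))

    rows = []
    for g in genotypes:
        for r in replicates:
            for s in SEXES:
                for f in range(1, n_flies_per_cell + 1):
                    rows.append(
                        {
                            "sample_id": f"{g}_{r}_{s}_f{f}",
                            "genotype": g,
                            "sex": s,
                            "replicate": r,
                            "fly_index": f,
                            "infected": g in infected_lines,
                        }
                    )
    design = pd.DataFrame(rows)
    if dropout_rate > 0:
        keep = rng.random(len(design)) >= dropout_rate
        # never empty a whole (G, R, S) cell
        design = design[keep | (design["fly_index"] == 1)].reset_index(drop=True)
    return design


def _center_sum_to_zero(arr: np.ndarray) -> np.ndarray:
    """Remove the mean along every factor axis (axes 1..ndim-1).

    Sequential mean removal leaves all one-axis margins exactly zero, which
    makes the intercept the grand log-mean.
    """
    out = arr.astype(float).copy()
    for ax in range(1, out.ndim):
        out -= out.mean(axis=ax, keepdims=True)
    return out


def generate_truth(
    n_genes: int,
    prop_active_per_term: dict[str, float] | None = None,
    effect_sd: float = 0.5,
    dispersion_range: tuple[float, float] = (0.05, 0.5),
    cve_config: dict | None = None,
    baseline_log_mean_range: tuple[float, float] = (np.log(20), np.log(2000)),
    n_genotypes: int = 16,
    n_replicates: int = 3,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw per-gene generative parameters.

    For each design term, ``round(prop * n_genes)`` genes (a seeded random
    subset) receive i.i.d. normal(0, effect_sd^2) level effects which are
    then centered to sum to zero over every factor axis; all other genes
    carry exactly-zero coefficients for that term.  Dispersions phi are
    drawn uniformly from ``dispersion_range``.

    ``cve_config`` plants within-cell variance (CV_E) heterogeneity:
    ``{"prop_active": p, "multiplier_range": (lo, hi), "prop_genotypes": q,
    "sex_dependent": bool}``.  For each selected gene, a random subset of
    genotypes gets its phi multiplied by a draw from ``multiplier_range``
    (per sex independently when ``sex_dependent``); multipliers are >= 1.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    prop_active_per_term = dict(prop_active_per_term or {})
    for term, p in prop_active_per_term.items():
        if term not in TERMS:
            raise ValueError(f"unknown design term {term!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion for {term} outside [0, 1]")
    lo, hi = dispersion_range
    if lo < 0 or hi < lo:
        raise ValueError("dispersion_range must be within [0, inf)")

    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    genotypes = [f"G{i + 1:02d}" for i in range(n_genotypes)]
    replicates = [f"R{j + 1}" for j in range(n_replicates)]
    levels = {"genotype": n_genotypes, "replicate": n_replicates, "sex": 2}

    baseline = rng.uniform(*baseline_log_mean_range, size=n_genes)
    dispersion = rng.uniform(lo, hi, size=n_genes)

    effects: dict[str, np.ndarray] = {}
    active: dict[str, np.ndarray] = {}
    for term in TERMS:
        shape = (n_genes,) + tuple(levels[f] for f in TERM_FACTORS[term])
        eff = np.zeros(shape)
        mask = np.zeros(n_genes, dtype=bool)
        p = prop_active_per_term.get(term, 0.0)
        k = int(round(p * n_genes))
        if k > 0:
            idx = rng.choice(n_genes, size=k, replace=False)
            mask[idx] = True
            raw = rng.normal(0.0, effect_sd, size=(k,) + shape[1:])
            eff[idx] = _center_sum_to_zero(raw)
        effects[term] = eff
        active[term] = mask

    cve_mult = np.ones((n_genes, n_genotypes, 2))
    if cve_config:
        p = float(cve_config.get("prop_active", 0.0))
        m_lo, m_hi = cve_config.get("multiplier_range", (2.0, 2.0))
        if m_lo < 1.0:
            raise ValueError("cve multipliers must be >= 1")
        q = float(cve_config.get("prop_genotypes", 0.5))
        sex_dep = bool(cve_config.get("sex_dependent", False))
        k = int(round(p * n_genes))
        if k > 0:
            genes = rng.choice(n_genes, size=k, replace=False)
            n_g_hit = max(1, int(round(q * n_genotypes)))
            for gi in genes:
                hit = rng.choice(n_genotypes, size=n_g_hit, replace=False)
                if sex_dep:
                    sx = rng.integers(0, 2)
                    cve_mult[gi, hit, sx] = rng.uniform(m_lo, m_hi, size=n_g_hit)
                else:
                    m = rng.uniform(m_lo, m_hi, size=(n_g_hit, 1))
                    cve_mult[gi, hit, :] = m

    return SyntheticTruth(
        gene_ids=gene_ids,
        baseline=baseline,
        effects=effects,
        dispersion=dispersion,
        cve_multiplier=cve_mult,
        active_terms=active,
        genotypes=genotypes,
        replicates=replicates,
    )


def expected_log_means(truth: SyntheticTruth, design: pd.DataFrame) -> np.ndarray:
    """(n_genes, n_samples) log-mean matrix eta implied by the truth table."""
    g_idx = pd.Categorical(design["genotype"], categories=truth.genotypes).codes
    r_idx = pd.Categorical(design["replicate"], categories=truth.replicates).codes
    s_idx = pd.Categorical(design["sex"], categories=list(SEXES)).codes
    if (g_idx < 0).any() or (r_idx < 0).any() or (s_idx < 0).any():
        raise ValueError("design contains levels absent from the truth table")
    idx = {"genotype": g_idx, "replicate": r_idx, "sex": s_idx}

    eta = np.repeat(truth.baseline[:, None], len(design), axis=1)
    for term, factors in TERM_FACTORS.items():
        eff = truth.effects[term]
        key = (slice(None),) + tuple(idx[f] for f in factors)
        eta += eff[key]
    return eta


def draw_size_factors(
    n_samples: int, size_factor_range: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Log-uniform size factors rescaled to geometric mean 1."""
    lo, hi = size_factor_range
    if lo <= 0 or hi < lo:
        raise ValueError("size_factor_range must be within (0, inf)")
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    return s / np.exp(np.mean(np.log(s)))


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, phi_eff: np.ndarray
) -> np.ndarray:
    """NB(mean, mean + phi*mean^2) draws; phi_eff = 0 degenerates to Poisson."""
    counts = np.empty(mean.shape, dtype=np.int64)
    pois = phi_eff <= 0
    if pois.any():
        counts[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi_eff[nb]
        p = r / (r + mean[nb])
        counts[nb] = rng.negative_binomial(r, p)
    return counts


def simulate_counts(
    design: pd.DataFrame,
    truth: SyntheticTruth,
    size_factor_range: tuple[float, float] = (0.7, 1.4),
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate the gene x sample count matrix for a design + truth pair.

    Counts for gene i in sample k are NB with mean ``s_k * exp(eta_ik)`` and
    variance ``mean + phi_eff * mean**2`` where ``phi_eff = phi_i *
    cve_multiplier_i[genotype_k, sex_k]``.

    Returns (counts DataFrame indexed by gene id with sample-id columns,
    size-factor array used).
    """
    if len(design) == 0 or truth.n_genes == 0:
        raise ValueError("design and truth must be non-empty")
    rng = np.random.default_rng(seed)
    eta = expected_log_means(truth, design)
    s = draw_size_factors(len(design), size_factor_range, rng)
    mean = s[None, :] * np.exp(eta)

    g_idx = pd.Categorical(design["genotype"], categories=truth.genotypes).codes
    s_idx = pd.Categorical(design["sex"], categories=list(SEXES)).codes
    phi_eff = truth.dispersion[:, None] * truth.cve_multiplier[:, g_idx, s_idx]

    counts = _nb_draw(rng, mean, phi_eff)
    cm = pd.DataFrame(counts, index=truth.gene_ids, columns=design["sample_id"].tolist())
    cm.index.name = "gene_id"
    return cm, s


def simulate_intergenic_counts(
    n_regions: int,
    design: pd.DataFrame,
    low_mean: float = 1.0,
    dispersion: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Background (intergenic) counts: NB noise with small mean.

    Region means are drawn log-normally around ``low_mean`` so the
    intergenic normalized-count density has spread, giving a recoverable
    crossing with the genic density.  ``low_mean = 0`` yields all zeros.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if low_mean < 0:
        raise ValueError("low_mean must be >= 0")
    rng = np.random.default_rng(seed)
    region_ids = [f"intergenic{i + 1:05d}" for i in range(n_regions)]
    n = len(design)
    if low_mean == 0:
        counts = np.zeros((n_regions, n), dtype=np.int64)
    else:
        mu_r = low_mean * np.exp(rng.normal(0.0, 0.5, size=n_regions))
        mean = np.broadcast_to(mu_r[:, None], (n_regions, n)).copy()
        phi = np.full((n_regions, n), dispersion)
        counts = _nb_draw(rng, mean, phi)
    cm = pd.DataFrame(counts, index=region_ids, columns=design["sample_id"].tolist())
    cm.index.name = "region_id"
    return cm
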