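"""End-to-end orchestration: simulate/ingest -> normalize -> filter ->
LRT ladder -> variance heterogeneity -> CV_E / heritability -> clustering
and enrichment -> covariate screens, under one seeded configuration.

Every stage writes its table under the output directory; the run summary
is a machine-readable JSON whose content is bit-identical across runs with
the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .clustering import correlation_matrix, mmc_cluster
from .diffexpr import test_all_terms
from .enrichment import geneset_enrichment, read_gmt
from .normalize import (
    DEFAULT_THRESHOLD,
    NormalizedMatrix,
    derive_threshold,
    filter_expressed,
    normalize,
    size_factors,
)
from .plasticity import cve_anova, cve_table, heritability_table, hov_tests
from .screens import covariate_correlation, infection_test, line_sd
from .simulate import (
    generate_design,
    generate_truth,
    simulate_counts,
    simulate_intergenic_counts,
)

logger = logging.getLogger(__name__)

CVE_TERMS = ("G", "S", "GxS")  # terms estimable in the CV_E ANOVA


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of (``counts_path`` + ``design_path``) or ``simulate``
    must be provided.  ``simulate`` keys mirror the generator signatures
    (n_genes, n_genotypes, n_replicates, n_flies_per_cell,
    infected_fraction, prop_active_per_term, effect_sd, dispersion_range,
    cve_config, size_factor_range, n_intergenic, intergenic_mean).
    """

    out_dir: str = "microplast_out"
    seed: int = 0
    counts_path: str | None = None
    design_path: str | None = None
    intergenic_path: str | None = None
    gene_sets_path: str | None = None
    covariates: dict[str, str] = field(default_factory=dict)  # screen -> path
    simulate: dict | None = None
    threshold: float | None = None  # override; None = derive or default
    alpha: float = 0.05
    terms: list[str] | None = None  # None = all seven
    cluster_term: str = "GxRxS"
    cluster_method: str = "pearson"
    run_hov: bool = True
    run_screens: bool = True

    def validate(self) -> None:
        problems = []
        has_paths = self.counts_path is not None and self.design_path is not None
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            problems.append(
                "exactly one of (counts_path + design_path) or simulate "
                "must be provided"
            )
        if not 0 < self.alpha < 1:
            problems.append("alpha must be in (0, 1)")
        if self.threshold is not None and self.threshold <= 0:
            problems.append("threshold must be > 0")
        if self.cluster_method not in {"pearson", "spearman"}:
            problems.append("cluster_method must be pearson or spearman")
        if problems:
            raise ValueError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        # hash only analysis-relevant fields: the output location does not
        # change any computed number
        fields = asdict(self)
        fields.pop("out_dir", None)
        canon = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage(name: str, t0: float, **counts) -> None:
    info = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, info)


def summarize_table1(
    term_tests: pd.DataFrame, cve_tests: pd.DataFrame | None, alpha: float = 0.05
) -> dict:
    """Per-term significant-gene counts for mean expression and CV_E,
    plus their overlap (the CV_E ANOVA estimates only G, S and GxS)."""
    if cve_tests is not None and len(cve_tests):
        de_genes = set(term_tests["gene_id"])
        cve_genes = set(cve_tests["gene_id"])
        if not cve_genes <= de_genes:
            raise ValueError("CV_E results contain genes absent from DE results")
    out = {}
    for term in term_tests["term"].unique():
        de_hit = set(
            term_tests.loc[
                (term_tests["term"] == term) & (term_tests["fdr"] < alpha), "gene_id"
            ]
        )
        entry: dict = {"de": len(de_hit)}
        if cve_tests is not None and term in CVE_TERMS and len(cve_tests):
            cv_hit = set(
                cve_tests.loc[
                    (cve_tests["term"] == term) & (cve_tests["fdr"] < alpha),
                    "gene_id",
                ]
            )
            entry["cve"] = len(cv_hit)
            entry["overlap"] = len(de_hit & cv_hit)
        else:
            entry["cve"] = None
            entry["overlap"] = None
        out[term] = entry
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run summary (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    rng_seed = int(config.seed)

    # ---- stage: input ----------------------------------------------------
    intergenic = None
    if config.simulate is not None:
        sim = dict(config.simulate)
        design = generate_design(
            n_genotypes=sim.get("n_genotypes", 16),
            n_replicates=sim.get("n_replicates", 3),
            n_flies_per_cell=sim.get("n_flies_per_cell", 8),
            infected_fraction=sim.get("infected_fraction", 9 / 16),
            seed=rng_seed,
            dropout_rate=sim.get("dropout_rate", 0.0),
        )
        truth = generate_truth(
            n_genes=sim.get("n_genes", 200),
            prop_active_per_term=sim.get("prop_active_per_term"),
            effect_sd=sim.get("effect_sd", 0.5),
            dispersion_range=tuple(sim.get("dispersion_range", (0.05, 0.5))),
            cve_config=sim.get("cve_config"),
            n_genotypes=sim.get("n_genotypes", 16),
            n_replicates=sim.get("n_replicates", 3),
            seed=rng_seed + 1,
        )
        counts, _ = simulate_counts(
            design, truth, tuple(sim.get("size_factor_range", (0.7, 1.4))), seed=rng_seed + 2
        )
        n_intergenic = sim.get("n_intergenic", 0)
        if n_intergenic:
            intergenic = simulate_intergenic_counts(
                n_intergenic, design, sim.get("intergenic_mean", 1.0), seed=rng_seed + 3
            )
        mio.write_counts(counts, out / "counts.tsv")
        mio.write_design(design, out / "design.tsv")
        mio.write_truth(truth, out / "truth.tsv")
    else:
        counts = mio.read_counts(config.counts_path)
        design = mio.read_design(config.design_path)
        if config.intergenic_path:
            intergenic = mio.read_counts(config.intergenic_path)
    if list(counts.columns) != list(design["sample_id"]):
        design = design.set_index("sample_id").loc[list(counts.columns)].reset_index()
    _stage("input", t0, genes=counts.shape[0], samples=counts.shape[1])

    # ---- stage: normalize + filter --------------------------------------
    sf = size_factors(counts)
    norm = normalize(counts, sf)
    if config.threshold is not None:
        threshold = float(config.threshold)
    elif intergenic is not None:
        norm_inter = normalize(intergenic, sf)
        threshold = derive_threshold(norm, norm_inter)
    else:
        threshold = DEFAULT_THRESHOLD
    kept, report = filter_expressed(norm, threshold)
    kept_counts = counts.loc[kept.values.index]
    kept.values.to_csv(out / "normalized.tsv", sep="\t")
    _stage(
        "normalize_filter",
        t0,
        threshold=round(threshold, 4),
        all_zero=report.n_all_zero,
        below=report.n_below_threshold,
        expressed=report.n_expressed,
    )

    # ---- stage: DE ladder -------------------------------------------------
    terms = tuple(config.terms) if config.terms else None
    tt = test_all_terms(kept_counts, design, sf.to_numpy())
    if terms:
        tt = tt[tt["term"].isin(terms)].reset_index(drop=True)
    tt.to_csv(out / "term_tests.tsv", sep="\t", index=False)
    _stage("de_ladder", t0, tests=len(tt))

    # ---- stage: variance heterogeneity -----------------------------------
    hov = None
    if config.run_hov:
        hov = hov_tests(kept.values, design, center="median")
        hov.to_csv(out / "hov_tests.tsv", sep="\t", index=False)
        _stage("hov", t0, n_sig=int((hov["fdr"] < config.alpha).sum()))

    # ---- stage: CV_E + ANOVA + heritability -------------------------------
    ctab = cve_table(kept.values, design)
    ctab.to_csv(out / "cve_table.tsv", sep="\t", index=False)
    canova = cve_anova(ctab, alpha=config.alpha)
    canova.to_csv(out / "cve_anova.tsv", sep="\t", index=False)
    h2_expr = heritability_table(kept.values, design, scheme="expression")
    h2_expr.to_csv(out / "heritability_expression.tsv", sep="\t", index=False)
    h2_cve = heritability_table(kept.values, design, scheme="cve", cve_tab=ctab)
    h2_cve.to_csv(out / "heritability_cve.tsv", sep="\t", index=False)
    _stage(
        "plasticity",
        t0,
        mean_h2_expr=round(float(h2_expr["h2"].mean()), 4),
        mean_h2_cve=round(float(h2_cve["h2"].mean()), 4),
    )

    # ---- stage: clustering + enrichment -----------------------------------
    sig = tt[(tt["term"] == config.cluster_term) & (tt["fdr"] < config.alpha)]
    modules_summary: dict = {"n_modules": 0, "q": None, "n_genes": 0}
    enrich_hits = 0
    if len(sig) >= 3:
        sub = kept.values.loc[sorted(sig["gene_id"])]
        cor = correlation_matrix(sub, method=config.cluster_method)
        assign = mmc_cluster(cor)
        assign.as_frame().to_csv(out / "modules.tsv", sep="\t", index=False)
        modules_summary = {
            "n_modules": int(assign.module_labels.max()),
            "q": round(float(assign.modularity_q), 6),
            "n_genes": len(assign.gene_ids),
        }
        if config.gene_sets_path:
            sets = read_gmt(config.gene_sets_path)
            universe = list(kept.values.index)
            blocks = []
            for m in np.unique(assign.module_labels):
                mg = [g for g, l in zip(assign.gene_ids, assign.module_labels) if l == m]
                blocks.append(geneset_enrichment(mg, sets, universe, module_label=int(m)))
            enr = pd.concat(blocks, ignore_index=True)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            enrich_hits = int((enr["bonferroni_p"] < config.alpha).sum())
    _stage("clustering", t0, **modules_summary)

    # ---- stage: screens ----------------------------------------------------
    screen_counts: dict = {}
    if config.run_screens and "infected" in design.columns and design["infected"].nunique() == 2:
        inf = infection_test(kept_counts, design, sf.to_numpy())
        inf.to_csv(out / "screen_infection.tsv", sep="\t", index=False)
        screen_counts["infection"] = int((inf["fdr"] < config.alpha).sum())
    if config.run_screens and config.covariates:
        sd_tab = line_sd(kept.values, design)
        for screen, path in sorted(config.covariates.items()):
            cov = mio.read_covariate(path)
            res = covariate_correlation(sd_tab, cov, screen=screen)
            res.to_csv(out / f"screen_{screen}.tsv", sep="\t", index=False)
            screen_counts[screen] = int((res["fdr"] < config.alpha).sum())
    _stage("screens", t0, **screen_counts)

    # ---- summary -----------------------------------------------------------
    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": rng_seed,
        "filter": {
            "n_input_genes": report.n_input_genes,
            "n_all_zero": report.n_all_zero,
            "n_below_threshold": report.n_below_threshold,
            "n_expressed": report.n_expressed,
            "threshold": round(threshold, 6),
        },
        "table1": summarize_table1(tt, canova, config.alpha),
        "hov_significant": (
            int((hov["fdr"] < config.alpha).sum()) if hov is not None else None
        ),
        "mean_h2_expression": round(float(h2_expr["h2"].mean()), 6),
        "mean_h2_cve": round(float(h2_cve["h2"].mean()), 6),
        "modules": modules_summary,
        "enrichment_hits": enrich_hits,
        "screens": screen_counts,
    }
    for term, entry in summary["table1"].items():
        if entry["de"] > report.n_expressed:
            raise AssertionError("DE count exceeds expressed genes")
    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    _stage("done", t0)
    return summary
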