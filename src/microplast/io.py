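"""Plain-text (TSV) readers and writers for the pipeline's tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SyntheticTruth, TERM_FACTORS


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label=counts.index.name or "gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    cm = pd.read_csv(path, sep="\t", index_col=0)
    if cm.index.duplicated().any():
        raise ValueError("duplicate gene ids in count table")
    if cm.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count table")
    vals = cm.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative entries in count table")
    return cm


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"genotype": str, "sex": str, "replicate": str})
    required = {"sample_id", "genotype", "sex", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if "infected" in design.columns:
        design["infected"] = design["infected"].astype(bool)
    return design


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Long-format truth table keyed by gene and term."""
    rows = []
    for gi, gene in enumerate(truth.gene_ids):
        rows.append(
            {
                "gene_id": gene,
                "term": "baseline",
                "levels": "",
                "value": truth.baseline[gi],
            }
        )
        rows.append(
            {"gene_id": gene, "term": "dispersion", "levels": "", "value": truth.dispersion[gi]}
        )
        for term, eff in truth.effects.items():
            if not truth.active_terms[term][gi]:
                continue
            flat = eff[gi].ravel()
            for j, v in enumerate(flat):
                idx = np.unravel_index(j, eff[gi].shape)
                rows.append(
                    {
                        "gene_id": gene,
                        "term": term,
                        "levels": "|".join(str(i) for i in idx),
                        "value": v,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_covariate(cov: pd.Series, path: str | Path) -> None:
    cov.rename("value").rename_axis("genotype").to_csv(path, sep="\t")


def read_covariate(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str})
    if df["genotype"].duplicated().any():
        raise ValueError("covariate table has duplicate genotypes")
    return df.set_index("genotype")["value"].astype(float)
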