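"""Gene-set enrichment (hypergeometric, Bonferroni) and the sex-bias test.

Enrichment of a module in user-supplied gene sets (GMT format) is tested
with the hypergeometric upper tail against a stated gene universe, with
Bonferroni control over the number of sets tested.  The sex-bias
contingency test compares the male-biased fraction inside a focus gene
list with the rest of the transcriptome by Fisher's exact test (two-sided,
by hypergeometric enumeration over the conditional support).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class EnrichmentResult:
    module_label: int | str
    set_name: str
    k_in: int
    K_set: int
    n_module: int
    N: int
    p_value: float
    bonferroni_p: float


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> member ids...."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")


def geneset_enrichment(
    module_genes,
    gene_sets: dict[str, list[str]],
    universe,
    module_label: int | str = 1,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of one module in each set.

    Sets are intersected with the universe before testing; Bonferroni
    multiplies by the number of sets tested.
    """
    universe = set(universe)
    module = set(module_genes)
    if not universe:
        raise ValueError("empty universe")
    if not module:
        raise ValueError("empty module")
    if not module <= universe:
        raise ValueError("module genes must be a subset of the universe")
    N, n = len(universe), len(module)
    m_tests = len(gene_sets)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & universe)
        k = len(set(members) & module)
        # P(overlap >= k) under sampling n of N with K marked
        p = float(hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append(
            EnrichmentResult(
                module_label=module_label,
                set_name=name,
                k_in=k,
                K_set=K,
                n_module=n,
                N=N,
                p_value=min(1.0, p),
                bonferroni_p=min(1.0, p * m_tests),
            ).__dict__
        )
    return pd.DataFrame(rows)


def sex_bias_fisher(
    n_biased_in_focus: int, n_focus: int, n_biased_in_rest: int, n_rest: int
) -> tuple[float, float]:
    """Fisher's exact test of bias enrichment in a focus gene list.

    2x2 table: rows focus/rest, columns biased/not.  Returns the sample
    odds ratio ad/bc and the two-sided p obtained by summing, over the
    conditional hypergeometric support, all tables at most as probable as
    the observed one.
    """
    a, b = n_biased_in_focus, n_focus - n_biased_in_focus
    c, d = n_biased_in_rest, n_rest - n_biased_in_rest
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if a * d == 0 and b * c == 0:
        odds = np.nan
    elif b * c == 0:
        odds = np.inf
    else:
        odds = (a * d) / (b * c)

    N = a + b + c + d
    K = a + c  # biased column total
    n = a + b  # focus row total
    if N == 0:
        return float(odds), 1.0
    support = np.arange(max(0, n + K - N), min(n, K) + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = hypergeom.pmf(a, N, K, n)
    p = float(pmf[pmf <= p_obs * (1 + 1e-10)].sum())
    return float(odds), min(1.0, p)
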