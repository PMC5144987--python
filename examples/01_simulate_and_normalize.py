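"""Simulate a balanced single-fly RNA-seq design and normalize it.

Builds a small version of the study layout (4 genotypes x 2 replicate
environments x 2 sexes x 3 flies), draws NB counts with gene-specific
overdispersion, then applies median-of-ratios normalization and the
empirical low-expression filter.
"""

import numpy as np

import microplast as mp

design = mp.generate_design(
    n_genotypes=4, n_replicates=2, n_flies_per_cell=3,
    infected_fraction=0.5, seed=1,
)
truth = mp.generate_truth(
    n_genes=200, prop_active_per_term={"G": 0.2},
    dispersion_range=(0.05, 0.5), n_genotypes=4, n_replicates=2, seed=2,
)
counts, true_sf = mp.simulate_counts(design, truth, seed=3)
print(f"design: {len(design)} flies; counts: {counts.shape[0]} genes")

sf = mp.size_factors(counts)
print("first size factors (estimated vs true):")
for sid, est, tru in zip(counts.columns[:4], sf[:4], true_sf[:4]):
    print(f"  {sid}: {est:.3f} vs {tru:.3f}")
# estimated factors track the true library-scale distortions closely

norm = mp.normalize(counts, sf)
kept, report = mp.filter_expressed(norm, threshold=mp.DEFAULT_THRESHOLD)
print(
    f"filter at {report.threshold} normalized counts: "
    f"{report.n_all_zero} all-zero, {report.n_below_threshold} below threshold, "
    f"{report.n_expressed} expressed"
)
# a gene survives if it clears the threshold in at least one fly

inter = mp.simulate_intergenic_counts(300, design, low_mean=1.0, seed=4)
thr = mp.derive_threshold(norm, mp.normalize(inter, sf))
print(f"threshold derived from the genic/intergenic density crossing: {thr:.3f}")
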