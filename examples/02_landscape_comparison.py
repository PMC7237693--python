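"""Cross-dataset landscape comparison and the diagonal-split test.

Recovers a configured correlation structure (germline-germline 0.65,
human-tumor 0.16, ape-tumor 0.55) from simulated catalogs and asks
whether tumor densities are higher in windows ranked hotter in the
chimpanzee-like dataset than in the human-like one -- the diagonal
split.  A small human-tumor correlation relative to ape-tumor makes the
split strongly significant.
"""

import logging

from mutland.studies import landscape_recovery

logging.basicConfig(level=logging.WARNING)

res = landscape_recovery(seed=7, n_windows=1000, mean_mutations_per_window=1500.0)
print("configured correlation structure:")
print(res.configured.round(2))
print("\nrecovered from the full pipeline (z-score Pearson):")
print(res.correlations.round(3))
print(
    f"\ndiagonal split (tumor response): U={res.split.statistic:.0f}, "
    f"p={res.split.p_value:.3g}, groups {res.split.n1}/{res.split.n2}, "
    f"ties excluded {res.split.metadata['ties_excluded']}"
)
print(f"95/5 fold-enrichment per dataset: { {k: round(v, 2) for k, v in res.fold_enrichment.items()} }")
# The recovered matrix matches the configured one up to log-normal and
# Poisson attenuation (a few hundredths); the split p value is far below
# 0.05 because windows where the ape-like landscape runs hotter than the
# human-like one systematically carry more tumor mutations.
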