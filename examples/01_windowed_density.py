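"""Windowed mutation densities from a simulated variant catalog.

Builds a small three-dataset study (human-like, chimpanzee-like, and a
tumor catalog), combines the accessibility masks, tiles overlapping
windows, applies the variant quality filters and prints each dataset's
density summary.  Densities are SNVs per Mbp of window corrected by the
window's passing fraction; the 95/5 fold-enrichment summarises how
uneven each landscape is.
"""

import logging

import numpy as np

from mutland.density import density_table, filter_variants
from mutland.landscape import quantile_fold_enrichment
from mutland.simulate import (
    SimulationConfig,
    simulate_density_field,
    simulate_masks,
    simulate_reference,
    simulate_variant_catalogs,
)
from mutland.windows import combine_masks, make_windows

logging.basicConfig(level=logging.WARNING)

config = SimulationConfig(
    n_chromosomes=2,
    chrom_length=1_000_000,
    window_size=50_000,
    step=25_000,
    mean_mutations_per_window=300.0,
    seed=7,
)
reference, _ = simulate_reference(config)
field = simulate_density_field(config)
sim = simulate_variant_catalogs(config, field, reference)
mappability, callability, cnv = simulate_masks(config)
mask = combine_masks(mappability, callability, cnv, config.genome_sizes)
windows = make_windows(config.genome_sizes, mask, config.window_size, config.step)

print(f"pass fraction of the genome: {mask.pass_length() / sum(config.genome_sizes.values()):.3f}")
print(f"windows: {len(windows)}, retained (>=50% passing): {int(windows['retained'].sum())}")
for name, catalog in sim.catalogs.items():
    filtered, tallies = filter_variants(catalog)
    table = density_table(filtered, windows, mask)
    fold = quantile_fold_enrichment(table["d"].to_numpy())
    print(
        f"{name:12s} {len(catalog):6d} records, {len(filtered):6d} after filters "
        f"(removed: {tallies.as_dict()}), mean density {table['d'].mean():8.1f}/Mbp, "
        f"95/5 fold-enrichment {fold:.2f}"
    )
# The filters remove records with >=20% missing genotypes, variants within
# 5 bp of an InDel, >80% heterozygous calls, and fixed-derived sites; the
# fold-enrichment shows the hottest windows carry ~2x the mutation rate of
# the coldest, as the log-normal intensity field prescribes.
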