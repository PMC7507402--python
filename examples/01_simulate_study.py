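"""Generate a synthetic bypass-suppression study and summarise it.

Builds a compact genome, a functional compendium, and a suppressor-
isolation cohort, then prints the cohort-level statistics the generator
is calibrated to: the fraction of dispensable query genes, the median
number of unique nonsynonymous variants per strain, and the fraction of
strains with genome-content changes.
"""

import numpy as np

from bypassnet import synthetic_data as sd

genes, chroms = sd.generate_genome(
    n_genes=2000, n_chromosomes=16, genome_bp=12_000_000, seed=7
)
comp = sd.generate_compendium(genes, n_complexes=150, n_pathways=50, seed=7)
strains, variants, experiments, truth = sd.generate_suppression_study(
    genes, comp, n_queries=200, seed=7
)

nonsyn_per_strain = (
    variants.loc[variants["nonsynonymous"]].groupby("strain_id").size()
)
content_change = np.mean(
    [st.mechanism != "snp" for st in truth.strains.values()]
)
print(f"queries tested: {len(truth.tested_queries)}")
print(f"dispensable queries: {len(truth.dispensable_queries)} "
      f"({len(truth.dispensable_queries) / len(truth.tested_queries):.0%})")
print(f"suppressor strains isolated: {len(strains)}")
print(f"median unique nonsynonymous variants per strain: "
      f"{nonsyn_per_strain.median():.0f}")
print(f"strains with genome-content changes: {content_change:.0%}")
# Roughly 17% of essential query genes should prove dispensable, strains
# should carry a median of 2-3 nonsynonymous variants, and about half of
# them should suppress via aneuploidy, partial amplification, or WGD.
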