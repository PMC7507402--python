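"""Estimate discovery saturation from an experiment log.

Splits each query's isolation experiments into four artificial screens,
averages new-discovery counts over 1,000 random assignments, fits the
logarithmic model C(k) = a + b ln k, and extrapolates.
"""

from bypassnet import synthetic_data as sd
from bypassnet.saturation import average_discovery_curve, fit_and_extrapolate

genes, _ = sd.generate_genome(n_genes=1000, n_chromosomes=8,
                              genome_bp=5_000_000, seed=11)
comp = sd.generate_compendium(genes, n_complexes=100, n_pathways=30, seed=11)
_, _, experiments, truth = sd.generate_suppression_study(
    genes, comp, n_queries=150, frac_dispensable=0.5, seed=11
)

curve = average_discovery_curve(
    experiments, endpoint="dispensable_genes", n_permutations=1000, seed=11
)
model = fit_and_extrapolate(curve, horizon=20)
print("mean new dispensable genes per screen:",
      [f"{x:.1f}" for x in curve.mean_new])
print(f"logarithmic fit: C(k) = {model.intercept:.1f} + {model.slope:.1f} ln k")
print(f"expected new discoveries in screens 5-8: "
      f"{model.extrapolated_new[:4].sum():.1f}")
print(f"fraction discovered by screen 4, horizon 20 screens: "
      f"{model.discovered_fraction:.0%}")
if model.bounded_fit:
    print(f"bounded-fit pool size: {model.bounded_fit['pool_size']:.0f} genes; "
          f"fraction discovered: {model.bounded_fit['discovered_fraction']:.0%}")
# New discoveries per screen decay roughly logarithmically; the
# discovered fraction is only meaningful against the stated horizon.
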