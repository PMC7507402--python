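"""Call chromosome copy numbers and partial amplifications from depth.

Generates noisy binned read-depth profiles for a cohort with planted
genome-content changes, calls copy numbers per chromosome, segments one
partially amplified chromosome, and reports recovery against the truth.
"""

from bypassnet import synthetic_data as sd
from bypassnet.genome_calls import (
    call_chromosome_copy_numbers,
    compute_genome_size,
    segment_partial_amplifications,
    StrainCall,
    AmplifiedSegment,
)

genes, chroms = sd.generate_genome(
    n_genes=800, n_chromosomes=8, genome_bp=4_000_000, seed=3
)
comp = sd.generate_compendium(genes, n_complexes=60, n_pathways=20, seed=3)
_, _, _, truth = sd.generate_suppression_study(
    genes, comp, n_queries=60, frac_dispensable=1.0, seed=3
)
depth = sd.generate_depth_profiles(
    truth, chroms, bin_bp=10_000, mean_depth=30, noise_cv=0.1, seed=3
)

correct = total = 0
partial_strain = None
for sid, st in truth.strains.items():
    calls = call_chromosome_copy_numbers(depth[depth["strain_id"] == sid], st.ploidy)
    for c, k in st.copy_numbers.items():
        total += 1
        correct += int(calls.loc[c, "copy_number"] == k)
    if st.mechanism == "partial_amplification" and partial_strain is None:
        partial_strain = st
print(f"chromosome copy numbers recovered: {correct}/{total}")
# Every chromosome call should match the planted copy number at 30x
# depth with 10% multiplicative noise.

if partial_strain is not None:
    c, s, e, k = partial_strain.partial_segments[0]
    prof = depth[depth["strain_id"] == partial_strain.strain_id]
    segs = segment_partial_amplifications(prof, c, partial_strain.ploidy)
    print(f"planted segment chr{c}:{s}-{e} copy {k}")
    for seg in segs:
        print(f"called  segment chr{seg.chromosome}:{seg.start_bp}-{seg.end_bp} "
              f"copy {seg.copy_number}")
    lengths = dict(zip(chroms["chromosome"], chroms["length_bp"]))
    call = StrainCall(
        partial_strain.strain_id, partial_strain.ploidy,
        dict(partial_strain.copy_numbers),
        [AmplifiedSegment(*partial_strain.partial_segments[0])],
    )
    print(f"genome size including the amplification: "
          f"{compute_genome_size(call, lengths) / 1e6:.2f} Mb")
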