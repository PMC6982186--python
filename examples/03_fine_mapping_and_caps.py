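"""Narrow a locus with codominant markers and score a CAPS assay.

Fine mapping: genotype the simulated F2 at a handful of markers around the
locus; every short plant must be homozygous (B) at the causal position, so
markers contradicted by recombinants bound the interval.  CAPS: a SNP that
destroys an EcoRI site makes the two parents' digest patterns differ.
"""

import numpy as np

from bsamap import (
    CapsAssay, CausalLocusSpec, caps_polymorphic, cosegregation_summary,
    default_map, extract_marker_genotypes, narrow_interval, simulate_f2_population,
)

genetic_map = default_map()
snps = genetic_map.snp_positions["Chr2"]
mid = snps.size // 2
causal = CausalLocusSpec("Chr2", int(snps[mid]))
population = simulate_f2_population(genetic_map, causal, n=430, seed=5)

marker_positions = snps[[mid - 25, mid - 12, mid - 5, mid - 2, mid, mid + 2, mid + 5, mid + 12, mid + 25]]
table = extract_marker_genotypes(population, {"Chr2": np.asarray(marker_positions)})

interval = narrow_interval(table)
print(f"interval: {interval.chromosome}:{interval.start:,}-{interval.end:,} "
      f"({interval.length / 1000:.1f} kb) between {interval.left_marker} and "
      f"{interval.right_marker}, using {interval.n_recombinants_used} recombinants")
print(f"planted locus {causal.position:,} lies inside: "
      f"{interval.start <= causal.position <= interval.end}")

coseg = cosegregation_summary(table, f"M_Chr2_{causal.position}")
print(f"\nmarker at the locus: classes A/H/B = {coseg.counts}, "
      f"concordance with phenotype = {coseg.concordance:.3f}, "
      f"1:2:1 fit p = {coseg.segregation.p:.3f}")

# CAPS assay: the G>C SNP destroys the only EcoRI site in parent B's amplicon
parent_a = "ATGC" * 10 + "GAATTC" + "TTAC" * 12
parent_b = "ATGC" * 10 + "GACTTC" + "TTAC" * 12
poly, frag_a, frag_b = caps_polymorphic(CapsAssay("EcoRI", "GAATTC", 1, parent_a, parent_b))
print(f"\nCAPS digest: parent A fragments {frag_a}, parent B fragments {frag_b} "
      f"-> {'polymorphic (scorable on a gel)' if poly else 'monomorphic'}")
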