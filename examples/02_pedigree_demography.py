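"""Pedigree demography of a simulated breed.

Computes completeness (g_e), depth-limited inbreeding, effective
population size from the rate of inbreeding, and the three gene-origin
diversity measures: effective numbers of earliest documented relatives
(EDR_e), of ancestors (EDR_a), and of founder genomes (EDR_g).
"""

import breedstruct as bs

config = bs.SimConfig(seed=42, n_founders=16, start_year=1950,
                      end_year=2000, closure_year=1956,
                      litters_per_year=6.0, litter_size_mean=3.0,
                      immigrants_per_year=2, bottleneck=(1975, 0.3))
ped, _ = bs.simulate_pedigree(config)

# reference population: dogs born in the last six years, plus ancestors
refped = bs.build_reference_pedigree(ped, (1995, 2000))
print(f"reference population: {len(refped.reference_ids)} dogs; "
      f"reference pedigree: {len(refped.closure_ids)} dogs")

comp = bs.completeness(refped)
print(f"equivalent complete generations g_e = {comp.g_e:.1f}")

for depth in (5, 10, "full"):
    series = bs.inbreeding(refped, depth=depth)
    print(f"mean F (depth {depth!s:>4}): {series.f_reference_mean:.4f}")
# Truncating the pedigree can only remove inbreeding loops, so F rises
# with depth; the full-depth value is the breed's true pedigree F.

series = bs.inbreeding(refped, depth="full")
ne = bs.ne_from_reference(series)
print(f"delta-F = {ne.delta_f:.4f}  ->  Ne = {ne.ne:.1f}" if ne.defined
      else f"Ne undefined: {ne.reason}")

contrib = bs.edr_ancestors(refped)
genomes = bs.edr_genomes(refped, reps=1000, seed=1)
print(f"EDR_e = {contrib.edr_e:.1f}  EDR_a = {contrib.edr_a:.1f}  "
      f"EDR_g = {genomes.edr_g:.1f}")
print(f"bottleneck ratio EDR_e/EDR_a = {bs.bottleneck_ratio(contrib):.2f} "
      "(> 1 signals a historical bottleneck)")
top_id, top_p = contrib.top_ancestors[0]
print(f"most influential ancestor: {top_id} explains {top_p:.0%} "
      "of the reference gene pool")
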