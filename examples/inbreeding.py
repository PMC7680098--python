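"""Estimate the inbreeding coefficient F of the diploid samples.

F compares a sample's observed homozygosity to the Hardy-Weinberg
expectation from subset allele frequencies: F ~ 0 means outbred, F > 0
an excess of homozygotes (e.g. selfing), F < 0 an excess of heterozygotes.
"""

from radclone import (
    SimulationConfig,
    call_ploidy,
    inbreeding_coefficient,
    recode_genotypes,
    simulate_population,
)

config = SimulationConfig(
    n_circles=10, samples_per_circle=2, ploidy_mix={2: 1.0},
    n_sites=10000, selfing_F=0.0, seed=5,
)
variants, sheet, hap_summary, truth = simulate_population(config)

# identify diploids from the data (here: all of them), then estimate F
calls = call_ploidy(variants, hap_summary)
diploids = [s for s in variants.sample_ids if calls[s].ploidy == 2]
matrix = recode_genotypes(variants)
result = inbreeding_coefficient(matrix, diploid_samples=diploids)

print(f"diploid samples: {len(diploids)}, polymorphic site set: {result.n_sites}")
print(f"mean F = {result.mean_f:+.3f}  "
      f"(95% CI [{result.ci_low:+.3f}, {result.ci_high:+.3f}], {result.ci_method})")
extremes = sorted(result.f_per_sample.items(), key=lambda kv: kv[1])
print(f"lowest : {extremes[0][0]} F={extremes[0][1]:+.3f}")
print(f"highest: {extremes[-1][0]} F={extremes[-1][1]:+.3f}")
# Simulated truth is F=0 (random mating): the CI should cover 0, indicating
# fully outbred plants.
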