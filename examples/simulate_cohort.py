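"""Generate a synthetic mixed-ploidy cohort and write it to disk.

Produces the three pipeline inputs (VCF with allele depths, sample sheet,
haplotype-count summary) plus the ground truth used for validation.
"""

from pathlib import Path

from radclone import (
    SimulationConfig,
    simulate_population,
    write_locus_haplotype_summary,
    write_sample_sheet,
    write_variant_table,
)

out = Path("cohort_out")
out.mkdir(exist_ok=True)

config = SimulationConfig(n_circles=15, samples_per_circle=3, n_sites=5000, seed=42)
variants, sheet, hap_summary, truth = simulate_population(config)

write_variant_table(variants, out / "cohort.vcf")
write_sample_sheet(sheet, out / "samples.tsv")
write_locus_haplotype_summary(hap_summary, out / "hap_counts.tsv")
truth.to_json(out / "ground_truth.json")

ploidies = sorted(truth.true_ploidy.values())
print(f"samples: {variants.n_samples}  sites: {variants.n_sites}")
print(f"circles: {len(sheet.circle_ids)}  (centers >= {config.circle_spacing_m} m apart)")
print("ploidy composition:", {k: ploidies.count(k) for k in (2, 4, 8)})
print(f"wrote VCF + TSVs + ground truth under {out}/")
# The ploidy composition reflects the configured cohort mix; every sample in
# the VCF carries per-site ref,alt read depths (FORMAT/AD) for the analysis.
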