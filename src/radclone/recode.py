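"""Site filtering and ternary genotype recoding.

Mixed-ploidy cohorts cannot share a dosage-based genotype code, so calls are
collapsed to {0, 0.5, 1}: 0 if essentially only reference reads, 1 if only
alternative reads, 0.5 if both alleles exceed the heterozygosity threshold
(default: strictly more than 5% of reads each).  Only sites covered at or
above the depth threshold in *every* analysed sample are kept, so the
recoded matrix has no missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VariantTable


@dataclass
class RecodedGenotypeMatrix:
    """Sites x samples matrix over {0, 0.5, 1} plus the filters that made it."""

    site_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        allowed = np.isin(self.values, (0.0, 0.5, 1.0))
        if not allowed.all():
            raise ValueError("recoded values must all be 0, 0.5 or 1")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def subset_samples(self, sample_ids: list[str]) -> "RecodedGenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return RecodedGenotypeMatrix(
            site_ids=self.site_ids,
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            provenance=dict(self.provenance),
        )


def recode_genotypes(vt: VariantTable, samples: list[str] | None = None,
                     min_depth: int = 11, het_threshold: float = 0.05,
                     min_individuals_variant: int = 1,
                     conserved_only: bool = False) -> RecodedGenotypeMatrix:
    """Recode allele depths into the ternary {0, 0.5, 1} genotype matrix.

    Per cell, with f = alt/(ref+alt) and threshold t: f <= t -> 0,
    f >= 1-t -> 1, otherwise 0.5 (both alleles must exceed t strictly for a
    heterozygous call).  Filters, in order: optional restriction to the
    conserved site subset; total depth >= ``min_depth`` in every selected
    sample; optional requirement that a non-reference code (0.5 or 1) occur
    in at least ``min_individuals_variant`` samples.

    Raises if no site survives, naming the filter that removed the last one.
    """
    if samples is None:
        samples = list(vt.sample_ids)
    sub = vt.subset_samples(samples)

    keep = np.ones(sub.n_sites, dtype=bool)
    if conserved_only:
        keep &= sub.conserved_flag
        if not keep.any():
            raise ValueError("no sites remain after the conserved-subset filter")

    total = sub.total_depth
    keep &= (total >= min_depth).all(axis=1)
    if not keep.any():
        raise ValueError(
            f"no sites remain after requiring depth >= {min_depth} in all samples"
        )

    ref = sub.ref_depth[keep].astype(float)
    alt = sub.alt_depth[keep].astype(float)
    f = alt / (ref + alt)
    values = np.full(f.shape, 0.5)
    values[f <= het_threshold] = 0.0
    values[f >= 1.0 - het_threshold] = 1.0

    site_ids = [s for s, k in zip(sub.site_ids, keep) if k]
    if min_individuals_variant > 1:
        variant_in = (values > 0.0).sum(axis=1)
        keep2 = variant_in >= min_individuals_variant
        if not keep2.any():
            raise ValueError(
                "no sites remain after requiring a non-reference call in "
                f">= {min_individuals_variant} individuals"
            )
        values = values[keep2]
        site_ids = [s for s, k in zip(site_ids, keep2) if k]

    return RecodedGenotypeMatrix(
        site_ids=site_ids,
        sample_ids=list(samples),
        values=values,
        provenance={
            "min_depth_all_samples": min_depth,
            "het_threshold": het_threshold,
            "min_individuals_variant": min_individuals_variant,
            "conserved_only": conserved_only,
        },
    )
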