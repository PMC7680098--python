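"""Readers, writers and validation for the pipeline's tabular artifacts.

The central input is a VCF with per-sample allele depths (FORMAT/AD), from
which only biallelic SNPs are carried forward.  Everything else is plain
TSV/JSON: the sample sheet describing the circle sampling design, the
per-sample RAD-locus haplotype-count summary, and distance matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = ["sample_id", "circle_id", "position_label", "center_x", "center_y"]
HAPLOTYPE_SUMMARY_COLUMNS = ["sample_id", "n_loci_1hap", "n_loci_2hap", "n_loci_3plus_hap"]


@dataclass
class VariantTable:
    """Biallelic SNP sites with per-sample ref/alt read depths.

    Depth arrays are sites x samples.  ``conserved_flag`` marks the stringent
    "conserved subset" of sites used for the stricter second-pass analysis
    (a stand-in for loci mappable to a conserved reference genome).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    sample_ids: list[str]
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    conserved_flag: np.ndarray

    def __post_init__(self) -> None:
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int64)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.conserved_flag = np.asarray(self.conserved_flag, dtype=bool)
        if self.ref_depth.shape != self.alt_depth.shape:
            raise ValueError("ref_depth and alt_depth must have identical shape")
        if self.ref_depth.shape != (self.n_sites, self.n_samples):
            raise ValueError(
                f"depth arrays must be sites x samples = {self.n_sites}x{self.n_samples}"
            )
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValueError("read depths must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if len(set(self.site_ids)) != self.n_sites:
            raise ValueError("site identifiers (chrom, pos) must be unique")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def site_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in variant table") from None

    def subset_samples(self, sample_ids: list[str]) -> "VariantTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return VariantTable(
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            sample_ids=list(sample_ids),
            ref_depth=self.ref_depth[:, idx],
            alt_depth=self.alt_depth[:, idx],
            conserved_flag=self.conserved_flag,
        )


@dataclass
class SampleSheet:
    """Sampling design: which circle each sample came from, and circle centers.

    Wraps a DataFrame with columns sample_id, circle_id, position_label,
    center_x, center_y (planar metres).  All samples of one circle share one
    center; converting geographic coordinates to a local tangent plane is the
    caller's job.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing required columns: {missing}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id in sample sheet: {sorted(set(dup))}")
        for circle, grp in self.table.groupby("circle_id"):
            if grp[["center_x", "center_y"]].drop_duplicates().shape[0] > 1:
                raise ValueError(f"inconsistent center coordinates within circle {circle!r}")
            if len(grp) < 2:
                logger.warning(
                    "circle %r has <2 samples; within-circle statistics will skip it", circle
                )
        centers = self.table.drop_duplicates("circle_id")[["circle_id", "center_x", "center_y"]]
        shared = centers.duplicated(subset=["center_x", "center_y"], keep=False)
        if shared.any():
            logger.warning(
                "circles share a center (distance 0 between centers): %s",
                sorted(centers.loc[shared, "circle_id"]),
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def circle_ids(self) -> list:
        return list(dict.fromkeys(self.table["circle_id"]))

    def circle_of(self) -> dict:
        return dict(zip(self.table["sample_id"], self.table["circle_id"]))

    def samples_of(self, circle_id) -> list[str]:
        return list(self.table.loc[self.table["circle_id"] == circle_id, "sample_id"])

    def centers(self) -> dict:
        sub = self.table.drop_duplicates("circle_id")
        return {
            row.circle_id: (float(row.center_x), float(row.center_y))
            for row in sub.itertuples()
        }

    def validate_against(self, vt: VariantTable) -> None:
        """Cross-check membership between the design sheet and a variant table."""
        sheet = set(self.sample_ids)
        table = set(vt.sample_ids)
        missing_from_table = sorted(sheet - table)
        if missing_from_table:
            raise ValueError(
                f"sample(s) in sheet but absent from variant table: {missing_from_table}"
            )
        missing_from_sheet = sorted(table - sheet)
        if missing_from_sheet:
            raise ValueError(
                f"sample(s) in variant table but absent from sheet: {missing_from_sheet}"
            )


@dataclass
class LocusHaplotypeSummary:
    """Per-sample counts of RAD loci with 1, 2 or >=3 distinct haplotypes."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in HAPLOTYPE_SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"haplotype summary missing required columns: {missing}")
        counts = self.table[HAPLOTYPE_SUMMARY_COLUMNS[1:]]
        if (counts.to_numpy() < 0).any():
            raise ValueError("haplotype locus counts must be non-negative")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def n_loci_3plus(self, sample_id: str) -> int:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in haplotype summary")
        return int(row["n_loci_3plus_hap"].iloc[0])

    def total_loci(self, sample_id: str) -> int:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in haplotype summary")
        return int(row[HAPLOTYPE_SUMMARY_COLUMNS[1:]].iloc[0].sum())


# ---------------------------------------------------------------------------
# VCF

def read_variant_table(path: str | Path) -> VariantTable:
    """Read a VCF with per-sample AD into a :class:`VariantTable`.

    Only biallelic SNP records are kept; multi-allelic or non-SNP records are
    dropped with a logged count.  The per-site INFO flag ``CONSERVED`` (if
    present) populates ``conserved_flag``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with pysam.VariantFile(str(path)) as vcf:
        if "AD" not in vcf.header.formats:
            raise ValueError(
                "variant file lacks the per-sample allele-depth annotation FORMAT/AD"
            )
        samples = list(vcf.header.samples)
        has_conserved = "CONSERVED" in vcf.header.info
        chrom, pos, ref_a, alt_a, conserved = [], [], [], [], []
        ref_rows, alt_rows = [], []
        n_dropped = 0
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or rec.ref is None or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_dropped += 1
                continue
            ad = [rec.samples[s].get("AD") for s in samples]
            if any(a is None or a[0] is None for a in ad):
                raise ValueError(
                    f"missing AD at {rec.chrom}:{rec.pos}; allele depths are required"
                )
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref_a.append(rec.ref)
            alt_a.append(alts[0])
            conserved.append(bool(rec.info.get("CONSERVED", False)) if has_conserved else False)
            ref_rows.append([a[0] for a in ad])
            alt_rows.append([a[1] for a in ad])
    if n_dropped:
        logger.warning("dropped %d multi-allelic or non-SNP site(s)", n_dropped)
    if not pos:
        raise ValueError("no usable biallelic SNP sites in variant file")
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos),
        ref_allele=np.array(ref_a, dtype=object),
        alt_allele=np.array(alt_a, dtype=object),
        sample_ids=samples,
        ref_depth=np.array(ref_rows),
        alt_depth=np.array(alt_rows),
        conserved_flag=np.array(conserved, dtype=bool),
    )


def write_variant_table(vt: VariantTable, path: str | Path) -> None:
    """Write a VariantTable as an uncompressed VCF with FORMAT/AD."""
    header = pysam.VariantHeader()
    for c in dict.fromkeys(vt.chrom):
        length = int(vt.pos[vt.chrom == c].max()) + 1000
        header.contigs.add(str(c), length=length)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.info.add("CONSERVED", 0, "Flag", "Site belongs to the conserved stringent subset")
    for s in vt.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(vt.n_sites):
            rec = out.new_record(
                contig=str(vt.chrom[i]),
                start=int(vt.pos[i]) - 1,
                stop=int(vt.pos[i]),
                alleles=(str(vt.ref_allele[i]), str(vt.alt_allele[i])),
            )
            if vt.conserved_flag[i]:
                rec.info["CONSERVED"] = True
            for j, s in enumerate(vt.sample_ids):
                rec.samples[s]["AD"] = (int(vt.ref_depth[i, j]), int(vt.alt_depth[i, j]))
            out.write(rec)


# ---------------------------------------------------------------------------
# TSV artifacts

def read_sample_sheet(path: str | Path, variant_table: VariantTable | None = None) -> SampleSheet:
    sheet = SampleSheet(pd.read_csv(path, sep="\t"))
    if variant_table is not None:
        sheet.validate_against(variant_table)
    return sheet


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_locus_haplotype_summary(path: str | Path) -> LocusHaplotypeSummary:
    return LocusHaplotypeSummary(pd.read_csv(path, sep="\t"))


def write_locus_haplotype_summary(lh: LocusHaplotypeSummary, path: str | Path) -> None:
    lh.table.to_csv(path, sep="\t", index=False)


def write_distance_matrix(d, path: str | Path) -> None:
    """Write a labeled square distance matrix as TSV (read-back exact to 1e-12)."""
    if d.values.size == 0:
        raise ValueError("refusing to write an empty distance matrix")
    df = pd.DataFrame(d.values, index=d.sample_ids, columns=d.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="sample_id")


def read_distance_matrix(path: str | Path):
    from .cluster import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(sample_ids=list(df.columns), values=df.to_numpy(dtype=float))
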