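"""Synthetic cohorts of mixed-ploidy, partly clonal grass samples.

The generator emulates the shape of a reduced-representation (ddRAD-like)
genotyping experiment on fairy-circle grasses: circles arranged on a plane
with a minimum spacing, three plants sampled per circle (two near each other
on the perimeter, one opposite), a cohort mixing diploids, allotetraploids
and octoploids, optional clonal circles whose samples are ramets of one
genet, and per-site ref/alt read depths with sequencing error.

Polyploids are modeled as allopolyploids built from independent diploid
subgenomes; a configurable fraction of sites carries a fixed difference
between subgenomes (homoeologous sites), which reads out as a permanently
balanced allele ratio and mimics heterozygosity.

Site allele frequencies default to a truncated neutral-SFS-like draw
(density proportional to 1/p), which makes simplex-dosage variants dominate
polyploid spectra — the regime in which allele-balance ploidy inference is
informative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import LocusHaplotypeSummary, SampleSheet, VariantTable

PLOIDY_LEVELS = (2, 4, 8)


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_population`.

    Parameters
    ----------
    n_circles, samples_per_circle
        Sampling design; the reference design is 15 circles x 3 plants.
    ploidy_mix
        Proportions of diploid, tetraploid and octoploid genets, keyed by
        ploidy level.
    clonal_circles
        Fraction of circles whose samples are all ramets of one genet.
    n_sites
        Number of biallelic SNP sites simulated.
    allele_freq_distribution
        "sfs" (density ~ 1/p, truncated; default) or "uniform", over
        ``freq_bounds``.
    homoeolog_fixed_fraction
        Fraction of sites at which allopolyploid subgenomes carry fixed
        opposite alleles (dosage ploidy/2 regardless of population
        frequency).
    mean_depth
        Expected total reads per site per sample (Poisson).
    error_rate
        Per-read probability that the read reports the wrong allele.
    selfing_F
        Inbreeding coefficient used for diploid genotype draws.
    circle_spacing_m
        Minimum distance between circle centers, metres.
    area_side_m
        Optional square study-area side; if set and too small for the
        requested circles at the requested spacing, simulation fails.
    conserved_fraction
        Fraction of sites flagged as the stringent "conserved subset".
    polyploid_locus_count
        Lower bound on a polyploid sample's count of RAD loci with >=3
        distinct haplotypes; diploids draw between ``diploid_locus_min`` and
        ``diploid_locus_max`` (about ten-fold lower).
    total_loci_mean, total_loci_sd
        Per-sample total RAD locus count draw (truncated normal).
    """

    n_circles: int = 15
    samples_per_circle: int = 3
    ploidy_mix: dict = field(default_factory=lambda: {2: 0.50, 4: 0.45, 8: 0.05})
    clonal_circles: float = 0.0
    n_sites: int = 5000
    allele_freq_distribution: str = "sfs"
    freq_bounds: tuple = (0.05, 0.95)
    homoeolog_fixed_fraction: float = 0.03
    mean_depth: float = 30.0
    error_rate: float = 0.005
    selfing_F: float = 0.0
    circle_spacing_m: float = 10.0
    area_side_m: float | None = None
    conserved_fraction: float = 0.3
    polyploid_locus_count: int = 2000
    diploid_locus_min: int = 50
    diploid_locus_max: int = 200
    total_loci_mean: float = 63096.0
    total_loci_sd: float = 15437.0
    seed: int = 0

    def validate(self) -> None:
        if not math.isclose(sum(self.ploidy_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("ploidy_mix proportions must sum to 1")
        if any(k not in PLOIDY_LEVELS for k in self.ploidy_mix):
            raise ValueError(f"ploidy_mix keys must be among {PLOIDY_LEVELS}")
        for name in ("clonal_circles", "homoeolog_fixed_fraction", "conserved_fraction",
                     "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.circle_spacing_m < 0:
            raise ValueError("circle_spacing_m must be non-negative")
        if not 0 <= self.freq_bounds[0] < self.freq_bounds[1] <= 1:
            raise ValueError("freq_bounds must satisfy 0 <= low < high <= 1")
        if not -1.0 <= self.selfing_F <= 1.0:
            raise ValueError("selfing_F must be in [-1, 1]")


@dataclass
class GroundTruth:
    """Recovery targets: true ploidy, genet membership and allele dosage."""

    sample_ids: list[str]
    true_ploidy: dict
    genet_id: dict
    dosage: np.ndarray  # sites x samples, integer allele dosage
    selfing_F: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sample_ids": self.sample_ids,
            "true_ploidy": {k: int(v) for k, v in self.true_ploidy.items()},
            "genet_id": {k: int(v) for k, v in self.genet_id.items()},
            "dosage": np.asarray(self.dosage).tolist(),
            "selfing_F": self.selfing_F,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            sample_ids=d["sample_ids"],
            true_ploidy=d["true_ploidy"],
            genet_id=d["genet_id"],
            dosage=np.array(d["dosage"], dtype=np.int64),
            selfing_F=d["selfing_F"],
        )


def draw_site_frequencies(n_sites: int, rng: np.random.Generator,
                          distribution: str = "sfs",
                          bounds: tuple = (0.05, 0.95)) -> np.ndarray:
    """Population alternative-allele frequencies, one per site."""
    lo, hi = bounds
    if distribution == "uniform":
        return rng.uniform(lo, hi, n_sites)
    if distribution == "sfs":
        # density ~ 1/p truncated to (lo, hi); inverse-CDF draw
        return lo * (hi / lo) ** rng.random(n_sites)
    raise ValueError(f"unknown allele_freq_distribution {distribution!r}")


def diploid_dosages(p: np.ndarray, inbreeding_f: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Allele dosage in {0, 1, 2} per site for one diploid genome.

    P(het) = 2p(1-p)(1-F); homozygote probabilities are the Hardy-Weinberg
    terms plus F*p*q each, which conserves the allele frequency.
    """
    q = 1.0 - p
    p_hom_alt = p * p + inbreeding_f * p * q
    p_het = 2.0 * p * q * (1.0 - inbreeding_f)
    u = rng.random(p.shape)
    return np.where(u < p_hom_alt, 2, np.where(u < p_hom_alt + p_het, 1, 0)).astype(np.int64)


def polyploid_dosages(p: np.ndarray, ploidy: int, homoeolog_sites: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Allopolyploid dosage: sum of ploidy/2 independent diploid subgenomes.

    At homoeologous sites the subgenomes carry fixed opposite alleles, so the
    dosage is ploidy/2 regardless of the population frequency.
    """
    n_sub = ploidy // 2
    dosage = sum(diploid_dosages(p, 0.0, rng) for _ in range(n_sub))
    return np.where(homoeolog_sites, ploidy // 2, dosage).astype(np.int64)


def depths_from_dosage(dosage: np.ndarray, ploidy, mean_depth: float,
                       error_rate: float, rng: np.random.Generator):
    """Sequencing model: Poisson total depth, binomial allele sampling, symmetric
    per-read miscalls.  Returns (ref_depth, alt_depth) with dosage's shape."""
    dosage = np.asarray(dosage)
    depth = rng.poisson(mean_depth, dosage.shape)
    alt = rng.binomial(depth, np.asarray(dosage) / np.asarray(ploidy, dtype=float))
    if error_rate > 0:
        alt = alt - rng.binomial(alt, error_rate) + rng.binomial(depth - alt, error_rate)
    return depth - alt, alt


def simulate_fixed_dosage_sample(n_sites: int, ploidy: int, dosage: int = 1,
                                 mean_depth: float = 30.0, error_rate: float = 0.005,
                                 seed: int = 0, sample_id: str = "S1") -> VariantTable:
    """One sample whose every site carries a fixed allele dosage.

    Useful for spectrum calibration: dosage 1 yields the het peak at 0.5 for
    diploids, the simplex peak at 0.25 for tetraploids, 0.125 for octoploids.
    """
    rng = np.random.default_rng(seed)
    dos = np.full(n_sites, dosage, dtype=np.int64)
    ref, alt = depths_from_dosage(dos, ploidy, mean_depth, error_rate, rng)
    return VariantTable(
        chrom=np.array(["sim1"] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1),
        ref_allele=np.array(["A"] * n_sites, dtype=object),
        alt_allele=np.array(["T"] * n_sites, dtype=object),
        sample_ids=[sample_id],
        ref_depth=ref[:, None],
        alt_depth=alt[:, None],
        conserved_flag=np.zeros(n_sites, dtype=bool),
    )


def _circle_centers(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered grid of centers respecting the minimum spacing."""
    sp = max(config.circle_spacing_m, 1e-9)
    pitch = 1.5 * sp
    if config.area_side_m is not None:
        per_side = int(config.area_side_m // pitch)
        if per_side * per_side < config.n_circles:
            raise ValueError(
                f"cannot place {config.n_circles} circles at >= {sp} m spacing "
                f"inside a {config.area_side_m} m square"
            )
    else:
        per_side = math.ceil(math.sqrt(config.n_circles))
    cells = [(i, j) for i in range(per_side) for j in range(per_side)][: config.n_circles]
    jitter = rng.uniform(-0.2 * sp, 0.2 * sp, size=(config.n_circles, 2))
    return np.array([(i * pitch, j * pitch) for i, j in cells]) + jitter


def _position_labels(k: int) -> list[str]:
    labels = ["near_1", "near_2", "far_3"]
    labels += [f"far_{i}" for i in range(4, k + 1)]
    return labels[:k]


def simulate_population(config: SimulationConfig):
    """Generate (VariantTable, SampleSheet, LocusHaplotypeSummary, GroundTruth).

    Deterministic given ``config.seed``: identical configs give bit-identical
    outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    p = draw_site_frequencies(config.n_sites, rng, config.allele_freq_distribution,
                              config.freq_bounds)
    homoeolog_sites = rng.random(config.n_sites) < config.homoeolog_fixed_fraction
    conserved = rng.random(config.n_sites) < config.conserved_fraction

    centers = _circle_centers(config, rng)
    n_clonal = int(round(config.clonal_circles * config.n_circles))
    clonal = np.zeros(config.n_circles, dtype=bool)
    clonal[rng.permutation(config.n_circles)[:n_clonal]] = True

    ploidy_levels = np.array(sorted(config.ploidy_mix))
    ploidy_probs = np.array([config.ploidy_mix[k] for k in ploidy_levels], dtype=float)

    def new_genet():
        ploidy = int(rng.choice(ploidy_levels, p=ploidy_probs))
        if ploidy == 2:
            # homoeologous sites are fixed differences between polyploid
            # subgenomes; the diploid gene pool is reference-fixed there
            dos = diploid_dosages(p, config.selfing_F, rng)
            dos = np.where(homoeolog_sites, 0, dos)
        else:
            dos = polyploid_dosages(p, ploidy, homoeolog_sites, rng)
        return ploidy, dos

    sample_ids: list[str] = []
    rows = []
    true_ploidy: dict = {}
    genet_of: dict = {}
    dosage_cols = []
    genet_counter = 0
    labels = _position_labels(config.samples_per_circle)
    for c in range(config.n_circles):
        circle_id = f"FC{c + 1:02d}"
        if clonal[c]:
            ploidy, dos = new_genet()
            circle_genet = genet_counter
            genet_counter += 1
        for k in range(config.samples_per_circle):
            sid = f"{circle_id}-{k + 1}"
            if not clonal[c]:
                ploidy, dos = new_genet()
                gid = genet_counter
                genet_counter += 1
            else:
                gid = circle_genet
            sample_ids.append(sid)
            true_ploidy[sid] = ploidy
            genet_of[sid] = gid
            dosage_cols.append(dos)
            rows.append(
                {
                    "sample_id": sid,
                    "circle_id": circle_id,
                    "position_label": labels[k],
                    "center_x": centers[c, 0],
                    "center_y": centers[c, 1],
                }
            )

    dosage = np.stack(dosage_cols, axis=1)
    ploidy_arr = np.array([true_ploidy[s] for s in sample_ids])
    ref, alt = depths_from_dosage(dosage, ploidy_arr[None, :], config.mean_depth,
                                  config.error_rate, rng)

    vt = VariantTable(
        chrom=np.array(["sim1"] * config.n_sites, dtype=object),
        pos=np.arange(1, config.n_sites + 1),
        ref_allele=np.array(["A"] * config.n_sites, dtype=object),
        alt_allele=np.array(["T"] * config.n_sites, dtype=object),
        sample_ids=sample_ids,
        ref_depth=ref,
        alt_depth=alt,
        conserved_flag=conserved,
    )
    sheet = SampleSheet(pd.DataFrame(rows))

    hap_rows = []
    for sid in sample_ids:
        total = max(1000, int(round(rng.normal(config.total_loci_mean, config.total_loci_sd))))
        if true_ploidy[sid] > 2:
            n3 = config.polyploid_locus_count + int(rng.poisson(0.25 * config.polyploid_locus_count))
        else:
            n3 = int(rng.integers(config.diploid_locus_min, config.diploid_locus_max + 1))
        total = max(total, n3 + 1000)  # library-size draw can undershoot the 3+ count
        n2 = int(round(0.3 * (total - n3)))
        hap_rows.append(
            {
                "sample_id": sid,
                "n_loci_1hap": total - n2 - n3,
                "n_loci_2hap": n2,
                "n_loci_3plus_hap": n3,
            }
        )
    lh = LocusHaplotypeSummary(pd.DataFrame(hap_rows))

    truth = GroundTruth(
        sample_ids=sample_ids,
        true_ploidy=true_ploidy,
        genet_id=genet_of,
        dosage=dosage,
        selfing_F=config.selfing_F,
    )
    return vt, sheet, lh, truth
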