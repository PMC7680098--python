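"""Clonality statistics: within- vs between-circle minimum genetic distances,
rank-sum comparison, genetic-vs-spatial distance decay, and inbreeding.

The clonality test asks whether the plants ringing one circle are ramets of
a single genet.  If they were, the minimum genetic distance within a circle
would collapse to ~0 and sit far below the minimum distances between
circles; the comparison of the two minimum-distance distributions is made
with a two-sided Wilcoxon rank-sum (Mann-Whitney) test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats

from .cluster import ClonePairSet, DistanceMatrix, call_clones
from .io import SampleSheet
from .recode import RecodedGenotypeMatrix

logger = logging.getLogger(__name__)


def min_within_between(d: DistanceMatrix, sheet: SampleSheet):
    """Minimum genetic distance per circle and per unordered circle pair.

    Returns ``(within, between)``: ``within`` maps each circle with >=2
    samples to the smallest intra-circle pairwise distance; ``between`` maps
    each unordered circle pair to the smallest distance between any sample of
    one and any sample of the other.
    """
    circle = sheet.circle_of()
    for s in d.sample_ids:
        if s not in circle:
            raise ValueError(f"sample {s!r} has no circle assignment in the sheet")
    idx = {s: i for i, s in enumerate(d.sample_ids)}
    members = {c: [idx[s] for s in sheet.samples_of(c) if s in idx] for c in sheet.circle_ids}

    within = {}
    for c, ids in members.items():
        if len(ids) < 2:
            logger.warning("circle %r has <2 samples; skipped for within-circle minima", c)
            continue
        within[c] = float(min(d.values[i, j] for i, j in combinations(ids, 2)))

    between = {}
    for c1, c2 in combinations(sheet.circle_ids, 2):
        ids1, ids2 = members[c1], members[c2]
        if not ids1 or not ids2:
            continue
        between[(c1, c2)] = float(d.values[np.ix_(ids1, ids2)].min())
    return within, between


def wilcoxon_rank_sum(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparing two samples.

    Uses the exact null distribution when min(n, m) <= 10 and the pooled data
    are tie-free, otherwise the normal approximation with tie and continuity
    corrections.  Degenerate input (all pooled values identical) returns
    p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both groups; rank-sum p set to 1")
        return {
            "statistic": len(x) * len(y) / 2.0,
            "p_value": 1.0,
            "method": "degenerate",
            "n_x": len(x),
            "n_y": len(y),
        }
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(x), len(y)) <= 10 and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": "exact" if exact else "asymptotic",
        "n_x": len(x),
        "n_y": len(y),
    }


def distance_decay(between_min: dict, sheet: SampleSheet) -> dict:
    """OLS of minimum between-circle genetic distance on center-to-center
    spatial distance; Pearson r reported.  Within-circle comparisons are not
    part of the regression.
    """
    if len(between_min) < 3:
        raise ValueError("need at least 3 circle pairs for the decay regression")
    centers = sheet.centers()
    spatial, genetic = [], []
    for (c1, c2), g in between_min.items():
        (x1, y1), (x2, y2) = centers[c1], centers[c2]
        spatial.append(float(np.hypot(x1 - x2, y1 - y2)))
        genetic.append(float(g))
    spatial = np.array(spatial)
    genetic = np.array(genetic)
    if np.ptp(spatial) == 0:
        raise ValueError("zero variance in spatial distances; regression undefined")
    if np.ptp(genetic) == 0:
        return {
            "slope": 0.0,
            "intercept": float(genetic[0]),
            "r": 0.0,
            "p_value": 1.0,
            "n_pairs": len(spatial),
            "degenerate": True,
        }
    fit = stats.linregress(spatial, genetic)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
        "p_value": float(fit.pvalue),
        "n_pairs": len(spatial),
        "degenerate": False,
    }


@dataclass
class InbreedingResult:
    f_per_sample: dict
    mean_f: float
    ci_low: float
    ci_high: float
    ci_method: str
    n_sites: int


def inbreeding_coefficient(m: RecodedGenotypeMatrix,
                           diploid_samples: list[str] | None = None,
                           ci_method: str = "t", n_boot: int = 2000,
                           seed: int = 0) -> InbreedingResult:
    """Method-of-moments per-sample inbreeding coefficient F with a 95% CI.

    Per sample, F = (O_hom - E_hom) / (L - E_hom), where O_hom counts sites
    coded 0 or 1, and E_hom = sum over sites of 1 - 2*p*q * 2k/(2k-1) with p
    the allele frequency in the analysed diploid subset (0.5 codes counting
    half) and 2k/(2k-1) the allele-count small-sample correction (k samples).
    The mean F's 95% CI is a t-interval over the per-sample values by
    default; ``ci_method="bootstrap"`` resamples samples instead.
    """
    if diploid_samples is not None:
        m = m.subset_samples(diploid_samples)
    k = m.n_samples
    if k < 2:
        raise ValueError("need at least 2 diploid samples to estimate F")
    codes = m.values
    p = codes.mean(axis=1)
    q = 1.0 - p
    polymorphic = (p > 0) & (p < 1)
    if not polymorphic.any():
        raise ValueError("site set is monomorphic across the diploid subset")
    corr = (2 * k) / (2 * k - 1)
    e_hom_site = 1.0 - 2.0 * p * q * corr
    e_hom = float(e_hom_site.sum())
    n_sites = codes.shape[0]
    f = {}
    for j, sid in enumerate(m.sample_ids):
        o_hom = float((codes[:, j] != 0.5).sum())
        denom = n_sites - e_hom
        if abs(denom) < 1e-12:
            raise ValueError("expected homozygosity equals site count; F undefined")
        f[sid] = (o_hom - e_hom) / denom
    values = np.array(list(f.values()))
    mean_f = float(values.mean())
    if ci_method == "t":
        se = values.std(ddof=1) / np.sqrt(k)
        tq = stats.t.ppf(0.975, k - 1)
        lo, hi = mean_f - tq * se, mean_f + tq * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.array([
            values[rng.integers(0, k, k)].mean() for _ in range(n_boot)
        ])
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        raise ValueError("ci_method must be 't' or 'bootstrap'")
    return InbreedingResult(
        f_per_sample=f,
        mean_f=mean_f,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_method=ci_method,
        n_sites=n_sites,
    )


@dataclass
class ClonalityReport:
    """All headline clonality statistics for one cohort."""

    within_min: dict
    between_min: dict
    wilcoxon: dict
    decay: dict
    clone_pairs: ClonePairSet

    def to_dict(self) -> dict:
        return {
            "within_min": {str(k): v for k, v in self.within_min.items()},
            "between_min": {f"{a}|{b}": v for (a, b), v in self.between_min.items()},
            "wilcoxon": self.wilcoxon,
            "decay": self.decay,
            "clone_pairs": {
                "epsilon": self.clone_pairs.epsilon,
                "pairs": [list(p) for p in self.clone_pairs.pairs],
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def clonality_report(d: DistanceMatrix, sheet: SampleSheet,
                     epsilon: float = 0.0) -> ClonalityReport:
    """Run the full clonality analysis on a distance matrix + design sheet."""
    within, between = min_within_between(d, sheet)
    wil = wilcoxon_rank_sum(list(within.values()), list(between.values()))
    decay = distance_decay(between, sheet)
    clones = call_clones(d, epsilon=epsilon)
    return ClonalityReport(
        within_min=within,
        between_min=between,
        wilcoxon=wil,
        decay=decay,
        clone_pairs=clones,
    )
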