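"""Per-sample ploidy inference from allele balance and haplotype counts.

Two independent lines of evidence are combined:

* the alternative-allele read-fraction spectrum, whose dominant peak sits
  near 1/ploidy for single-copy (simplex) variants — 0.5 in diploids, 0.25
  in tetraploids, 0.125 in octoploids;
* the number of RAD loci carrying more than two distinct haplotypes, which
  only a polyploid genome can produce in large numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LocusHaplotypeSummary, VariantTable

#: Expected simplex-peak position per ploidy level.
CANDIDATE_PEAKS = {2: 0.5, 4: 0.25, 8: 0.125}

#: Spectra with fewer retained sites than this are flagged low-confidence.
MIN_INFORMATIVE_SITES = 50


@dataclass
class AlleleFrequencySpectrum:
    """Per-site alternative-allele read fractions for one sample, after filters."""

    sample_id: str
    frequencies: np.ndarray
    min_depth: int
    bounds: tuple
    n_dropped_depth: int
    n_dropped_bounds: int

    @property
    def n_retained(self) -> int:
        return len(self.frequencies)

    @property
    def low_confidence(self) -> bool:
        return self.n_retained < MIN_INFORMATIVE_SITES


@dataclass
class PloidyCall:
    sample_id: str
    ploidy: int
    method: str  # "spectrum" | "haplotype_counts" | "combined"
    spectrum_mode: float | None = None
    n_loci_3plus_hap: int | None = None
    flags: set = field(default_factory=set)

    @property
    def is_polyploid(self) -> bool:
        return self.ploidy >= 4


def allele_frequency_spectrum(vt: VariantTable, sample_id: str, min_depth: int = 11,
                              bounds: tuple = (0.05, 0.95)) -> AlleleFrequencySpectrum:
    """Alt-read fractions alt/(ref+alt) at sites passing depth and bound filters.

    Sites with total depth below ``min_depth`` are dropped, then fractions at
    or outside the open interval ``bounds`` (near-homozygous sites) are
    dropped.  Defaults: depth >= 11 and 0.05 < f < 0.95.
    """
    j = vt.sample_index(sample_id)
    ref = vt.ref_depth[:, j].astype(float)
    alt = vt.alt_depth[:, j].astype(float)
    total = ref + alt
    deep = total >= min_depth
    n_dropped_depth = int((~deep).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, alt / np.maximum(total, 1.0), np.nan)
    lo, hi = bounds
    inside = deep & (f > lo) & (f < hi)
    n_dropped_bounds = int(deep.sum() - inside.sum())
    spec = AlleleFrequencySpectrum(
        sample_id=sample_id,
        frequencies=f[inside],
        min_depth=min_depth,
        bounds=tuple(bounds),
        n_dropped_depth=n_dropped_depth,
        n_dropped_bounds=n_dropped_bounds,
    )
    return spec


def spectrum_mode(spec: AlleleFrequencySpectrum, bin_width: float = 0.02,
                  smooth_window: int = 5) -> float:
    """Peak of a fixed-width histogram of the spectrum over (0, 1).

    Returns the center of the bin maximising the histogram counts averaged
    over a centered ``smooth_window``-bin window (default 5).  Read fractions
    are ratios of small integers, so raw 0.02-wide bins are subject to
    heaping: at moderate depth individual bins gain or lose whole atoms of
    probability and the raw argmax can sit a full bin away from the
    underlying peak.  A fixed small window removes that artifact while
    staying deterministic and bandwidth-free; ``smooth_window=1`` recovers
    the raw histogram mode.  Ties break toward the lower bin so a symmetric
    polyploid double peak (e.g. 0.25/0.75) resolves to the sub-0.5 peak.
    """
    if spec.n_retained == 0:
        raise ValueError(f"empty allele-frequency spectrum for {spec.sample_id}")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, edges = np.histogram(spec.frequencies, bins=edges)
    smoothed = np.convolve(counts, np.ones(smooth_window), mode="same")
    # ties on the smoothed criterion resolve by raw count, then lower bin
    best = np.flatnonzero(smoothed == smoothed.max())
    i = int(best[np.argmax(counts[best])])
    return float((edges[i] + edges[i + 1]) / 2)


def estimate_ploidy_from_spectrum(spec: AlleleFrequencySpectrum,
                                  bin_width: float = 0.02,
                                  smooth_window: int = 5) -> PloidyCall:
    """Call ploidy as the level whose simplex peak is nearest the spectrum mode.

    A mode above 0.7 (or exactly equidistant candidates) is flagged
    ``ambiguous``; combination with haplotype-count evidence then lets the
    haplotype classifier take precedence.
    """
    mode = spectrum_mode(spec, bin_width=bin_width, smooth_window=smooth_window)
    dists = {k: abs(mode - peak) for k, peak in CANDIDATE_PEAKS.items()}
    best = min(dists.values())
    nearest = sorted(k for k, v in dists.items() if np.isclose(v, best, atol=1e-12))
    flags = set()
    if spec.low_confidence:
        flags.add("low_confidence")
    if mode > 0.7 or len(nearest) > 1:
        flags.add("ambiguous")
    return PloidyCall(
        sample_id=spec.sample_id,
        ploidy=nearest[0],
        method="spectrum",
        spectrum_mode=mode,
        flags=flags,
    )


def classify_by_haplotype_counts(lh: LocusHaplotypeSummary, sample_id: str,
                                 threshold: int = 1000) -> PloidyCall:
    """Polyploid iff strictly more than ``threshold`` loci show >=3 haplotypes.

    This evidence cannot separate tetraploid from octoploid; polyploids are
    emitted as ploidy 4 with a ``cannot_distinguish_4_8`` flag.
    """
    n3 = lh.n_loci_3plus(sample_id)
    if n3 > threshold:
        return PloidyCall(
            sample_id=sample_id,
            ploidy=4,
            method="haplotype_counts",
            n_loci_3plus_hap=n3,
            flags={"cannot_distinguish_4_8"},
        )
    return PloidyCall(
        sample_id=sample_id, ploidy=2, method="haplotype_counts", n_loci_3plus_hap=n3
    )


def combine_ploidy_calls(spectrum_call: PloidyCall, haplotype_call: PloidyCall) -> PloidyCall:
    """Reconcile the two evidence lines into one call.

    Concordant calls (both diploid, or both polyploid) keep the spectrum's
    ploidy (which resolves 4 vs 8).  If the spectrum is flagged ambiguous the
    haplotype classification takes precedence.  Otherwise the spectrum wins
    but the call carries a ``discordant`` flag.
    """
    if spectrum_call.sample_id != haplotype_call.sample_id:
        raise ValueError("cannot combine calls for different samples")
    flags = set(spectrum_call.flags) | set(haplotype_call.flags)
    if "ambiguous" in spectrum_call.flags:
        ploidy = haplotype_call.ploidy
    elif spectrum_call.is_polyploid == haplotype_call.is_polyploid:
        ploidy = spectrum_call.ploidy
        flags.discard("cannot_distinguish_4_8")
    else:
        ploidy = spectrum_call.ploidy
        flags.add("discordant")
    return PloidyCall(
        sample_id=spectrum_call.sample_id,
        ploidy=ploidy,
        method="combined",
        spectrum_mode=spectrum_call.spectrum_mode,
        n_loci_3plus_hap=haplotype_call.n_loci_3plus_hap,
        flags=flags,
    )


def call_ploidy(vt: VariantTable, lh: LocusHaplotypeSummary, min_depth: int = 11,
                bounds: tuple = (0.05, 0.95), bin_width: float = 0.02,
                hap_threshold: int = 1000) -> dict:
    """Combined ploidy calls for every sample in the variant table."""
    calls = {}
    for sid in vt.sample_ids:
        spec = allele_frequency_spectrum(vt, sid, min_depth=min_depth, bounds=bounds)
        sc = estimate_ploidy_from_spectrum(spec, bin_width=bin_width)
        hc = classify_by_haplotype_counts(lh, sid, threshold=hap_threshold)
        calls[sid] = combine_ploidy_calls(sc, hc)
    return calls
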