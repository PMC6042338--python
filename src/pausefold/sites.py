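"""Calling and annotating highly stable secondary-structure sites.

A stable site is a maximal run of at least ``min_run`` consecutive scan
windows whose free energy lies in the most stable tail (lowest quantile) of
the genome-wide distribution.  With the 300-nt / 150-nt scan geometry the
shortest callable site spans (7 - 1) * 150 + 300 = 1200 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import FreeEnergyProfile, GeneModel
from .intervals import IntervalIndex, merge_intervals, subtract_intervals, total_length

__all__ = ["StableSite", "RegionAnnotation", "genome_quantile_threshold",
           "call_stable_sites", "annotate_sites", "REGION_CLASSES"]

REGION_CLASSES = ["TSS", "TTS", "promoter", "gene_body", "intergenic"]


@dataclass(frozen=True)
class StableSite:
    chrom: str
    start: int
    end: int
    n_windows: int
    min_dg: float


@dataclass
class RegionAnnotation:
    """Per-class site counts and densities (sites per Mb of class territory).

    Classes partition both the sites (by precedence TSS > TTS > promoter >
    gene_body > intergenic) and the genome territory used for
    normalisation, so counts sum to the total and densities are
    sum-stable."""

    counts: dict[str, int]
    territory: dict[str, int]
    site_classes: list[str]

    @property
    def normalized_density(self) -> dict[str, float]:
        return {c: (self.counts[c] / self.territory[c] * 1e6
                    if self.territory[c] > 0 else float("nan"))
                for c in REGION_CLASSES}


def genome_quantile_threshold(profiles, q: float = 0.05) -> float:
    """Free-energy threshold at the lower (most stable) empirical quantile.

    The threshold is the ``ceil(q*N)``-th order statistic of all non-missing
    window values (an inverted-CDF quantile), so "lowest 5%" keeps ties on
    the stable side under the ``<=`` comparison used by the caller.
    """
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    if isinstance(profiles, FreeEnergyProfile):
        profiles = [profiles]
    vals = np.concatenate([np.asarray(p.values, dtype=float) for p in profiles]) \
        if profiles else np.empty(0)
    vals = vals[~np.isnan(vals)]
    if vals.size < 20:
        raise ValueError("need at least 20 non-missing window values")
    return float(np.quantile(vals, q, method="inverted_cdf"))


def call_stable_sites(profile: FreeEnergyProfile, threshold: float,
                      min_run: int = 7) -> list[StableSite]:
    """Maximal runs of >= min_run consecutive below-threshold windows.

    Missing (NaN) windows break runs.  Each site spans from the first
    window's start to the last window's end:
    ``(k - 1) * step + window`` nt for a k-window run.
    """
    vals = np.asarray(profile.values, dtype=float)
    below = ~np.isnan(vals) & (vals <= threshold)
    sites = []
    i = 0
    n = len(below)
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        k = j - i + 1
        if k >= min_run:
            start = profile.anchor_start + i * profile.step
            end = profile.anchor_start + j * profile.step + profile.window
            sites.append(StableSite(profile.chrom, start, end, k,
                                    float(np.min(vals[i:j + 1]))))
        i = j + 1
    return sites


def _class_regions(genes: list[GeneModel], tss_flank: int = 250,
                   promoter_span: tuple[int, int] = (-1000, -250)):
    """Raw genomic intervals per class (before precedence partition)."""
    regions = {c: [] for c in REGION_CLASSES[:4]}
    for g in genes:
        regions["TSS"].append((g.tss - tss_flank, g.tss + tss_flank + 1))
        regions["TTS"].append((g.tts - tss_flank, g.tts + tss_flank + 1))
        a, b = promoter_span
        if g.strand == "+":
            regions["promoter"].append((g.tss + a, g.tss + b))
        else:
            regions["promoter"].append((g.tss - b + 1, g.tss - a + 1))
        if g.length > 2 * tss_flank + 1:
            body_lo = g.genomic_position(tss_flank)
            body_hi = g.genomic_position(g.length - 1 - tss_flank)
            lo, hi = sorted((body_lo, body_hi))
            regions["gene_body"].append((lo, hi + 1))
    return regions


def annotate_sites(sites: list[StableSite], genes: list[GeneModel],
                   chrom_sizes: dict[str, int]) -> RegionAnnotation:
    """Assign each site one region class and compute class densities.

    Precedence is TSS > TTS > promoter > gene_body > intergenic, applied
    both to the sites and to the genome territory used for normalisation.
    """
    by_chrom_regions: dict[str, dict[str, list]] = {
        c: {cls: [] for cls in REGION_CLASSES[:4]} for c in chrom_sizes}
    for g in genes:
        regs = _class_regions([g])
        for cls, ivs in regs.items():
            by_chrom_regions[g.chrom][cls].extend(ivs)

    territory = {c: 0 for c in REGION_CLASSES}
    indexes: dict[str, dict[str, IntervalIndex]] = {}
    for chrom, size in chrom_sizes.items():
        regs = by_chrom_regions[chrom]
        clipped = {cls: [(max(s, 0), min(e, size)) for s, e in regs[cls]]
                   for cls in regs}
        taken: list[tuple[int, int]] = []
        indexes[chrom] = {}
        for cls in REGION_CLASSES[:4]:
            merged = merge_intervals(clipped[cls])
            part = subtract_intervals(merged, taken)
            territory[cls] += total_length(part)
            taken = merge_intervals(taken + merged)
            indexes[chrom][cls] = IntervalIndex(merged)
        territory["intergenic"] += size - total_length(taken)

    counts = {c: 0 for c in REGION_CLASSES}
    site_classes = []
    for site in sites:
        cls_found = "intergenic"
        for cls in REGION_CLASSES[:4]:
            idx = indexes.get(site.chrom, {}).get(cls)
            if idx is not None and idx.overlaps(site.start, site.end):
                cls_found = cls
                break
        counts[cls_found] += 1
        site_classes.append(cls_found)
    return RegionAnnotation(counts, territory, site_classes)
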