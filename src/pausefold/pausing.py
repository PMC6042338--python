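"""Traveling-ratio classification of genes into pausing states.

Genes are first stratified by Pol II ChIP peak overlap into bound and
unbound (NP2).  For bound genes the traveling ratio TR is the per-base read
density over the TSS -30..+300 window (transcription-oriented, anchored on
the TSS and not clipped to the transcript) divided by the density over the
rest of the gene; TR > 2 defines a paused gene (PAU), TR <= 2 non-paused
(NPA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .genome import GeneModel
from .intervals import IntervalIndex

__all__ = ["TravelingRatioRecord", "select_transcripts", "traveling_ratio",
           "classify_pausing", "concordance", "TSS_WINDOW"]

#: traveling-ratio TSS window, transcription-oriented offsets [lo, hi)
TSS_WINDOW = (-30, 301)


@dataclass(frozen=True)
class TravelingRatioRecord:
    gene_id: str
    tss_density: float
    body_density: float
    tr: float  # may be inf (empty body) or nan (no coverage at all)
    state: str  # NP2 | NPA | PAU


def select_transcripts(genes: list[GeneModel], genome: dict[str, str] | None = None,
                       min_length: int = 660, flank: int = 2000) -> list[GeneModel]:
    """One transcript per gene and the standard analysis filters.

    Keeps the longest transcript of each gene group (ties: leftmost start,
    then lexicographic id), removes transcripts shorter than ``min_length``
    (twice the TSS window plus margin), and, when a genome is supplied,
    removes transcripts with undetermined sequence (N, or a span past the
    chromosome end) within TSS +/- ``flank``.
    """
    by_group: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_group.setdefault(g.gene_group, []).append(g)
    picked = []
    for group in sorted(by_group):
        best = sorted(by_group[group],
                      key=lambda g: (-g.length, g.tx_start, g.gene_id))[0]
        picked.append(best)
    picked = [g for g in picked if g.length >= min_length]
    if genome is not None:
        kept = []
        for g in picked:
            lo, hi = g.tss - flank, g.tss + flank + 1
            seq = genome[g.chrom]
            if lo < 0 or hi > len(seq) or "N" in seq[lo:hi]:
                continue
            kept.append(g)
        picked = kept
    return picked


def _tss_window_interval(gene: GeneModel) -> tuple[int, int]:
    lo, hi = TSS_WINDOW
    if gene.strand == "+":
        return gene.tss + lo, gene.tss + hi
    return gene.tss - hi + 1, gene.tss - lo + 1


def traveling_ratio(gene: GeneModel, coverage: CoverageTrack,
                    state_hint: str | None = None) -> TravelingRatioRecord:
    """TR of one gene from per-base coverage (unstranded ChIP signal)."""
    ws, we = _tss_window_interval(gene)
    tss_sum = coverage.interval_sum(gene.chrom, ws, we)
    tss_len = we - ws
    # body = transcript minus the TSS window
    body_len = 0
    body_sum = 0.0
    for s, e in ((gene.tx_start, gene.tx_end),):
        cut_s, cut_e = max(s, ws), min(e, we)
        if cut_e > cut_s:
            segs = [(s, cut_s), (cut_e, e)]
        else:
            segs = [(s, e)]
        for a, b in segs:
            if b > a:
                body_sum += coverage.interval_sum(gene.chrom, a, b)
                body_len += b - a
    tss_d = tss_sum / tss_len
    body_d = body_sum / body_len if body_len > 0 else 0.0
    if tss_d == 0 and body_d == 0:
        tr = float("nan")
    elif body_d == 0:
        tr = float("inf")
    else:
        tr = tss_d / body_d
    state = state_hint if state_hint is not None else \
        ("PAU" if tr > 2 else "NPA")
    return TravelingRatioRecord(gene.gene_id, tss_d, body_d, tr, state)


def classify_pausing(genes: list[GeneModel], polII_peaks: pd.DataFrame,
                     coverage: CoverageTrack):
    """Stratify genes by Pol II peak overlap, then by traveling ratio.

    Returns ``(table, fractions)``: a per-gene DataFrame (gene_id, densities,
    tr, state) and the NP2/NPA/PAU fractions over all input genes.
    """
    peak_idx: dict[str, IntervalIndex] = {}
    for chrom in set(g.chrom for g in genes):
        sub = polII_peaks[polII_peaks["chrom"] == chrom] if len(polII_peaks) else polII_peaks
        peak_idx[chrom] = IntervalIndex(
            list(zip(sub["start"], sub["end"])) if len(sub) else [])
    rows = []
    for g in genes:
        bound = bool(peak_idx[g.chrom].overlaps(g.tx_start, g.tx_end)) \
            if len(peak_idx[g.chrom].starts) else False
        if not bound:
            rec = TravelingRatioRecord(g.gene_id, float("nan"), float("nan"),
                                       float("nan"), "NP2")
        else:
            rec = traveling_ratio(g, coverage)
        rows.append((rec.gene_id, rec.tss_density, rec.body_density,
                     rec.tr, rec.state))
    table = pd.DataFrame(rows, columns=["gene_id", "tss_density",
                                        "body_density", "tr", "state"])
    n = len(table)
    fractions = {s: float((table["state"] == s).sum()) / n if n else float("nan")
                 for s in ("NP2", "NPA", "PAU")}
    return table, fractions


def concordance(tr_tables: dict[str, pd.DataFrame]):
    """Cross-sample agreement of pausing: Spearman correlation of TR over
    shared Pol II-bound genes and PAU<->NPA switched-gene counts per pair.

    Infinite TRs rank above all finite values.  Pairs sharing fewer than 10
    bound genes are flagged with NaN correlation.
    """
    names = list(tr_tables)
    if len(names) < 2:
        raise ValueError("need at least two samples")
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    switched = pd.DataFrame(0, index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            ta = tr_tables[a].set_index("gene_id")
            tb = tr_tables[b].set_index("gene_id")
            shared = ta.index.intersection(tb.index)
            bound = [g for g in shared
                     if ta.loc[g, "state"] != "NP2" and tb.loc[g, "state"] != "NP2"]
            if len(bound) < 10:
                warnings.warn(f"fewer than 10 shared bound genes for {a}/{b}")
                rho = float("nan")
            else:
                rho = float(stats.spearmanr(
                    ta.loc[bound, "tr"], tb.loc[bound, "tr"]).statistic)
            sw = sum(1 for g in bound
                     if {ta.loc[g, "state"], tb.loc[g, "state"]} == {"PAU", "NPA"})
            corr.loc[a, b] = corr.loc[b, a] = rho
            switched.loc[a, b] = switched.loc[b, a] = sw
    return corr, switched
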