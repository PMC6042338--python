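"""Anchored matrices and average profiles of free energy and coverage.

Rows are loci (genes or pause loci), columns are transcription-oriented
offsets around an anchor (TSS, mNET spike, or ChIP summit); minus-strand
rows are flipped so negative offsets are always upstream.  Missing values
(chromosome edges, N windows) are NaN and excluded from averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fold import fold_windows
from .genome import GeneModel, non_template_sequence, scan_tss_highres
from .params import FoldParams, revcomp

__all__ = ["ProfileMatrix", "anchored_matrix", "average_profile",
           "locate_min", "strand_bias", "extreme_density", "dg_genome_track",
           "gc_genome_track"]


@dataclass
class ProfileMatrix:
    ids: list
    offsets: np.ndarray  # transcription-oriented, negative = upstream
    values: np.ndarray   # loci x offsets
    anchor: str
    ordering_key: str = "input order"


def anchored_matrix(anchors: pd.DataFrame, track: dict[str, np.ndarray],
                    flank: int, anchor_label: str = "anchor",
                    order_by: np.ndarray | str | None = None,
                    ordering_desc: str = "input order") -> ProfileMatrix:
    """Per-locus track values at offsets -flank..+flank around each anchor.

    ``anchors`` needs columns chrom, pos, strand and optionally id;
    ``track`` maps chromosome -> per-base value array (NaN allowed).  Rows
    of minus-strand loci are flipped into transcription orientation; anchors
    too close to a chromosome edge are NaN-padded.
    """
    n = len(anchors)
    width = 2 * flank + 1
    values = np.full((n, width), np.nan)
    ids = list(anchors["id"]) if "id" in anchors.columns else list(range(n))
    for r, row in enumerate(anchors.itertuples()):
        arr = track[row.chrom]
        lo, hi = row.pos - flank, row.pos + flank + 1
        clo, chi = max(lo, 0), min(hi, len(arr))
        if chi > clo:
            values[r, clo - lo:chi - lo] = arr[clo:chi]
        if row.strand == "-":
            values[r] = values[r, ::-1]
    offsets = np.arange(-flank, flank + 1)
    if order_by is not None:
        key = anchors[order_by].to_numpy() if isinstance(order_by, str) \
            else np.asarray(order_by)
        order = np.argsort(key, kind="stable")
        values = values[order]
        ids = [ids[i] for i in order]
        if isinstance(order_by, str):
            ordering_desc = order_by
    return ProfileMatrix(ids, offsets, values, anchor_label, ordering_desc)


def average_profile(matrix: ProfileMatrix):
    """Missing-aware column means; returns (offsets, mean, n_per_offset)."""
    vals = matrix.values
    n = np.sum(~np.isnan(vals), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nanmean(vals, axis=0), np.nan)
    return matrix.offsets, mean, n


def locate_min(offsets: np.ndarray, avg: np.ndarray,
               search_window: tuple[int, int] = (-100, 50),
               eps: float = 0.05):
    """Offset interval at the minimum of an average free-energy profile.

    Returns ``(lo, hi, min_value, degenerate)`` where [lo, hi] is the
    contiguous offset interval around the argmin whose values lie within
    ``eps`` kcal/mol of the minimum; ``degenerate`` flags a flat profile
    (the interval covers the whole search window).
    """
    mask = (offsets >= search_window[0]) & (offsets <= search_window[1])
    off = offsets[mask]
    v = avg[mask]
    if np.isnan(v).any():
        raise ValueError("average profile has missing values in the search window")
    i = int(np.argmin(v))
    vmin = float(v[i])
    lo = i
    while lo > 0 and v[lo - 1] <= vmin + eps:
        lo -= 1
    hi = i
    while hi < len(v) - 1 and v[hi + 1] <= vmin + eps:
        hi += 1
    degenerate = (lo == 0 and hi == len(v) - 1)
    return int(off[lo]), int(off[hi]), vmin, degenerate


def strand_bias(genes: list[GeneModel], genome: dict[str, str],
                params: FoldParams | None = None,
                region: tuple[int, int] = (-30, 301), window: int = 30):
    """Per-gene mean windowed free energy on the non-template vs template
    strand over a TSS-proximal region, with a paired t-test summary.

    Returns ``(table, summary)`` where the table has one row per gene
    (dg_non_template, dg_template, difference) and the summary carries the
    mean paired difference and t statistic/p-value.
    """
    rows = []
    for g in genes:
        seq_nt = non_template_sequence(g, genome, region[0], region[1])
        seq_t = revcomp(seq_nt)
        dg_nt = np.nanmean(fold_windows(seq_nt, params, window=window, step=1))
        dg_t = np.nanmean(fold_windows(seq_t, params, window=window, step=1))
        rows.append((g.gene_id, dg_nt, dg_t, dg_nt - dg_t))
    table = pd.DataFrame(rows, columns=["gene_id", "dg_non_template",
                                        "dg_template", "difference"])
    diff = table["difference"].to_numpy()
    if len(diff) >= 2 and np.ptp(diff) > 0:
        t = stats.ttest_rel(table["dg_non_template"], table["dg_template"])
        t_stat, p = float(t.statistic), float(t.pvalue)
    else:
        t_stat, p = float("nan"), float("nan")
    summary = {"mean_difference": float(np.mean(diff)),
               "t_statistic": t_stat, "p_value": p, "n": len(diff)}
    return table, summary


def extreme_density(matrix: ProfileMatrix, which: str = "low",
                    frac: float = 0.02):
    """Per-offset frequency of windows whose value falls in the global
    lowest (most stable) or highest ``frac`` band of the pooled values.

    Returns ``(offsets, frequency, band_threshold)``; frequencies are
    fractions of the non-missing rows at each offset, so averaged over
    offsets they recover the band's global mass share.
    """
    vals = matrix.values
    pooled = vals[~np.isnan(vals)]
    if pooled.size == 0:
        raise ValueError("no values to pool")
    if which == "low":
        thr = np.quantile(pooled, frac)
        in_band = vals <= thr
    elif which == "high":
        thr = np.quantile(pooled, 1 - frac)
        in_band = vals >= thr
    else:
        raise ValueError("which must be 'low' or 'high'")
    ok = ~np.isnan(vals)
    n = ok.sum(axis=0)
    freq = np.where(n > 0, (in_band & ok).sum(axis=0) / np.maximum(n, 1), np.nan)
    return matrix.offsets, freq, float(thr)


def dg_genome_track(genes: list[GeneModel], genome: dict[str, str],
                    params: FoldParams | None = None, flank: int = 2000,
                    window: int = 30) -> dict[str, np.ndarray]:
    """Genome-space free-energy track from per-gene TSS-proximal scans.

    Each 30-nt window's energy is written at the genomic position of its
    assigned (15th) nucleotide on the gene's non-template strand; positions
    not covered by any scan stay NaN.
    """
    track = {c: np.full(len(s), np.nan) for c, s in genome.items()}
    for g in genes:
        prof = scan_tss_highres(g, genome, params, flank=flank, window=window)
        arr = track[g.chrom]
        for off, v in zip(prof.center_offsets, prof.values):
            pos = g.genomic_position(int(off))
            if 0 <= pos < len(arr):
                arr[pos] = v
    return track


def gc_genome_track(genome: dict[str, str], window: int = 30) -> dict[str, np.ndarray]:
    """Per-base GC fraction with the same window/assignment geometry as the
    free-energy scans (value of the window assigned to its 15th nt)."""
    out = {}
    for chrom, seq in genome.items():
        isgc = np.frombuffer(seq.encode(), dtype=np.uint8)
        isgc = ((isgc == ord("G")) | (isgc == ord("C"))).astype(float)
        if len(seq) < window:
            out[chrom] = np.full(len(seq), np.nan)
            continue
        kern = np.convolve(isgc, np.ones(window), mode="valid") / window
        arr = np.full(len(seq), np.nan)
        arr[window // 2 - 1:window // 2 - 1 + len(kern)] = kern
        out[chrom] = arr
    return out
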