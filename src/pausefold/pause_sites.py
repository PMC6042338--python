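"""Annotation-free Pol II pause-site calling and ranking.

Candidate loci are GRO-seq peaks that overlap a Pol II ChIP-seq peak over
more than half their length.  A power-law fit to the low-coverage mNET-seq
noise (N_x = a * x^-b over coverage 3..100) provides the null from which
per-locus p-values are computed and Benjamini-Hochberg corrected; retained
loci are ranked by the sum of their per-assay signal ranks (ChIP, GRO, NET,
mNET), rank 1 = strongest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageTrack
from .genome import GeneModel

__all__ = ["PowerLawNull", "PauseLocus", "overlap_filter", "fit_powerlaw_null",
           "coverage_histogram", "mnet_fdr_filter", "rank_loci",
           "strongest_spike", "classify_genic"]

ASSAYS = ("chip", "gro", "net", "mnet")


@dataclass
class PowerLawNull:
    """Fitted power-law noise model N_x = a * x^-b.

    ``survival(c)`` is the discrete upper-tail mass P(X >= c) of the
    normalized null; values below the fit range have p = 1, values above it
    use the analytic (Hurwitz zeta) extrapolation of the tail.
    """

    a: float
    b: float
    fit_range: tuple[int, int]
    a_err: float = float("nan")
    b_err: float = float("nan")

    def density(self, x) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** (-self.b)

    def survival(self, c, method: str = "tail-sum") -> float:
        x_lo = self.fit_range[0]
        if c <= x_lo:
            return 1.0
        if method == "tail-sum":
            # discrete tail: sum_{x >= c} x^-b / sum_{x >= x_lo} x^-b
            return float(special.zeta(self.b, c) / special.zeta(self.b, x_lo))
        if method == "integral":
            return float((c / x_lo) ** (1.0 - self.b))
        raise ValueError("method must be 'tail-sum' or 'integral'")


@dataclass
class PauseLocus:
    chrom: str
    start: int
    end: int
    strand: str
    signals: dict = field(default_factory=dict)
    ranks: dict = field(default_factory=dict)
    sum_rank: float = float("nan")
    final_rank: int = -1
    spike_pos: int = -1
    second_spike_pos: int | None = None
    mnet_fdr_q: float = float("nan")
    genic_class: str = ""
    dist_tss: float = float("nan")
    dist_tts: float = float("nan")


def overlap_filter(gro_peaks: pd.DataFrame, polII_peaks: pd.DataFrame,
                   min_frac: float = 0.5) -> pd.DataFrame:
    """GRO peaks whose intersection with some single Pol II peak is strictly
    greater than ``min_frac`` of the GRO peak's length."""
    kept = []
    for chrom, sub in gro_peaks.groupby("chrom", sort=False):
        chip = polII_peaks[polII_peaks["chrom"] == chrom]
        cs = chip["start"].to_numpy()
        ce = chip["end"].to_numpy()
        order = np.argsort(cs)
        cs, ce = cs[order], ce[order]
        for row in sub.itertuples():
            length = row.end - row.start
            # candidate chip peaks: start < row.end
            hi = np.searchsorted(cs, row.end, side="left")
            best = 0
            for k in range(hi):
                ov = min(ce[k], row.end) - max(cs[k], row.start)
                if ov > best:
                    best = ov
            if best > min_frac * length:
                kept.append(row.Index)
    return gro_peaks.loc[kept]


def coverage_histogram(values, x_max: int = 1000) -> np.ndarray:
    """Frequency of integer coverage values 0..x_max (clipped above)."""
    v = np.clip(np.asarray(values, dtype=int), 0, x_max)
    return np.bincount(v, minlength=x_max + 1)


def fit_powerlaw_null(coverage_freq: np.ndarray,
                      fit_range: tuple[int, int] = (3, 100),
                      normalize: bool = False) -> PowerLawNull:
    """Least-squares fit of log N_x against log x over the fit range.

    ``coverage_freq[x]`` is the frequency (or density) of per-position
    coverage x.  The fit preserves the input's scale, so fitting a
    tabulated density a * x^-b returns (a, b) exactly; with
    ``normalize=True`` frequencies are first rescaled to sum to 1 over the
    fit range.  The choice only shifts the prefactor: the null's tail
    probabilities depend on the exponent alone.
    """
    x_lo, x_hi = fit_range
    freq = np.asarray(coverage_freq, dtype=float)
    xs = np.arange(x_lo, min(x_hi, len(freq) - 1) + 1)
    ys = freq[xs]
    mask = ys > 0
    if mask.sum() < 10:
        raise ValueError("need >= 10 distinct coverage values with nonzero "
                         "frequency in the fit range")
    xs, ys = xs[mask], ys[mask]
    dens = ys / ys.sum() if normalize else ys
    res = stats.linregress(np.log(xs), np.log(dens))
    b = -res.slope
    a = float(np.exp(res.intercept))
    a_err = a * res.intercept_stderr
    return PowerLawNull(a, float(b), (x_lo, x_hi), float(a_err),
                        float(res.stderr))


def mnet_fdr_filter(loci: pd.DataFrame, null: PowerLawNull,
                    fdr: float = 0.05, coverage_col: str = "mnet_cov",
                    method: str = "tail-sum") -> pd.DataFrame:
    """Benjamini-Hochberg filter of candidate loci on mNET coverage.

    Each locus's p-value is the upper-tail mass of the power-law null at its
    mNET coverage (the maximum single-nucleotide count within the locus);
    loci with q <= fdr are retained, with the q-value in ``mnet_fdr_q``.
    """
    cov = loci[coverage_col].to_numpy()
    pvals = np.array([null.survival(int(c), method=method) for c in cov])
    if len(pvals) == 0:
        out = loci.copy()
        out["mnet_p"] = []
        out["mnet_fdr_q"] = []
        return out
    _, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    out = loci.copy()
    out["mnet_p"] = pvals
    out["mnet_fdr_q"] = qvals
    return out[out["mnet_fdr_q"] <= fdr]


def rank_loci(loci: pd.DataFrame, signals: dict[str, np.ndarray] | None = None
              ) -> pd.DataFrame:
    """Rank loci by the sum of per-assay descending signal ranks.

    Strongest signal per assay gets rank 1 (ties share the average rank);
    the final order is ascending in the rank sum, ties broken by the mNET
    rank and then by genomic position.  ``final_rank`` is the permutation
    1..n, 1 = strongest locus.
    """
    out = loci.copy()
    cols = {}
    for assay in ASSAYS:
        col = f"{assay}_signal"
        if signals is not None and assay in signals:
            out[col] = np.asarray(signals[assay])
        if col not in out.columns:
            raise ValueError(f"missing signal track: {assay}")
        cols[assay] = stats.rankdata(-out[col].to_numpy(), method="average")
        out[f"{assay}_rank"] = cols[assay]
    out["sum_rank"] = sum(cols.values())
    order = np.lexsort((out["start"].to_numpy(),
                        out["chrom"].astype(str).to_numpy(),
                        out["mnet_rank"].to_numpy(),
                        out["sum_rank"].to_numpy()))
    out = out.iloc[order].reset_index(drop=True)
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out


def strongest_spike(chrom: str, start: int, end: int, strand: str,
                    mnet: CoverageTrack):
    """Position of the strongest and second-strongest single-nucleotide mNET
    signal inside a locus.

    Ties go to the 5'-most position in transcription orientation.  Returns
    ``(spike_pos, second_spike_pos, spike_distance)``; the second spike is
    None when no second nonzero position exists, and spike_pos is None for
    an all-zero locus.
    """
    vals = mnet.interval_values(chrom, start, end,
                                strand if mnet.stranded else None)
    if not np.any(vals > 0):
        return None, None, None

    def argbest(v):
        m = v.max()
        idxs = np.flatnonzero(v == m)
        return int(idxs[0] if strand != "-" else idxs[-1])

    i1 = argbest(vals)
    rest = vals.copy()
    rest[i1] = -1
    second = None
    if np.any(rest > 0):
        second = start + argbest(rest)
    spike = start + i1
    dist = abs(second - spike) if second is not None else None
    return spike, second, dist


def classify_genic(loci: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Intragenic/intergenic classification and signed TSS/TTS distances.

    A locus is intragenic when its midpoint lies inside a transcript.
    Distances are measured from the locus midpoint (or its mNET spike if
    present) to the nearest gene's TSS and TTS, signed in that gene's
    transcription orientation (positive = downstream).
    """
    out = loci.copy()
    classes, d_tss, d_tts = [], [], []
    for row in out.itertuples():
        pos = int(getattr(row, "spike_pos", -1))
        if pos < 0:
            pos = (row.start + row.end) // 2
        chrom_genes = [g for g in genes if g.chrom == row.chrom]
        inside = [g for g in chrom_genes if g.tx_start <= pos < g.tx_end]
        if inside:
            g = min(inside, key=lambda g: abs(pos - g.tss))
            classes.append("intragenic")
        elif chrom_genes:
            g = min(chrom_genes, key=lambda g: abs(pos - g.tss))
            classes.append("intergenic")
        else:
            classes.append("intergenic")
            d_tss.append(float("inf"))
            d_tts.append(float("inf"))
            continue
        sign = 1 if g.strand == "+" else -1
        d_tss.append(sign * (pos - g.tss))
        d_tts.append(sign * (pos - g.tts))
    out["genic_class"] = classes
    out["dist_tss"] = d_tss
    out["dist_tts"] = d_tts
    return out
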