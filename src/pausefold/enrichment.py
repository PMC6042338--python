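"""Permutation (shuffle) enrichment of interval sets against Pol II features.

The null model re-places the query intervals uniformly at random across the
genome (optionally excluding assembly gaps), preserving their number and
lengths, and compares the observed overlap statistic with the mean over
shuffles.  Fold enrichment 1 means "no association"; the empirical p-value
uses the add-one estimator and can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import complement_intervals, merge_intervals

__all__ = ["EnrichmentResult", "shuffle_intervals", "peak_overlap_enrichment",
           "coverage_enrichment"]


@dataclass
class EnrichmentResult:
    observed: float
    null_mean: float
    null_sd: float
    fold_enrichment: float
    empirical_p: float
    n_shuffles: int
    seed: int | None
    flagged: str | None = None


class _ShuffleSpace:
    """Uniform placement space: the allowed [start, start+L) positions for
    each interval length, across all chromosomes minus exclusions."""

    def __init__(self, chrom_sizes: dict[str, int], excluded=None,
                 per_chrom_excluded: dict | None = None):
        excluded = excluded or {}
        self.chroms = list(chrom_sizes)
        self.spans = []  # (chrom_index, span_start, span_end) allowed spans
        for ci, (chrom, size) in enumerate(chrom_sizes.items()):
            excl = merge_intervals(excluded.get(chrom, []))
            for s, e in complement_intervals(excl, size):
                self.spans.append((ci, s, e))
        self.span_chrom = np.array([c for c, _, _ in self.spans])
        self.span_start = np.array([s for _, s, _ in self.spans], dtype=np.int64)
        self.span_len = np.array([e - s for _, s, e in self.spans], dtype=np.int64)

    def sample(self, lengths: np.ndarray, rng: np.random.Generator,
               n_draws: int):
        """(n_draws, n_sites) chromosome indices and starts, uniform over all
        admissible placements of each length."""
        n_sites = len(lengths)
        chrom_idx = np.empty((n_draws, n_sites), dtype=np.int64)
        starts = np.empty((n_draws, n_sites), dtype=np.int64)
        for uniq in np.unique(lengths):
            cols = np.flatnonzero(lengths == uniq)
            valid = np.maximum(self.span_len - uniq + 1, 0)
            cum = np.cumsum(valid)
            total = cum[-1] if len(cum) else 0
            if total <= 0:
                raise ValueError(f"no admissible placement for length {uniq}")
            draws = rng.integers(0, total, size=(n_draws, len(cols)))
            span_i = np.searchsorted(cum, draws, side="right")
            offset = draws - (cum[span_i] - valid[span_i])
            chrom_idx[:, cols] = self.span_chrom[span_i]
            starts[:, cols] = self.span_start[span_i] + offset
        return chrom_idx, starts


def _sites_frame(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        return sites
    return pd.DataFrame({"chrom": [s.chrom for s in sites],
                         "start": [s.start for s in sites],
                         "end": [s.end for s in sites]})


def shuffle_intervals(sites, chrom_sizes: dict[str, int], excluded=None,
                      seed=None) -> pd.DataFrame:
    """One random re-placement of the intervals: same multiset of lengths,
    uniform over allowed positions genome-wide, reproducible under seed.

    ``excluded`` maps chromosome -> list of [start, end) intervals that no
    shuffled site may overlap."""
    df = _sites_frame(sites)
    rng = np.random.default_rng(seed)
    space = _ShuffleSpace(chrom_sizes, excluded)
    lengths = (df["end"] - df["start"]).to_numpy(dtype=np.int64)
    chrom_idx, starts = space.sample(lengths, rng, 1)
    chroms = [space.chroms[i] for i in chrom_idx[0]]
    return pd.DataFrame({"chrom": chroms, "start": starts[0],
                         "end": starts[0] + lengths})


class _MergedPeaks:
    """Per-chromosome merged peak intervals for vectorized overlap tests."""

    def __init__(self, peaks: pd.DataFrame, chroms: list[str]):
        self.starts = {}
        self.ends = {}
        for ci, chrom in enumerate(chroms):
            sub = peaks[peaks["chrom"] == chrom]
            merged = merge_intervals(zip(sub["start"], sub["end"]))
            self.starts[ci] = np.array([s for s, _ in merged], dtype=np.int64)
            self.ends[ci] = np.array([e for _, e in merged], dtype=np.int64)

    def overlaps(self, chrom_idx: np.ndarray, starts: np.ndarray,
                 ends: np.ndarray) -> np.ndarray:
        out = np.zeros(chrom_idx.shape, dtype=bool)
        for ci in np.unique(chrom_idx):
            ps, pe = self.starts[ci], self.ends[ci]
            mask = chrom_idx == ci
            if len(ps) == 0:
                continue
            idx = np.searchsorted(ps, ends[mask], side="left")
            hit = idx > 0
            prev_end = np.where(hit, pe[np.maximum(idx - 1, 0)], 0)
            out[mask] = hit & (prev_end > starts[mask])
        return out


def peak_overlap_enrichment(sites, peaks, chrom_sizes: dict[str, int],
                            excluded=None, n_shuffles: int = 10_000,
                            seed=None) -> EnrichmentResult:
    """Fold enrichment of sites overlapping (>= 1 bp) Pol II peaks over the
    mean overlap count of uniformly shuffled sites."""
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    df = _sites_frame(sites)
    peaks = _sites_frame(peaks)
    rng = np.random.default_rng(seed)
    space = _ShuffleSpace(chrom_sizes, excluded)
    merged = _MergedPeaks(peaks, space.chroms)
    chrom_to_idx = {c: i for i, c in enumerate(space.chroms)}

    obs_ci = df["chrom"].map(chrom_to_idx).to_numpy()
    observed = int(merged.overlaps(obs_ci, df["start"].to_numpy(),
                                   df["end"].to_numpy()).sum())

    lengths = (df["end"] - df["start"]).to_numpy(dtype=np.int64)
    chrom_idx, starts = space.sample(lengths, rng, n_shuffles)
    null = merged.overlaps(chrom_idx, starts, starts + lengths).sum(axis=1)

    null_mean = float(null.mean())
    null_sd = float(null.std())
    p = float((1 + np.sum(null >= observed)) / (1 + n_shuffles))
    flag = None
    if len(peaks) == 0:
        fold = float("nan")
        flag = "empty peak set: fold enrichment undefined"
    else:
        fold = observed / null_mean if null_mean > 0 else float("inf")
    return EnrichmentResult(observed, null_mean, null_sd, fold, p,
                            n_shuffles, seed, flag)


def coverage_enrichment(sites, reads: CoverageTrack,
                        chrom_sizes: dict[str, int], excluded=None,
                        n_shuffles: int = 1000, seed=None) -> EnrichmentResult:
    """Fold enrichment of total read coverage under the sites over the mean
    coverage under uniformly shuffled sites."""
    df = _sites_frame(sites)
    rng = np.random.default_rng(seed)
    space = _ShuffleSpace(chrom_sizes, excluded)
    # prefix sums per chromosome for O(1) interval totals
    prefix = {}
    for ci, chrom in enumerate(space.chroms):
        arr = reads.array(chrom)
        prefix[ci] = np.concatenate(([0.0], np.cumsum(arr)))

    def totals(chrom_idx, starts, ends):
        out = np.zeros(chrom_idx.shape)
        for ci in np.unique(chrom_idx):
            mask = chrom_idx == ci
            cs = prefix[ci]
            s = np.clip(starts[mask], 0, len(cs) - 1)
            e = np.clip(ends[mask], 0, len(cs) - 1)
            out[mask] = cs[e] - cs[s]
        return out

    chrom_to_idx = {c: i for i, c in enumerate(space.chroms)}
    obs_ci = df["chrom"].map(chrom_to_idx).to_numpy()
    observed = float(totals(obs_ci, df["start"].to_numpy(),
                            df["end"].to_numpy()).sum())

    lengths = (df["end"] - df["start"]).to_numpy(dtype=np.int64)
    chrom_idx, starts = space.sample(lengths, rng, n_shuffles)
    null = totals(chrom_idx, starts, starts + lengths).sum(axis=1)

    null_mean = float(null.mean())
    flag = None
    if reads.total() == 0:
        flag = "zero total coverage: fold enrichment undefined"
        fold = float("nan")
    else:
        fold = observed / null_mean if null_mean > 0 else float("inf")
    p = float((1 + np.sum(null >= observed)) / (1 + n_shuffles))
    return EnrichmentResult(observed, null_mean, float(null.std()), fold, p,
                            n_shuffles, seed, flag)
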