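"""Per-base coverage tracks and plain-text genomics I/O (bedGraph, BED,
narrowPeak).

Toy-genome scale: tracks are dense float arrays per chromosome, which keeps
interval sums exact and trivially fast for the simulated genomes the test
suite works on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CoverageTrack", "read_bedgraph", "write_bedgraph", "read_bed",
           "write_bed", "read_narrowpeak", "write_narrowpeak"]

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLS = BED_COLS + ["signalValue", "pValue", "qValue", "summit"]


class CoverageTrack:
    """Non-negative per-base read coverage, optionally stranded.

    For a stranded track, signal lives on '+' and '-' separately; an
    unstranded track stores everything under '+' and ignores the strand
    argument on access.
    """

    def __init__(self, chrom_sizes: dict[str, int], stranded: bool = False):
        self.chrom_sizes = dict(chrom_sizes)
        self.stranded = stranded
        strands = ("+", "-") if stranded else ("+",)
        self._data = {st: {c: np.zeros(n) for c, n in chrom_sizes.items()}
                      for st in strands}

    def _strand(self, strand: str | None) -> str:
        if not self.stranded:
            return "+"
        if strand not in ("+", "-"):
            raise ValueError("stranded track requires strand '+' or '-'")
        return strand

    def array(self, chrom: str, strand: str | None = None) -> np.ndarray:
        return self._data[self._strand(strand)][chrom]

    def add(self, chrom: str, start: int, end: int, value: float,
            strand: str | None = None) -> None:
        arr = self.array(chrom, strand)
        arr[max(start, 0):min(end, len(arr))] += value

    def add_profile(self, chrom: str, start: int, values: np.ndarray,
                    strand: str | None = None) -> None:
        arr = self.array(chrom, strand)
        lo, hi = max(start, 0), min(start + len(values), len(arr))
        arr[lo:hi] += values[lo - start:hi - start]

    def interval_sum(self, chrom: str, start: int, end: int,
                     strand: str | None = None) -> float:
        arr = self.array(chrom, strand)
        return float(arr[max(start, 0):min(end, len(arr))].sum())

    def interval_values(self, chrom: str, start: int, end: int,
                        strand: str | None = None) -> np.ndarray:
        """Values over [start, end), zero-padded outside the chromosome."""
        arr = self.array(chrom, strand)
        out = np.zeros(end - start)
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start:hi - start] = arr[lo:hi]
        return out

    def total(self, strand: str | None = None) -> float:
        return float(sum(a.sum() for a in self._data[self._strand(strand)].values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        out = CoverageTrack(self.chrom_sizes, self.stranded)
        for st, chroms in self._data.items():
            for c, a in chroms.items():
                out._data[st][c] = a * factor
        return out


def write_bedgraph(track: CoverageTrack, path, strand: str | None = None) -> None:
    """Run-length-encoded bedGraph of the non-zero coverage."""
    rows = []
    for chrom in track.chrom_sizes:
        arr = track.array(chrom, strand)
        if arr.size == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        for s, e in zip(starts, ends):
            v = arr[s]
            if v != 0:
                rows.append((chrom, int(s), int(e), float(v)))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).to_csv(
        path, sep="\t", header=False, index=False)


def read_bedgraph(path, chrom_sizes: dict[str, int],
                  minus_path=None) -> CoverageTrack:
    """Load a bedGraph into a dense track; a second file yields a stranded
    track with the minus-strand signal."""
    track = CoverageTrack(chrom_sizes, stranded=minus_path is not None)
    for p, strand in ((path, "+"), (minus_path, "-")):
        if p is None:
            continue
        df = pd.read_csv(p, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"])
        for row in df.itertuples(index=False):
            track.add(row.chrom, int(row.start), int(row.end),
                      float(row.value), strand)
    return track


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLS[:df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = NARROWPEAK_COLS[:df.shape[1]]
    return df


def write_narrowpeak(df: pd.DataFrame, path) -> None:
    out = df.copy()
    defaults = {"name": ".", "score": 0, "strand": ".", "signalValue": 0.0,
                "pValue": -1, "qValue": -1, "summit": -1}
    for c in NARROWPEAK_COLS:
        if c not in out.columns:
            out[c] = defaults.get(c, ".")
    out[NARROWPEAK_COLS].to_csv(path, sep="\t", header=False, index=False)
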