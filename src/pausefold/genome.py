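"""Genome sequences, gene models, and free-energy window scans.

Coordinates are 0-based, half-open throughout; BED on disk.  The TSS of a
minus-strand transcript is its rightmost base (``tx_end - 1``), and all
offsets used by the TSS-proximal scans are transcription-oriented (negative
= upstream of the TSS in the direction of transcription).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fold import fold_windows
from .params import FoldParams, revcomp

__all__ = ["GeneModel", "FreeEnergyProfile", "read_fasta", "write_fasta",
           "read_genes_bed", "genes_to_frame", "non_template_sequence",
           "scan_genome", "scan_tss_highres"]


@dataclass(frozen=True)
class GeneModel:
    """A transcript with strand-aware TSS/TTS accessors.

    ``gene_group`` ties together isoforms of the same gene for the
    longest-transcript selection; it defaults to ``gene_id``.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    gene_group: str = ""

    def __post_init__(self):
        if self.tx_start >= self.tx_end:
            raise ValueError("tx_start must be < tx_end")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not self.gene_group:
            object.__setattr__(self, "gene_group", self.gene_id)

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    def genomic_position(self, offset: int) -> int:
        """Reference coordinate of a transcription-oriented TSS offset."""
        return self.tss + offset if self.strand == "+" else self.tss - offset


@dataclass
class FreeEnergyProfile:
    """Per-window free energies with window geometry.

    ``values[i]`` is the MFE free energy (kcal/mol, NaN = window contained N)
    of the window starting at ``anchor_start + i * step`` in scan
    orientation.  ``center_offsets[i]`` is the position each value is
    assigned to: the window's 15th nucleotide (start + 14) for the 30-nt
    high-resolution scans, the window start for interval-assigned
    low-resolution scans.
    """

    chrom: str
    anchor_start: int
    window: int
    step: int
    strand: str
    values: np.ndarray
    center_offsets: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def window_interval(self, i: int) -> tuple[int, int]:
        s = self.anchor_start + i * self.step
        return s, s + self.window


def read_fasta(path) -> dict[str, str]:
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise ValueError(f"no sequences found in {path}")
    return genome


def write_fasta(genome: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def genes_to_frame(genes) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [g.chrom for g in genes],
        "start": [g.tx_start for g in genes],
        "end": [g.tx_end for g in genes],
        "name": [g.gene_id for g in genes],
        "score": 0,
        "strand": [g.strand for g in genes],
        "gene_group": [g.gene_group for g in genes],
    })


def read_genes_bed(path) -> list[GeneModel]:
    """Gene models from BED6 (optional 7th column = gene grouping id)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = []
    for row in df.itertuples(index=False):
        group = str(row[6]) if len(row) > 6 else ""
        genes.append(GeneModel(str(row[3]), str(row[0]), str(row[5]),
                               int(row[1]), int(row[2]), group))
    return genes


def non_template_sequence(gene: GeneModel, genome: dict[str, str],
                          from_off: int, to_off: int) -> str:
    """Non-template (coding) strand sequence over transcription-oriented
    offsets [from_off, to_off) relative to the TSS, 5'->3' in the direction
    of transcription.  Spans reaching past the chromosome are clipped with a
    warning."""
    chrom_seq = genome[gene.chrom]
    n = len(chrom_seq)
    if gene.strand == "+":
        lo, hi = gene.tss + from_off, gene.tss + to_off
    else:
        lo, hi = gene.tss - to_off + 1, gene.tss - from_off + 1
    if lo < 0 or hi > n:
        warnings.warn(f"span [{lo}, {hi}) clipped to chromosome {gene.chrom}")
        lo, hi = max(lo, 0), min(hi, n)
    sub = chrom_seq[lo:hi]
    return sub if gene.strand == "+" else revcomp(sub)


def scan_genome(genome: dict[str, str], params: FoldParams | None = None, *,
                window: int = 300, step: int = 150) -> dict[str, FreeEnergyProfile]:
    """Low-resolution plus-strand scan: one MFE free energy per complete
    sliding window on each chromosome.  Windows containing N are NaN."""
    if not genome:
        raise ValueError("empty genome")
    if window < step:
        raise ValueError("window must be >= step")
    out = {}
    for chrom, seq in genome.items():
        if len(seq) < window:
            warnings.warn(f"chromosome {chrom} shorter than one window")
            values = np.empty(0)
        else:
            values = fold_windows(seq, params, window=window, step=step)
        starts = np.arange(len(values)) * step
        out[chrom] = FreeEnergyProfile(chrom, 0, window, step, "+",
                                       values, starts)
    return out


def scan_tss_highres(gene: GeneModel, genome: dict[str, str],
                     params: FoldParams | None = None, *, flank: int = 2000,
                     window: int = 30, step: int = 1,
                     strand: str = "non-template") -> FreeEnergyProfile:
    """High-resolution scan of the TSS +/- flank region of one gene.

    The scanned span covers transcription-oriented offsets
    [-flank, +flank] inclusive (2*flank + 1 nt), yielding
    ``2*flank + 2 - window`` windows at step 1; each value is assigned to
    the window's 15th nucleotide, so for flank 2000 / window 30 the profile
    covers assigned offsets -1986 .. +1985 (3972 values).
    """
    seq = non_template_sequence(gene, genome, -flank, flank + 1)
    if len(seq) != 2 * flank + 1:
        raise ValueError(f"TSS flank of {gene.gene_id} extends past chromosome")
    if "N" in seq:
        raise ValueError(f"N within TSS +/- {flank} of {gene.gene_id}")
    if strand == "template":
        seq = revcomp(seq)
    elif strand != "non-template":
        raise ValueError("strand must be 'non-template' or 'template'")
    values = fold_windows(seq, params, window=window, step=step)
    offsets = -flank + np.arange(len(values)) * step + (window // 2 - 1)
    if strand == "template":
        # the template scan runs 3'->5' relative to transcription: flip so
        # offsets remain transcription-oriented
        values = values[::-1].copy()
    return FreeEnergyProfile(gene.chrom, -flank, window, step, strand,
                             values, offsets)
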