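"""Synthetic genomes, annotations and nascent-transcription tracks with a
truth manifest, so every analysis stage is testable without downloads.

The generator emulates the statistical structure the pipeline assumes:

* an i.i.d. background genome at a configurable GC content, with optional
  N-gap blocks;
* non-overlapping genes with guard spacing so TSS +/- 2 kb regions never
  overlap, deterministically assigned to pausing states (PAU / NPA / NP2);
* for each paused gene, a GC-rich inverted repeat (hairpin) written on the
  non-template strand with its center a fixed offset upstream of the pause
  position (default -30 nt from a pause at TSS + 75), optionally joined by
  a G-quadruplex motif;
* Gaussian Pol II ChIP coverage centered on the pause with a matching
  narrowPeak, strand-specific promoter-proximal GRO/NET coverage, and an
  mNET track carrying a tall single-nucleotide spike at the pause over a
  genome-wide integer noise floor sampled from the power law
  N_x = a * x^-b on coverage 3..100 (counts of 1-2 come from a documented
  two-point completion below the fit range);
* intergenic decoy loci with GRO + ChIP peaks but only noise-level mNET
  signal, exercising the FDR filter's specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import (BED_COLS, NARROWPEAK_COLS, CoverageTrack, write_bed,
                       write_bedgraph, write_narrowpeak)
from .genome import GeneModel, genes_to_frame, write_fasta
from .params import revcomp

__all__ = ["SimulationConfig", "SimulatedData", "make_genome",
           "plant_structures", "simulate_tracks", "simulate",
           "write_manifest", "read_manifest"]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    background_gc: float = 0.45
    n_gaps: int = 0
    gap_length: int = 2000
    n_genes: int = 100
    paused_fraction: float = 0.6
    no_polii_fraction: float = 0.2
    gene_length_range: tuple[int, int] = (1500, 4500)
    pause_offset: int = 75           # nt downstream of the TSS
    hairpin_stem: int = 12
    hairpin_loop: int = 4
    hairpin_offset: int = -30        # hairpin center relative to the pause
    hairpin_stem_gc: float = 0.85
    g4_fraction: float = 0.1
    noise_a: float = 0.965
    noise_b: float = 2.443
    noise_range: tuple[int, int] = (3, 100)
    noise_density: float = 0.05      # fraction of positions with mNET noise
    low_count_fraction: float = 0.6  # noise positions completed below range
    chip_height: float = 30.0
    chip_sd: float = 75.0
    chip_peak_halfwidth: int = 150
    chip_body_height: float = 3.0
    gro_height: float = 20.0
    mnet_spike_height: float = 500.0
    n_decoy_loci: int = 30

    def __post_init__(self):
        if not 0 <= self.paused_fraction <= 1:
            raise ValueError("paused_fraction must be in [0, 1]")
        if self.paused_fraction + self.no_polii_fraction > 1:
            raise ValueError("state fractions exceed 1")
        if min(self.chrom_length, self.gene_length_range[0],
               self.hairpin_stem, self.hairpin_loop) <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: dict[str, str]
    gaps: dict[str, list[tuple[int, int]]]
    genes: list[GeneModel]
    manifest: pd.DataFrame
    chip: CoverageTrack
    chip_peaks: pd.DataFrame
    gro: CoverageTrack
    gro_peaks: pd.DataFrame
    net: CoverageTrack
    mnet: CoverageTrack
    decoys: pd.DataFrame

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write_all(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        write_bed(genes_to_frame(self.genes), out / "genes.bed")
        write_manifest(self.manifest, out / "truth_manifest.tsv")
        write_narrowpeak(self.chip_peaks, out / "chip_peaks.narrowPeak")
        write_bed(self.gro_peaks, out / "gro_peaks.bed")
        write_bedgraph(self.chip, out / "chip.bedgraph")
        for name, track in (("gro", self.gro), ("net", self.net),
                            ("mnet", self.mnet)):
            write_bedgraph(track, out / f"{name}_plus.bedgraph", "+")
            write_bedgraph(track, out / f"{name}_minus.bedgraph", "-")


def make_genome(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Background genome: i.i.d. bases at ``background_gc``, plus N gaps."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gc = config.background_gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = {}
    gaps: dict[str, list[tuple[int, int]]] = {}
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                           size=config.chrom_length, p=probs)
        gaps[chrom] = []
        for _ in range(config.n_gaps):
            s = int(rng.integers(0, config.chrom_length - config.gap_length))
            bases[s:s + config.gap_length] = ord("N")
            gaps[chrom].append((s, s + config.gap_length))
        genome[chrom] = bases.tobytes().decode("ascii")
    return genome, gaps


def _place_genes(config: SimulationConfig, gaps, rng) -> list[GeneModel]:
    """Non-overlapping genes with guard spacing >= 2 * 2000 nt between
    TSS-proximal regions, avoiding N gaps."""
    guard = 2 * 2000 + 500
    genes = []
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        n = len(idxs)
        if n == 0:
            continue
        lo_len, hi_len = config.gene_length_range
        slot = (config.chrom_length - guard) // max(n, 1)
        if slot < hi_len + guard:
            raise ValueError("chromosome too short for the requested genes")
        for k, gi in enumerate(idxs):
            length = int(rng.integers(lo_len, hi_len + 1))
            slot_lo = guard // 2 + k * slot
            start = slot_lo + int(rng.integers(0, max(slot - length - guard, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel(f"gene{gi:04d}", chrom, strand, start, start + length)
            # avoid N gaps in the TSS-proximal span
            span = (g.tss - 2100, g.tss + 2100)
            if any(s < span[1] and e > span[0] for s, e in gaps[chrom]):
                continue
            genes.append(g)
    return genes


def _assign_states(config: SimulationConfig, genes, rng) -> list[str]:
    """Deterministic state counts: exactly round(n * fraction) of each."""
    n = len(genes)
    n_pau = round(n * config.paused_fraction)
    n_np2 = round(n * config.no_polii_fraction)
    states = ["PAU"] * n_pau + ["NP2"] * n_np2 + ["NPA"] * (n - n_pau - n_np2)
    rng.shuffle(states)
    return states


def _hairpin_element(config: SimulationConfig, rng) -> str:
    gc = config.hairpin_stem_gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    stem = "".join(rng.choice(list("ACGT"), size=config.hairpin_stem, p=probs))
    loop = "".join(rng.choice(list("ACGT"), size=config.hairpin_loop))
    return stem + loop + revcomp(stem)


G4_ELEMENT = "GGGTTAGGGTTAGGGTTAGGG"


def plant_structures(genome: dict[str, str], manifest: pd.DataFrame,
                     config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> dict[str, str]:
    """Write the planted hairpins (and optional G4 motifs) of paused genes
    into the genome, on each gene's non-template strand."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    arrs = {c: bytearray(s.encode()) for c, s in genome.items()}
    for row in manifest.itertuples():
        if row.state != "PAU":
            continue
        hairpin = _hairpin_element(config, rng)
        prefix = G4_ELEMENT + "TT" if row.has_g4 else ""
        element = prefix + hairpin
        # place the hairpin center at pause_offset + hairpin_offset
        # (transcription-oriented); an optional G4 sits just upstream
        center_off = config.pause_offset + config.hairpin_offset
        start_off = center_off - (len(prefix) + len(hairpin) // 2)
        _write_oriented(arrs[row.chrom], row.strand, row.tss, start_off, element)
        ends = sorted((_genomic(row, start_off),
                       _genomic(row, start_off + len(element) - 1)))
        manifest.loc[row.Index, "hairpin_start"] = ends[0]
        manifest.loc[row.Index, "hairpin_end"] = ends[1] + 1
    return {c: bytes(a).decode() for c, a in arrs.items()}


def _genomic(row, offset: int) -> int:
    return row.tss + offset if row.strand == "+" else row.tss - offset


def _write_oriented(arr: bytearray, strand: str, tss: int, start_off: int,
                    element: str) -> None:
    if strand == "+":
        pos = tss + start_off
        arr[pos:pos + len(element)] = element.encode()
    else:
        pos = tss - (start_off + len(element) - 1)
        arr[pos:pos + len(element)] = revcomp(element).encode()


def _powerlaw_pmf(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    x = np.arange(config.noise_range[0], config.noise_range[1] + 1)
    w = x.astype(float) ** (-config.noise_b)
    return x, w / w.sum()


def simulate_tracks(genome: dict[str, str], manifest: pd.DataFrame,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None):
    """Signal tracks and peak sets consistent with the manifest."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    sizes = {c: len(s) for c, s in genome.items()}
    chip = CoverageTrack(sizes)
    gro = CoverageTrack(sizes, stranded=True)
    net = CoverageTrack(sizes, stranded=True)
    mnet = CoverageTrack(sizes, stranded=True)
    chip_peaks, gro_peaks = [], []

    # genome-wide mNET noise floor on both strands
    x_noise, pmf = _powerlaw_pmf(config)
    for chrom, size in sizes.items():
        for strand in "+-":
            n_noise = rng.binomial(size, config.noise_density)
            pos = rng.choice(size, size=n_noise, replace=False)
            low = rng.random(n_noise) < config.low_count_fraction
            counts = np.empty(n_noise)
            counts[low] = rng.choice([1, 2], p=[0.7, 0.3], size=int(low.sum()))
            counts[~low] = rng.choice(x_noise, p=pmf, size=int((~low).sum()))
            arr = mnet.array(chrom, strand)
            arr[pos] += counts

    for row in manifest.itertuples():
        tss, strand, chrom = row.tss, row.strand, row.chrom
        sign = 1 if strand == "+" else -1
        if row.state == "NP2":
            continue
        if row.state == "PAU":
            pause = row.pause_pos
            # Gaussian ChIP enrichment centered on the pause
            half = int(4 * config.chip_sd)
            offs = np.arange(-half, half + 1)
            prof = config.chip_height * np.exp(-offs ** 2 / (2 * config.chip_sd ** 2))
            chip.add_profile(chrom, pause - half, prof)
            chip_peaks.append((chrom, pause - config.chip_peak_halfwidth,
                               pause + config.chip_peak_halfwidth + 1,
                               f"{row.gene_id}_peak", 0, ".",
                               config.chip_height, -1.0, -1.0,
                               config.chip_peak_halfwidth))
            # promoter-proximal nascent RNA on the coding strand
            lo, hi = sorted((tss, pause + sign * 50))
            gro.add(chrom, lo, hi + 1, config.gro_height, strand)
            net.add(chrom, lo, hi + 1, config.gro_height / 2, strand)
            gro_peaks.append((chrom, lo, hi + 1, f"{row.gene_id}_gro",
                              0, strand))
            mnet.array(chrom, strand)[pause] += config.mnet_spike_height
        else:  # NPA: uniform elongating signal, no promoter spike
            chip.add(chrom, row.tx_start, row.tx_end, config.chip_body_height)
            mid = (row.tx_start + row.tx_end) // 2
            chip_peaks.append((chrom, mid - 300, mid + 301,
                               f"{row.gene_id}_peak", 0, ".",
                               config.chip_body_height, -1.0, -1.0, 300))
            gro.add(chrom, row.tx_start, row.tx_end,
                    config.gro_height / 10, strand)

    chip_peaks = pd.DataFrame(chip_peaks, columns=NARROWPEAK_COLS)
    gro_peaks = pd.DataFrame(gro_peaks, columns=BED_COLS)
    return chip, chip_peaks, gro, gro_peaks, net, mnet


def _make_decoys(config: SimulationConfig, genes, sizes, chip, gro,
                 chip_peaks, gro_peaks, rng) -> pd.DataFrame:
    """Intergenic GRO+ChIP decoy loci with only noise-level mNET signal."""
    occupied = [(g.chrom, g.tx_start - 4200, g.tx_end + 4200) for g in genes]
    rows = []
    chroms = list(sizes)
    tries = 0
    while len(rows) < config.n_decoy_loci and tries < 10_000:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(5000, sizes[chrom] - 5000))
        if any(c == chrom and s < pos < e for c, s, e in occupied):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, pos, strand))
        chip.add(chrom, pos - 150, pos + 151, config.chip_height / 3)
        gro.add(chrom, pos - 60, pos + 61, config.gro_height / 2, strand)
        chip_peaks.loc[len(chip_peaks)] = (chrom, pos - 150, pos + 151,
                                           f"decoy{len(rows)}_peak", 0, ".",
                                           config.chip_height / 3, -1.0, -1.0,
                                           150)
        gro_peaks.loc[len(gro_peaks)] = (chrom, pos - 60, pos + 61,
                                         f"decoy{len(rows)}_gro", 0, strand)
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


def simulate(config: SimulationConfig | None = None) -> SimulatedData:
    """Full deterministic simulation under ``config.seed``."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genome, gaps = make_genome(config, rng)
    genes = _place_genes(config, gaps, rng)
    states = _assign_states(config, genes, rng)
    manifest = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "chrom": [g.chrom for g in genes],
        "strand": [g.strand for g in genes],
        "tx_start": [g.tx_start for g in genes],
        "tx_end": [g.tx_end for g in genes],
        "tss": [g.tss for g in genes],
        "state": states,
        "has_g4": False,
        "pause_pos": -1,
        "hairpin_start": -1,
        "hairpin_end": -1,
    })
    pau = manifest["state"] == "PAU"
    n_g4 = round(int(pau.sum()) * config.g4_fraction)
    g4_rows = manifest.index[pau][:n_g4]
    manifest.loc[g4_rows, "has_g4"] = True
    manifest.loc[pau, "pause_pos"] = [
        _genomic(row, config.pause_offset)
        for row in manifest[pau].itertuples()]
    genome = plant_structures(genome, manifest, config, rng)
    chip, chip_peaks, gro, gro_peaks, net, mnet = simulate_tracks(
        genome, manifest, config, rng)
    sizes = {c: len(s) for c, s in genome.items()}
    decoys = _make_decoys(config, genes, sizes, chip, gro,
                          chip_peaks, gro_peaks, rng)
    return SimulatedData(config, genome, gaps, genes, manifest, chip,
                         chip_peaks, gro, gro_peaks, net, mnet, decoys)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
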