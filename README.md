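# pausefold

Single-stranded DNA secondary-structure free energy and RNA polymerase II
promoter-proximal pausing analysis.

## The problem

During transcription the DNA duplex is transiently unwound; the non-template
(coding) strand is free to fold back on itself into hairpins and
G-quadruplexes. Stable secondary structure forming just upstream of the
polymerase has been proposed as a determinant of promoter-proximal Pol II
pausing. Testing that idea genome-wide requires a chain of analyses:

1. **Folding-energy landscapes** — minimum free energy (MFE, ΔG in
   kcal/mol) of single-stranded DNA in sliding windows, genome-wide
   (300 nt / 150 nt step) and at high resolution around transcription start
   sites (30 nt / 1 nt step on the non-template strand, each value assigned
   to the window's 15th nucleotide). More negative ΔG = more stable.
2. **Stable-structure sites** — maximal runs of ≥ 7 consecutive windows in
   the most stable 5% of the genome-wide ΔG distribution (minimum callable
   site: (7 − 1)·150 + 300 = 1200 nt).
3. **Permutation enrichment** — association of those sites with Pol II
   ChIP-seq peaks/reads against a shuffled-placement null; fold enrichment
   = observed / mean over shuffles, 1 = no association.
4. **Traveling ratio (TR)** — per-gene read density over TSS−30..+300
   divided by the density over the rest of the gene; Pol II-bound genes with
   TR > 2 are paused (PAU), TR ≤ 2 non-paused (NPA), unbound genes NP2.
5. **Annotation-free pause sites** — GRO-seq peaks overlapping Pol II peaks
   by > 50%, filtered at 5% FDR against a power-law mNET-seq noise model
   `N_x = a·x^−b` fitted on coverage 3..100, ranked by summed per-assay
   signal ranks, and localized by the strongest single-nucleotide mNET
   spike.
6. **Anchored profiles** — ΔG/coverage matrices and averages around TSSs or
   spikes, locating the free-energy minimum upstream of pausing positions.
7. **Mutant regression** — cumulative ΔΔG of promoter point mutations over
   all affected 30-nt windows (folded under nuclear-extract conditions:
   60 mM KCl, 7 mM MgCl₂, 30 °C) regressed against measured paused
   fractions with a Huber-weighted robust linear fit.

`pausefold` implements this pipeline as a tested library plus a thin CLI,
with a synthetic-data generator (`pausefold.simulate`) that plants hairpins,
G4 motifs, pausing spikes, and power-law noise with a truth manifest, so
every stage is verifiable without external downloads.

The folding engine is a self-contained Zuker-style dynamic program over
Watson–Crick pairs with unified DNA nearest-neighbor (ΔH, ΔS) stacks,
tabulated loop penalties, salt and temperature corrections, no lonely
pairs, and an optional G-quadruplex layer; an exhaustive-enumeration oracle
validates it exactly on short sequences. See `docs/methods.md` for the full
model description and its limitations.

## Worked example

```python
from pausefold import mfe_fold
from pausefold.simulate import SimulationConfig, simulate
from pausefold.pipeline import run_pipeline, recovery_stats

print(mfe_fold("GCGCTTTTGCGC"))
# FoldResult(delta_g=-3.12, structure='((((....))))', seq_length=12)

data = simulate(SimulationConfig(seed=7))   # 100 genes on a 1-Mb genome
result = run_pipeline(data)
print(result.state_fractions)
# {'NP2': 0.2, 'NPA': 0.2, 'PAU': 0.6}
print(round(result.null.b, 3))              # fitted mNET noise exponent
# 2.458
print(len(result.loci), "of", result.n_candidates, "candidate loci retained")
# 64 of 90 candidate loci retained
print(result.dg_min_interval, round(result.dg_min_value, 2))
# (-31, -31) -17.11
print(recovery_stats(result, data))
# {'state_accuracy': 1.0, 'spike_recovery': 1.0, 'n_planted': 60, 'n_loci': 64}
```

Reading the output: a 12-mer GC hairpin folds at −3.12 kcal/mol; on the
simulated genome the traveling-ratio classifier recovers every planted
pausing state, the pause caller retains 64 loci (60 planted + a few
noise-level decoys at the FDR boundary) and finds every planted mNET spike
exactly, and the spike-anchored average free-energy profile reaches its
minimum 31 nt upstream of the pause — the planted hairpins are centered
30 nt upstream.

The same stages are available from the shell:

```bash
pausefold simulate --seed 7 --out sim/
pausefold scan --fasta sim/genome.fa --window 300 --step 150 --out scan.tsv
pausefold call-sites --profile scan.tsv --quantile 0.05 --min-run 7 --out sites.bed
pausefold fold --seq GCGCTTTTGCGC
```

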