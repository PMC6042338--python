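# Methods

## Folding energy model

The builtin engine computes the minimum-free-energy (MFE) secondary
structure of single-stranded DNA by Zuker-style dynamic programming over
Watson–Crick pairs (A:T, G:C; no G:T wobble, matching the duplex chemistry
of DNA). The energy function is:

- **Stacks.** Unified DNA nearest-neighbor (ΔH, ΔS) parameters for the ten
  unique duplex steps, completed to all sixteen by reverse-complement
  symmetry, shipped as a plain TSV (`pausefold/data/nn_params.tsv`).
  ΔG(T) = ΔH − T·ΔS′/1000 with the entropic salt correction
  ΔS′ = ΔS + 0.368·ln[Na⁺]eq applied per stack; divalent magnesium enters
  through the equivalent-monovalent relation [Na⁺]eq = [Na⁺] +
  3.795·√[Mg²⁺] (the standard 120·√mM rule in molar units).
- **Loops.** Tabulated hairpin / bulge / internal-loop penalties (ΔG37),
  linearly interpolated between tabulated sizes, extrapolated beyond the
  largest entry with a Jacobson–Stockmayer 1.75·RT·ln(n/n₀) term, and
  scaled linearly with absolute temperature (treated as purely entropic).
  Internal-loop asymmetry costs 0.5 kcal/mol per nt, capped at 3.0.
  Interior/bulge loops are capped at 15 unpaired nt total; multibranch
  loops use an affine cost a + b·(branches+1) + c·unpaired with
  (a, b, c) = (3.4, 0.4, 0.1) kcal/mol at 37 °C.
- **Constraints.** Minimum hairpin loop 3 nt; lonely (isolated) pairs
  disallowed by default — every helix must be at least two pairs long —
  implemented directly in the recursion, not by post-filtering.
- **Convention.** The unpaired chain has energy 0; if no structure is
  negative, the sequence is reported unfolded at ΔG = 0, so ΔG ≤ 0 always.

Energies are integers in units of 0.01 kcal/mol throughout the dynamic
program, the traceback and the enumeration oracle, so all three agree
*exactly* (no floating-point tie ambiguity). The recursion is banded: for a
1-nt-step scan with window w, all pair matrices are filled once over the
whole sequence for spans < w and each window only pays an O(w²) external
loop, which makes the TSS ±2 knt scans (3972 windows per gene) cheap. The
kernels are numba-compiled.

**Omissions, by design.** Terminal A·T penalties, hairpin terminal-mismatch
bonuses, special tetraloop/triloop tables, coaxial stacking and dangles are
not modeled. The package's analyses consume ΔG *rankings* (quantile
thresholds, profile minima, ΔΔG signs), which are robust to these terms;
exact numerical agreement with Mfold or ViennaRNA output is a non-goal. An
external folding program can be plugged in through
`FoldParams(backend="external-command")`, which parses "dot-bracket (ΔG)"
output; the builtin engine is the default and the test target.

**G-quadruplexes.** `g4_scan` finds maximal matches of four G-tracts
(G≥3, loops 1–7 nt, span ≤ 45 nt). The stability model is deliberately
minimal: −6.0 kcal/mol per tetrad beyond the second, +0.25 kcal/mol per
loop nucleotide (never above 0). With `allow_g4`, the MFE is the minimum
over the plain fold and every "fold left flank + G4 + fold right flank"
split, so enabling G4s can only lower ΔG. Only the presence and rough
magnitude of the G4 contribution matters downstream (it shifts profile
minima by a few tenths of kcal/mol without moving them).

**Validation oracle.** `enumerate_structures_oracle` generates every
non-crossing Watson–Crick pair set (≤ 18 nt) respecting the hairpin
minimum, the lonely-pair rule and the interior-loop cap, and scores each
with the same integer energy function via explicit loop decomposition. The
test suite asserts exact DP/oracle agreement on hundreds of random
sequences, and that every traceback structure re-scores to its reported
energy.

## Conditions

Two presets: genome scans use 1.0 M Na⁺, 0 Mg²⁺, 37 °C; the mutant ΔΔG
analysis uses nuclear-extract transcription conditions (60 mM KCl, 7 mM
MgCl₂, 30 °C).

## Coordinates and scan geometry

0-based half-open coordinates internally, BED dialect on disk. The TSS of a
minus-strand transcript is `tx_end − 1`; all TSS-relative offsets are
transcription-oriented (negative = upstream). The genome-wide scan folds
the plus strand (300 nt / 150 nt); the high-resolution scan folds the
non-template strand over TSS ± flank inclusive of both ends (for flank
2000: 4001 nt, 3972 windows of 30 nt at step 1), assigning each window's
value to its 15th nucleotide (start + 14), i.e. assigned offsets
−1986..+1985. Windows containing N are emitted as missing and break
stable-site runs. Incomplete trailing windows are dropped.

## Stable sites and annotation

The stability threshold is the lower empirical q-quantile (default 5%) of
all non-missing window values, taken as the ⌈qN⌉-th order statistic so
boundary ties stay on the stable side of the ≤ comparison. Sites are
maximal runs of ≥ 7 consecutive qualifying windows. Region classes —
TSS ±250, TTS ±250, promoter (−1000..−250 upstream of the TSS,
strand-aware), gene body (TSS+250..TTS−250), intergenic — are applied with
precedence TSS > TTS > promoter > gene body > intergenic both to the sites
and to the genome territory used for density normalization, so counts
partition the sites and territories partition the genome.

## Permutation enrichment

Shuffles re-place the query intervals uniformly at random genome-wide
(optionally excluding gap intervals), preserving the length multiset.
Overlap is ≥ 1 bp against the merged peak set; the coverage variant sums
per-base reads under the sites via prefix sums. Fold enrichment = observed
/ null mean; the empirical p-value uses the add-one estimator
(1 + #{null ≥ obs}) / (1 + n_shuffles) and can never be 0. Placement and
overlap tests are vectorized over all shuffles (10,000 shuffles of 100
sites run in well under a second).

## Traveling ratio

Densities are per-base coverage sums divided by region length. The TSS
window −30..+300 is anchored on the TSS and not clipped to the transcript;
the body is the transcript minus that window. TR = +∞ when the body is
empty of signal but the window is not (+∞ ranks above all finite TRs); a
bound gene with no signal anywhere has undefined TR and is classified NPA
(not > 2). Transcript selection keeps the longest isoform per gene group
(ties: leftmost start, then lexicographic id), drops transcripts < 660 nt
and transcripts with undetermined sequence (N, or a span beyond the
chromosome) within TSS ± 2 knt.

## Power-law noise null and FDR

The mNET noise model N_x = a·x^−b is fitted by least squares of log N_x on
log x over coverage 3..100 using zero-count-free cells. The fit preserves
the input scale (so refitting a tabulated density returns its parameters
identically); the per-locus p-value is the discrete upper tail
P(X ≥ c) = ζ(b, c)/ζ(b, x_lo) (Hurwitz zeta), which depends only on the
exponent — the prefactor convention is therefore immaterial to inference.
A continuous-integral tail is available as an alternative. The per-locus
statistic is the maximum single-nucleotide mNET count inside the locus;
Benjamini–Hochberg controls the FDR at 5% by default. Coverage below the
fit range has p = 1. Because the discrete tail p-values are conservative,
realized false-retention on pure-null draws stays at or below the nominal
level (asserted over 20 seeds in the tests).

## Pause-locus construction and ranking

Candidates are GRO peaks whose intersection with a *single* Pol II peak
strictly exceeds half the GRO peak's length. Loci inherit the GRO peak's
strand; mNET spikes are sought on that strand, ties resolved to the 5′-most
position in transcription orientation. Per-assay signal is total per-base
coverage within the locus (configurable); per-assay descending ranks use
average ranks for ties; the final order is ascending in the rank sum with
ties broken by mNET rank then genomic position. Ranks are computed on the
post-FDR set. A locus is intragenic when its spike (midpoint if absent)
lies inside a transcript; TSS/TTS distances are signed in the nearest
gene's transcription orientation.

## Profiles

Anchored matrices extract per-base track values at offsets −flank..+flank
around each anchor, flipping minus-strand rows so negative offsets are
always upstream; edge rows are NaN-padded and missing values are excluded
from column means (per-offset n is reported). `locate_min` returns the
contiguous offset interval within ε = 0.05 kcal/mol of the average-profile
minimum (the interval-width convention the bounds depend on is ours; a flat
window is flagged degenerate). GC tracks use the same 30-nt/15th-nt
assignment geometry as ΔG so the two are directly comparable. The
extreme-density summary reports, per offset, the fraction of loci whose
value falls in the global lowest/highest 2% band.

## Mutant ΔΔG and robust regression

"Windows affected by a mutation" are all complete 30-nt windows containing
a mutated position (≤ 30 per mutation, fewer at sequence edges); the
cumulative ΔΔG sums (ΔG_mut − ΔG_ref) over the union of affected windows,
so well-separated mutations contribute additively. The regression of
measured paused fraction on cumulative ΔΔG is iteratively reweighted least
squares with Huber's weight function (tuning constant 1.345, MAD scale;
statsmodels RLM). Full MM-estimation with an S-estimator start is not used:
only the slope's sign and rough magnitude are consumed, and Huber-IRLS
reduces exactly to OLS when all residuals are within threshold. Points with
final weight < 0.5 are flagged as outliers; an exact fit (zero residual
scale) reports unit weights.

## Synthetic data

The generator emulates the statistical structure the analyses assume, with
a truth manifest for every planted feature. Defaults (the study conditions
for the test suite): one 1-Mb chromosome at GC 0.45; 100 non-overlapping
genes of 1.5–4.5 knt placed with ≥ 4.5 knt guard spacing so TSS ± 2 knt
regions never overlap; exact state counts 60% PAU / 20% NPA / 20% NP2;
pause at TSS + 75 on the coding strand; for each paused gene a GC-rich
12-bp-stem, 4-nt-loop inverted repeat written on the non-template strand
with its center 30 nt upstream of the pause (10% of paused genes also get
an upstream G4 motif). Signals: Gaussian ChIP enrichment (σ = 75, height
30) at the pause with a ±150 nt narrowPeak; promoter-proximal GRO/NET
coverage from the TSS to pause+50 on the coding strand; an mNET spike of
500 counts at the pause over genome-wide integer noise in which 5% of
positions per strand carry signal — 60% of them completed below the fit
range with counts of 1–2, the rest drawn from x^−2.443 on 3..100. The 5%
density reflects a realistic nonzero-coverage floor for TSS-proximal
mNET-seq and gives the 3..100 log-log fit enough tail mass to be
well-conditioned. Thirty intergenic decoy loci carry GRO+ChIP peaks but
only noise-level mNET signal, exercising the FDR filter's specificity.

What the simulation does **not** model: read-level sampling noise,
mappability and GC bias, overlapping genes and isoforms, enhancer RNAs,
divergent transcription, and any coupling between sequence composition and
signal strength beyond the planted elements. Passing the end-to-end tests
therefore demonstrates correctness of the machinery under its stated
assumptions, not performance on real sequencing data.

## Problem sizes and numerical choices

The test suite runs the full pipeline at the default 100-gene / 1-Mb scale
(seconds, one core) and a compact 20-gene / 300-kb configuration for unit
fixtures. Genome-scale inputs (hg19, ~2·10⁷ windows) are an optional
overnight run of the same code paths, not a test path; published
genome-scale counts and thresholds require the original genome, data sets
and folding programs and are intentionally out of the desk-scale test
surface. Quantile thresholds use the inverted-CDF convention; interval
arithmetic is 0-based half-open with ties documented at each boundary; all
stochastic components take explicit seeds and the simulation is
byte-deterministic under its seed.
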