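"""Minimum-free-energy folding of single-stranded DNA.

The builtin engine is a Zuker-style dynamic program over Watson-Crick pairs
with nearest-neighbor stack energies, tabulated hairpin / bulge / interior
loop penalties, an affine multibranch term, and no lonely pairs by default
(see :mod:`pausefold.params` for the energy model).  A sequence whose best
structure is not negative in free energy is reported as unfolded with
``delta_g = 0``.

G-quadruplex motifs (four tracts of >= 3 G separated by 1-7 nt loops) can
optionally substitute a segment of the structure; their stability is scored
with a simple per-tetrad bonus so that enabling G4s never raises the MFE.
"""

from __future__ import annotations

import re
import shlex
import subprocess
from dataclasses import dataclass

import numpy as np

from . import _dp
from .params import (ENERGY_SCALE, G4_BONUS_PER_TETRAD, G4_PENALTY_PER_LOOP_NT,
                     MAX_INTERIOR_LOOP, FoldParams, encode, get_model)

__all__ = ["FoldResult", "G4Motif", "mfe_fold", "fold_windows", "g4_scan"]

_G4_RE = re.compile(r"G{3,}(?:[ACT]{1,7}G{3,}){3}")
_GTRACT_RE = re.compile(r"G{3,}")


@dataclass(frozen=True)
class FoldResult:
    """MFE prediction: free energy (kcal/mol), dot-bracket structure
    ('+' marks positions inside a G-quadruplex tract), sequence length."""

    delta_g: float
    structure: str
    seq_length: int

    def pairs(self) -> list[tuple[int, int]]:
        stack, out = [], []
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                out.append((stack.pop(), i))
        return sorted(out)


@dataclass(frozen=True)
class G4Motif:
    """A four-G-tract quadruplex motif (0-based half-open coordinates)."""

    start: int
    end: int
    n_tracts: int
    bonus_energy: float  # kcal/mol, <= 0


def g4_scan(seq: str) -> list[G4Motif]:
    """All maximal matches of the G-quadruplex pattern (G>=3 tracts, 1-7 nt
    loops, total span <= 45 nt), with the simplified stability bonus."""
    seq = seq.upper()
    out = []
    for m in _G4_RE.finditer(seq):
        if m.end() - m.start() > 45:
            continue
        tracts = _GTRACT_RE.findall(m.group())
        tetrads = min(min(len(t) for t in tracts), 6)
        loop_nt = (m.end() - m.start()) - sum(len(t) for t in tracts)
        bonus = G4_BONUS_PER_TETRAD * (tetrads - 2) + G4_PENALTY_PER_LOOP_NT * loop_nt
        out.append(G4Motif(m.start(), m.end(), len(tracts), min(bonus, 0.0)))
    return out


def _g4_marks(seq: str, motif: G4Motif) -> str:
    sub = seq[motif.start:motif.end]
    return "".join("+" if c == "G" else "." for c in sub)


def _fill(codes: np.ndarray, band: int, model, minloop: int, lonely: bool):
    return _dp.fill_banded(
        codes, band, minloop, MAX_INTERIOR_LOOP,
        model.stack, model.hairpin, model.bulge, model.internal,
        model.asym, model.asym_max,
        model.ml_close, model.ml_branch, model.ml_unpaired, lonely)


class _Tracer:
    """Reconstruct one optimal pair set from the filled integer matrices.

    Every branch test is an exact integer comparison against the stored
    optimum, so the traceback is deterministic and the returned structure
    re-scores to exactly the reported energy.
    """

    def __init__(self, codes, mats, model, minloop, lonely):
        self.codes = codes
        self.CL, self.D, self.CH, self.M, self.M1 = mats
        self.model = model
        self.minloop = minloop
        self.lonely = lonely
        self.pairs: list[tuple[int, int]] = []

    def external(self, W, ws, we):
        band = self.CH.shape[1]
        t = we - ws
        while t > 0:
            p = ws + t - 1
            if W[t] == W[t - 1]:
                t -= 1
                continue
            for k in range(max(p - band + 1, ws), p):
                ch = self.CH[k, p - k]
                if ch < _dp.INF32 and W[k - ws] + ch == W[t]:
                    self.trace_ch(k, p)
                    t = k - ws
                    break
            else:  # pragma: no cover - would indicate a DP/traceback mismatch
                raise RuntimeError("external traceback failed")
        return self.pairs

    def trace_ch(self, i, j):
        if self.lonely:
            self.trace_d(i, j)
        else:
            self.pairs.append((i, j))
            self.trace_d(i + 1, j - 1)

    def trace_d(self, i, j):
        self.pairs.append((i, j))
        s = j - i
        d = self.D[i, s]
        if d == self.CL[i, s]:
            self.trace_cl(i, j)
            return
        st = self.model.stack[self.codes[i], self.codes[i + 1]]
        inner = self.D[i + 1, s - 2]
        if inner < _dp.INF32 and st + inner == d:
            self.trace_d(i + 1, j - 1)
            return
        raise RuntimeError("helix traceback failed")  # pragma: no cover

    def trace_cl(self, i, j):
        s = j - i
        v = self.CL[i, s]
        m = self.model
        if s - 1 < m.hairpin.shape[0] and v == m.hairpin[s - 1]:
            return
        for n1 in range(0, MAX_INTERIOR_LOOP + 1):
            k = i + 1 + n1
            if k >= j:
                break
            for n2 in range(0, MAX_INTERIOR_LOOP + 1 - n1):
                if n1 == 0 and n2 == 0:
                    continue
                l = j - 1 - n2
                if l <= k:
                    break
                inner = self.CH[k, l - k]
                if inner >= _dp.INF32:
                    continue
                if n1 == 0 or n2 == 0:
                    pen = m.bulge[n1 + n2]
                else:
                    pen = m.internal[n1 + n2] + min(m.asym * abs(n1 - n2), m.asym_max)
                if pen + inner == v:
                    self.trace_ch(k, l)
                    return
        for k in range(i + 2, j - 1):
            a1 = self.M[i + 1, k - (i + 1)]
            a2 = self.M1[k + 1, j - 1 - (k + 1)] if j - 1 > k + 1 else _dp.INF32
            if a1 < _dp.INF32 and a2 < _dp.INF32 and \
                    m.ml_close + m.ml_branch + a1 + a2 == v:
                self.trace_m(i + 1, k)
                self.trace_m1(k + 1, j - 1)
                return
        raise RuntimeError("loop traceback failed")  # pragma: no cover

    def trace_m(self, i, j):
        s = j - i
        v = self.M[i, s]
        m = self.model
        if v == self.M1[i, s]:
            self.trace_m1(i, j)
            return
        if s >= 1 and self.M[i + 1, s - 1] < _dp.INF32 and \
                v == self.M[i + 1, s - 1] + m.ml_unpaired:
            self.trace_m(i + 1, j)
            return
        for k in range(i + 1, j + 1):
            a1 = self.M[i, k - 1 - i]
            a2 = self.M1[k, j - k]
            if a1 < _dp.INF32 and a2 < _dp.INF32 and a1 + a2 == v:
                self.trace_m(i, k - 1)
                self.trace_m1(k, j)
                return
        raise RuntimeError("multibranch traceback failed")  # pragma: no cover

    def trace_m1(self, i, j):
        s = j - i
        v = self.M1[i, s]
        m = self.model
        if s >= 1 and self.M1[i, s - 1] < _dp.INF32 and \
                v == self.M1[i, s - 1] + m.ml_unpaired:
            self.trace_m1(i, j - 1)
            return
        ch = self.CH[i, s]
        if ch < _dp.INF32 and ch + m.ml_branch == v:
            self.trace_ch(i, j)
            return
        raise RuntimeError("branch traceback failed")  # pragma: no cover


def _fold_builtin(seq: str, params: FoldParams) -> tuple[int, str]:
    """Fold one all-ACGT sequence; returns (integer energy, structure)."""
    n = len(seq)
    codes = encode(seq)
    model = get_model(params)
    model.ensure_hairpin(max(n, 2))
    mats = _fill(codes, n, model, params.min_hairpin_loop,
                 params.allow_lonely_pairs)
    CH = mats[2]
    W = _dp.external_trace_arrays(CH, 0, n)
    e = int(min(W[n], 0))
    if e == 0:
        struct = "." * n
    else:
        tracer = _Tracer(codes, mats, model, params.min_hairpin_loop,
                         params.allow_lonely_pairs)
        pairs = tracer.external(W, 0, n)
        chars = ["."] * n
        for i, j in pairs:
            chars[i], chars[j] = "(", ")"
        struct = "".join(chars)

    if params.allow_g4:
        for motif in g4_scan(seq):
            eg4 = round(ENERGY_SCALE * motif.bonus_energy)
            el, sl = (_fold_builtin(seq[:motif.start], params)
                      if motif.start > 0 else (0, ""))
            er, sr = (_fold_builtin(seq[motif.end:], params)
                      if motif.end < n else (0, ""))
            total = el + eg4 + er
            if total < e:
                e = total
                struct = sl + _g4_marks(seq, motif) + sr
    return e, struct


def _fold_external(seq: str, params: FoldParams) -> FoldResult:
    """Adapter for an external folding command.

    The command receives the sequence on stdin and must print a dot-bracket
    structure and a parenthesised free energy, RNAfold-style::

        ((((...)))) ( -3.10)
    """
    if not params.external_command:
        raise ValueError("external backend selected but no command configured")
    proc = subprocess.run(shlex.split(params.external_command), input=seq + "\n",
                          capture_output=True, text=True, check=True)
    for line in proc.stdout.splitlines():
        m = re.search(r"([.()+]+)\s+\(\s*(-?\d+\.?\d*)\s*\)", line)
        if m:
            return FoldResult(float(m.group(2)), m.group(1), len(seq))
    raise ValueError("could not parse external folding output")


def mfe_fold(seq: str, params: FoldParams | None = None) -> FoldResult:
    """Minimum-free-energy structure of a single-stranded DNA sequence.

    Parameters
    ----------
    seq : str
        DNA over {A, C, G, T}; 1 to 10,000 nt.  Sequences containing N are
        rejected (window scans mask N windows before folding).
    params : FoldParams, optional
        Folding conditions; defaults to the genome-scan preset
        (1 M Na+, 37 C, no lonely pairs).
    """
    if params is None:
        params = FoldParams()
    if not 1 <= len(seq) <= 10_000:
        raise ValueError("sequence length must be in [1, 10000]")
    seq = seq.upper()
    if params.backend == "external-command":
        return _fold_external(seq, params)
    e, struct = _fold_builtin(seq, params)
    return FoldResult(e / ENERGY_SCALE, struct, len(seq))


def fold_windows(seq: str, params: FoldParams | None = None, *,
                 window: int = 30, step: int = 1) -> np.ndarray:
    """MFE free energy (kcal/mol) of every complete sliding window.

    Windows containing any non-ACGT base are reported as NaN.  Interior
    dynamic-programming work is shared across overlapping windows (banded
    recursion), so a 1-nt-step scan costs barely more than a single pass.
    """
    if params is None:
        params = FoldParams()
    seq = seq.upper()
    n = len(seq)
    n_win = (n - window) // step + 1 if n >= window else 0
    out = np.full(n_win, np.nan)
    if n_win == 0:
        return out
    model = get_model(params)
    model.ensure_hairpin(window)
    valid = np.array([c in "ACGT" for c in seq], dtype=bool)
    # maximal runs of valid sequence
    run_start = None
    runs = []
    for i, v in enumerate(valid):
        if v and run_start is None:
            run_start = i
        elif not v and run_start is not None:
            runs.append((run_start, i))
            run_start = None
    if run_start is not None:
        runs.append((run_start, n))
    for rs, re_ in runs:
        if re_ - rs < window:
            continue
        # window indices of the global step grid fully inside this run
        w_lo = (rs + step - 1) // step
        w_hi = (re_ - window) // step
        if w_hi < w_lo or w_lo >= n_win:
            continue
        w_hi = min(w_hi, n_win - 1)
        sub = encode(seq[rs:re_])
        band = min(window, re_ - rs)
        CH = _fill(sub, band, model, params.min_hairpin_loop,
                   params.allow_lonely_pairs)[2]
        off = w_lo * step - rs
        mfes = _dp.window_mfe(CH[off:], re_ - rs - off, band, window, step)
        out[w_lo:w_lo + mfes.shape[0]] = mfes / ENERGY_SCALE
    if params.allow_g4:
        motifs = g4_scan(seq)
        for motif in motifs:
            # windows fully containing the motif may include it
            first = max(0, -(-(motif.end - window) // step))
            last = min(n_win - 1, motif.start // step)
            for w in range(first, last + 1):
                ws = w * step
                if ws <= motif.start and motif.end <= ws + window and \
                        not np.isnan(out[w]):
                    res = mfe_fold(seq[ws:ws + window], params)
                    out[w] = min(out[w], res.delta_g)
    return out
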