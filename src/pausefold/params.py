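"""Folding conditions and the table-driven nearest-neighbor energy model.

The builtin energy model scores single-stranded DNA secondary structures with
Watson-Crick (A:T, G:C) stacks from a unified DNA nearest-neighbor table plus
tabulated hairpin / bulge / internal-loop penalties and an affine multibranch
term.  Stack free energies are computed from (dH, dS) at the requested
temperature with an entropic monovalent-salt correction; divalent cations are
folded into an equivalent monovalent concentration.  Loop penalties are
treated as purely entropic and scaled linearly with absolute temperature.

All energies are handled internally as integers in units of 0.01 kcal/mol so
that dynamic programming, traceback and the exhaustive enumeration oracle
agree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

#: integer energy scale: energies are stored in units of 0.01 kcal/mol
ENERGY_SCALE = 100
#: sentinel for "no admissible structure"
INF = np.int32(1 << 28)

R_GAS = 1.9872e-3  # kcal / (mol K)
T37_K = 310.15

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# largest bulge/internal loop searched by the dynamic program (nt, both sides
# combined); larger interior loops are never more stable than a multibranch
# decomposition at this penalty scale
MAX_INTERIOR_LOOP = 15


@dataclass(frozen=True)
class FoldParams:
    """Conditions under which a sequence is folded.

    Parameters
    ----------
    temperature : float
        Folding temperature in degrees Celsius, within [0, 100].
    monovalent_salt : float
        Monovalent cation concentration (Na+ or K+) in mol/L.
    divalent_salt : float
        Divalent cation concentration (Mg2+) in mol/L; converted to an
        equivalent monovalent concentration for the salt correction.
    allow_g4 : bool
        Allow a G-quadruplex motif to substitute part of the structure.
    allow_lonely_pairs : bool
        Permit isolated base pairs (helices of length one).  Off by default;
        lonely pairs are disallowed throughout the analyses.
    min_hairpin_loop : int
        Minimum number of unpaired nucleotides closed by a hairpin.
    backend : str
        ``"builtin"`` for the table-driven engine, or ``"external-command"``
        to delegate to an external folding program (see :mod:`pausefold.fold`).
    """

    temperature: float = 37.0
    monovalent_salt: float = 1.0
    divalent_salt: float = 0.0
    allow_g4: bool = False
    allow_lonely_pairs: bool = False
    min_hairpin_loop: int = 3
    backend: str = "builtin"
    external_command: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.temperature <= 100.0):
            raise ValueError("temperature must be within [0, 100] degC")
        if self.monovalent_salt < 0 or self.divalent_salt < 0:
            raise ValueError("salt concentrations must be non-negative")
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")

    @property
    def kelvin(self) -> float:
        return self.temperature + 273.15

    @property
    def equivalent_monovalent(self) -> float:
        """Monovalent-equivalent cation concentration (mol/L).

        Mg2+ contributes as 3.795 * sqrt([Mg2+]), the standard
        120*sqrt(mM) equivalence expressed in molar units.
        """
        na = self.monovalent_salt + 3.795 * math.sqrt(self.divalent_salt)
        return max(na, 1e-4)


# Genome-wide scan conditions: 1.0 M Na+, no Mg2+, 37 C.
GENOME_PRESET = FoldParams()

# Nuclear-extract transcription conditions: 60 mM KCl, 7 mM MgCl2, 30 C.
INVITRO_PRESET = FoldParams(temperature=30.0, monovalent_salt=0.060,
                            divalent_salt=0.007)

# G-quadruplex scoring: a fixed stabilisation per G-tetrad beyond the first
# two, offset by a per-loop-nucleotide destabilisation.  Deliberately simple:
# only the direction and rough magnitude of the G4 contribution matter for
# the window-scan analyses.
G4_BONUS_PER_TETRAD = -6.0   # kcal/mol per tetrad above 2
G4_PENALTY_PER_LOOP_NT = 0.25  # kcal/mol per loop nucleotide

# multibranch loop: a + b * (branches + 1) + c * unpaired, at 37 C
MULTILOOP_CLOSE = 3.4
MULTILOOP_BRANCH = 0.4
MULTILOOP_UNPAIRED = 0.1

# internal-loop asymmetry penalty (per nt difference, capped)
ASYMMETRY_PER_NT = 0.5
ASYMMETRY_MAX = 3.0


def _read_table(path=None):
    if path is None:
        ref = resources.files("pausefold").joinpath("data/nn_params.tsv")
        lines = ref.read_text().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    stacks: dict[str, tuple[float, float]] = {}
    loops: dict[str, dict[int, float]] = {"hairpin": {}, "bulge": {}, "internal": {}}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("kind\t"):
            continue
        kind, key, dh, ds, dg37 = line.split("\t")
        if kind == "stack":
            stacks[key] = (float(dh), float(ds))
        else:
            loops[kind][int(key)] = float(dg37)
    return stacks, loops


def _complete_stacks(stacks: dict[str, tuple[float, float]]):
    """Fill all 16 duplex steps from the 10 unique ones by reverse-complement
    symmetry: 5'XY3' == 5'(comp Y)(comp X)3'."""
    full = dict(stacks)
    for x in BASES:
        for y in BASES:
            key = x + y
            if key not in full:
                rc = COMPLEMENT[y] + COMPLEMENT[x]
                full[key] = stacks[rc]
    return full


def _interp_loop_table(tab: dict[int, float], max_size: int, t_kelvin: float):
    """Dense per-size loop penalty (0.01 kcal/mol ints), linear interpolation
    between tabulated sizes, Jacobson-Stockmayer extrapolation beyond, and
    linear-in-T entropic scaling."""
    sizes = sorted(tab)
    lo, hi = sizes[0], sizes[-1]
    out = np.full(max_size + 1, INF, dtype=np.int32)
    scale = t_kelvin / T37_K
    xs = np.array(sizes, dtype=float)
    ys = np.array([tab[s] for s in sizes], dtype=float)
    for n in range(lo, max_size + 1):
        if n <= hi:
            dg37 = float(np.interp(n, xs, ys))
        else:
            dg37 = tab[hi] + 1.75 * R_GAS * T37_K * math.log(n / hi)
        out[n] = round(ENERGY_SCALE * dg37 * scale)
    return out


class EnergyModel:
    """Integer energy tables realised for a specific :class:`FoldParams`.

    Attributes are plain numpy arrays so they can be handed to the
    numba-compiled dynamic program unchanged.
    """

    def __init__(self, params: FoldParams, table_path=None, max_loop_size: int = 64):
        self.params = params
        stacks, loops = _read_table(table_path)
        stacks = _complete_stacks(stacks)
        t_k = params.kelvin
        salt_ds = 0.368 * math.log(params.equivalent_monovalent)
        self.stack = np.full((4, 4), INF, dtype=np.int32)
        for x in BASES:
            for y in BASES:
                dh, ds = stacks[x + y]
                dg = dh - t_k * (ds + salt_ds) / 1000.0
                self.stack[BASE_INDEX[x], BASE_INDEX[y]] = round(ENERGY_SCALE * dg)
        self._loops_raw = loops
        self.max_loop_size = max_loop_size
        self.hairpin = _interp_loop_table(loops["hairpin"], max_loop_size, t_k)
        self.bulge = _interp_loop_table(loops["bulge"], MAX_INTERIOR_LOOP, t_k)
        self.internal = _interp_loop_table(loops["internal"], MAX_INTERIOR_LOOP, t_k)
        scale = t_k / T37_K
        self.ml_close = round(ENERGY_SCALE * MULTILOOP_CLOSE * scale)
        self.ml_branch = round(ENERGY_SCALE * MULTILOOP_BRANCH * scale)
        self.ml_unpaired = round(ENERGY_SCALE * MULTILOOP_UNPAIRED * scale)
        self.asym = round(ENERGY_SCALE * ASYMMETRY_PER_NT * scale)
        self.asym_max = round(ENERGY_SCALE * ASYMMETRY_MAX * scale)

    def ensure_hairpin(self, max_size: int) -> None:
        if max_size > self.max_loop_size:
            self.max_loop_size = max_size
            self.hairpin = _interp_loop_table(
                self._loops_raw["hairpin"], max_size, self.params.kelvin)

    def stack_energy(self, x: str, y: str) -> int:
        """Integer stack energy for the duplex step 5'xy3' (top strand)."""
        return int(self.stack[BASE_INDEX[x], BASE_INDEX[y]])

    def hairpin_energy(self, size: int) -> int:
        self.ensure_hairpin(size)
        return int(self.hairpin[size])


_model_cache: dict[tuple, EnergyModel] = {}


def get_model(params: FoldParams, table_path=None) -> EnergyModel:
    key = (params.temperature, params.monovalent_salt, params.divalent_salt,
           params.min_hairpin_loop, table_path)
    if key not in _model_cache:
        _model_cache[key] = EnergyModel(params, table_path)
    return _model_cache[key]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 codes; raises on any other character."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        codes[arr == ord(b)] = i
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return codes


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]
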