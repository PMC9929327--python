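"""Monoisotopic mass arithmetic for intact proteoforms.

Top-down identification engines work in the deconvoluted neutral-mass domain:
an observed precursor mass is compared with the mass of a database sequence
segment plus an N-terminal form and up to two unknown mass shifts, and MS/MS
evidence is matched against prefix (b-type) and suffix (y-type) fragment
ladders.  This module provides that arithmetic from first principles: a
packaged monoisotopic element table, residue chain masses derived from
elemental composition, the four N-terminal forms considered during
identification (no modification, initiator-Met excision, and their acetylated
variants), and shifted fragment ladders.

All masses are neutral monoisotopic daltons; charge and isotope envelope
handling is out of scope because the input data are already deconvoluted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np

from .errors import FormulaError, LadderError, SequenceError

#: Monoisotopic masses of the elements occurring in proteins and the packaged
#: modification table (Da).  Values follow the CODATA/NIST recommended
#: monoisotopic atomic masses.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Se": 79.9165213,
    "Fe": 55.9349375,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(?:\((-?\d+)\)|(\d+))?")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula into a symbol -> count mapping.

    Two count syntaxes are accepted: bare non-negative integers (``C2H2O``)
    and parenthesised signed integers in the Unimod style (``H(-2) O(-1)``).
    Whitespace between tokens is ignored; counts of repeated symbols add up.
    """
    counts: dict[str, int] = {}
    pos = 0
    text = formula.replace(" ", "")
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None:
            raise FormulaError(f"invalid formula {formula!r} at offset {pos}")
        symbol = m.group(1)
        if symbol not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {symbol!r} in {formula!r}")
        n = int(m.group(2) or m.group(3) or 1)
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return {s: n for s, n in counts.items() if n != 0}


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula, in Da.

    Linear in composition; the empty formula has mass 0.  Signed counts are
    allowed (parenthesised), so net composition differences such as a water
    loss ``H(-2) O(-1)`` evaluate to negative masses.
    """
    return sum(ELEMENT_MASSES[s] * n for s, n in parse_formula(formula).items())


#: Elemental composition of the 20 canonical amino acid residues (chain
#: residues, i.e. the repeating unit inside a peptide bond).
RESIDUE_COMPOSITIONS: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

#: Monoisotopic residue (chain) masses computed from composition (Da).
RESIDUE_MASSES: dict[str, float] = {
    aa: monoisotopic_mass(f) for aa, f in RESIDUE_COMPOSITIONS.items()
}

WATER: float = monoisotopic_mass("H2O")
ACETYL_DELTA: float = monoisotopic_mass("C2H2O")
MET_RESIDUE_MASS: float = RESIDUE_MASSES["M"]

#: Allowed range for an unexpected mass shift (Da), matching the search window
#: used during identification.
MASS_SHIFT_WINDOW: tuple[float, float] = (-500.0, 500.0)


class NTerminalForm(Enum):
    """N-terminal forms considered during proteoform identification.

    The proteoform sequence is always the database segment; the form carries
    the mass delta applied on top of it.  ``NME`` (N-terminal methionine
    excision) therefore subtracts one Met residue mass even though the
    sequence string retains the initiator M.
    """

    NONE = "NONE"
    NME = "NME"
    NME_ACETYLATION = "NME_ACETYLATION"
    M_ACETYLATION = "M_ACETYLATION"

    @property
    def delta(self) -> float:
        """Mass delta (Da) applied to the database segment mass."""
        return _NTERM_DELTAS[self]

    @property
    def excises_met(self) -> bool:
        return self in (NTerminalForm.NME, NTerminalForm.NME_ACETYLATION)


_NTERM_DELTAS: dict[NTerminalForm, float] = {
    NTerminalForm.NONE: 0.0,
    NTerminalForm.NME: -MET_RESIDUE_MASS,
    NTerminalForm.NME_ACETYLATION: -MET_RESIDUE_MASS + ACETYL_DELTA,
    NTerminalForm.M_ACETYLATION: ACETYL_DELTA,
}


class Shift(NamedTuple):
    """An unexpected mass shift with its placement interval.

    ``start``/``end`` are 1-based inclusive residue positions within the
    matched segment (not the parent protein).
    """

    delta: float
    start: int
    end: int


@dataclass(frozen=True)
class ProteoformSpec:
    """A proteoform: database segment + N-terminal form + up to two shifts.

    Coordinates are 1-based inclusive throughout.  ``first_residue`` /
    ``last_residue`` place the segment in the parent protein; shift intervals
    are relative to the segment.  Flanking residues, when known from the
    search output, are carried for round-tripping but never contribute mass.
    """

    sequence: str
    nterm_form: NTerminalForm = NTerminalForm.NONE
    shifts: tuple[Shift, ...] = ()
    first_residue: int = 1
    last_residue: int | None = None
    flank_n: str = ""
    flank_c: str = ""

    def __post_init__(self):
        L = len(self.sequence)
        object.__setattr__(self, "shifts", tuple(Shift(*s) for s in self.shifts))
        if self.last_residue is None:
            object.__setattr__(self, "last_residue", self.first_residue + L - 1)
        if self.last_residue - self.first_residue + 1 != L:
            raise SequenceError(
                f"segment coordinates [{self.first_residue},{self.last_residue}] "
                f"inconsistent with sequence length {L}"
            )
        if len(self.shifts) > 2:
            raise ValueError(f"at most two mass shifts allowed, got {len(self.shifts)}")
        lo, hi = MASS_SHIFT_WINDOW
        for s in self.shifts:
            if not lo <= s.delta <= hi:
                raise ValueError(f"mass shift {s.delta} outside window [{lo}, {hi}]")
            if not 1 <= s.start <= s.end <= L:
                raise ValueError(f"shift interval [{s.start},{s.end}] outside [1,{L}]")
        ordered = sorted(self.shifts, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"shift intervals [{a.start},{a.end}] and [{b.start},{b.end}] overlap"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def total_shift(self) -> float:
        return sum(s.delta for s in self.shifts)

    def shifts_by_position(self) -> tuple[Shift, ...]:
        return tuple(sorted(self.shifts, key=lambda s: s.start))

    def to_parent_coordinates(self, position: int) -> int:
        """Convert a 1-based segment position to parent-protein numbering."""
        return self.first_residue + position - 1


def _residue_mass(aa: str) -> float:
    try:
        return RESIDUE_MASSES[aa]
    except KeyError:
        raise SequenceError(f"non-canonical residue {aa!r}") from None


def proteoform_neutral_mass(spec: ProteoformSpec) -> float:
    """Theoretical neutral monoisotopic mass of the proteoform (Da).

    Sum of residue chain masses, one water, the N-terminal form delta and all
    shift deltas.
    """
    if not spec.sequence:
        raise SequenceError("empty sequence")
    return (
        sum(_residue_mass(aa) for aa in spec.sequence)
        + WATER
        + spec.nterm_form.delta
        + spec.total_shift
    )


@dataclass(frozen=True)
class Ladders:
    """Neutral b/y fragment ladders of a proteoform.

    ``prefix[i-1]`` is the neutral b-type mass for cleavage site ``i`` (after
    residue ``i``); ``suffix[j-1]`` the neutral y-type mass of the last ``j``
    residues.  A shift whose placement interval straddles a cleavage site
    makes that side's value undefined for matching; the validity masks flag
    those sites False.
    """

    prefix: np.ndarray
    suffix: np.ndarray
    prefix_valid: np.ndarray
    suffix_valid: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.prefix)


def fragment_ladders(spec: ProteoformSpec) -> Ladders:
    """Prefix (b) and suffix (y) neutral ladders with shifts applied.

    Prefix values include the N-terminal form delta plus every shift whose
    interval lies entirely within the prefix; suffix values include one water
    plus shifts entirely within the suffix.
    """
    L = len(spec.sequence)
    if L < 2:
        raise LadderError(f"sequence of length {L} has no cleavage site")
    masses = np.array([_residue_mass(aa) for aa in spec.sequence])
    cum = np.cumsum(masses)
    prefix = cum[:-1] + spec.nterm_form.delta
    suffix = cum[-1] - cum[:-1] + WATER  # suffix at site i covers residues i+1..L
    prefix_valid = np.ones(L - 1, dtype=bool)
    suffix_valid = np.ones(L - 1, dtype=bool)
    sites = np.arange(1, L)
    for s in spec.shifts:
        in_prefix = s.end <= sites
        in_suffix = s.start >= sites + 1
        straddle = ~in_prefix & ~in_suffix
        prefix = prefix + np.where(in_prefix, s.delta, 0.0)
        suffix = suffix + np.where(in_suffix, s.delta, 0.0)
        prefix_valid &= ~straddle
        suffix_valid &= ~straddle
    # suffix array is indexed by suffix length j: suffix_by_length[j-1] covers
    # residues L-j+1..L, i.e. cleavage site i = L - j.
    suffix_by_length = suffix[::-1].copy()
    suffix_valid_by_length = suffix_valid[::-1].copy()
    return Ladders(prefix, suffix_by_length, prefix_valid, suffix_valid_by_length)


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1, -0.5 -> -1)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))
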