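"""Fragment-evidence localization of mass shifts.

A mass shift reported on a proteoform is initially placed on an interval of
residues; backbone fragments narrow it down.  A prefix (b-type) fragment that
matches the *unshifted* ladder proves the shift lies C-terminal of its
cleavage site, while one matching the *shifted* ladder proves the opposite;
suffix (y-type) fragments constrain symmetrically.  The minimal residue
interval consistent with every matched fragment is reported, and only
singleton intervals yield an unambiguous residue call — ambiguous placements
are never attributed to a residue.

Matching happens in the deconvoluted neutral-mass domain at a ppm tolerance
(default 15 ppm, a customary fragment tolerance for top-down engines; the
value is configurable).  An observation within tolerance of both a shifted
and an unshifted ladder value at indistinguishable error is uninformative and
is excluded rather than allowed to narrow an interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LocalizationError
from .masses import NTerminalForm, ProteoformSpec, fragment_ladders
from .prsm_io import PrSMRecord

DEFAULT_TOL_PPM = 15.0

#: |ppm| margin below which two candidate assignments are considered tied.
#: Assignments separated by less than this are far beyond any instrument's
#: mass accuracy (e.g. a dehydrated suffix ladder colliding with an unshifted
#: prefix ladder, 3e-7 Da apart), so the observation cannot arbitrate between
#: them and is treated as uninformative.
_TIE_EPS_PPM = 0.01


@dataclass(frozen=True)
class FragmentMatch:
    """One observation assigned to a ladder position.

    ``shift_subset`` lists the indices (into the position-sorted shift tuple)
    whose deltas the matched ladder value includes; ``shifted`` is its
    non-empty flag.  ``cleavage_index`` is the site i in 1..L-1: a prefix
    covers residues 1..i, a suffix covers i+1..L.
    """

    ion_kind: str  # "prefix" | "suffix"
    cleavage_index: int
    shift_subset: tuple[int, ...]
    ppm: float
    observed_mass: float

    @property
    def shifted(self) -> bool:
        return bool(self.shift_subset)


@dataclass(frozen=True)
class FragmentMatching:
    """Result of matching a spectrum's observations against one proteoform."""

    matches: tuple[FragmentMatch, ...]
    n_unmatched: int
    n_ambiguous: int

    @property
    def n_dropped(self) -> int:
        return self.n_unmatched + self.n_ambiguous


@dataclass(frozen=True)
class LocalizationResult:
    """Minimal residue interval for one shift (1-based inclusive)."""

    start: int
    end: int
    residue: str | None
    support: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"empty interval [{self.start},{self.end}]")

    @property
    def is_unambiguous(self) -> bool:
        return self.start == self.end


def _candidate_table(spec: ProteoformSpec):
    """Enumerate every matchable ladder value of a proteoform.

    For k position-sorted shifts the realizable inclusion subsets are the
    prefix-closed ones for b-ions and suffix-closed ones for y-ions (a prefix
    cannot contain the right-hand shift without the left-hand one).
    Returns parallel arrays (values sorted ascending, kind code, site,
    subset id) plus the subset lookup list.
    """
    shifts = spec.shifts_by_position()
    bare = ProteoformSpec(
        spec.sequence,
        nterm_form=spec.nterm_form,
        first_residue=spec.first_residue,
        last_residue=spec.last_residue,
    )
    ladders = fragment_ladders(bare)
    L = len(spec.sequence)
    k = len(shifts)
    prefix_subsets = [tuple(range(j)) for j in range(k + 1)]  # (), (0,), (0,1)
    suffix_subsets = [tuple(range(k - j, k)) for j in range(k + 1)]  # (), (1,), (0,1)
    subsets = list(dict.fromkeys(prefix_subsets + suffix_subsets))
    subset_id = {s: i for i, s in enumerate(subsets)}
    values, kinds, sites, sub_ids = [], [], [], []
    for s in prefix_subsets:
        extra = sum(shifts[i].delta for i in s)
        for site in range(1, L):
            v = ladders.prefix[site - 1] + extra
            if v > 0:
                values.append(v)
                kinds.append(0)
                sites.append(site)
                sub_ids.append(subset_id[s])
    for s in suffix_subsets:
        extra = sum(shifts[i].delta for i in s)
        for site in range(1, L):
            v = ladders.suffix[L - site - 1] + extra  # suffix length L - site
            if v > 0:
                values.append(v)
                kinds.append(1)
                sites.append(site)
                sub_ids.append(subset_id[s])
    order = np.argsort(values, kind="stable")
    return (
        np.asarray(values)[order],
        np.asarray(kinds)[order],
        np.asarray(sites)[order],
        np.asarray(sub_ids)[order],
        subsets,
    )


def match_fragments(
    spec: ProteoformSpec,
    observations: Sequence[float] | np.ndarray,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> FragmentMatching:
    """Assign each observed neutral mass to its nearest ladder value.

    One match per observation; observations outside ``tol_ppm`` of every
    ladder value are dropped and counted, and observations tied between two
    distinct assignments are marked uninformative (counted separately) so
    ambiguous evidence never narrows an interval.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    values, kinds, sites, sub_ids, subsets = _candidate_table(spec)
    rel = tol_ppm * 1e-6
    matches: list[FragmentMatch] = []
    n_unmatched = 0
    n_ambiguous = 0
    obs_arr = np.asarray(observations, dtype=float)
    lo_idx = np.searchsorted(values, obs_arr / (1.0 + rel), side="left")
    hi_idx = np.searchsorted(values, obs_arr / (1.0 - rel), side="right")
    for o, lo, hi in zip(obs_arr, lo_idx, hi_idx):
        if hi <= lo:
            n_unmatched += 1
            continue
        cand = slice(lo, hi)
        ppm = (o - values[cand]) / values[cand] * 1e6
        abs_ppm = np.abs(ppm)
        keep = abs_ppm <= tol_ppm
        if not keep.any():
            n_unmatched += 1
            continue
        abs_kept = np.where(keep, abs_ppm, np.inf)
        best = int(np.argmin(abs_kept))
        tied = np.flatnonzero(abs_kept <= abs_kept[best] + _TIE_EPS_PPM)
        if len(tied) > 1:
            n_ambiguous += 1
            continue
        idx = lo + best
        matches.append(
            FragmentMatch(
                ion_kind="prefix" if kinds[idx] == 0 else "suffix",
                cleavage_index=int(sites[idx]),
                shift_subset=subsets[sub_ids[idx]],
                ppm=float(ppm[best]),
                observed_mass=float(o),
            )
        )
    return FragmentMatching(tuple(matches), n_unmatched, n_ambiguous)


def localize_shift(
    spec: ProteoformSpec, matches: Iterable[FragmentMatch]
) -> LocalizationResult:
    """Minimal single-residue placement interval for a one-shift proteoform.

    Equivalent to testing every single-residue placement against all matches:
    the constraints are interval-shaped, so intersecting lower bounds (from
    unshifted prefixes / shifted suffixes) with upper bounds (shifted
    prefixes / unshifted suffixes) yields exactly the consistent placements.
    """
    if len(spec.shifts) != 1:
        raise ValueError("localize_shift requires exactly one shift")
    L = len(spec.sequence)
    lb, ub = 1, L
    lb_witness = ub_witness = None
    matches = tuple(matches)
    for m in matches:
        i = m.cleavage_index
        # lower bounds come from unshifted prefixes / shifted suffixes,
        # upper bounds from the complementary cases.
        if (m.ion_kind == "prefix" and not m.shifted) or (
            m.ion_kind == "suffix" and m.shifted
        ):
            if i + 1 > lb:
                lb, lb_witness = i + 1, m
        else:
            if i < ub:
                ub, ub_witness = i, m
    if lb > ub:
        raise LocalizationError(
            f"no placement consistent with matches (bounds [{lb},{ub}])",
            conflict=(lb_witness, ub_witness),
        )
    residue = spec.sequence[lb - 1] if lb == ub else None
    return LocalizationResult(lb, ub, residue, support=len(matches))


def localize_two_shifts(
    spec: ProteoformSpec,
    matches: Iterable[FragmentMatch],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> tuple[LocalizationResult, LocalizationResult]:
    """Placement intervals for a two-shift proteoform.

    Scans every ordered single-residue placement pair p1 <= p2 (shifts in
    position order along the sequence; two modifications may land on the same
    residue); a pair is consistent when every matched fragment lies within
    tolerance of the ladder value that pair implies at the fragment's site.
    The reported intervals are the projections of all consistent pairs.
    """
    shifts = spec.shifts_by_position()
    if len(shifts) != 2:
        raise ValueError("localize_two_shifts requires exactly two shifts")
    L = len(spec.sequence)
    d1, d2 = shifts[0].delta, shifts[1].delta
    bare = ProteoformSpec(spec.sequence, nterm_form=spec.nterm_form)
    ladders = fragment_ladders(bare)
    rel = tol_ppm * 1e-6
    positions = np.arange(1, L + 1)
    matches = tuple(matches)
    consistent = np.triu(np.ones((L, L), dtype=bool))  # p1 <= p2
    prev_ok: list[tuple[FragmentMatch, np.ndarray]] = []
    for m in matches:
        i = m.cleavage_index
        base = (
            ladders.prefix[i - 1]
            if m.ion_kind == "prefix"
            else ladders.suffix[L - i - 1]
        )
        # inclusion indicators: prefix contains shift at p iff p <= i,
        # suffix (covering i+1..L) iff p > i.
        if m.ion_kind == "prefix":
            a = positions <= i
        else:
            a = positions > i
        allowed = np.zeros((2, 2), dtype=bool)
        for ai in (0, 1):
            for bi in (0, 1):
                v = base + ai * d1 + bi * d2
                allowed[ai, bi] = v > 0 and abs(m.observed_mass - v) <= rel * v
        ok = allowed[np.ix_(a.astype(int), a.astype(int))]
        new = consistent & ok
        if not new.any():
            conflict = next(
                ((pm, m) for pm, pok in prev_ok if not (pok & ok & np.triu(np.ones((L, L), bool))).any()),
                (None, m),
            )
            raise LocalizationError(
                "no placement pair consistent with matches", conflict=conflict
            )
        consistent = new
        prev_ok.append((m, ok))
    p1s, p2s = np.nonzero(consistent)
    results = []
    for ps in (p1s, p2s):
        start, end = int(ps.min()) + 1, int(ps.max()) + 1
        residue = spec.sequence[start - 1] if start == end else None
        results.append(LocalizationResult(start, end, residue, support=len(matches)))
    return results[0], results[1]


def residue_call(
    result: LocalizationResult,
    sequence: str,
    nterm_form: NTerminalForm = NTerminalForm.NONE,
) -> str | None:
    """Residue letter for unambiguous localizations, else None.

    A shift localized to more than one residue is never attributed.  Under
    initiator-Met excision, residue 1 of the database segment is absent, so
    an interval touching only positions 1-2 resolves to the first retained
    residue.
    """
    start, end = result.start, result.end
    if nterm_form.excises_met and start == 1:
        start = 2
        end = max(end, 2)
    if start == end:
        return sequence[start - 1]
    return None


LOCALIZATION_COLUMNS = [
    "prsm_id",
    "shift_index",
    "start",
    "end",
    "residue",
    "support",
    "n_dropped_fragments",
    "note",
]


def localize_records(
    records: Iterable[PrSMRecord],
    fragments: Mapping[int, np.ndarray],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> tuple[dict[tuple[int, int], LocalizationResult], pd.DataFrame]:
    """Localize every shift of every modified PrSM.

    Returns a ``(prsm_id, shift_index) -> LocalizationResult`` mapping plus a
    tabular report.  PrSMs whose evidence is self-contradictory are reported
    with a note instead of an interval.
    """
    results: dict[tuple[int, int], LocalizationResult] = {}
    rows = []
    for rec in records:
        spec = rec.proteoform
        if not spec.shifts:
            continue
        obs = fragments.get(rec.prsm_id, np.empty(0))
        matching = match_fragments(spec, obs, tol_ppm)
        try:
            if len(spec.shifts) == 1:
                locs = [localize_shift(spec, matching.matches)]
            else:
                locs = list(localize_two_shifts(spec, matching.matches, tol_ppm))
        except LocalizationError as exc:
            for idx in range(len(spec.shifts)):
                rows.append(
                    {
                        "prsm_id": rec.prsm_id,
                        "shift_index": idx,
                        "start": pd.NA,
                        "end": pd.NA,
                        "residue": "",
                        "support": 0,
                        "n_dropped_fragments": matching.n_dropped,
                        "note": f"inconsistent: {exc}",
                    }
                )
            continue
        for idx, loc in enumerate(locs):
            results[(rec.prsm_id, idx)] = loc
            rows.append(
                {
                    "prsm_id": rec.prsm_id,
                    "shift_index": idx,
                    "start": loc.start,
                    "end": loc.end,
                    "residue": residue_call(loc, spec.sequence, spec.nterm_form) or "",
                    "support": loc.support,
                    "n_dropped_fragments": matching.n_dropped,
                    "note": "",
                }
            )
    return results, pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)
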