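"""Explaining observed mass shifts against a modification table.

An unexpected Δm on a proteoform can be explained three ways: a single
modification whose monoisotopic delta falls within a Da tolerance of the
observation (default 0.5 Da, the effective tolerance of nominal-mass
matching), an unordered pair of modifications whose deltas sum to it, or a
detergent adduct series — n dodecyl-sulfate (SDS) adducts, optionally
combined with loss of the initiator methionine, which produces the
characteristic +266 / +532 / +401 Da pattern on intact proteins.

The packaged table covers the community-database entries relevant to
bacterial top-down data plus common sample-handling artefacts; a full
database export in either the packaged TSV schema or unimod.xml can be
loaded instead.  Site compatibility (allowed residues/termini) is reported
as an advisory flag, never used to exclude candidates: open-search
annotations rank by mass agreement alone and must be treated with caution.
"""

from __future__ import annotations

import csv
import functools
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import TableFormatError
from .masses import (
    MASS_SHIFT_WINDOW,
    MET_RESIDUE_MASS,
    monoisotopic_mass,
    round_half_away,
)

#: Tolerance (Da) for Δm-to-modification matching; nominal-mass comparison
#: implies an effective window of about half a dalton.
DEFAULT_TOLERANCE_DA = 0.5


@dataclass(frozen=True)
class ModificationDef:
    """One modification-table entry.

    ``sites`` holds one-letter residue codes plus the tokens ``N-term``,
    ``C-term`` or ``*`` (anywhere).  ``category`` is ``PTM``, ``adduct`` or
    ``artefact``; adducts are excluded from pair search and handled by the
    dedicated series matcher.
    """

    name: str
    unimod_accession: int
    delta: float
    composition: str | None
    sites: frozenset[str]
    category: str = "PTM"

    def __post_init__(self):
        if self.composition:
            computed = monoisotopic_mass(self.composition)
            if abs(computed - self.delta) > 1e-5:
                raise ValueError(
                    f"{self.name}: delta {self.delta} differs from composition "
                    f"mass {computed:.6f} by more than 1e-5 Da"
                )

    def compatible_with(self, residues: str) -> bool:
        """Advisory site check against the residues of a placement region."""
        if "*" in self.sites or "N-term" in self.sites or "C-term" in self.sites:
            return True
        return any(aa in self.sites for aa in residues)


def load_modification_table(path: str | Path | None = None) -> list[ModificationDef]:
    """Load a modification table TSV (packaged table when ``path`` is None)."""
    if path is None:
        source = resources.files("topform").joinpath("data/modifications.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    required = {"accession", "name", "delta", "composition", "sites", "category"}
    missing = required - set(reader.fieldnames or [])
    if missing:
        raise TableFormatError(f"modification table missing column(s) {sorted(missing)}")
    table = []
    for row in reader:
        table.append(
            ModificationDef(
                name=row["name"],
                unimod_accession=int(row["accession"]),
                delta=float(row["delta"]),
                composition=row["composition"] or None,
                sites=frozenset(t for t in row["sites"].split(",") if t),
                category=row["category"],
            )
        )
    return table


def load_unimod_xml(path: str | Path) -> list[ModificationDef]:
    """Optional loader for a local unimod.xml export (full database import).

    Only the fields used by annotation are read: record id, title,
    monoisotopic delta and allowed sites.  Composition is not reconstructed
    from the XML (the delta is taken as authoritative).
    """
    ns = {"u": "http://www.unimod.org/xmlns/schema/unimod_2"}
    root = ET.parse(str(path)).getroot()
    table = []
    for mod in root.iterfind(".//u:modifications/u:mod", ns):
        delta_el = mod.find("u:delta", ns)
        if delta_el is None:
            continue
        sites = set()
        for spec in mod.iterfind("u:specificity", ns):
            site = spec.get("site", "")
            if site in ("N-term", "C-term"):
                sites.add(site)
            elif len(site) == 1 and site.isalpha():
                sites.add(site)
        table.append(
            ModificationDef(
                name=mod.get("title", ""),
                unimod_accession=int(mod.get("record_id", 0)),
                delta=float(delta_el.get("mono_mass", 0.0)),
                composition=None,
                sites=frozenset(sites),
            )
        )
    return table


@functools.lru_cache(maxsize=1)
def default_modifications() -> tuple[ModificationDef, ...]:
    return tuple(load_modification_table())


def sds_adduct() -> ModificationDef:
    """The packaged dodecyl-sulfate adduct entry (~266.155 Da)."""
    return next(m for m in default_modifications() if m.name == "SDS")


def nominal_bin(delta: float, window: tuple[float, float] | None = MASS_SHIFT_WINDOW) -> int:
    """Round a Δm half-away-from-zero to its nominal integer bin.

    Frequency analysis of mass shifts runs on these rounded values.  The
    default window rejects values outside the search range; pass
    ``window=None`` when binning net multi-shift sums (e.g. two adducts,
    +532 Da).
    """
    if window is not None and not window[0] <= delta <= window[1]:
        raise ValueError(f"delta {delta} outside window {window}")
    return round_half_away(delta)


@dataclass(frozen=True)
class ShiftAnnotation:
    """One candidate explanation of an observed Δm.

    ``kind`` is ``single``, ``pair`` or ``adduct_series``.  For series
    explanations ``members`` holds the adduct definition and ``n_adducts`` /
    ``met_loss`` describe the series term; ``mass_error`` is observed minus
    explained delta.  ``site_compatible`` is advisory (None when no sequence
    context was supplied).
    """

    delta_observed: float
    kind: str
    members: tuple[ModificationDef, ...]
    mass_error: float
    n_adducts: int | None = None
    met_loss: bool | None = None
    site_compatible: bool | None = None

    @property
    def delta_explained(self) -> float:
        return self.delta_observed - self.mass_error

    @property
    def nominal(self) -> int:
        return round_half_away(self.delta_observed)

    def describe(self) -> str:
        if self.kind == "adduct_series":
            tail = " - Met" if self.met_loss else ""
            return f"{self.n_adducts}x{self.members[0].name}{tail}"
        return " + ".join(m.name for m in self.members)


def _site_flag(members: Sequence[ModificationDef], residues: str | None) -> bool | None:
    if residues is None:
        return None
    return all(m.compatible_with(residues) for m in members)


def match_single(
    delta: float,
    table: Sequence[ModificationDef] | None = None,
    tolerance: float = DEFAULT_TOLERANCE_DA,
    residues: str | None = None,
) -> list[ShiftAnnotation]:
    """All single-modification explanations within ``tolerance`` Da.

    Ranked by ascending absolute mass error, ties broken by ascending
    accession.  An empty table yields an empty result.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    table = default_modifications() if table is None else table
    hits = [
        ShiftAnnotation(
            delta_observed=delta,
            kind="single",
            members=(m,),
            mass_error=delta - m.delta,
            site_compatible=_site_flag([m], residues),
        )
        for m in table
        if abs(delta - m.delta) <= tolerance
    ]
    hits.sort(key=lambda a: (abs(a.mass_error), a.members[0].unimod_accession))
    return hits


def match_pair(
    delta: float,
    table: Sequence[ModificationDef] | None = None,
    tolerance: float = DEFAULT_TOLERANCE_DA,
    residues: str | None = None,
) -> list[ShiftAnnotation]:
    """All unordered two-modification explanations within ``tolerance`` Da.

    Equivalent to the brute-force double loop over i <= j (a modification may
    pair with itself, e.g. two oxidations for +32 Da).  Adduct-category
    entries are excluded; adduct stoichiometry is the series matcher's job.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    table = default_modifications() if table is None else table
    entries = [m for m in table if m.category != "adduct"]
    hits = []
    for i, a in enumerate(entries):
        for b in entries[i:]:
            err = delta - (a.delta + b.delta)
            if abs(err) <= tolerance:
                pair = tuple(sorted((a, b), key=lambda m: m.unimod_accession))
                hits.append(
                    ShiftAnnotation(
                        delta_observed=delta,
                        kind="pair",
                        members=pair,
                        mass_error=err,
                        site_compatible=_site_flag(pair, residues),
                    )
                )
    hits.sort(
        key=lambda a: (
            abs(a.mass_error),
            a.members[0].unimod_accession,
            a.members[1].unimod_accession,
        )
    )
    return hits


def match_adduct_series(
    delta: float,
    adduct: ModificationDef | None = None,
    max_n: int = 3,
    allow_met_loss: bool = True,
    tolerance: float = DEFAULT_TOLERANCE_DA,
) -> list[ShiftAnnotation]:
    """Explain a Δm as n adducts, optionally minus the initiator methionine.

    Covers the detergent-artifact pattern on intact proteins: one adduct
    (+266 Da), two adducts (+532 Da), and two adducts plus Met loss
    (+401 Da).  Candidates are ranked by ascending absolute mass error.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    adduct = sds_adduct() if adduct is None else adduct
    if adduct.delta <= 0:
        raise ValueError("adduct delta must be positive")
    if max_n < 1:
        raise ValueError("max_n must be at least 1")
    hits = []
    for n in range(1, max_n + 1):
        for met_loss in (False, True) if allow_met_loss else (False,):
            expected = n * adduct.delta - (MET_RESIDUE_MASS if met_loss else 0.0)
            err = delta - expected
            if abs(err) <= tolerance:
                hits.append(
                    ShiftAnnotation(
                        delta_observed=delta,
                        kind="adduct_series",
                        members=(adduct,),
                        mass_error=err,
                        n_adducts=n,
                        met_loss=met_loss,
                    )
                )
    hits.sort(key=lambda a: abs(a.mass_error))
    return hits


def annotate_records(
    records: Iterable,
    table: Sequence[ModificationDef] | None = None,
    tolerance: float = DEFAULT_TOLERANCE_DA,
) -> pd.DataFrame:
    """Annotate every shift of every PrSM; one report row per shift instance.

    Columns: PrSM id, shift index, observed delta, nominal bin, best single /
    pair / adduct-series explanation with their mass errors, and the advisory
    site flag of the best single candidate.
    """
    table = default_modifications() if table is None else table
    rows = []
    for rec in records:
        for idx, shift in enumerate(rec.proteoform.shifts_by_position()):
            region = rec.proteoform.sequence[shift.start - 1 : shift.end]
            singles = match_single(shift.delta, table, tolerance, residues=region)
            pairs = match_pair(shift.delta, table, tolerance)
            series = match_adduct_series(shift.delta, tolerance=tolerance)
            best_single = singles[0] if singles else None
            best_pair = pairs[0] if pairs else None
            best_series = series[0] if series else None
            rows.append(
                {
                    "prsm_id": rec.prsm_id,
                    "shift_index": idx,
                    "delta_observed": shift.delta,
                    "nominal_bin": nominal_bin(shift.delta),
                    "single_best": best_single.describe() if best_single else "",
                    "single_error": best_single.mass_error if best_single else float("nan"),
                    "single_site_ok": best_single.site_compatible if best_single else None,
                    "pair_best": best_pair.describe() if best_pair else "",
                    "pair_error": best_pair.mass_error if best_pair else float("nan"),
                    "adduct_best": best_series.describe() if best_series else "",
                    "adduct_error": best_series.mass_error if best_series else float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "prsm_id",
            "shift_index",
            "delta_observed",
            "nominal_bin",
            "single_best",
            "single_error",
            "single_site_ok",
            "pair_best",
            "pair_error",
            "adduct_best",
            "adduct_error",
        ],
    )
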