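"""Reading and writing PrSM tables, fragment sidecars and FASTA proteomes.

The PrSM table is a fixed tab-separated dialect modelled on the text output
of top-down search engines: one row per proteoform-spectrum match, with the
proteoform written in bracketed notation (``M.AK(VD)[15.9949]LER.T``) where a
parenthesised residue range followed by a bracketed signed value marks an
unexpected mass shift and single residues around the ``.`` separators are
flanking database context.  Matched fragment neutral masses travel in a
sidecar TSV keyed by PrSM id, because engine text output does not carry them
uniformly.

Coordinates are 1-based inclusive throughout, matching the "First residue" /
"Last residue" convention of the consumed tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
from Bio import SeqIO

from .errors import ProteoformParseError, TableFormatError
from .masses import MASS_SHIFT_WINDOW, NTerminalForm, ProteoformSpec, Shift

DECOY_PREFIX = "DECOY_"

#: Mandatory columns of the PrSM table dialect, in canonical order.
PRSM_COLUMNS = [
    "Prsm ID",
    "Spectrum ID",
    "Protein accession",
    "First residue",
    "Last residue",
    "N-terminal form",
    "Proteoform",
    "Precursor mass",
    "#unexpected modifications",
    "E-value",
]

#: Header aliases seen in TopPIC-style exports, mapped onto the dialect above.
TOPPIC_COLUMN_ALIASES = {
    "Prsm ID": "Prsm ID",
    "PrSM ID": "Prsm ID",
    "Spectrum ID": "Spectrum ID",
    "Scan(s)": "Spectrum ID",
    "Protein accession": "Protein accession",
    "First residue": "First residue",
    "Last residue": "Last residue",
    "Proteoform": "Proteoform",
    "Precursor mass": "Precursor mass",
    "Adjusted precursor mass": "Precursor mass",
    "#unexpected modifications": "#unexpected modifications",
    "#Unexpected modifications": "#unexpected modifications",
    "E-value": "E-value",
}


@dataclass(frozen=True)
class PrSMRecord:
    """One proteoform-spectrum match."""

    prsm_id: int
    spectrum_id: str
    protein_accession: str
    first_residue: int
    last_residue: int
    proteoform: ProteoformSpec
    precursor_mass_observed: float
    n_shifts: int
    e_value: float
    is_decoy: bool = False

    def __post_init__(self):
        if self.n_shifts != len(self.proteoform.shifts):
            raise ValueError(
                f"PrSM {self.prsm_id}: #unexpected modifications {self.n_shifts} "
                f"!= {len(self.proteoform.shifts)} shifts in proteoform"
            )
        if self.last_residue - self.first_residue + 1 != len(self.proteoform.sequence):
            raise ValueError(
                f"PrSM {self.prsm_id}: residue span does not match sequence length"
            )
        if not self.e_value > 0:
            raise ValueError(f"PrSM {self.prsm_id}: E-value must be positive")

    @property
    def is_modified(self) -> bool:
        return self.n_shifts >= 1


class FragmentObservation(NamedTuple):
    """One observed fragment neutral mass attributed to a PrSM."""

    prsm_id: int
    neutral_mass: float


def parse_proteoform_string(text: str) -> ProteoformSpec:
    """Parse bracketed proteoform notation into a :class:`ProteoformSpec`.

    Grammar: optional single flanking residue and ``.`` on either side; the
    core is a residue string in which ``(SEG)[delta]`` attaches a signed mass
    shift to the residue interval covered by ``SEG``.  At most two shifts,
    each within the +-500 Da search window.  Unicode minus is accepted.
    """
    core, flank_n, flank_c = text, "", ""
    if len(core) >= 2 and core[1] == ".":
        flank_n, core = core[0], core[2:]
    if len(core) >= 2 and core[-2] == ".":
        flank_c, core = core[-1], core[:-2]
    seq: list[str] = []
    shifts: list[Shift] = []
    i = 0
    while i < len(core):
        c = core[i]
        if c == "(":
            close = core.find(")", i)
            if close < 0:
                raise ProteoformParseError("unbalanced '('", i)
            segment = core[i + 1 : close]
            if not segment.isalpha():
                raise ProteoformParseError(f"invalid interval segment {segment!r}", i + 1)
            start = len(seq) + 1
            seq.extend(segment.upper())
            end = len(seq)
            if close + 1 >= len(core) or core[close + 1] != "[":
                raise ProteoformParseError("expected '[shift]' after ')'", close + 1)
            bclose = core.find("]", close + 1)
            if bclose < 0:
                raise ProteoformParseError("unbalanced '['", close + 1)
            raw = core[close + 2 : bclose].replace("−", "-")
            try:
                delta = float(raw)
            except ValueError:
                raise ProteoformParseError(f"invalid shift value {raw!r}", close + 2) from None
            lo, hi = MASS_SHIFT_WINDOW
            if not lo <= delta <= hi:
                raise ProteoformParseError(
                    f"shift {delta} outside window [{lo}, {hi}]", close + 2
                )
            shifts.append(Shift(delta, start, end))
            if len(shifts) > 2:
                raise ProteoformParseError("more than two mass shifts", i)
            i = bclose + 1
        elif c.isalpha():
            seq.append(c.upper())
            i += 1
        else:
            raise ProteoformParseError(f"unexpected character {c!r}", i)
    if not seq:
        raise ProteoformParseError("empty sequence")
    return ProteoformSpec(
        "".join(seq), shifts=tuple(shifts), flank_n=flank_n, flank_c=flank_c
    )


def _format_float(x: float) -> str:
    return repr(float(x))


def proteoform_to_string(spec: ProteoformSpec) -> str:
    """Serialise a proteoform back to bracketed notation (writer half of the
    round trip)."""
    parts: list[str] = []
    pos = 1
    for s in spec.shifts_by_position():
        parts.append(spec.sequence[pos - 1 : s.start - 1])
        parts.append(f"({spec.sequence[s.start - 1 : s.end]})[{_format_float(s.delta)}]")
        pos = s.end + 1
    parts.append(spec.sequence[pos - 1 :])
    core = "".join(parts)
    if spec.flank_n:
        core = f"{spec.flank_n}.{core}"
    if spec.flank_c:
        core = f"{core}.{spec.flank_c}"
    return core


def _record_from_row(row: dict[str, str]) -> PrSMRecord:
    spec = parse_proteoform_string(row["Proteoform"])
    first = int(row["First residue"])
    last = int(row["Last residue"])
    spec = replace(
        spec,
        nterm_form=NTerminalForm(row["N-terminal form"]),
        first_residue=first,
        last_residue=last,
    )
    accession = row["Protein accession"]
    return PrSMRecord(
        prsm_id=int(row["Prsm ID"]),
        spectrum_id=row["Spectrum ID"],
        protein_accession=accession,
        first_residue=first,
        last_residue=last,
        proteoform=spec,
        precursor_mass_observed=float(row["Precursor mass"]),
        n_shifts=int(row["#unexpected modifications"]),
        e_value=float(row["E-value"]),
        is_decoy=accession.startswith(DECOY_PREFIX),
    )


def read_prsm_table(path: str | Path) -> list[PrSMRecord]:
    """Read a PrSM table; row order is preserved.

    Raises :class:`TableFormatError` naming the missing column, or carrying
    the 1-based line number of an unparseable row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in PRSM_COLUMNS if c not in header]
        if missing:
            raise TableFormatError(f"{path}: missing mandatory column(s) {missing}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_record_from_row(row))
            except (ValueError, KeyError) as exc:
                raise TableFormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_prsm_table(records: Iterable[PrSMRecord], path: str | Path) -> None:
    """Write records in the canonical dialect; bit-stable for identical input."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PRSM_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.prsm_id,
                    r.spectrum_id,
                    r.protein_accession,
                    r.first_residue,
                    r.last_residue,
                    r.proteoform.nterm_form.value,
                    proteoform_to_string(r.proteoform),
                    _format_float(r.precursor_mass_observed),
                    r.n_shifts,
                    _format_float(r.e_value),
                ]
            )


def read_toppic_table(path: str | Path) -> list[PrSMRecord]:
    """Import shim for TopPIC-style exports.

    Skips any leading parameter block, renames known header aliases onto the
    canonical dialect and defaults the N-terminal form column to NONE when
    absent.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    start = next((i for i, ln in enumerate(lines) if "Prsm ID" in ln or "PrSM ID" in ln), None)
    if start is None:
        raise TableFormatError(f"{path}: no header row containing 'Prsm ID'")
    header = lines[start].split("\t")
    renamed = [TOPPIC_COLUMN_ALIASES.get(h, h) for h in header]
    records = []
    for lineno, ln in enumerate(lines[start + 1 :], start=start + 2):
        if not ln.strip():
            continue
        row = dict(zip(renamed, ln.split("\t")))
        row.setdefault("N-terminal form", "NONE")
        row.setdefault("Spectrum ID", row.get("Prsm ID", ""))
        try:
            records.append(_record_from_row(row))
        except (ValueError, KeyError) as exc:
            raise TableFormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


FRAGMENT_COLUMNS = ["Prsm ID", "Neutral mass"]


def read_fragment_table(path: str | Path) -> list[FragmentObservation]:
    """Read the fragment sidecar (PrSM id, neutral mass)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in FRAGMENT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise TableFormatError(f"{path}: missing mandatory column(s) {missing}")
        out = []
        for lineno, row in enumerate(reader, start=2):
            try:
                mass = float(row["Neutral mass"])
                if mass <= 0:
                    raise ValueError(f"non-positive neutral mass {mass}")
                out.append(FragmentObservation(int(row["Prsm ID"]), mass))
            except ValueError as exc:
                raise TableFormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_fragment_table(observations: Iterable[FragmentObservation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FRAGMENT_COLUMNS)
        for obs in observations:
            writer.writerow([obs.prsm_id, _format_float(obs.neutral_mass)])


def fragments_by_prsm(observations: Iterable[FragmentObservation]) -> dict[int, np.ndarray]:
    """Group sidecar observations into per-PrSM mass arrays."""
    grouped: dict[int, list[float]] = {}
    for obs in observations:
        grouped.setdefault(obs.prsm_id, []).append(obs.neutral_mass)
    return {k: np.asarray(v) for k, v in grouped.items()}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA proteome into an accession -> sequence mapping.

    The accession is the first whitespace-delimited token of the header;
    sequences are upper-cased.  Duplicate accessions and empty sequences are
    rejected.
    """
    mapping: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in mapping:
            raise TableFormatError(f"{path}: duplicate accession {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise TableFormatError(f"{path}: empty sequence for {rec.id!r}")
        mapping[rec.id] = seq
    return mapping


def write_fasta(mapping: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write an accession -> sequence mapping as FASTA (fixed line width)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for accession, seq in mapping.items():
            fh.write(f">{accession}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
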