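"""Dataset-level summaries of a filtered PrSM population.

Covers the standard descriptive layer of a top-down mass-shift study: the
nominal Δm histogram over the search window (bin width 1 Da, limits
±500 Da), the top-k most frequent shifts, the per-residue ratio statistic
(what fraction of the PrSMs carrying a given nominal shift localize
unambiguously to each residue), modified fractions at PrSM and protein
level, and distinct-proteoform counts per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import nominal_bin
from .localize import LocalizationResult, residue_call
from .masses import MASS_SHIFT_WINDOW, round_half_away
from .prsm_io import PrSMRecord


@dataclass
class ShiftHistogram:
    """Counts of shift instances per nominal bin.

    PrSMs with two shifts contribute two instances.  ``n_out_of_range``
    counts instances outside the window (zero for tables produced by this
    package, whose parser enforces the window).
    """

    bin_width: float = 1.0
    window: tuple[float, float] = MASS_SHIFT_WINDOW
    counts: dict[int, int] = field(default_factory=dict)
    n_out_of_range: int = 0

    @property
    def n_instances(self) -> int:
        return sum(self.counts.values()) + self.n_out_of_range

    def top_k(self, k: int = 10) -> list[tuple[int, int]]:
        """The k most frequent bins; count ties break toward smaller |Δm|."""
        ranked = sorted(self.counts.items(), key=lambda kv: (-kv[1], abs(kv[0]), kv[0]))
        return ranked[:k]


def shift_histogram(
    records: Iterable[PrSMRecord],
    bin_width: float = 1.0,
    window: tuple[float, float] = MASS_SHIFT_WINDOW,
) -> ShiftHistogram:
    """Histogram of every shift instance, binned on rounded values."""
    hist = ShiftHistogram(bin_width=bin_width, window=window)
    for rec in records:
        for shift in rec.proteoform.shifts:
            if not window[0] <= shift.delta <= window[1]:
                hist.n_out_of_range += 1
                continue
            b = round_half_away(shift.delta / bin_width)
            hist.counts[b] = hist.counts.get(b, 0) + 1
    return hist


RESIDUE_RATIO_COLUMNS = ["bin", "residue", "n_unambiguous", "n_prsms_in_bin", "ratio"]


def residue_ratio(
    records: Iterable[PrSMRecord],
    localizations: Mapping[tuple[int, int], LocalizationResult],
) -> pd.DataFrame:
    """Per (nominal bin, residue) unambiguous-localization ratios.

    The denominator of a bin is the number of PrSMs carrying at least one
    shift in that bin; the numerator counts PrSMs whose shift localizes to a
    single residue.  Shifts without a single-residue call are excluded from
    numerators, and a two-shift PrSM contributes only when *each* of its
    shifts independently resolves to a single residue.  Bins with no
    unambiguous call are kept with an empty residue and ratio 0 so that
    denominators remain visible.
    """
    denominators: dict[int, set[int]] = {}
    numerators: dict[tuple[int, str], set[int]] = {}
    for rec in records:
        shifts = rec.proteoform.shifts_by_position()
        if not shifts:
            continue
        locs = [localizations.get((rec.prsm_id, i)) for i in range(len(shifts))]
        calls = [
            residue_call(loc, rec.proteoform.sequence, rec.proteoform.nterm_form)
            if loc is not None
            else None
            for loc in locs
        ]
        all_resolved = all(c is not None for c in calls)
        for shift, call in zip(shifts, calls):
            b = nominal_bin(shift.delta)
            denominators.setdefault(b, set()).add(rec.prsm_id)
            if all_resolved:
                numerators.setdefault((b, call), set()).add(rec.prsm_id)
    rows = []
    for b in sorted(denominators):
        denom = len(denominators[b])
        bin_rows = [
            (b, res, len(ids), denom, len(ids) / denom)
            for (bb, res), ids in sorted(numerators.items())
            if bb == b
        ]
        if not bin_rows:
            bin_rows = [(b, "", 0, denom, 0.0)]
        rows.extend(bin_rows)
    return pd.DataFrame(rows, columns=RESIDUE_RATIO_COLUMNS)


class ModifiedFraction:
    """Counts and display percentage of shift-carrying items."""

    def __init__(self, n_modified: int, n_total: int):
        self.n_modified = n_modified
        self.n_total = n_total

    @property
    def fraction(self) -> float | None:
        return self.n_modified / self.n_total if self.n_total else None

    @property
    def percent(self) -> int | None:
        """Nearest-integer percentage, as printed in study reports."""
        return round_half_away(100.0 * self.fraction) if self.n_total else None

    def __iter__(self):
        return iter((self.n_modified, self.n_total, self.percent))

    def __repr__(self):
        return f"ModifiedFraction({self.n_modified}/{self.n_total} = {self.percent}%)"


def modified_fraction(records: Sequence[PrSMRecord]) -> ModifiedFraction:
    """Fraction of PrSMs carrying at least one mass shift."""
    n_mod = sum(1 for r in records if r.is_modified)
    return ModifiedFraction(n_mod, len(records))


def protein_modified_fraction(records: Sequence[PrSMRecord]) -> ModifiedFraction:
    """Fraction of proteins with at least one shift-carrying PrSM."""
    proteins = {r.protein_accession for r in records}
    shifted = {r.protein_accession for r in records if r.is_modified}
    return ModifiedFraction(len(shifted), len(proteins))


def proteoform_key(record: PrSMRecord, use_nominal: bool = True) -> tuple:
    """Identity of a proteoform for counting purposes.

    Two PrSMs are the same proteoform when they share accession, segment
    coordinates, N-terminal form and the multiset of shift classes (nominal
    bins by default; exact deltas when ``use_nominal`` is False).
    """
    shifts = record.proteoform.shifts
    classes = tuple(
        sorted(nominal_bin(s.delta) if use_nominal else s.delta for s in shifts)
    )
    return (
        record.protein_accession,
        record.first_residue,
        record.last_residue,
        record.proteoform.nterm_form.value,
        classes,
    )


def proteoforms_per_protein(
    records: Iterable[PrSMRecord],
    thresholds: tuple[int, ...] = (15, 9),
    use_nominal: bool = True,
) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """Distinct-proteoform counts per accession plus above-threshold flags.

    Returns the per-protein table (descending count) and, for each threshold
    t, the accessions with strictly more than t proteoforms.
    """
    seen: dict[str, set[tuple]] = {}
    for rec in records:
        seen.setdefault(rec.protein_accession, set()).add(
            proteoform_key(rec, use_nominal)
        )
    table = pd.DataFrame(
        sorted(
            ((acc, len(keys)) for acc, keys in seen.items()),
            key=lambda t: (-t[1], t[0]),
        ),
        columns=["accession", "n_proteoforms"],
    )
    flagged = {
        t: table.loc[table["n_proteoforms"] > t, "accession"].tolist()
        for t in thresholds
    }
    return table, flagged


def summarize(
    records: Sequence[PrSMRecord],
    localizations: Mapping[tuple[int, int], LocalizationResult] | None = None,
    top_k: int = 10,
) -> dict:
    """Assemble the dataset-level summary as a plain dict (JSON-friendly).

    Without localizations the residue-ratio table is omitted (degraded
    mode); everything else is computed from the PrSM table alone.
    """
    hist = shift_histogram(records)
    mf = modified_fraction(records)
    pf = protein_modified_fraction(records)
    table, flagged = proteoforms_per_protein(records)
    out = {
        "n_prsms": len(records),
        "n_proteins": pf.n_total,
        "n_proteoforms": int(table["n_proteoforms"].sum()) if len(table) else 0,
        "modified_prsms": {
            "n_modified": mf.n_modified,
            "n_total": mf.n_total,
            "percent": mf.percent,
        },
        "modified_proteins": {
            "n_modified": pf.n_modified,
            "n_total": pf.n_total,
            "percent": pf.percent,
        },
        "histogram_top": hist.top_k(top_k),
        "n_shift_instances": hist.n_instances,
        "proteins_above_threshold": {
            str(t): accs for t, accs in flagged.items()
        },
    }
    if localizations is not None:
        ratio = residue_ratio(records, localizations)
        out["residue_ratio"] = ratio.to_dict(orient="records")
    return out


def plot_shift_histogram(hist: ShiftHistogram, path, top_k: int = 10) -> None:
    """Histogram of shift instances vs nominal Δm with the top bins marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    bins = sorted(hist.counts)
    ax.bar(bins, [hist.counts[b] for b in bins], width=hist.bin_width, color="0.6")
    for b, c in hist.top_k(top_k):
        ax.bar([b], [c], width=hist.bin_width, color="tab:red")
        ax.annotate(str(b), (b, c), fontsize=7, ha="center", va="bottom")
    ax.set_xlim(hist.window)
    ax.set_xlabel("mass shift (Da)")
    ax.set_ylabel("PrSM count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_residue_ratio(ratio: pd.DataFrame, path) -> None:
    """Grouped bars of unambiguous-residue ratios per nominal bin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = ratio[ratio["residue"] != ""]
    fig, ax = plt.subplots(figsize=(8, 4))
    residues = sorted(data["residue"].unique())
    bins = sorted(data["bin"].unique())
    width = 0.8 / max(1, len(bins))
    for k, b in enumerate(bins):
        sub = data[data["bin"] == b].set_index("residue")["ratio"]
        xs = [i + k * width for i in range(len(residues))]
        ax.bar(xs, [sub.get(r, 0.0) for r in residues], width=width, label=f"{b} Da")
    ax.set_xticks([i + 0.4 for i in range(len(residues))])
    ax.set_xticklabels(residues)
    ax.set_ylabel("unambiguous PrSM ratio")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
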