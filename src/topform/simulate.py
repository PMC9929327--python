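"""Synthetic proteomes and PrSM populations with planted ground truth.

The generator emulates the statistical structure of a bacterial top-down
dataset as the downstream analysis assumes it: a proteome of random
Met-initiated sequences; a PrSM population in which a configurable fraction
carries mass shifts (default 47%); a shift-class spectrum whose defaults
mirror a measured global modification profile (16 Da oxidation at 10.15% of
modified PrSMs, 15 Da at 6.11%, −18 Da dehydration at 2.97%, 32 Da double
oxidation at 1.32%) on top of a set of background classes and a continuous
uniform remainder emulating the long tail of rare shifts; a small two-shift
fraction; an N-terminal form mixture; b/y fragment observations with
per-site coverage and Gaussian ppm noise; and decoy plus false-target
matches with a null score model for FDR exercises.

Every emitted PrSM is covered by a truth ledger (planted deltas, sites,
N-terminal form, false-match flag), enabling parameter-recovery tests.
Output is fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import ConfigError, FixtureError
from .fdr import generate_decoy
from .masses import NTerminalForm, ProteoformSpec, Shift, fragment_ladders, proteoform_neutral_mass
from .prsm_io import FragmentObservation, PrSMRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ShiftClass(NamedTuple):
    """One planted shift class: exact delta, probability among modified
    PrSMs, and the residue letters it may land on (None = any residue)."""

    delta: float
    probability: float
    sites: str | None = None


def default_shift_spectrum() -> dict[int, ShiftClass]:
    """Default nominal-class spectrum.

    The four headline classes carry their measured shares of modified PrSMs;
    the remaining named classes are common PTM/artefact masses at plausible
    minor shares.  Probabilities sum to < 1; the remainder is drawn from a
    continuous uniform background over the search window (see
    :func:`simulate_prsms`).
    """
    return {
        16: ShiftClass(15.994915, 0.1015, "MWHCFY"),
        15: ShiftClass(14.999666, 0.0611, "NQ"),
        -18: ShiftClass(-18.010565, 0.0297, "STYD"),
        32: ShiftClass(31.989829, 0.0132, "MWC"),
        42: ShiftClass(42.010565, 0.07, "K"),
        28: ShiftClass(27.994915, 0.06, "KST"),
        14: ShiftClass(14.015650, 0.04, "KRQ"),
        -2: ShiftClass(-2.015650, 0.03, "C"),
        80: ShiftClass(79.966331, 0.02, "STY"),
        266: ShiftClass(266.155180, 0.04, None),
    }


def default_nterm_mixture() -> dict[str, float]:
    return {"NONE": 0.70, "NME": 0.15, "NME_ACETYLATION": 0.10, "M_ACETYLATION": 0.05}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults are the emulated study
    conditions, not tuning dials."""

    n_proteins: int = 50
    length_range: tuple[int, int] = (50, 200)
    n_prsms: int = 1000
    fraction_modified: float = 0.47
    fraction_two_shift: float = 8 / 2423  # two-shift share among modified PrSMs
    shift_spectrum: dict[int, ShiftClass] = field(default_factory=default_shift_spectrum)
    nterm_mixture: dict[str, float] = field(default_factory=default_nterm_mixture)
    truncation_fraction: float = 0.10
    fragment_coverage: float = 0.80
    fragment_noise_ppm_sd: float = 2.0
    fraction_false: float = 0.02  # false target matches (null score model)
    fraction_decoy: float = 0.02  # decoy matches appended to the table
    true_score_range: tuple[float, float] = (4.0, 16.0)  # -log10 E-value
    null_score_range: tuple[float, float] = (0.0, 4.0)
    exact_fractions: bool = False  # deterministic counts instead of Bernoulli
    seed: int = 0

    def validate(self) -> None:
        if self.length_range[0] < 5 or self.length_range[0] > self.length_range[1]:
            raise ConfigError(f"degenerate length range {self.length_range}")
        for name in (
            "fraction_modified",
            "fraction_two_shift",
            "truncation_fraction",
            "fragment_coverage",
            "fraction_false",
            "fraction_decoy",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        total = sum(c.probability for c in self.shift_spectrum.values())
        if total > 1.0 + 1e-9:
            raise ConfigError(f"shift-spectrum probabilities sum to {total} > 1")
        if self.fragment_noise_ppm_sd < 0:
            raise ConfigError("fragment noise sd must be non-negative")
        mix = sum(self.nterm_mixture.values())
        if abs(mix - 1.0) > 1e-9:
            raise ConfigError(f"N-terminal mixture sums to {mix}, expected 1")


class TruthRecord(NamedTuple):
    """Planted ground truth for one emitted PrSM."""

    prsm_id: int
    deltas: tuple[float, ...]
    sites: tuple[int, ...]  # 1-based positions within the matched segment
    nterm_kind: str
    is_false: bool


class Dataset(NamedTuple):
    proteome: dict[str, str]
    records: list[PrSMRecord]
    fragments: list[FragmentObservation]
    truth: list[TruthRecord]


def simulate_proteome(config: SimulationConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random proteome: Met-initiated sequences, residues otherwise uniform
    over the 20 canonical letters; reproducible under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    proteome = {}
    letters = np.array(list(AMINO_ACIDS))
    for i in range(config.n_proteins):
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        body = "".join(rng.choice(letters, size=L - 1))
        proteome[f"SYN_{i:04d}"] = "M" + body
    return proteome


def _draw_flags(rng, n: int, fraction: float, exact: bool) -> np.ndarray:
    if exact:
        k = int(round(fraction * n))
        flags = np.zeros(n, dtype=bool)
        flags[:k] = True
        rng.shuffle(flags)
        return flags
    return rng.random(n) < fraction


def _pick_site(rng, sequence: str, sites: str | None, forbidden: set[int], min_pos: int) -> int | None:
    candidates = [
        p
        for p in range(min_pos, len(sequence) + 1)
        if p not in forbidden and (sites is None or sequence[p - 1] in sites)
    ]
    if not candidates:
        candidates = [p for p in range(min_pos, len(sequence) + 1) if p not in forbidden]
    if not candidates:
        return None
    return int(candidates[rng.integers(0, len(candidates))])


def _draw_shift_class(rng, spectrum: dict[int, ShiftClass]) -> ShiftClass:
    classes = list(spectrum.values())
    probs = np.array([c.probability for c in classes])
    background = 1.0 - probs.sum()
    r = rng.random()
    acc = 0.0
    for c, p in zip(classes, probs):
        acc += p
        if r < acc:
            return c
    # continuous background: uniform magnitude in [1, 499.5], random sign,
    # emulating the long tail of rare/unexplained shifts
    assert background > -1e-12
    delta = float(rng.uniform(1.0, 499.5)) * (1 if rng.random() < 0.5 else -1)
    return ShiftClass(delta, 0.0, None)


def simulate_prsms(
    config: SimulationConfig,
    proteome: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> Dataset:
    """Generate a PrSM table, fragment sidecar and truth ledger.

    Shift classes are drawn per the configured spectrum; sites uniformly over
    residues compatible with the class; fragments for each cleavage site and
    ion kind independently with the configured coverage and Gaussian ppm
    noise.  False targets and decoy matches receive null-model scores and no
    fragment evidence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if proteome is None:
        proteome = simulate_proteome(config, rng)
    if not proteome:
        raise ConfigError("proteome is empty")
    decoys = generate_decoy(proteome)
    accs = sorted(proteome)
    decoy_accs = sorted(decoys)
    n = config.n_prsms
    modified_flags = _draw_flags(rng, n, config.fraction_modified, config.exact_fractions)
    false_flags = _draw_flags(rng, n, config.fraction_false, config.exact_fractions)
    n_modified = int(modified_flags.sum())
    if config.exact_fractions:
        two_flags_mod = np.zeros(n_modified, dtype=bool)
        two_flags_mod[: int(round(config.fraction_two_shift * n_modified))] = True
        rng.shuffle(two_flags_mod)
    else:
        two_flags_mod = rng.random(n_modified) < config.fraction_two_shift
    nterm_kinds = list(config.nterm_mixture)
    nterm_probs = np.array([config.nterm_mixture[k] for k in nterm_kinds])

    records: list[PrSMRecord] = []
    fragments: list[FragmentObservation] = []
    truth: list[TruthRecord] = []
    mod_idx = 0
    for prsm_id in range(1, n + 1):
        is_false = bool(false_flags[prsm_id - 1])
        accession = accs[rng.integers(0, len(accs))]
        protein = proteome[accession]
        L = len(protein)
        if rng.random() < config.truncation_fraction and L > 15:
            first = int(rng.integers(2, L // 3 + 1))
        else:
            first = 1
        segment = protein[first - 1 :]
        last = L
        if first == 1 and segment.startswith("M"):
            kind = nterm_kinds[rng.choice(len(nterm_kinds), p=nterm_probs)]
        else:
            kind = "NONE"
        form = NTerminalForm(kind)
        min_pos = 2 if form.excises_met else 1
        shifts: list[Shift] = []
        deltas: list[float] = []
        sites: list[int] = []
        if modified_flags[prsm_id - 1]:
            k = 2 if two_flags_mod[mod_idx] else 1
            mod_idx += 1
            taken: set[int] = set()
            for _ in range(k):
                cls = _draw_shift_class(rng, config.shift_spectrum)
                pos = _pick_site(rng, segment, cls.sites, taken, min_pos)
                if pos is None:
                    continue
                taken.add(pos)
                shifts.append(Shift(cls.delta, pos, pos))
                deltas.append(cls.delta)
                sites.append(pos)
            order = np.argsort([s.start for s in shifts])
            shifts = [shifts[i] for i in order]
            deltas = [deltas[i] for i in order]
            sites = [sites[i] for i in order]
        spec = ProteoformSpec(
            segment,
            nterm_form=form,
            shifts=tuple(shifts),
            first_residue=first,
            last_residue=last,
        )
        if is_false:
            score = rng.uniform(*config.null_score_range)
        else:
            score = rng.uniform(*config.true_score_range)
        records.append(
            PrSMRecord(
                prsm_id=prsm_id,
                spectrum_id=f"scan_{prsm_id}",
                protein_accession=accession,
                first_residue=first,
                last_residue=last,
                proteoform=spec,
                precursor_mass_observed=proteoform_neutral_mass(spec),
                n_shifts=len(shifts),
                e_value=10.0 ** (-score),
                is_decoy=False,
            )
        )
        truth.append(TruthRecord(prsm_id, tuple(deltas), tuple(sites), kind, is_false))
        if not is_false and config.fragment_coverage > 0 and len(segment) >= 2:
            ladders = fragment_ladders(spec)
            for arr, valid in ((ladders.prefix, ladders.prefix_valid), (ladders.suffix, ladders.suffix_valid)):
                emit = rng.random(len(arr)) < config.fragment_coverage
                noise = (
                    rng.normal(0.0, config.fragment_noise_ppm_sd, size=len(arr))
                    if config.fragment_noise_ppm_sd > 0
                    else np.zeros(len(arr))
                )
                for v, ok, e, keep in zip(arr, valid, noise, emit):
                    if keep and ok and v > 0:
                        fragments.append(
                            FragmentObservation(prsm_id, float(v * (1.0 + e * 1e-6)))
                        )

    n_decoy = int(round(config.fraction_decoy * n))
    for j in range(n_decoy):
        prsm_id = n + j + 1
        accession = decoy_accs[rng.integers(0, len(decoy_accs))]
        segment = decoys[accession]
        spec = ProteoformSpec(segment)
        score = rng.uniform(*config.null_score_range)
        records.append(
            PrSMRecord(
                prsm_id=prsm_id,
                spectrum_id=f"scan_{prsm_id}",
                protein_accession=accession,
                first_residue=1,
                last_residue=len(segment),
                proteoform=spec,
                precursor_mass_observed=proteoform_neutral_mass(spec),
                n_shifts=0,
                e_value=10.0 ** (-score),
                is_decoy=True,
            )
        )
        truth.append(TruthRecord(prsm_id, (), (), "NONE", True))
    return Dataset(proteome, records, fragments, truth)


TRUTH_COLUMNS = ["prsm_id", "deltas", "sites", "nterm_form", "is_false"]


def write_truth(truth: list[TruthRecord], path) -> None:
    """Truth ledger as TSV (deltas/sites are ;-joined)."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for t in truth:
            w.writerow(
                [
                    t.prsm_id,
                    ";".join(repr(d) for d in t.deltas),
                    ";".join(str(s) for s in t.sites),
                    t.nterm_kind,
                    int(t.is_false),
                ]
            )


def read_truth(path) -> list[TruthRecord]:
    import csv
    from pathlib import Path

    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            deltas = tuple(float(x) for x in row["deltas"].split(";") if x)
            sites = tuple(int(x) for x in row["sites"].split(";") if x)
            out.append(
                TruthRecord(
                    int(row["prsm_id"]), deltas, sites, row["nterm_form"], bool(int(row["is_false"]))
                )
            )
    return out


# --- packaged fixtures -------------------------------------------------------

_SDS_DELTA = 266.155180


def _fixture_mini47() -> Dataset:
    """100 PrSMs, exactly 47 modified, clean fragment evidence."""
    cfg = SimulationConfig(
        n_proteins=10,
        length_range=(40, 80),
        n_prsms=100,
        exact_fractions=True,
        fraction_false=0.0,
        fraction_decoy=0.0,
        fragment_coverage=1.0,
        fragment_noise_ppm_sd=0.0,
        seed=47,
    )
    return simulate_prsms(cfg)


def _fixture_two_shift() -> Dataset:
    """24 modified PrSMs, half carrying two concomitant shifts."""
    cfg = SimulationConfig(
        n_proteins=6,
        length_range=(40, 60),
        n_prsms=24,
        fraction_modified=1.0,
        fraction_two_shift=0.5,
        exact_fractions=True,
        fraction_false=0.0,
        fraction_decoy=0.0,
        fragment_coverage=1.0,
        fragment_noise_ppm_sd=0.0,
        seed=208,
    )
    return simulate_prsms(cfg)


def _fixture_adduct_series() -> Dataset:
    """One protein seen as +266.155, +532.310 (two adducts, two shifts) and
    +401.270 (two adducts minus initiator Met) proteoforms."""
    cfg = SimulationConfig(
        n_proteins=1,
        length_range=(60, 60),
        n_prsms=1,
        fraction_modified=0.0,
        fraction_false=0.0,
        fraction_decoy=0.0,
        fragment_coverage=0.0,
        seed=266,
    )
    rng = np.random.default_rng(cfg.seed)
    proteome = simulate_proteome(cfg, rng)
    accession, sequence = next(iter(proteome.items()))
    L = len(sequence)
    met_loss_net = 2 * _SDS_DELTA - 131.040485  # within the single-shift window
    variants: list[tuple[tuple[Shift, ...], NTerminalForm]] = [
        ((), NTerminalForm.NONE),
        ((Shift(_SDS_DELTA, 5, 5),), NTerminalForm.NONE),
        ((Shift(_SDS_DELTA, 5, 5), Shift(_SDS_DELTA, 20, 20)), NTerminalForm.NONE),
        ((Shift(round(met_loss_net, 6), 5, 5),), NTerminalForm.NONE),
    ]
    records, truth = [], []
    for i, (shifts, form) in enumerate(variants, start=1):
        spec = ProteoformSpec(sequence, nterm_form=form, shifts=shifts)
        records.append(
            PrSMRecord(
                prsm_id=i,
                spectrum_id=f"scan_{i}",
                protein_accession=accession,
                first_residue=1,
                last_residue=L,
                proteoform=spec,
                precursor_mass_observed=proteoform_neutral_mass(spec),
                n_shifts=len(shifts),
                e_value=1e-10,
            )
        )
        truth.append(
            TruthRecord(
                i,
                tuple(s.delta for s in shifts),
                tuple(s.start for s in shifts),
                form.value,
                False,
            )
        )
    return Dataset(proteome, records, [], truth)


FIXTURES = {
    "mini47": _fixture_mini47,
    "two_shift": _fixture_two_shift,
    "adduct_series": _fixture_adduct_series,
}


def make_fixture(name: str) -> Dataset:
    """Deterministic tiny datasets for tests and documentation."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise FixtureError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder()
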