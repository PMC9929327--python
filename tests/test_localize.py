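"""Fragment matching and shift localization against brute-force oracles."""

import numpy as np
import pytest

from topform.errors import LocalizationError
from topform.localize import (
    FragmentMatch,
    LocalizationResult,
    localize_records,
    localize_shift,
    localize_two_shifts,
    match_fragments,
    residue_call,
)
from topform.masses import (
    NTerminalForm,
    ProteoformSpec,
    Shift,
    fragment_ladders,
)
from topform.prsm_io import fragments_by_prsm
from topform.simulate import make_fixture

AA = "ACDEFGHIKLMNPQRSTVWY"
# deltas well below the smallest residue mass (Gly, 57.02 Da) with pairwise
# gaps over 1 Da, so shifted and unshifted ladder variants never collide
SAFE_DELTAS = [15.994915, -18.010565, 42.010565, 27.994915, 31.989829, -2.015650]
TOL = 15.0


def _ladder_value(spec, kind, site):
    lad = fragment_ladders(spec)
    L = len(spec.sequence)
    if kind == "prefix":
        return lad.prefix[site - 1], lad.prefix_valid[site - 1]
    return lad.suffix[L - site - 1], lad.suffix_valid[L - site - 1]


def _placement_consistent(spec, placements, matches, tol_ppm):
    """Mass-level check: does this single-residue placement (tuple of
    positions, one per shift) explain every matched fragment at its site?"""
    deltas = [s.delta for s in spec.shifts_by_position()]
    bare = ProteoformSpec(spec.sequence, spec.nterm_form)
    for m in matches:
        base, _ = _ladder_value(bare, m.ion_kind, m.cleavage_index)
        v = base
        for d, p in zip(deltas, placements):
            included = p <= m.cleavage_index if m.ion_kind == "prefix" else p > m.cleavage_index
            if included:
                v += d
        if v <= 0 or abs(m.observed_mass - v) > tol_ppm * 1e-6 * v:
            return False
    return True


def oracle_single(spec, matches, tol_ppm=TOL):
    """Brute force over every single-residue placement."""
    return [
        p
        for p in range(1, len(spec.sequence) + 1)
        if _placement_consistent(spec, (p,), matches, tol_ppm)
    ]


def oracle_pairs(spec, matches, tol_ppm=TOL):
    """Brute force over every ordered placement pair p1 <= p2."""
    L = len(spec.sequence)
    return [
        (p1, p2)
        for p1 in range(1, L + 1)
        for p2 in range(p1, L + 1)
        if _placement_consistent(spec, (p1, p2), matches, tol_ppm)
    ]


def observe(spec, rng, coverage=1.0, noise_ppm=0.0):
    """Emit fragment observations from the true ladders of a proteoform."""
    lad = fragment_ladders(spec)
    obs = []
    for arr, valid in ((lad.prefix, lad.prefix_valid), (lad.suffix, lad.suffix_valid)):
        for v, ok in zip(arr, valid):
            if ok and v > 0 and rng.random() < coverage:
                obs.append(v * (1 + rng.uniform(-noise_ppm, noise_ppm) * 1e-6))
    return obs


class TestMatchFragments:
    def setup_method(self):
        self.spec = ProteoformSpec("AKMDEF", shifts=(Shift(15.994915, 3, 3),))
        self.bare = fragment_ladders(ProteoformSpec("AKMDEF"))

    def test_exact_unshifted_prefix(self):
        res = match_fragments(self.spec, [self.bare.prefix[2]])
        (m,) = res.matches
        assert (m.ion_kind, m.cleavage_index, m.shifted) == ("prefix", 3, False)
        assert m.ppm == pytest.approx(0.0, abs=1e-9)

    def test_exact_shifted_prefix(self):
        res = match_fragments(self.spec, [self.bare.prefix[2] + 15.994915])
        (m,) = res.matches
        assert (m.ion_kind, m.cleavage_index, m.shifted) == ("prefix", 3, True)
        assert m.ppm == pytest.approx(0.0, abs=1e-9)

    def test_far_observation_dropped(self):
        res = match_fragments(self.spec, [self.bare.prefix[2] + 1000.0])
        assert res.matches == () and res.n_unmatched == 1

    def test_exact_tie_is_uninformative(self):
        # a shift of exactly one Ala residue mass makes shifted-prefix[1]
        # coincide with unshifted-prefix[2]: ambiguous evidence must drop out
        ala = float(fragment_ladders(ProteoformSpec("AAAA")).prefix[0])
        spec = ProteoformSpec("AAAA", shifts=(Shift(ala, 1, 1),))
        res = match_fragments(spec, [2 * ala])
        assert res.n_ambiguous == 1 and res.matches == ()


class TestLocalizeSingle:
    def test_spec_worked_example(self):
        """Unshifted prefixes at sites 1-2, shifted at 3-5 pin residue 3."""
        spec = ProteoformSpec("AKMDEF", shifts=(Shift(16.0, 1, 6),))
        matches = [
            FragmentMatch("prefix", i, (), 0.0, 0.0) for i in (1, 2)
        ] + [FragmentMatch("prefix", i, (0,), 0.0, 0.0) for i in (3, 4, 5)]
        res = localize_shift(spec, matches)
        assert (res.start, res.end, res.residue) == (3, 3, "M")

    def test_no_matches_full_interval(self):
        spec = ProteoformSpec("AKMDEF", shifts=(Shift(16.0, 1, 6),))
        res = localize_shift(spec, [])
        assert (res.start, res.end, res.residue) == (1, 6, None)

    def test_nterminal_pattern_shifted_prefixes_only(self):
        """Shifted b4..b12 with nothing unshifted bound the shift to [1,4]."""
        spec = ProteoformSpec("AKMDEFGHIWKLM", shifts=(Shift(27.99, 1, 13),))
        matches = [FragmentMatch("prefix", i, (0,), 0.0, 0.0) for i in range(4, 13)]
        res = localize_shift(spec, matches)
        assert (res.start, res.end, res.residue) == (1, 4, None)

    def test_contradiction_raises_with_conflict(self):
        spec = ProteoformSpec("AKMDEF", shifts=(Shift(16.0, 1, 6),))
        matches = [
            FragmentMatch("prefix", 4, (), 0.0, 0.0),  # shift right of 4
            FragmentMatch("prefix", 2, (0,), 0.0, 0.0),  # shift left of 3
        ]
        with pytest.raises(LocalizationError) as err:
            localize_shift(spec, matches)
        assert err.value.conflict is not None

    def test_fuzz_equals_bruteforce_oracle(self, rng):
        for _ in range(300):
            L = int(rng.integers(3, 16))
            seq = "".join(rng.choice(list(AA), size=L))
            delta = float(rng.choice(SAFE_DELTAS))
            p = int(rng.integers(1, L + 1))
            spec = ProteoformSpec(seq, shifts=(Shift(delta, p, p),))
            obs = observe(spec, rng, coverage=float(rng.uniform(0.2, 1.0)),
                          noise_ppm=float(rng.uniform(0, TOL / 3)))
            matching = match_fragments(spec, obs, TOL)
            oracle = oracle_single(spec, matching.matches)
            try:
                res = localize_shift(spec, matching.matches)
            except LocalizationError:
                assert not oracle
                continue
            assert oracle, "true placement must be consistent"
            assert (res.start, res.end) == (min(oracle), max(oracle))
            assert res.start <= p <= res.end

    def test_more_fragments_never_widen(self, rng):
        for _ in range(40):
            L = int(rng.integers(4, 14))
            seq = "".join(rng.choice(list(AA), size=L))
            p = int(rng.integers(1, L + 1))
            spec = ProteoformSpec(seq, shifts=(Shift(15.994915, p, p),))
            obs = observe(spec, rng, coverage=1.0)
            matching = match_fragments(spec, obs, TOL)
            full = localize_shift(spec, matching.matches)
            k = int(rng.integers(0, len(matching.matches) + 1))
            subset = list(matching.matches)[:k]
            partial = localize_shift(spec, subset)
            assert partial.start <= full.start and full.end <= partial.end


class TestLocalizeTwo:
    def test_full_coverage_resolves_both(self, rng):
        spec = ProteoformSpec(
            "AKMDEFGHIW", shifts=(Shift(15.994915, 3, 3), Shift(-18.010565, 7, 7))
        )
        obs = observe(spec, rng)
        matching = match_fragments(spec, obs, TOL)
        r1, r2 = localize_two_shifts(spec, matching.matches, TOL)
        assert (r1.start, r1.end, r1.residue) == (3, 3, "M")
        assert (r2.start, r2.end, r2.residue) == (7, 7, "G")

    def test_no_fragments_full_intervals(self):
        spec = ProteoformSpec(
            "AKMDEFGHIW", shifts=(Shift(16.0, 3, 3), Shift(-18.0, 7, 7))
        )
        r1, r2 = localize_two_shifts(spec, [])
        assert (r1.start, r1.end) == (1, 10)
        assert (r2.start, r2.end) == (1, 10)

    def test_fuzz_equals_pair_enumeration_oracle(self, rng):
        for _ in range(120):
            L = int(rng.integers(4, 16))
            seq = "".join(rng.choice(list(AA), size=L))
            d1, d2 = rng.choice(SAFE_DELTAS, size=2)
            p1 = int(rng.integers(1, L))
            p2 = int(rng.integers(p1 + 1, L + 1))
            spec = ProteoformSpec(
                seq, shifts=(Shift(float(d1), p1, p1), Shift(float(d2), p2, p2))
            )
            obs = observe(spec, rng, coverage=float(rng.uniform(0.3, 1.0)),
                          noise_ppm=float(rng.uniform(0, TOL / 3)))
            matching = match_fragments(spec, obs, TOL)
            pairs = oracle_pairs(spec, matching.matches)
            try:
                r1, r2 = localize_two_shifts(spec, matching.matches, TOL)
            except LocalizationError:
                assert not pairs
                continue
            assert pairs, "true pair must be consistent"
            assert (r1.start, r1.end) == (
                min(p for p, _ in pairs),
                max(p for p, _ in pairs),
            )
            assert (r2.start, r2.end) == (
                min(q for _, q in pairs),
                max(q for _, q in pairs),
            )


class TestResidueCall:
    def test_singleton(self):
        assert residue_call(LocalizationResult(3, 3, "M", 1), "AKMDE") == "M"

    def test_ambiguous_interval_not_attributed(self):
        assert residue_call(LocalizationResult(2, 4, None, 5), "AKMDE") is None

    def test_nme_maps_position_one_to_first_retained_residue(self):
        res = LocalizationResult(1, 1, "M", 2)
        assert residue_call(res, "MKDEF", NTerminalForm.NME) == "K"
        res12 = LocalizationResult(1, 2, None, 2)
        assert residue_call(res12, "MKDEF", NTerminalForm.NME) == "K"


def test_planted_site_recovery_full_coverage_zero_noise():
    """With complete, noise-free ladders every planted shift localizes exactly."""
    ds = make_fixture("mini47")
    fragments = fragments_by_prsm(ds.fragments)
    results, report = localize_records(ds.records, fragments)
    truth = {t.prsm_id: t for t in ds.truth}
    n_checked = 0
    for (prsm_id, idx), loc in results.items():
        sites = truth[prsm_id].sites
        assert loc.start == loc.end == sites[idx]
        n_checked += 1
    assert n_checked == sum(len(t.sites) for t in ds.truth)
    assert (report["note"] == "").all()
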