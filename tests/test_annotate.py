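"""Δm explanation: nominal binning, single/pair matching, adduct series."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from topform.annotate import (
    ModificationDef,
    annotate_records,
    default_modifications,
    load_unimod_xml,
    match_adduct_series,
    match_pair,
    match_single,
    nominal_bin,
    sds_adduct,
)
from topform.masses import monoisotopic_mass

from conftest import make_record


def by_accession(*accs):
    table = {m.unimod_accession: m for m in default_modifications()}
    return [table[a] for a in accs]


class TestNominalBin:
    @pytest.mark.parametrize(
        "delta, expected",
        [(15.994915, 16), (0.0, 0), (-18.010565, -18), (0.5, 1), (-0.5, -1)],
    )
    def test_examples(self, delta, expected):
        assert nominal_bin(delta) == expected

    def test_window_enforced_but_disableable(self):
        with pytest.raises(ValueError):
            nominal_bin(532.31)
        assert nominal_bin(532.31, window=None) == 532

    def test_odd_symmetry(self):
        for d in (0.3, 17.7, 266.155, 499.9):
            assert nominal_bin(-d) == -nominal_bin(d)


class TestPackagedTable:
    def test_every_composition_reproduces_its_delta(self):
        for mod in default_modifications():
            assert mod.composition, mod.name
            assert monoisotopic_mass(mod.composition) == pytest.approx(
                mod.delta, abs=1e-5
            )

    def test_cited_accessions_present(self):
        accs = {m.unimod_accession for m in default_modifications()}
        assert {1, 23, 35, 36, 122, 342, 401, 419, 421, 425, 449, 528, 721,
                1145, 1217, 1289, 2020} <= accs

    def test_inconsistent_definition_rejected(self):
        with pytest.raises(ValueError):
            ModificationDef("bogus", 9, 10.0, "O", frozenset("M"))


class TestMatchSingle:
    def test_oxidation_for_16(self):
        hits = match_single(16.0)
        assert hits[0].members[0].unimod_accession == 35
        assert hits[0].mass_error == pytest.approx(0.005085, abs=1e-6)

    def test_15_matches_both_candidates(self):
        accs = {h.members[0].unimod_accession for h in match_single(15.0)}
        assert {528, 342} <= accs

    def test_no_match_far_from_table(self):
        assert match_single(250.0) == []
        assert match_single(5.0, table=[]) == []

    def test_ranking_by_error_then_accession(self):
        hits = match_single(-2.0)
        errors = [abs(h.mass_error) for h in hits]
        assert errors == sorted(errors)
        tied = [h.members[0].unimod_accession for h in hits if abs(abs(h.mass_error) - errors[0]) < 1e-12]
        assert tied == sorted(tied)  # 401 / 1217 / 2020 share a delta


class TestMatchPair:
    def test_formyl_plus_acetyl_explains_70(self):
        hits = match_pair(70.0)
        pair_accs = [tuple(m.unimod_accession for m in h.members) for h in hits]
        idx = pair_accs.index((1, 122))
        assert hits[idx].mass_error == pytest.approx(-0.00548, abs=1e-5)

    def test_methyl_plus_oxidation_explains_30(self):
        pairs = {tuple(m.unimod_accession for m in h.members) for h in match_pair(30.0)}
        assert (34, 35) in pairs

    def test_one_plus_dioxidation_explains_186(self):
        pairs = {tuple(m.unimod_accession for m in h.members) for h in match_pair(186.0)}
        assert (425, 721) in pairs

    def test_self_pair_allowed_and_adducts_excluded(self):
        pairs = {tuple(m.unimod_accession for m in h.members) for h in match_pair(32.0)}
        assert (35, 35) in pairs  # two oxidations
        sds = sds_adduct()
        assert all(sds.unimod_accession not in p for p in
                   {tuple(m.unimod_accession for m in h.members)
                    for h in match_pair(2 * sds.delta, tolerance=0.5)})


class TestAdductSeries:
    @pytest.mark.parametrize(
        "delta, expected",
        [(266.155, (1, False)), (532.310, (2, False)), (401.27, (2, True))],
    )
    def test_series_terms(self, delta, expected):
        hits = match_adduct_series(delta)
        assert (hits[0].n_adducts, hits[0].met_loss) == expected

    def test_two_adducts_minus_met_brute_force(self):
        # exhaustive (n, flag) enumeration pins the expected delta
        sds = sds_adduct()
        target = 2 * sds.delta - 131.040485
        combos = {
            (n, f): n * sds.delta - (131.040485 if f else 0.0)
            for n in (1, 2, 3)
            for f in (False, True)
        }
        best = min(combos, key=lambda k: abs(target - combos[k]))
        hits = match_adduct_series(target)
        assert (hits[0].n_adducts, hits[0].met_loss) == best == (2, True)
        assert target == pytest.approx(401.26987, abs=1e-5)

    def test_no_series_for_100(self):
        assert match_adduct_series(100.0) == []

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            match_adduct_series(266.0, max_n=0)
        with pytest.raises(ValueError):
            match_single(16.0, tolerance=-1)


def _random_table(rng, n):
    return [
        ModificationDef(
            name=f"m{i}",
            unimod_accession=i,
            delta=float(rng.uniform(-200, 200)),
            composition=None,
            sites=frozenset("K"),
        )
        for i in range(n)
    ]


def test_matching_equals_bruteforce_oracle(rng):
    """Single and pair matching agree with an exhaustive scan on random tables."""
    for _ in range(25):
        table = _random_table(rng, int(rng.integers(1, 200)))
        delta = float(rng.uniform(-400, 400))
        tol = float(rng.uniform(0.05, 2.0))
        single = {h.members[0].unimod_accession for h in match_single(delta, table, tol)}
        expected_single = {
            m.unimod_accession for m in table if abs(delta - m.delta) <= tol
        }
        assert single == expected_single
        pairs = {
            tuple(m.unimod_accession for m in h.members)
            for h in match_pair(delta, table, tol)
        }
        expected_pairs = set()
        for i, a in enumerate(table):
            for b in table[i:]:
                if abs(delta - (a.delta + b.delta)) <= tol:
                    expected_pairs.add(
                        tuple(sorted((a.unimod_accession, b.unimod_accession)))
                    )
        assert pairs == expected_pairs


@given(
    st.floats(-400, 400, allow_nan=False),
    st.floats(0.01, 0.4, allow_nan=False),
    st.floats(0.0, 0.6, allow_nan=False),
)
def test_tolerance_monotonicity_and_error_audit(delta, tol, widen):
    narrow = match_single(delta, tolerance=tol) + match_pair(delta, tolerance=tol)
    wide = match_single(delta, tolerance=tol + widen) + match_pair(
        delta, tolerance=tol + widen
    )
    def keys(hits):
        return {(h.kind, tuple(m.unimod_accession for m in h.members)) for h in hits}
    assert keys(narrow) <= keys(wide)
    assert all(abs(h.mass_error) <= tol for h in narrow)
    assert all(abs(h.mass_error) <= tol + widen for h in wide)


def test_annotate_records_report():
    records = [
        make_record(1, "AKMDEFGHIW", shifts=((15.994915, 3, 3),)),
        make_record(2, "AKMDEFGHIW", shifts=((27.994915, 2, 2), (42.010565, 5, 5))),
        make_record(3, "AKMDEFGHIW"),
    ]
    report = annotate_records(records)
    assert len(report) == 3  # one row per shift instance, unmodified PrSM absent
    row16 = report[(report.prsm_id == 1)].iloc[0]
    assert row16["nominal_bin"] == 16
    assert "Oxidation" in row16["single_best"]
    assert bool(row16["single_site_ok"])


def test_unimod_xml_loader(tmp_path):
    xml = """<?xml version="1.0"?>
<umod:unimod xmlns:umod="http://www.unimod.org/xmlns/schema/unimod_2">
 <umod:modifications>
  <umod:mod title="Oxidation" record_id="35">
   <umod:specificity site="M" position="Anywhere"/>
   <umod:delta mono_mass="15.994915" avge_mass="15.9994"/>
  </umod:mod>
 </umod:modifications>
</umod:unimod>"""
    path = tmp_path / "unimod.xml"
    path.write_text(xml)
    table = load_unimod_xml(path)
    assert len(table) == 1
    assert table[0].unimod_accession == 35
    assert table[0].delta == pytest.approx(15.994915)
    assert "M" in table[0].sites
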