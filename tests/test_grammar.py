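import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifarch.errors import InputError, PatternError
from motifarch.grammar import (
    Alternation,
    CANONICAL_RESIDUES,
    ClassSymbol,
    DEFAULT_PSI,
    Fixed,
    ResidueClass,
    Wildcard,
    compile_pattern,
    scan_composition,
    scan_pattern,
    scan_repeats,
)

AA = sorted(CANONICAL_RESIDUES)


class TestResidueClass:
    def test_membership(self):
        rc = ResidueClass("ACIDIC", "DE")
        assert "D" in rc and "E" in rc and "S" not in rc

    def test_non_canonical_rejected(self):
        with pytest.raises(InputError):
            ResidueClass("BAD", "DU")


class TestCompilePattern:
    def test_psi_kxe(self):
        pat = compile_pattern("ΨKxE")
        assert len(pat) == 4
        kinds = [type(e) for e in pat.elements]
        assert kinds == [ClassSymbol, Fixed, Wildcard, Fixed]
        assert pat.elements[1].residue == "K"
        assert pat.elements[3].residue == "E"

    def test_nls_two_alternations(self):
        pat = compile_pattern("K(K/R)x(K/R)")
        assert len(pat) == 4
        alts = [e for e in pat.elements if isinstance(e, Alternation)]
        assert len(alts) == 2
        assert all(e.options == ("K", "R") for e in alts)

    def test_malformed_alternation(self):
        with pytest.raises(PatternError) as exc:
            compile_pattern("K(K/")
        assert exc.value.position == 2

    def test_bad_alternation_body(self):
        with pytest.raises(PatternError):
            compile_pattern("K(KR)E")
        with pytest.raises(PatternError):
            compile_pattern("K(K/U)E")

    def test_unknown_symbol_names_position(self):
        with pytest.raises(PatternError) as exc:
            compile_pattern("KK?E")
        assert "position 3" in str(exc.value)

    def test_too_short(self):
        with pytest.raises(PatternError):
            compile_pattern("K")

    def test_round_trip_catalog_sources(self, catalog):
        for pat in catalog.iter_patterns():
            again = compile_pattern(pat.render())
            assert again.render() == pat.render() == pat.source


def _regex_oracle(source, psi=DEFAULT_PSI):
    """Independent matcher: translate the notation to a lookahead regex."""
    pat = compile_pattern(source, psi)
    parts = []
    for el in pat.elements:
        if isinstance(el, Fixed):
            parts.append(el.residue)
        elif isinstance(el, Wildcard):
            parts.append("[%s]" % "".join(AA))
        elif isinstance(el, ClassSymbol):
            parts.append("[%s]" % "".join(sorted(el.residue_class.members)))
        else:
            parts.append("[%s]" % "".join(el.options))
    rx = re.compile("(?=(" + "".join(parts) + "))")
    return rx, pat


class TestScanPattern:
    def test_sumo_hit(self):
        pat = compile_pattern("ΨKxE")
        hits = scan_pattern("GLKSEG", pat)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].matched) == (2, 5, "LKSE")
        assert hits[0].score == 1.0

    def test_sumo_no_hit_outside_psi(self):
        assert scan_pattern("GAKSEG", compile_pattern("ΨKxE")) == []

    def test_nls_hit(self):
        hits = scan_pattern("AKKRKA", compile_pattern("K(K/R)x(K/R)"))
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].matched) == (2, 5, "KKRK")

    def test_overlapping_hits_all_reported(self):
        hits = scan_pattern("SPSP", compile_pattern("SP"))
        assert [(h.start, h.end) for h in hits] == [(1, 2), (3, 4)]

    def test_illegal_residue_reports_offset(self):
        with pytest.raises(InputError) as exc:
            scan_pattern("GLAZE", compile_pattern("SP"))
        assert "'Z'" in str(exc.value) and "position 4" in str(exc.value)

    def test_mismatch_tolerance_scores(self):
        pat = compile_pattern("NGxSPSxxSSYDxxYSP")
        seq = "NGASPSAASSYAAAYSP"  # D at 12 replaced by A
        assert scan_pattern(seq, pat) == []
        hits = scan_pattern(seq, pat, max_mismatches=2)
        assert len(hits) == 1
        assert hits[0].detail["mismatches"] == 1
        assert hits[0].score == pytest.approx(16 / 17)

    @settings(max_examples=150, deadline=None)
    @given(
        seq=st.text(alphabet=AA, min_size=0, max_size=200),
        src=st.sampled_from(
            ["ΨKxE", "K(K/R)x(K/R)", "(D/E)(D/E)W", "(K/R)RRW", "TxxΨW", "SP", "D(T/S)S"]
        ),
    )
    def test_matches_regex_oracle(self, seq, src):
        rx, pat = _regex_oracle(src)
        expected = [(m.start() + 1, m.start() + len(pat)) for m in rx.finditer(seq)]
        got = [(h.start, h.end) for h in scan_pattern(seq, pat)]
        assert got == expected

    @settings(max_examples=100, deadline=None)
    @given(seq=st.text(alphabet=AA, min_size=4, max_size=120))
    def test_hit_bounds_and_content(self, seq):
        pat = compile_pattern("ΨKxE")
        for h in scan_pattern(seq, pat):
            assert 1 <= h.start <= h.end <= len(seq)
            assert h.matched == seq[h.start - 1 : h.end]
            assert all(
                el.matches(c) for el, c in zip(pat.elements, h.matched)
            )


class TestScanRepeats:
    def test_three_tandem_units(self):
        unit = compile_pattern("D(T/S)S")
        hits = scan_repeats("DTSDTSDTS", unit, min_repeats=2)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, 9)
        assert hits[0].detail["repeats"] == 3

    def test_single_unit_insufficient(self):
        unit = compile_pattern("D(T/S)S")
        assert scan_repeats("GGDTSGG", unit, min_repeats=2) == []

    def test_interrupted_units_not_merged(self):
        unit = compile_pattern("D(T/S)S")
        assert scan_repeats("DTSGDTS", unit, min_repeats=2) == []


def _fraction_oracle(seq, members, start, end):
    """Naive hand-count of class membership over a 1-based inclusive span."""
    span = seq[start - 1 : end]
    return sum(c in members for c in span) / len(span)


class TestScanComposition:
    def test_dlrich_hand_count(self, dlrich_members):
        seq = "DIGEVDLDFWDLDL"
        hits = scan_composition(seq, dlrich_members, 10, 0.8)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (1, 14)
        # frozen from the naive membership oracle: only G is outside the class
        assert h.score == pytest.approx(13 / 14)
        assert h.score == pytest.approx(
            _fraction_oracle(seq, dlrich_members, h.start, h.end)
        )

    def test_srich_with_core(self, catalog, srich_members):
        seq = "GDEASAEVSSSS"
        core = [("canonical", compile_pattern("EV(T/S)SS"))]
        hits = scan_composition(seq, srich_members, 8, 0.6, core_patterns=core)
        assert len(hits) == 1
        h = hits[0]
        assert "EVSSS" in h.matched
        assert h.detail["core"] == "canonical"
        # frozen from the naive membership oracle over the reported span
        # (2..12): members are D,E,S,E,S,S,S,S -> 8 of 11
        assert (h.start, h.end) == (2, 12)
        assert h.score == pytest.approx(8 / 11)
        assert h.score == pytest.approx(
            _fraction_oracle(seq, srich_members, h.start, h.end)
        )

    def test_core_filter_discards_runs(self, srich_members):
        core = [("canonical", compile_pattern("EV(T/S)SS"))]
        assert (
            scan_composition("DSDSDSDSDSDS", srich_members, 8, 0.6, core_patterns=core)
            == []
        )

    def test_no_hit_outside_classes(self, dlrich_members):
        assert scan_composition("GGGGGGGGGG", dlrich_members, 5, 0.7) == []

    def test_window_longer_than_sequence(self, dlrich_members):
        assert scan_composition("DIGEV", dlrich_members, 10, 0.8) == []

    def test_parameter_validation(self, dlrich_members):
        with pytest.raises(InputError):
            scan_composition("DIGEVDLDFW", dlrich_members, 10, 0.0)
        with pytest.raises(InputError):
            scan_composition("DIGEVDLDFW", dlrich_members, 2, 0.5)

    def test_min_run_filter(self, dlrich_members):
        hits = scan_composition("GGDEDWDGG", dlrich_members, 3, 0.8)
        assert hits
        assert scan_composition("GGDEDWDGG", dlrich_members, 3, 0.8, min_run=8) == []

    @settings(max_examples=100, deadline=None)
    @given(
        seq=st.text(alphabet=AA, min_size=0, max_size=150),
        lo=st.floats(min_value=0.3, max_value=0.6),
        hi=st.floats(min_value=0.61, max_value=0.95),
    )
    def test_monotone_in_threshold(self, dlrich_members, seq, lo, hi):
        loose = scan_composition(seq, dlrich_members, 6, lo)
        strict = scan_composition(seq, dlrich_members, 6, hi)
        for h in strict:
            assert any(g.start <= h.start and h.end <= g.end for g in loose)
        for h in loose + strict:
            assert 0.0 <= h.score <= 1.0
            assert 1 <= h.start <= h.end <= len(seq)
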