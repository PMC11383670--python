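"""Venn arithmetic, overlap enrichment, ESR filtering, epistasis sectors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from decaptools import (
    GeneSet,
    classify_redundancy,
    esr_signature,
    exclude_esr,
    hypergeometric_overlap,
    patterns_from_sets,
    shared_fraction,
    solve_venn3_from_totals,
    venn3,
)


def _gs(label, members):
    return GeneSet(label=label, members=frozenset(members))


small_sets = st.sets(st.integers(0, 30).map(lambda i: f"g{i}"), max_size=25)


class TestVenn3:
    def test_disjoint_sets(self):
        v = venn3(_gs("A", "ab"), _gs("B", "cde"), _gs("C", "fghi"))
        assert v.exclusive == (2, 3, 4)
        assert v.pairwise_only == (0, 0, 0) and v.triple == 0

    def test_identical_sets(self):
        s = _gs("A", "abcde")
        v = venn3(s, s, s)
        assert v.triple == 5 and v.exclusive == (0, 0, 0)

    @settings(max_examples=200, deadline=None)
    @given(small_sets, small_sets, small_sets)
    def test_regions_match_membership_enumeration(self, a, b, c):
        v = venn3(_gs("A", a), _gs("B", b), _gs("C", c))
        universe = a | b | c
        regions = {(True, True, True): 0}
        counts = {}
        for g in universe:
            key = (g in a, g in b, g in c)
            counts[key] = counts.get(key, 0) + 1
        assert v.triple == counts.get((True, True, True), 0)
        assert v.exclusive == (
            counts.get((True, False, False), 0),
            counts.get((False, True, False), 0),
            counts.get((False, False, True), 0),
        )
        assert v.pairwise_only == (
            counts.get((True, True, False), 0),
            counts.get((True, False, True), 0),
            counts.get((False, True, True), 0),
        )

    @settings(max_examples=200, deadline=None)
    @given(small_sets, small_sets, small_sets)
    def test_solve_from_totals_round_trips(self, a, b, c):
        v = venn3(_gs("A", a), _gs("B", b), _gs("C", c))
        solved = solve_venn3_from_totals(v.totals, v.exclusive, v.triple)
        assert solved == v

    def test_inconsistent_specification_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            solve_venn3_from_totals((10, 10, 10), (9, 9, 0), 2)


class TestSharedFraction:
    def test_disjoint_sets_share_nothing(self):
        v = venn3(_gs("A", "ab"), _gs("B", "cd"), _gs("C", "ef"))
        assert shared_fraction(v, "A", "B") == (0.0, 0)

    def test_zero_total_errors(self):
        v = venn3(_gs("A", ""), _gs("B", "cd"), _gs("C", "ef"))
        with pytest.raises(ValueError, match="empty"):
            shared_fraction(v, "A", "B")


def brute_force_hypergeom_upper(k, N, nA, nB):
    total = comb(N, nB, exact=True)
    return sum(
        comb(nA, x, exact=True) * comb(N - nA, nB - x, exact=True)
        for x in range(k, min(nA, nB) + 1)
    ) / total


class TestHypergeometric:
    def test_fold_enrichment_arithmetic(self):
        fold, p = hypergeometric_overlap(187, 741, 283, 5391)
        assert fold == pytest.approx(4.81, abs=0.01)
        assert p < 1e-50

    def test_empty_partner_set_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(0, 10, 0, 100)

    @settings(max_examples=150, deadline=None)
    @given(st.data())
    def test_p_matches_exhaustive_enumeration(self, data):
        N = data.draw(st.integers(1, 30))
        nA = data.draw(st.integers(1, N))
        nB = data.draw(st.integers(1, N))
        k = data.draw(st.integers(max(0, nA + nB - N), min(nA, nB)))
        _, p = hypergeometric_overlap(k, nA, nB, N)
        assert math.isclose(p, brute_force_hypergeom_upper(k, N, nA, nB),
                            rel_tol=1e-10, abs_tol=1e-12)


class TestESR:
    def test_no_esr_members_unchanged(self):
        s = _gs("up", {"a", "b"})
        out, retained = exclude_esr(s, {"c": "iESR"}, "up")
        assert out.members == s.members and retained == 100.0

    def test_all_esr_set_empties(self):
        s = _gs("up", {"a", "b"})
        out, retained = exclude_esr(s, {"a": "iESR", "b": "iESR"}, "up")
        assert len(out) == 0 and retained == 0.0

    def test_direction_selects_esr_class(self):
        s = _gs("dn", {"a", "b"})
        out, _ = exclude_esr(s, {"a": "iESR", "b": "rESR"}, "down")
        assert out.members == frozenset({"a"})

    def test_signature_recovers_simulated_shift(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(300)]
        fc = pd.Series(rng.normal(0, 0.05, 300), index=genes)
        iesr, resr = set(genes[:40]), set(genes[40:80])
        fc[list(iesr)] += 1.0
        fc[list(resr)] -= 1.0
        med_i, med_r = esr_signature(fc, iesr, resr)
        assert med_i == pytest.approx(1.0, abs=0.05)
        assert med_r == pytest.approx(-1.0, abs=0.05)

    def test_signature_trivia(self):
        fc = pd.Series({"a": 0.0, "b": 0.0, "c": 0.7})
        assert esr_signature(fc, {"a"}, {"b"}) == (0.0, 0.0)
        assert esr_signature(fc, {"c"}, {"a"})[0] == pytest.approx(0.7)
        with pytest.raises(ValueError, match="intersect"):
            esr_signature(fc, {"zz"}, {"a"})


class TestRedundancyClassification:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            (("ns", "ns", "up"), "redundant_double_only"),
            (("ns", "ns", "down"), "redundant_double_only"),
            (("ns", "up", "up"), "single_shared"),
            (("up", "ns", "up"), "single_shared"),
            (("ns", "up", "ns"), "single_exclusive"),
            (("down", "ns", "ns"), "single_exclusive"),
            (("up", "down", "ns"), "opposite_in_other_single"),
            (("up", "down", "up"), "opposite_in_other_single"),
            (("ns", "ns", "ns"), "unclassified"),
            (("up", "up", "up"), "unclassified"),
        ],
    )
    def test_sector_mapping(self, pattern, expected):
        df = pd.DataFrame([pattern], columns=["scd6", "edc3", "double"], index=["g"])
        calls = classify_redundancy(df)
        assert calls[0].call == expected

    def test_missing_contrast_errors(self):
        df = pd.DataFrame({"scd6": ["ns"], "edc3": ["ns"]})
        with pytest.raises(ValueError, match="missing contrasts"):
            classify_redundancy(df)

    def test_patterns_from_sets(self):
        up = {k: _gs(k, m) for k, m in
              [("scd6", set()), ("edc3", {"g1"}), ("double", {"g1", "g2"})]}
        down = {k: _gs(k, m) for k, m in
                [("scd6", {"g3"}), ("edc3", set()), ("double", set())]}
        pat = patterns_from_sets(["g1", "g2", "g3"], up, down)
        calls = {c.gene_id: c.call for c in classify_redundancy(pat)}
        assert calls == {
            "g1": "single_shared",
            "g2": "redundant_double_only",
            "g3": "single_exclusive",
        }
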