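"""Technique mining: n-gram enumeration, functional filter, usage counts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethonet import (
    build_technique_catalog,
    enumerate_ngrams,
    is_functional_technique,
    repertoire_summary,
    technique_frequencies,
)
from ethonet.errors import ConfigurationError, ParameterError
from ethonet.ethogram import Ethogram
from tests.conftest import make_events


def brute_force_ngrams(seq, k_min, k_max):
    return [
        tuple(seq[i : i + k])
        for i in range(len(seq))
        for k in range(k_min, k_max + 1)
        if i + k <= len(seq)
    ]


class TestEnumerateNgrams:
    def test_four_elements_yield_six_grams(self):
        grams = enumerate_ngrams(list("abcd"), 2, 7)
        assert len(grams) == 6
        assert sorted(len(g) for g in grams) == [2, 2, 2, 3, 3, 4]

    def test_single_element_empty(self):
        assert enumerate_ngrams(["a"]) == []

    def test_counts_match_closed_form(self):
        for n in range(1, 12):
            grams = enumerate_ngrams(list(range(n)), 2, 7)
            expect = sum(n - k + 1 for k in range(2, min(7, n) + 1))
            assert len(grams) == max(expect, 0)

    def test_bad_k_rejected(self):
        with pytest.raises(ParameterError):
            enumerate_ngrams(list("ab"), k_min=1)
        with pytest.raises(ParameterError):
            enumerate_ngrams(list("ab"), k_min=3, k_max=2)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from("pqrs"), min_size=0, max_size=12))
def test_ngrams_equal_brute_force(seq):
    assert enumerate_ngrams(seq, 2, 7) == brute_force_ngrams(seq, 2, 7)


class TestFunctionalFilter:
    def test_probe_then_extract_is_functional(self, ethogram):
        assert is_functional_technique(("Probe 1h", "Extract 1h"), ethogram)

    def test_extract_before_probe_is_not(self, ethogram):
        assert not is_functional_technique(("Extract 1h", "Probe 1h"), ethogram)

    def test_no_functional_elements(self, ethogram):
        assert not is_functional_technique(("Sit", "Lean"), ethogram)

    def test_intervening_elements_allowed(self, ethogram):
        assert is_functional_technique(
            ("Sit", "Probe 1h", "Oscillate", "Extract 2h"), ethogram
        )


def brute_force_catalog(events, ethogram, k_min=2, k_max=7):
    grams = {
        g
        for _s, _v, seq in events.sequences()
        for g in brute_force_ngrams(seq, k_min, min(k_max, len(seq)))
        if is_functional_technique(g, ethogram)
    }
    return sorted(grams, key=lambda g: (len(g), g))


class TestCatalog:
    def test_minimal_functional_pair(self, ethogram):
        ev = make_events([("A", "v1", "Probe 1h", 0.0), ("A", "v1", "Extract 1h", 1.0)])
        cat = build_technique_catalog(ev, ethogram)
        assert len(cat) == 1
        assert cat.by_id(0).elements == ("Probe 1h", "Extract 1h")

    def test_matches_brute_force(self, toy_events, ethogram):
        cat = build_technique_catalog(toy_events, ethogram)
        assert [t.elements for t in cat.techniques] == brute_force_catalog(
            toy_events, ethogram
        )

    def test_no_extract_events_empty_catalog(self, ethogram):
        ev = make_events([("A", "v1", "Probe 1h", 0.0), ("A", "v1", "Sit", 1.0)])
        assert len(build_technique_catalog(ev, ethogram)) == 0

    def test_invariant_under_video_order(self, toy_events, ethogram):
        shuffled = make_events(
            [
                (r.subject, r.video_id, r.element, r.start_time_s)
                for r in toy_events.df.sort_values(
                    ["video_id", "start_time_s"], ascending=[False, True]
                ).itertuples()
            ]
        )
        a = build_technique_catalog(toy_events, ethogram)
        b = build_technique_catalog(shuffled, ethogram)
        assert [t.elements for t in a.techniques] == [t.elements for t in b.techniques]

    def test_roleless_ethogram_rejected(self):
        eth = Ethogram.from_records([("Sit", "posture", ""), ("Lean", "posture", "")])
        ev = make_events([("A", "v1", "Sit", 0.0)])
        with pytest.raises(ConfigurationError):
            build_technique_catalog(ev, eth)


def sliding_window_counts(seq, gram):
    k = len(gram)
    return sum(1 for i in range(len(seq) - k + 1) if tuple(seq[i : i + k]) == gram)


class TestFrequencies:
    def test_overlapping_occurrences_counted(self, ethogram):
        ev = make_events(
            [
                ("A", "v1", "Probe 1h", 0.0),
                ("A", "v1", "Extract 1h", 1.0),
                ("A", "v1", "Probe 1h", 2.0),
                ("A", "v1", "Extract 1h", 3.0),
            ]
        )
        cat = build_technique_catalog(ev, ethogram)
        freq = technique_frequencies(cat, ev)
        pe = next(t.id for t in cat.techniques if t.elements == ("Probe 1h", "Extract 1h"))
        assert freq.loc["A", pe] == 2

    def test_matches_sliding_window_oracle(self, ethogram, rng):
        labels = ["Probe 1h", "Extract 1h", "Sit", "Oscillate"]
        rows = []
        for s in ("A", "B"):
            for v in range(3):
                seq = rng.choice(labels, size=rng.integers(2, 10))
                rows += [(s, f"v{s}{v}", el, 1.0 * i) for i, el in enumerate(seq)]
        ev = make_events(rows)
        cat = build_technique_catalog(ev, ethogram)
        freq = technique_frequencies(cat, ev)
        for t in cat.techniques:
            for s in ("A", "B"):
                expect = sum(
                    sliding_window_counts(seq, t.elements)
                    for s2, _v, seq in ev.sequences()
                    if s2 == s
                )
                assert freq.loc[s, t.id] == expect

    def test_maximal_only_suppresses_nested(self, ethogram):
        # [P, E, Sit]: the bigram (P, E) occurrence is nested inside the
        # functional trigram (P, E, Sit) at the same position; maximal-only
        # counts only the trigram
        ev = make_events(
            [
                ("A", "v1", "Probe 1h", 0.0),
                ("A", "v1", "Extract 1h", 1.0),
                ("A", "v1", "Sit", 2.0),
            ]
        )
        cat = build_technique_catalog(ev, ethogram)
        full = technique_frequencies(cat, ev)
        maximal = technique_frequencies(cat, ev, maximal_only=True)
        tri = next(t.id for t in cat.techniques if t.length == 3)
        assert full.loc["A"].sum() > maximal.loc["A"].sum()
        assert maximal.loc["A", tri] == 1
        assert (maximal.loc["A"].drop(tri) == 0).all()

    def test_totals_monotone_in_videos(self, toy_events, ethogram):
        cat = build_technique_catalog(toy_events, ethogram)
        first_video = make_events(
            [
                (r.subject, r.video_id, r.element, r.start_time_s)
                for r in toy_events.df.itertuples()
                if r.video_id in ("v1", "v3")
            ]
        )
        partial = technique_frequencies(cat, first_video)
        full = technique_frequencies(cat, toy_events)
        assert (full.sum(axis=1) >= partial.sum(axis=1)).all()


class TestRepertoireSummary:
    def test_unweighted_mean_length(self, ethogram):
        ev = make_events(
            [
                ("A", "v1", "Probe 1h", 0.0),
                ("A", "v1", "Extract 1h", 1.0),
                ("A", "v2", "Sit", 0.0),
                ("A", "v2", "Probe 1h", 1.0),
                ("A", "v2", "Extract 1h", 2.0),
            ]
        )
        cat = build_technique_catalog(ev, ethogram)
        freq = technique_frequencies(cat, ev)
        summ = repertoire_summary(freq, cat)
        assert summ.loc["A", "repertoire_size"] == int((freq.loc["A"] > 0).sum())

    def test_weighted_mean_length_hand_value(self, ethogram):
        import pandas as pd

        from ethonet.mining import Technique, TechniqueCatalog

        cat = TechniqueCatalog(
            (
                Technique(("Probe 1h", "Extract 1h"), 0),
                Technique(("Sit", "Probe 1h", "Oscillate", "Extract 1h"), 1),
            )
        )
        freq = pd.DataFrame({0: [3], 1: [1]}, index=["A"])
        summ = repertoire_summary(freq, cat)
        # (3 uses * len 2 + 1 use * len 4) / 4 uses = 2.5
        assert summ.loc["A", "mean_technique_length"] == pytest.approx(2.5)

    def test_age_class_breakdown(self, toy_events, ethogram):
        cat = build_technique_catalog(toy_events, ethogram)
        freq = technique_frequencies(cat, toy_events)
        summ = repertoire_summary(freq, cat, age_class={"A": "adult", "B": "juvenile"})
        assert set(summ.attrs["by_age_class"]) == {"adult", "juvenile"}


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(
            st.sampled_from(["Probe 1h", "Extract 1h", "Sit", "Oscillate", "Fray bite"]),
            min_size=1,
            max_size=10,
        ),
        min_size=1,
        max_size=6,
    )
)
def test_catalog_and_counts_equal_brute_force(sequences):
    """Exhaustive equivalence on small corpora: catalog set and every count."""
    from ethonet import aerial_ethogram

    eth = aerial_ethogram()
    rows = []
    for v, seq in enumerate(sequences):
        subj = "A" if v % 2 == 0 else "B"
        rows += [(subj, f"v{v}", el, 1.0 * i) for i, el in enumerate(seq)]
    ev = make_events(rows)
    cat = build_technique_catalog(ev, eth)
    assert [t.elements for t in cat.techniques] == brute_force_catalog(ev, eth)
    assert all(is_functional_technique(t.elements, eth) for t in cat.techniques)
    freq = technique_frequencies(cat, ev)
    for t in cat.techniques:
        for subj in freq.index:
            expect = sum(
                sliding_window_counts(s, t.elements)
                for s2, _v, s in ev.sequences()
                if s2 == subj
            )
            assert freq.loc[subj, t.id] == expect
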