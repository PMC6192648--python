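"""Read recruitment, presence/RPKG matrices and ecology summaries."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funkfams.catalog_io import AlignmentHit
from funkfams.family_screen import ConfigurationError
from funkfams.metagenome_profile import (
    best_hit_per_read,
    beta_diversity_groups,
    bray_curtis,
    bray_curtis_matrix,
    call_presence,
    entropy_filter,
    phylum_filter,
    presence_entropy,
    prevalence,
    rpkg,
)
from funkfams.taxonomy_breadth import BreadthProfile, FunkFamSelection


def hit(read="r1", subject="p1", pident=99.5, length=100, evalue=1e-20, bit=80.0):
    return AlignmentHit(read, subject, pident, length, evalue, bit)


FAMILY_OF = {"p1": "famA", "p2": "famB", "pA": "famA", "pB": "famB"}


class TestBestHit:
    def test_argmax_bit_score(self):
        hits = [hit(bit=60.0, subject="p2"), hit(bit=80.0, subject="p1")]
        [a] = best_hit_per_read(hits, FAMILY_OF)
        assert a.best_hit.bit_score == 80.0 and a.family_id == "famA"

    def test_tie_breaks_to_smallest_subject_id(self):
        hits = [hit(subject="pB"), hit(subject="pA")]
        [a] = best_hit_per_read(hits, FAMILY_OF)
        assert a.best_hit.subject_id == "pA"

    def test_lower_evalue_breaks_bit_tie(self):
        hits = [hit(subject="pB", evalue=1e-30), hit(subject="pA", evalue=1e-10)]
        [a] = best_hit_per_read(hits, FAMILY_OF)
        assert a.best_hit.subject_id == "pB"

    def test_read_without_hits_absent(self):
        assert best_hit_per_read([], FAMILY_OF) == []

    def test_unmapped_subjects_dropped(self):
        hits = [hit(subject="mystery", bit=999.0), hit(subject="p1", bit=10.0)]
        [a] = best_hit_per_read(hits, FAMILY_OF)
        assert a.best_hit.subject_id == "p1"


class TestCallPresence:
    def _assignments(self, *hits_):
        return best_hit_per_read(list(hits_), FAMILY_OF)

    def test_full_length_high_identity_read_counted(self):
        counts = call_presence(self._assignments(hit(pident=99.5, length=100)), 100)
        assert counts == {"famA": 1}

    def test_identity_below_threshold_rejected(self):
        counts = call_presence(self._assignments(hit(pident=98.0)), 100)
        assert counts == {}

    def test_alignment_shorter_than_read_rejected(self):
        counts = call_presence(self._assignments(hit(length=99)), 100)
        assert counts == {}

    def test_single_accepted_read_gives_presence(self):
        counts = call_presence(self._assignments(hit()), 100)
        assert counts.get("famA", 0) >= 1

    def test_missing_read_length_rejected(self):
        with pytest.raises(ValueError):
            call_presence([], 0)


class TestRpkg:
    def test_hand_worked_value(self):
        counts = pd.DataFrame({"s1": [10]}, index=["famA"])
        out = rpkg(counts, {"famA": 250.0}, pd.Series({"s1": 20.0}))
        # 10 reads / (250 aa * 3 / 1000 = 0.75 kb) / 20 genome equivalents
        assert out.loc["famA", "s1"] == pytest.approx(10 / 0.75 / 20, abs=1e-12)

    def test_zero_count_zero_rpkg(self):
        counts = pd.DataFrame({"s1": [0]}, index=["famA"])
        out = rpkg(counts, {"famA": 250.0}, pd.Series({"s1": 20.0}))
        assert out.loc["famA", "s1"] == 0.0

    def test_doubling_genome_equivalents_halves_rpkg(self):
        counts = pd.DataFrame({"s1": [7], "s2": [7]}, index=["famA"])
        ge = pd.Series({"s1": 10.0, "s2": 20.0})
        out = rpkg(counts, {"famA": 100.0}, ge)
        assert out.loc["famA", "s2"] == pytest.approx(out.loc["famA", "s1"] / 2)

    def test_linearity_in_counts(self):
        ge = pd.Series({"s1": 10.0})
        one = rpkg(pd.DataFrame({"s1": [3]}, index=["f"]), {"f": 100.0}, ge)
        two = rpkg(pd.DataFrame({"s1": [6]}, index=["f"]), {"f": 100.0}, ge)
        assert two.loc["f", "s1"] == pytest.approx(2 * one.loc["f", "s1"])

    def test_nonpositive_genome_equivalents_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["famA"])
        with pytest.raises(ValueError):
            rpkg(counts, {"famA": 100.0}, pd.Series({"s1": 0.0}))


class TestPrevalence:
    def test_fraction_of_environment_samples(self):
        presence = pd.DataFrame(
            [[True] * 9 + [False]], index=["famA"], columns=[f"s{i}" for i in range(10)]
        )
        envs = pd.Series("ENV_A", index=presence.columns)
        out = prevalence(presence, envs)
        assert out.loc["famA", "ENV_A"] == pytest.approx(0.9)

    def test_absent_everywhere_zero(self):
        presence = pd.DataFrame([[False, False]], index=["famA"], columns=["s1", "s2"])
        envs = pd.Series("ENV_A", index=presence.columns)
        assert prevalence(presence, envs).loc["famA", "ENV_A"] == 0.0

    def test_two_environments_computed_independently(self):
        presence = pd.DataFrame(
            {"a1": [True], "a2": [False], "b1": [False], "b2": [False]}, index=["famA"]
        )
        envs = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        out = prevalence(presence, envs)
        assert out.loc["famA", "A"] == 0.5 and out.loc["famA", "B"] == 0.0


class TestEntropy:
    def test_half_prevalence_is_one_bit(self):
        row = pd.Series([True, False, True, False])
        assert presence_entropy(row) == pytest.approx(1.0)

    def test_uniform_presence_zero_bits(self):
        assert presence_entropy(pd.Series([True, True, True])) == pytest.approx(0.0)
        assert presence_entropy(pd.Series([False, False])) == pytest.approx(0.0)

    def test_quarter_prevalence_matches_formula(self):
        row = pd.Series([True, False, False, False])
        expect = -(0.25 * math.log2(0.25) + 0.75 * math.log2(0.75))
        assert presence_entropy(row) == pytest.approx(expect, abs=1e-9)

    def test_matrix_form_matches_row_form(self):
        presence = pd.DataFrame(
            [[True, False, True, True], [False, False, False, True]],
            index=["f1", "f2"], columns=list("abcd"),
        )
        series = presence_entropy(presence)
        for fid in presence.index:
            assert series[fid] == pytest.approx(presence_entropy(presence.loc[fid]))


class TestEntropyFilter:
    def test_top_quarter_of_eight_distinct_values(self):
        entropies = {f"f{i}": i / 10 for i in range(8)}
        kept = entropy_filter(entropies, 0.25)
        assert kept == {"f6", "f7"}

    def test_all_equal_all_retained(self):
        entropies = {f"f{i}": 0.5 for i in range(5)}
        assert entropy_filter(entropies, 0.25) == set(entropies)

    def test_single_family_retained(self):
        assert entropy_filter({"f1": 0.3}, 0.25) == {"f1"}

    def test_top_fraction_one_retains_everything(self):
        entropies = {f"f{i}": i / 7 for i in range(7)}
        assert entropy_filter(entropies, 1.0) == set(entropies)

    @pytest.mark.parametrize("frac", [0.0, -0.5, 1.5])
    def test_bad_fraction_rejected(self, frac):
        with pytest.raises(ConfigurationError):
            entropy_filter({"f": 0.5}, frac)


class TestPhylumFilter:
    def _selection(self, fid, is_funkfam=True):
        return FunkFamSelection(fid, is_funkfam, "class", 2, (1, 1, 2, 3))

    def _breadth(self, fid, phyla):
        distinct = {r: 1 for r in ("species", "genus", "family", "order",
                                   "class", "phylum", "kingdom", "domain")}
        distinct["phylum"] = phyla
        return BreadthProfile(fid, distinct, 3)

    def test_two_phyla_retained_one_dropped(self):
        selections = [self._selection("f1"), self._selection("f2")]
        breadths = {"f1": self._breadth("f1", 2), "f2": self._breadth("f2", 1)}
        assert phylum_filter(selections, breadths) == {"f1"}

    def test_min_phyla_one_drops_nothing_selected(self):
        selections = [self._selection("f1"), self._selection("f2")]
        breadths = {"f1": self._breadth("f1", 2), "f2": self._breadth("f2", 1)}
        assert phylum_filter(selections, breadths, min_phyla=1) == {"f1", "f2"}

    def test_non_funkfams_never_retained(self):
        selections = [self._selection("f1", is_funkfam=False)]
        breadths = {"f1": self._breadth("f1", 5)}
        assert phylum_filter(selections, breadths) == set()


class TestBrayCurtis:
    def test_identical_vectors_zero(self):
        assert bray_curtis(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])) == 0.0

    def test_disjoint_support_one(self):
        assert bray_curtis(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == pytest.approx(1.0)

    def test_hand_worked_pair(self):
        assert bray_curtis(np.array([1.0, 2.0]), np.array([2.0, 1.0])) == pytest.approx(1 / 3)

    def test_both_all_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.zeros(3), np.zeros(3))

    @given(
        x=st.lists(st.floats(0, 100), min_size=2, max_size=6),
        y=st.lists(st.floats(0, 100), min_size=2, max_size=6),
        c=st.floats(0.01, 50),
    )
    @settings(max_examples=150, deadline=None)
    def test_symmetry_range_and_scale_invariance(self, x, y, c):
        n = min(len(x), len(y))
        xv, yv = np.array(x[:n]), np.array(y[:n])
        if xv.sum() == 0 and yv.sum() == 0:
            return
        d = bray_curtis(xv, yv)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(yv, xv))
        assert bray_curtis(c * xv, c * yv) == pytest.approx(d, abs=1e-9)

    def test_manual_formula_agreement(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.uniform(0, 10, size=6)
            y = rng.uniform(0, 10, size=6)
            manual = 1 - 2 * np.minimum(x, y).sum() / (x.sum() + y.sum())
            assert bray_curtis(x, y) == pytest.approx(manual, abs=1e-12)


class TestBetaDiversityGroups:
    def _bc(self, abundance):
        return bray_curtis_matrix(abundance)

    def test_two_plus_two_pair_partition(self):
        abundance = pd.DataFrame(
            np.array([[5, 4, 0, 0], [1, 2, 0, 0], [0, 0, 6, 5], [0, 0, 2, 3]]).T,
            index=["f1", "f2", "f3", "f4"],
            columns=["a1", "a2", "b1", "b2"],
        )
        envs = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        groups = beta_diversity_groups(self._bc(abundance), envs)
        assert groups.within_a.size == 1 and groups.within_b.size == 1
        assert groups.between.size == 4

    def test_single_environment_has_empty_between(self):
        abundance = pd.DataFrame(
            {"a1": [1.0, 2.0], "a2": [2.0, 1.0], "a3": [1.0, 1.0]}, index=["f1", "f2"]
        )
        envs = pd.Series({"a1": "A", "a2": "A", "a3": "A"})
        groups = beta_diversity_groups(self._bc(abundance), envs)
        assert groups.between.size == 0
        assert math.isnan(groups.p_value)

    def test_planted_separation_yields_small_p(self):
        # disjoint family support between environments -> between-BC = 1 > within
        rng = np.random.default_rng(0)
        n = 6
        block_a = np.vstack([rng.uniform(1, 3, size=(4, n)), np.zeros((4, n))])
        block_b = np.vstack([np.zeros((4, n)), rng.uniform(1, 3, size=(4, n))])
        abundance = pd.DataFrame(
            np.hstack([block_a, block_b]),
            index=[f"f{i}" for i in range(8)],
            columns=[f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)],
        )
        envs = pd.Series(["A"] * n + ["B"] * n, index=abundance.columns)
        groups = beta_diversity_groups(self._bc(abundance), envs)
        assert groups.between.min() > max(groups.within_a.max(), groups.within_b.max())
        assert groups.p_value < 0.05

    def test_all_zero_sample_rejected(self):
        abundance = pd.DataFrame({"s1": [1.0], "s2": [0.0]}, index=["f1"])
        with pytest.raises(ValueError, match="s2"):
            bray_curtis_matrix(abundance)
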