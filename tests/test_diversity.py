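import math

import pytest
from hypothesis import given, settings, strategies as st

from mycodiv import (
    AbundanceVector,
    colonization_frequency,
    diversity_profile,
    diversity_table,
    gleason,
    pielou,
    relative_gleason,
    shannon,
    simpson_diversity,
    simpson_dominance,
    species_richness,
)
from mycodiv.diversity import round_half_up


def brute_shannon(counts):
    """Independent per-species summation oracle."""
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            h -= (c / total) * math.log(c / total)
    return h


def brute_simpson(counts):
    total = sum(counts)
    d = 0.0
    for c in counts:
        d += (c / total) ** 2
    return d


def vec(counts):
    return AbundanceVector({f"sp{i}": c for i, c in enumerate(counts)})


counts_strategy = st.lists(st.integers(0, 500), min_size=1, max_size=30).filter(
    lambda c: sum(c) > 0
)


class TestColonizationFrequency:
    @pytest.mark.parametrize(
        "colonized,total,expected", [(0, 45, 0.0), (45, 45, 100.0), (9, 45, 20.0)]
    )
    def test_direct_formula(self, colonized, total, expected):
        assert colonization_frequency(colonized, total) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            colonization_frequency(1, 0)
        with pytest.raises(ValueError):
            colonization_frequency(46, 45)


class TestIndexFormulas:
    def test_richness(self):
        assert species_richness(AbundanceVector({})) == 0
        assert species_richness(vec([1, 0, 3])) == 2

    @pytest.mark.parametrize(
        "np_, s, printed",
        [(17, 762, 2.411), (22, 320, 3.640), (17, 366, 2.710), (24, 272, 4.103)],
    )
    def test_gleason_printed_rows(self, np_, s, printed):
        # agreement to one unit in the last printed digit (the published
        # table mixes truncation and rounding in its display)
        assert abs(gleason(np_, s) - printed) < 1e-3

    def test_gleason_degenerate_and_errors(self):
        assert gleason(1, 100) == 0.0
        with pytest.raises(ValueError):
            gleason(17, 1)

    def test_relative_gleason(self):
        assert abs(relative_gleason(17, 762) - 0.021) < 1e-3
        assert relative_gleason(1, 50) == 0.0
        assert relative_gleason(22, 320) == pytest.approx(21 / 320)

    def test_simpson_hand_values(self):
        assert simpson_dominance(vec([5])) == 1.0
        assert simpson_dominance(vec([3, 3])) == pytest.approx(0.5)
        assert simpson_dominance(vec([1, 2, 3])) == pytest.approx(14 / 36)
        assert simpson_diversity(14 / 36) == pytest.approx(22 / 36)
        with pytest.raises(ValueError):
            simpson_diversity(1.5)

    def test_shannon_hand_values(self):
        assert shannon(vec([7])) == 0.0
        assert shannon(vec([2, 2, 2, 2])) == pytest.approx(math.log(4))
        assert shannon(vec([1, 2, 3])) == pytest.approx(1.0114, abs=5e-5)

    def test_pielou_hand_values(self):
        assert round_half_up(pielou(2.545, 22), 2) == 0.82
        assert pielou(math.log(5), 5) == pytest.approx(1.0)
        assert pielou(1.0114, 3) == pytest.approx(0.9206, abs=5e-5)
        with pytest.raises(ValueError):
            pielou(1.0, 1)


class TestProfile:
    def test_single_species_convention(self):
        row = diversity_profile(vec([9]), label="solo")
        assert (row.Np, row.G, row.GR, row.D, row.one_minus_D, row.H) == (1, 0, 0, 1, 0, 0)
        assert row.E == 1.0
        assert not row.evenness_defined

    def test_uniform_community(self):
        row = diversity_profile(vec([10] * 10))
        assert row.D == pytest.approx(0.1)
        assert row.H == pytest.approx(math.log(10))
        assert row.E == pytest.approx(1.0)

    def test_derived_row(self):
        row = diversity_profile(vec([1, 2, 3]))
        assert row.S == 6 and row.Np == 3
        assert row.D == pytest.approx(14 / 36)
        assert row.H == pytest.approx(brute_shannon([1, 2, 3]))
        assert row.E == pytest.approx(row.H / math.log(3))

    def test_table_from_survey(self, survey):
        table = diversity_table(survey, by="season")
        assert list(table.columns) == ["label", "S", "Np", "G", "GR", "D", "1-D", "H", "E"]
        assert set(table["label"]) == {"winter", "summer", "rainy"}
        np_by_label = dict(zip(table["label"], table["Np"]))
        assert np_by_label["winter"] == 17
        assert np_by_label["rainy"] == 24


class TestProperties:
    @settings(max_examples=300, derandomize=True)
    @given(counts_strategy)
    def test_matches_bruteforce_and_complement(self, counts):
        a = vec(counts)
        D = simpson_dominance(a)
        H = shannon(a)
        assert D == pytest.approx(brute_simpson(counts), rel=1e-12)
        assert H == pytest.approx(brute_shannon(counts), rel=1e-12)
        assert D + simpson_diversity(D) == pytest.approx(1.0, abs=1e-15)
        np_ = species_richness(a)
        assert 1 / np_ - 1e-12 <= D <= 1 + 1e-12
        assert -1e-12 <= H <= math.log(max(np_, 1)) + 1e-12

    @settings(max_examples=200, derandomize=True)
    @given(counts_strategy, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, counts, rnd):
        shuffled = list(counts)
        rnd.shuffle(shuffled)
        assert shannon(vec(shuffled)) == pytest.approx(shannon(vec(counts)), rel=1e-12)
        assert simpson_dominance(vec(shuffled)) == pytest.approx(
            simpson_dominance(vec(counts)), rel=1e-12
        )

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(1, 200), min_size=2, max_size=20))
    def test_merging_species_lowers_entropy_raises_dominance(self, counts):
        merged = [counts[0] + counts[1]] + counts[2:]
        assert shannon(vec(merged)) <= shannon(vec(counts)) + 1e-12
        assert simpson_dominance(vec(merged)) >= simpson_dominance(vec(counts)) - 1e-12


def test_round_half_up_at_boundary():
    # 0.125 is exactly representable: half-away-from-zero differs from
    # banker's rounding here
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(-0.125, 2) == -0.13
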