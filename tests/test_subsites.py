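"""Binding-mode enumeration, product prediction, and frequency inference."""

import pytest

from _oracles import brute_force_modes
from conftest import all_glycans
from mannomap import (
    BindingMode,
    Glycan,
    LabelPair,
    LabelingConfig,
    ModeFrequencies,
    ProductTable,
    SubsiteCleft,
    correct_labeling,
    enumerate_modes,
    format_name,
    infer_mode_frequencies,
    mode_count,
    pair_shares,
    parse_name,
    products_of_mode,
    simulate_digest,
)


class TestEnumerateModes:
    def test_m5_has_four_modes(self, m5, cleft):
        labels = [m.label for m in enumerate_modes(m5, cleft)]
        assert sorted(labels) == sorted(["-4..+1", "-3..+2", "-2..+3", "-1..+4"])

    def test_monosaccharide_has_no_productive_mode(self, cleft):
        assert enumerate_modes(Glycan(1), cleft) == []

    def test_decoration_filter_excludes_galactosyl_in_plus2(self, mggmm, cleft):
        """MGGMM in −1..+4 would place a galactosyl in +2, which the cleft
        does not tolerate."""
        unfiltered = {m.label for m in enumerate_modes(mggmm, cleft)}
        filtered = {m.label for m in enumerate_modes(mggmm, cleft, enforce_decoration=True)}
        assert "-1..+4" in unfiltered
        # −1..+4 puts the 6^3 galactosyl in +2; every other mode keeps both
        # galactosyls within the tolerated subsites
        assert unfiltered - filtered == {"-1..+4"}
        assert {"-4..+1", "-3..+2", "-2..+3"} <= filtered

    def test_nonamer_does_not_fit_the_default_cleft(self, cleft):
        assert enumerate_modes(Glycan(9), cleft) == []


class TestModeCount:
    @pytest.mark.parametrize("n, expected", [(2, 1), (5, 4), (8, 1), (9, 0)])
    def test_default_cleft_examples(self, n, expected, cleft):
        assert mode_count(n, cleft) == expected

    @pytest.mark.parametrize("n_neg", [1, 2, 4, 6])
    @pytest.mark.parametrize("n_pos", [1, 3, 6])
    def test_closed_form_matches_brute_force(self, n_neg, n_pos):
        cleft = SubsiteCleft(n_neg, n_pos, frozenset({-1, 1}))
        for n in range(1, 13):
            oracle = brute_force_modes(n, n_neg, n_pos)
            assert mode_count(n, cleft) == len(oracle)
            got = [(m.k_neg, m.k_pos) for m in enumerate_modes(Glycan(n), cleft)]
            assert sorted(got) == sorted(oracle)


class TestProductsOfMode:
    @pytest.mark.parametrize(
        "substrate, mode, heavy, light",
        [
            ("M5", BindingMode(4, 1), "M4", "M1"),
            ("MGGMM", BindingMode(4, 1), "MGGM", "M1"),
            ("MGGMM", BindingMode(3, 2), "MGG", "M2"),
            ("MGGMM", BindingMode(1, 4), "M1", "GGMM"),
        ],
    )
    def test_cleavage_products(self, substrate, mode, heavy, light):
        h, l = products_of_mode(parse_name(substrate), mode)
        assert (format_name(h), format_name(l)) == (heavy, light)

    def test_conserves_hexoses_and_decorations(self, cleft):
        for g in all_glycans(8):
            for mode in enumerate_modes(g, SubsiteCleft(8, 8, frozenset({-1, 1}))):
                h, l = products_of_mode(g, mode)
                assert h.backbone_length + l.backbone_length == g.backbone_length
                assert h.hexose_count + l.hexose_count == g.hexose_count
                rebuilt = l.decorations | {d + mode.k_pos for d in h.decorations}
                assert rebuilt == g.decorations

    def test_wrong_length_mode_rejected(self, m5):
        with pytest.raises(ValueError):
            products_of_mode(m5, BindingMode(2, 2))


class TestInferModeFrequencies:
    def test_wild_type_dominant_minus4_plus1_is_80_percent(self, m5, cleft):
        table = ProductTable({"M4": 0.89, "M1": 0.89, "M3": 0.11, "M2": 0.11})
        pairs = [
            LabelPair(parse_name("M4"), 1.0, 8.9, corrected=True),
            LabelPair(parse_name("M3"), 1.0, 1.0, corrected=True),
        ]
        freqs = infer_mode_frequencies(m5, cleft, table, pairs)
        assert freqs.as_percent()[BindingMode(4, 1)] == 80

    def test_variant_dominant_minus3_plus2_is_63_percent(self, m5, cleft):
        table = ProductTable({"M4": 0.30, "M1": 0.30, "M3": 0.70, "M2": 0.70})
        pairs = [
            LabelPair(parse_name("M3"), 1.0, 9.2, corrected=True),
            LabelPair(parse_name("M4"), 1.0, 1.0, corrected=True),
        ]
        freqs = infer_mode_frequencies(m5, cleft, table, pairs)
        assert freqs.as_percent()[BindingMode(3, 2)] == 63

    def test_single_mode_substrate_needs_no_pair(self, cleft):
        m2 = Glycan(2)
        freqs = infer_mode_frequencies(m2, cleft, ProductTable({"M1": 2.0}), [])
        assert freqs.frequencies[BindingMode(1, 1)] == pytest.approx(1.0)

    def test_missing_pair_for_ambiguous_size_errors(self, m5, cleft):
        table = ProductTable({"M4": 0.89, "M1": 0.89, "M3": 0.11, "M2": 0.11})
        with pytest.raises(ValueError, match="missing corrected label pair"):
            infer_mode_frequencies(m5, cleft, table, [])

    def test_uncorrected_pair_rejected(self, m5, cleft):
        table = ProductTable({"M4": 0.89, "M1": 0.89, "M3": 0.11, "M2": 0.11})
        pairs = [LabelPair(parse_name("M4"), 1.0, 8.9)]
        with pytest.raises(ValueError, match="not corrected"):
            infer_mode_frequencies(m5, cleft, table, pairs)

    def test_invariant_to_uniform_table_scaling(self, m5, cleft):
        pairs = [
            LabelPair(parse_name("M4"), 1.0, 8.9, corrected=True),
            LabelPair(parse_name("M3"), 1.0, 1.0, corrected=True),
        ]
        t1 = ProductTable({"M4": 0.89, "M1": 0.89, "M3": 0.11, "M2": 0.11})
        t2 = ProductTable({"M4": 890, "M1": 890, "M3": 110, "M2": 110})
        f1 = infer_mode_frequencies(m5, cleft, t1, pairs)
        f2 = infer_mode_frequencies(m5, cleft, t2, pairs)
        for mode in f1.frequencies:
            assert f1.frequencies[mode] == pytest.approx(f2.frequencies[mode], abs=1e-12)

    def test_disagreeing_small_large_shares_error(self, m5, cleft):
        table = ProductTable({"M4": 0.50, "M1": 0.89, "M3": 0.50, "M2": 0.11})
        pairs = [LabelPair(parse_name("M4"), 1.0, 8.9, corrected=True)]
        with pytest.raises(ValueError, match="disagree"):
            infer_mode_frequencies(m5, cleft, table, pairs)


class TestPairShares:
    def test_shares_from_amounts(self, m5, cleft):
        table = ProductTable({"M4": 89, "M1": 89, "M3": 11, "M2": 11})
        shares = pair_shares(m5, cleft, table)
        assert shares[(1, 4)] == pytest.approx(0.89)
        assert shares[(2, 3)] == pytest.approx(0.11)

    def test_symmetric_pair_amount_halved(self, cleft):
        # M4 cleaved −2..+2 yields two M2 per event
        m4 = Glycan(4)
        table = ProductTable({"M3": 50, "M1": 50, "M2": 100})
        shares = pair_shares(m4, cleft, table)
        assert shares[(1, 3)] == pytest.approx(0.5)
        assert shares[(2, 2)] == pytest.approx(0.5)


class TestSimulateDigest:
    def test_single_mode_full_labelling(self, m5):
        freqs = ModeFrequencies({BindingMode(4, 1): 1.0})
        table, counts = simulate_digest(m5, freqs, 1000, LabelingConfig(p=1.0), seed=0)
        assert table.amounts == {"M4": 1000, "M1": 1000}
        assert counts["M4"] == (1000, 0)
        assert counts["M1"] == (0, 1000)

    def test_zero_labelling_gives_no_heavy_counts(self, m5, wild_type_freqs):
        cfg = LabelingConfig(p=1e-12)  # p=0 is outside the config contract
        _, counts = simulate_digest(m5, wild_type_freqs, 1000, cfg, seed=0)
        assert all(h == 0 for h, _ in counts.values())

    def test_round_trip_recovers_frequencies_within_one_point(
        self, m5, cleft, wild_type_freqs, labeling
    ):
        """simulate → infer is the identity to ±1 percentage point at 10⁶
        events (Monte-Carlo, seeded)."""
        table, counts = simulate_digest(m5, wild_type_freqs, 10**6, labeling, seed=7)
        pairs = []
        for name in ("M4", "M3"):
            h, l = counts[name]
            pairs.append(
                correct_labeling(LabelPair(parse_name(name), l, h), labeling)
            )
        inferred = infer_mode_frequencies(m5, cleft, table, pairs)
        for mode, truth in wild_type_freqs.frequencies.items():
            assert abs(inferred.frequencies[mode] - truth) < 0.01

    def test_expectation_matches_closed_form(self, m5, wild_type_freqs, labeling):
        table, counts = simulate_digest(m5, wild_type_freqs, 10**6, labeling, seed=3)
        share = table.amounts["M4"] / (table.amounts["M4"] + table.amounts["M3"])
        assert share == pytest.approx(0.89, abs=0.01)
        h, l = counts["M4"]
        expected_hf = labeling.p * 0.80 / 0.89
        assert h / (h + l) == pytest.approx(expected_hf, abs=0.01)


class TestModeFrequenciesContainer:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ModeFrequencies({BindingMode(4, 1): 0.5})

    def test_percent_rounding(self, wild_type_freqs):
        assert sum(wild_type_freqs.as_percent().values()) == 100
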