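"""In-silico digestion, peak arithmetic, binning, and affiliation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from siptrflp.errors import ConfigurationError, DegenerateInputError
from siptrflp.trflp import (
    AffiliationParams,
    BUILTIN_ENZYMES,
    DigestPrediction,
    EnzymeSpec,
    HHAI,
    MSPI,
    NO_CUT,
    TRFPeak,
    affiliate,
    bin_lengths,
    peak_proportions,
    predict_trf_table,
    terminal_fragment_length,
)


def brute_force_trf(seq: str, enzyme: EnzymeSpec):
    """Independent oracle: check every window against the site."""
    seq = seq.upper()
    site = enzyme.recognition_site
    for i in range(len(seq) - len(site) + 1):
        if seq[i : i + len(site)] == site:
            return i + enzyme.cut_offset
    return NO_CUT


class TestTerminalFragmentLength:
    @pytest.mark.parametrize(
        "seq, enzyme, expected",
        [
            ("AAAAGCGCTT", HHAI, 7),
            ("TTCCGGAA", MSPI, 3),
            ("AAAATTTT", HHAI, NO_CUT),
            ("GCGC", HHAI, 3),  # site at the very 5' end
            ("AAAAGCGCTTCCGGAA", HHAI, 7),
            ("AAAAGCGCTTCCGGAA", MSPI, 11),
        ],
    )
    def test_examples(self, seq, enzyme, expected):
        assert terminal_fragment_length(seq, enzyme) == expected

    def test_lowercase_accepted(self):
        assert terminal_fragment_length("aaaagcgctt", HHAI) == 7

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            terminal_fragment_length("AAXGCGC", HHAI)

    def test_shorter_than_site_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            terminal_fragment_length("GCG", HHAI)

    def test_ambiguity_codes_never_match(self):
        # N could stand for C, but ambiguous windows must not cut
        assert terminal_fragment_length("AAGCGNTT", HHAI) is NO_CUT
        # the unambiguous site downstream still cuts
        assert terminal_fragment_length("GCGNGCGC", HHAI) == 7

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            n = int(rng.integers(50, 1500))
            seq = "".join(rng.choice(list("ACGT"), n))
            for enzyme in (HHAI, MSPI):
                assert terminal_fragment_length(seq, enzyme) == brute_force_trf(
                    seq, enzyme
                )

    def test_matches_biopython_restriction(self):
        """Cross-check against an independent restriction-site engine."""
        from Bio.Restriction import HhaI as BioHhaI
        from Bio.Restriction import MspI as BioMspI
        from Bio.Seq import Seq

        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(60, 600))))
            for enzyme, bio in ((HHAI, BioHhaI), (MSPI, BioMspI)):
                cuts = bio.search(Seq(seq))  # 1-based first base after cut
                expected = cuts[0] - 1 if cuts else NO_CUT
                assert terminal_fragment_length(seq, enzyme) == expected

    @given(
        st.text(alphabet="ACGT", min_size=10, max_size=200),
        st.text(alphabet="ACGT", min_size=0, max_size=50),
    )
    def test_appending_after_first_cut_never_changes_trf(self, seq, suffix):
        first = terminal_fragment_length(seq, HHAI)
        if first is not NO_CUT:
            assert terminal_fragment_length(seq + suffix, HHAI) == first


class TestPredictTable:
    def test_one_prediction_per_sequence_enzyme(self):
        preds = predict_trf_table({"s1": "AAAAGCGCTTCCGGAA"}, [HHAI, MSPI])
        assert {(p.enzyme, p.expected_length_bp) for p in preds} == {
            ("HhaI", 7),
            ("MspI", 11),
        }

    def test_no_cut_recorded_not_dropped(self):
        preds = predict_trf_table({"s1": "AAAAGCGCTTAA"}, [HHAI, MSPI])
        by_enzyme = {p.enzyme: p.expected_length_bp for p in preds}
        assert by_enzyme == {"HhaI": 7, "MspI": NO_CUT}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            predict_trf_table({}, [HHAI])
        with pytest.raises(ValueError):
            predict_trf_table({"s": "ACGTACGT"}, [])


class TestPeakProportions:
    def test_single_peak(self):
        assert peak_proportions([TRFPeak(337, 1000.0)]) == {337: 1.0}

    def test_two_peaks(self):
        props = peak_proportions([TRFPeak(337, 300.0), TRFPeak(398, 700.0)])
        assert props == pytest.approx({337: 0.3, 398: 0.7})

    def test_peak_at_exactly_the_floor_is_kept(self):
        props = peak_proportions([TRFPeak(337, 995.0), TRFPeak(500, 5.0)])
        assert props == pytest.approx({337: 0.995, 500: 0.005})

    def test_peak_below_floor_removed_and_renormalized(self):
        props = peak_proportions([TRFPeak(337, 996.0), TRFPeak(500, 4.0)])
        assert props == {337: 1.0}

    def test_duplicate_lengths_merge(self):
        props = peak_proportions([TRFPeak(100, 10.0), TRFPeak(100, 30.0)])
        assert props == {100: 1.0}

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            peak_proportions([TRFPeak(100, 0.0)])

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        peaks = [
            TRFPeak(int(L), float(f))
            for L, f in zip(rng.integers(20, 900, 40), rng.uniform(0, 100, 40))
        ]
        assert sum(peak_proportions(peaks).values()) == pytest.approx(1.0, abs=1e-9)


class TestBinLengths:
    def test_published_pair_bins_together(self):
        (bin_,) = bin_lengths([337, 341], tolerance_bp=5)
        assert bin_.member_lengths == frozenset({337, 341})
        assert bin_.representative_length_bp == 337

    def test_single_length(self):
        (bin_,) = bin_lengths([100], tolerance_bp=5)
        assert bin_.member_lengths == frozenset({100})

    def test_chain_splits_at_anchor_distance(self):
        bins = bin_lengths([100, 105, 110], tolerance_bp=5)
        assert [sorted(b.member_lengths) for b in bins] == [[100, 105], [110]]

    def test_empty_input(self):
        assert bin_lengths([], tolerance_bp=5) == []

    def test_sample_id_tuples_accepted(self):
        bins = bin_lengths([("a", 100), ("b", 103)], tolerance_bp=5)
        assert bins[0].member_lengths == frozenset({100, 103})

    @given(
        st.lists(st.integers(min_value=20, max_value=900), min_size=1, max_size=40),
        st.integers(min_value=0, max_value=10),
    )
    def test_members_within_tolerance_and_order_invariant(self, lengths, tol):
        bins = bin_lengths(lengths, tol)
        for b in bins:
            assert max(b.member_lengths) - min(b.member_lengths) <= tol
            assert b.representative_length_bp == min(b.member_lengths)
        assert bin_lengths(list(reversed(lengths)), tol) == bins
        covered = {L for b in bins for L in b.member_lengths}
        assert covered == set(lengths)


TABLE_PREDICTIONS = [
    DigestPrediction("cloneD", "HhaI", 341, "Hyphomicrobium-like"),
    DigestPrediction("cloneD", "MspI", 403, "Hyphomicrobium-like"),
    DigestPrediction("cloneB", "HhaI", 355, "Propioniferax-like"),
    DigestPrediction("cloneB", "MspI", 158, "Propioniferax-like"),
]


class TestAffiliate:
    def test_dcm_clone_matches_both_enzymes(self):
        matches = affiliate({"HhaI": 337, "MspI": 398}, TABLE_PREDICTIONS)
        assert [m.sequence_id for m in matches] == ["cloneD"]
        assert matches[0].diffs_bp == {"HhaI": 4, "MspI": 5}

    def test_benzene_clone_matches_both_enzymes(self):
        matches = affiliate({"HhaI": 352, "MspI": 154}, TABLE_PREDICTIONS)
        assert [m.sequence_id for m in matches] == ["cloneB"]
        assert matches[0].diffs_bp == {"HhaI": 3, "MspI": 4}

    def test_unrelated_lengths_unaffiliated(self):
        assert affiliate({"HhaI": 200, "MspI": 300}, TABLE_PREDICTIONS) == []

    def test_enzyme_order_symmetric(self):
        a = affiliate({"HhaI": 337, "MspI": 398}, TABLE_PREDICTIONS)
        b = affiliate({"MspI": 398, "HhaI": 337}, TABLE_PREDICTIONS)
        assert [m.sequence_id for m in a] == [m.sequence_id for m in b]

    @pytest.mark.parametrize("tol", [6, 8, 10])
    def test_match_monotone_in_tolerance(self, tol):
        base = affiliate(
            {"HhaI": 337, "MspI": 398},
            TABLE_PREDICTIONS,
            AffiliationParams(tolerance_bp=5),
        )
        wider = affiliate(
            {"HhaI": 337, "MspI": 398},
            TABLE_PREDICTIONS,
            AffiliationParams(tolerance_bp=tol),
        )
        assert {m.sequence_id for m in base} <= {m.sequence_id for m in wider}

    def test_exact_ties_flagged_ambiguous(self):
        preds = TABLE_PREDICTIONS + [
            DigestPrediction("cloneX", "HhaI", 341, "twin"),
            DigestPrediction("cloneX", "MspI", 403, "twin"),
        ]
        matches = affiliate({"HhaI": 337, "MspI": 398}, preds)
        assert len(matches) == 2 and all(m.ambiguous for m in matches)

    def test_missing_enzyme_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="RsaI"):
            affiliate({"RsaI": 100}, TABLE_PREDICTIONS)

    def test_single_enzyme_mode(self):
        matches = affiliate(
            {"HhaI": 337},
            TABLE_PREDICTIONS,
            AffiliationParams(require_both_enzymes=False),
        )
        assert [m.sequence_id for m in matches] == ["cloneD"]

    def test_tolerance_cap(self):
        with pytest.raises(ValueError):
            AffiliationParams(tolerance_bp=11)


def test_builtin_enzyme_geometry():
    assert BUILTIN_ENZYMES["HhaI"].recognition_site == "GCGC"
    assert BUILTIN_ENZYMES["HhaI"].cut_offset == 3
    assert BUILTIN_ENZYMES["MspI"].recognition_site == "CCGG"
    assert BUILTIN_ENZYMES["MspI"].cut_offset == 1
    with pytest.raises(ValueError):
        EnzymeSpec("bad", "GCGC", 5)
    with pytest.raises(ValueError):
        EnzymeSpec("bad", "GCNC", 2)
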