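import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protnorm.classify import (
    FractionSummary,
    NormalisationCall,
    RegulationCall,
    Thresholds,
    call_normalisation,
    call_regulation,
    classify_records,
    count_filter_tiers,
    summarise,
)
from protnorm.errors import SummaryError

from ._oracles import oracle_normalisation, oracle_regulation
from .conftest import make_ratio, random_ratio_records


class TestThresholds:
    def test_fc_low_defaults_to_reciprocal(self):
        t = Thresholds(fc_high=4.0)
        assert t.fc_low == pytest.approx(0.25)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(fc_high=0.9)
        with pytest.raises(ValueError):
            Thresholds(up_min_standard=5, up_min_strict=2)
        with pytest.raises(ValueError):
            Thresholds(biomarker_fold=1.0)


class TestCallRegulation:
    @pytest.mark.parametrize(
        "r, up, level, expected",
        [
            (2.5, 6, "strict", RegulationCall.REGULATED_UP),
            (2.0, 6, "strict", RegulationCall.UNREGULATED),  # strict boundary
            (0.5, 6, "strict", RegulationCall.UNREGULATED),  # strict boundary
            (0.49, 6, "strict", RegulationCall.REGULATED_DOWN),
            (0.3, 1, "standard", RegulationCall.INSUFFICIENT_EVIDENCE),
            (0.3, 2, "standard", RegulationCall.REGULATED_DOWN),
            (8.0, 4, "strict", RegulationCall.INSUFFICIENT_EVIDENCE),
            (8.0, 5, "strict", RegulationCall.REGULATED_UP),
        ],
    )
    def test_ratio_and_evidence_rules(self, thresholds, r, up, level, expected):
        call = call_regulation(
            r,
            detected_disease=True,
            detected_reference=True,
            unique_peptides=up,
            thresholds=thresholds,
            level=level,
        )
        assert call is expected

    def test_exclusive_detection(self, thresholds):
        assert (
            call_regulation(
                None,
                detected_disease=True,
                detected_reference=False,
                unique_peptides=9,
                thresholds=thresholds,
            )
            is RegulationCall.EXCLUSIVE_DISEASE
        )
        assert (
            call_regulation(
                None,
                detected_disease=False,
                detected_reference=True,
                unique_peptides=9,
                thresholds=thresholds,
            )
            is RegulationCall.EXCLUSIVE_REFERENCE
        )
        assert (
            call_regulation(
                None,
                detected_disease=False,
                detected_reference=False,
                unique_peptides=9,
                thresholds=thresholds,
            )
            is RegulationCall.UNDETECTED
        )

    def test_nonpositive_ratio_rejected(self, thresholds):
        with pytest.raises(ValueError):
            call_regulation(
                0.0,
                detected_disease=True,
                detected_reference=True,
                unique_peptides=9,
                thresholds=thresholds,
            )


class TestCallNormalisation:
    @pytest.mark.parametrize(
        "r_d, r_t, expected",
        [
            (4.0, 1.2, NormalisationCall.NORMALISED),
            (4.0, 2.0, NormalisationCall.NORMALISED),   # inclusive band edge
            (0.1, 0.5, NormalisationCall.NORMALISED),   # inclusive band edge
            (0.1, 0.3, NormalisationCall.TREND),
            (4.0, 3.0, NormalisationCall.TREND),
            (4.0, 6.0, NormalisationCall.NOT_NORMALISED),
            (4.0, 0.2, NormalisationCall.NOT_NORMALISED),  # overshoot
            (0.2, 0.1, NormalisationCall.NOT_NORMALISED),  # worsened
            (4.0, 4.0, NormalisationCall.NOT_NORMALISED),  # unchanged
        ],
    )
    def test_band_trend_and_overshoot(self, thresholds, r_d, r_t, expected):
        reg = (
            RegulationCall.REGULATED_UP
            if r_d > 1
            else RegulationCall.REGULATED_DOWN
        )
        assert call_normalisation(r_d, r_t, reg, thresholds) is expected

    def test_not_applicable_without_regulation_or_ratio(self, thresholds):
        assert (
            call_normalisation(1.5, 1.0, RegulationCall.UNREGULATED, thresholds)
            is NormalisationCall.NOT_APPLICABLE
        )
        assert (
            call_normalisation(4.0, None, RegulationCall.REGULATED_UP, thresholds)
            is NormalisationCall.NOT_APPLICABLE
        )


class TestSummarise:
    def test_published_scale_counts_give_47_percent(self, thresholds):
        # 348 up + 281 down regulated, 295 of them normalised
        summary = FractionSummary.from_counts(
            n_regulated_up=348, n_regulated_down=281, n_normalised=295,
            n_trend=31, n_not_normalised=303,
        )
        assert summary.pct_normalised == pytest.approx(46.899, abs=1e-3)
        assert round(summary.pct_normalised) == 47

    def test_all_normalised_degenerate(self):
        s = FractionSummary.from_counts(2, 1, 3)
        assert s.pct_normalised == pytest.approx(100.0)

    def test_empty_regulated_set_errors(self, thresholds):
        records = [make_ratio("P1", 1.0, 1.0, 9)]
        frame = classify_records(records, thresholds)
        with pytest.raises(SummaryError):
            summarise(frame)

    def test_summarise_matches_from_counts(self, thresholds):
        records = [
            make_ratio("P1", 4.0, 1.2, 9),   # up, normalised
            make_ratio("P2", 0.1, 0.3, 9),   # down, trend
            make_ratio("P3", 4.0, 6.0, 9),   # up, not normalised
            make_ratio("P4", 8.0, None, 9),  # up, no treated ratio
            make_ratio("P5", 1.0, 1.0, 9),   # unregulated
        ]
        s = summarise(classify_records(records, thresholds))
        assert (s.n_regulated_up, s.n_regulated_down) == (3, 1)
        assert (s.n_normalised, s.n_trend, s.n_not_normalised) == (1, 1, 1)
        # partition excludes the regulated protein lacking a treated ratio
        assert s.n_with_outcome == s.n_regulated - 1
        assert s.pct_normalised + s.pct_trend + s.pct_not_normalised == (
            pytest.approx(100.0)
        )


class TestCountFilterTiers:
    def test_hand_enumerated_fixture(self, thresholds):
        records = [
            make_ratio("A01", 4.0, None, 6),   # regulated both tiers
            make_ratio("A02", 0.3, None, 5),   # regulated both tiers
            make_ratio("A03", 2.5, None, 3),   # regulated standard only
            make_ratio("A04", 0.4, None, 2),   # regulated standard only
            make_ratio("A05", 1.5, None, 7),   # unregulated
            make_ratio("A06", 2.0, None, 9),   # boundary -> unregulated
            make_ratio("A07", 0.5, None, 2),   # boundary -> unregulated
            make_ratio("A08", 3.0, None, 1),   # insufficient evidence
            make_ratio("A09", None, None, 8,
                       detected={"reference": False, "disease": True,
                                 "treated": False}),  # exclusive
            make_ratio("A10", 0.1, None, 4),   # regulated standard only
        ]
        tiers = count_filter_tiers(records, thresholds)
        assert tiers.n_identified == 10
        assert tiers.n_regulated_standard == 5
        assert tiers.n_unregulated_standard == 3
        assert tiers.n_regulated_strict == 2

    def test_up_filter_blocks_everything(self, thresholds):
        records = [make_ratio(f"P{i}", 8.0, None, 1) for i in range(4)]
        tiers = count_filter_tiers(records, thresholds)
        assert tiers.n_regulated_standard == 0
        assert tiers.n_regulated_strict == 0

    @settings(max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_strict_tier_never_exceeds_standard(self, seed):
        rng = np.random.default_rng(seed)
        records = random_ratio_records(rng, 25)
        tiers = count_filter_tiers(records, Thresholds())
        assert tiers.n_regulated_strict <= tiers.n_regulated_standard


class TestOracleEquivalence:
    @settings(max_examples=80, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_calls_match_clausewise_oracle(self, seed):
        thresholds = Thresholds()
        rng = np.random.default_rng(seed)
        records = random_ratio_records(rng, 50)
        for level in ("standard", "strict"):
            frame = classify_records(records, thresholds, level=level)
            for rec, (_, row) in zip(records, frame.iterrows()):
                expected_reg = oracle_regulation(
                    rec.r_disease,
                    rec.detected["disease"],
                    rec.detected["reference"],
                    rec.unique_peptides,
                    thresholds,
                    level,
                )
                assert row["regulation_call"] == expected_reg
                expected_norm = oracle_normalisation(
                    rec.r_disease, rec.r_treated, expected_reg, thresholds
                )
                assert row["normalisation_call"] == expected_norm


class TestInvariants:
    @settings(max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_partition_exactly_one_call_each(self, seed):
        thresholds = Thresholds()
        rng = np.random.default_rng(seed)
        records = random_ratio_records(rng, 30)
        frame = classify_records(records, thresholds)
        assert len(frame) == len(records)
        assert frame["regulation_call"].isin(
            [c.value for c in RegulationCall]
        ).all()
        assert frame["normalisation_call"].isin(
            [c.value for c in NormalisationCall]
        ).all()
        counts = frame["regulation_call"].value_counts().sum()
        assert counts == len(records)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotonicity_in_up_minimum_and_band(self, seed):
        rng = np.random.default_rng(seed)
        records = random_ratio_records(rng, 30)
        narrow = Thresholds(fc_high=2.0)
        wide = Thresholds(fc_high=3.0)
        stricter_up = Thresholds(up_min_standard=2, up_min_strict=8)

        def n_regulated(t, level):
            frame = classify_records(records, t, level=level)
            return int(
                frame["regulation_call"]
                .isin(["regulated_up", "regulated_down"])
                .sum()
            )

        # raising the UP minimum never increases regulated counts
        assert n_regulated(stricter_up, "strict") <= n_regulated(narrow, "strict")
        # widening the band never increases regulated counts ...
        assert n_regulated(wide, "strict") <= n_regulated(narrow, "strict")
        # ... and, among proteins still regulated under the wider band, the
        # normalised set only grows (a protein leaving the regulated set
        # loses its outcome altogether, so the comparison is per protein)
        a = classify_records(records, narrow).set_index("accession")
        b = classify_records(records, wide).set_index("accession")
        still_regulated = b["regulation_call"].isin(
            ["regulated_up", "regulated_down"]
        )
        was_normalised = a.loc[still_regulated, "normalisation_call"] == "normalised"
        now = b.loc[still_regulated, "normalisation_call"]
        assert (now[was_normalised] == "normalised").all()

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_log_symmetry_under_ratio_inversion(self, seed):
        thresholds = Thresholds()
        rng = np.random.default_rng(seed)
        records = random_ratio_records(rng, 30)
        inverted = [
            make_ratio(
                r.accession,
                None if r.r_disease is None else 1.0 / r.r_disease,
                None if r.r_treated is None else 1.0 / r.r_treated,
                r.unique_peptides,
                detected=r.detected,
            )
            for r in records
        ]
        a = classify_records(records, thresholds)
        b = classify_records(inverted, thresholds)
        up_a = (a["regulation_call"] == "regulated_up").sum()
        down_a = (a["regulation_call"] == "regulated_down").sum()
        up_b = (b["regulation_call"] == "regulated_up").sum()
        down_b = (b["regulation_call"] == "regulated_down").sum()
        assert (up_a, down_a) == (down_b, up_b)
        for col in ("normalisation_call",):
            assert (a[col] == "normalised").sum() == (b[col] == "normalised").sum()
            assert (a[col] == "trend").sum() == (b[col] == "trend").sum()
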