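"""Detection limits, presence calling and survey tables."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ednamark import assaycall, datasets
from ednamark.assaycall import (
    STANDARD_DILUTIONS,
    DilutionSeries,
    SurveyObservation,
    build_survey_table,
    call_presence,
    detection_limit,
)


def series(stock, last_positive_factor, dilutions=STANDARD_DILUTIONS):
    outcomes = tuple(d <= last_positive_factor for d in dilutions)
    return DilutionSeries(stock_ng_ml=stock, dilutions=dilutions, outcomes=outcomes)


class TestDetectionLimit:
    @pytest.mark.parametrize(
        "stock, last_pos, expected",
        [
            (3000, 1000, 3.0),       # positives through 1:1000, negative from 1:5000
            (3750, 10000, 0.375),
            (3800, 5000, 0.76),
            (2020, 10000, 0.202),
        ],
    )
    def test_first_negative_rule(self, stock, last_pos, expected):
        lim = detection_limit(series(stock, last_pos))
        assert lim.limit_ng_ml == pytest.approx(expected)
        assert not (lim.censored or lim.undetected or lim.non_monotone)

    def test_all_positive_censored(self):
        lim = detection_limit(series(1000, 100000))
        assert lim.limit_ng_ml == pytest.approx(0.01)
        assert lim.censored
        assert str(lim).startswith("<=")

    def test_first_step_negative_undetected(self):
        lim = detection_limit(series(1000, 0))
        assert lim.undetected and lim.limit_ng_ml is None

    def test_non_monotone_warns_but_uses_first_negative(self):
        s = DilutionSeries(stock_ng_ml=1000, dilutions=(5, 10, 25),
                           outcomes=(True, False, True))
        with pytest.warns(assaycall.NonMonotoneDilutionWarning):
            lim = detection_limit(s)
        assert lim.limit_ng_ml == pytest.approx(200.0)
        assert lim.non_monotone

    def test_invalid_series(self):
        with pytest.raises(ValueError):
            DilutionSeries(stock_ng_ml=1000, dilutions=(10, 5), outcomes=(True, True))
        with pytest.raises(ValueError):
            DilutionSeries(stock_ng_ml=1000, dilutions=(), outcomes=())

    @given(st.floats(0.1, 100.0), st.integers(1, len(STANDARD_DILUTIONS) - 1))
    @settings(max_examples=60, deadline=None)
    def test_scale_equivariance(self, scale, k):
        base = series(1000.0, STANDARD_DILUTIONS[k - 1])
        scaled = DilutionSeries(stock_ng_ml=1000.0 * scale,
                                dilutions=base.dilutions, outcomes=base.outcomes)
        a = detection_limit(base).limit_ng_ml
        b = detection_limit(scaled).limit_ng_ml
        assert b == pytest.approx(a * scale)

    def test_bundled_series_reproduce_reported_limits(self):
        got = {s.assay: detection_limit(s).limit_ng_ml
               for s in datasets.reference_dilution_series()}
        assert got == pytest.approx(
            {"CoFl-16S": 0.375, "MeTu-16S": 3.0, "MyLe-COI": 0.76, "SiWo-COI": 0.202}
        )


def obs(extractions, universal=True, ext_neg=False, pcr_neg=False):
    return SurveyObservation(site_id="s", assay="a",
                             extractions=tuple(tuple(e) for e in extractions),
                             universal_control=universal,
                             extraction_negative=ext_neg, pcr_negative=pcr_neg)


class TestCallPresence:
    def test_two_positives_one_extraction(self):
        c = call_presence(obs([[True, True], [False, False]]))
        assert c.call == "present" and "one extraction" in c.reason

    def test_one_positive_each_of_two_extractions(self):
        c = call_presence(obs([[True, False], [True, False]]))
        assert c.call == "present" and "two extractions" in c.reason

    def test_single_unreplicated_positive_absent(self):
        assert call_presence(obs([[True, False], [False, False]])).call == "absent"

    def test_batch_control_contamination_invalidates(self):
        c = call_presence(obs([[True, True], [True, True]], ext_neg=True))
        assert c.call == "invalid_batch"
        assert call_presence(obs([[True, True]], pcr_neg=True)).call == "invalid_batch"

    def test_failed_universal_control_invalidates_sample(self):
        assert call_presence(obs([[True, True]], universal=False)).call == "invalid_sample"

    def test_gating_precedes_presence(self):
        c = call_presence(obs([[True, True], [True, True]], universal=False, ext_neg=True))
        assert c.call == "invalid_batch"

    def test_truth_table_two_by_two(self):
        """All 16 outcome patterns of the 2-extraction x 2-PCR design."""
        for pattern in itertools.product([False, True], repeat=4):
            e1, e2 = pattern[:2], pattern[2:]
            got = call_presence(obs([e1, e2])).call
            expected = "present" if (sum(e1) >= 2 or sum(e2) >= 2
                                     or (sum(e1) >= 1 and sum(e2) >= 1)) else "absent"
            assert got == expected, pattern

    def test_loose_second_clause_reading(self):
        o = obs([[True, False], [False, False]])
        assert call_presence(o, require_two_extractions=False).call == "present"
        assert call_presence(obs([[True, False]]), require_two_extractions=False).call \
            == "absent"  # only one extraction run

    def test_ragged_replicates_accepted(self):
        assert call_presence(obs([[True], [True, False, False]])).call == "present"

    @given(st.lists(st.lists(st.booleans(), min_size=1, max_size=3),
                    min_size=1, max_size=3))
    @settings(max_examples=150, deadline=None)
    def test_monotone_in_positives(self, extractions):
        """Turning any negative into a positive never flips present -> absent."""
        base = call_presence(obs(extractions)).call
        for i, ext in enumerate(extractions):
            for j in range(len(ext)):
                if not extractions[i][j]:
                    up = [list(e) for e in extractions]
                    up[i][j] = True
                    upgraded = call_presence(obs(up)).call
                    if base == "present":
                        assert upgraded == "present"


class TestSurveyTable:
    def test_bundled_survey_counts(self):
        calls = [call_presence(o) for o in datasets.reference_survey()]
        table = build_survey_table(calls, site_order=datasets.SURVEY_SITES,
                                   assay_order=["CoFl-16S", "MeTu-16S",
                                                "MyLe-COI", "SiWo-COI"])
        assert table.counts == {"CoFl-16S": 3, "MeTu-16S": 1,
                                "MyLe-COI": 2, "SiWo-COI": 1}
        assert list(table.matrix.loc["CoFl-16S", ["Z1", "Z2", "Z3"]]) == ["X", "X", "X"]
        assert list(table.matrix.loc["MyLe-COI", ["S1", "S2", "S3"]]) == ["X", "X", "-"]

    def test_counts_equal_x_cells(self):
        calls = [call_presence(o) for o in datasets.reference_survey()]
        table = build_survey_table(calls)
        for assay, n in table.counts.items():
            assert n == (table.matrix.loc[assay] == "X").sum()

    def test_invalid_cells_excluded_from_counts(self):
        calls = [
            assaycall.PresenceCall("s1", "a", "present", ""),
            assaycall.PresenceCall("s2", "a", "invalid_batch", ""),
            assaycall.PresenceCall("s3", "a", "absent", ""),
        ]
        table = build_survey_table(calls)
        assert table.counts == {"a": 1}
        assert list(table.matrix.loc["a"]) == ["X", "!", "-"]

    def test_duplicate_call_rejected(self):
        c = assaycall.PresenceCall("s", "a", "present", "")
        with pytest.raises(ValueError, match="duplicate"):
            build_survey_table([c, c])

    def test_empty_calls(self):
        table = build_survey_table([])
        assert table.counts == {} and table.matrix.empty


def test_survey_tsv_round_trip(tmp_path):
    srcs = datasets.reference_survey()
    by_key = {(o.site_id, o.assay): o for o in srcs}
    o = by_key[("Z1", "CoFl-16S")]
    assert o.extractions == ((True, True), (True, True))
    assert o.universal_control and not o.extraction_negative
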