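"""Reading raw tables, the missingness taxonomy, the audit, case deletion."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hrucost as h
from hrucost.ingest import CATEGORIES, IngestError

from conftest import wide_row


def classify(catalog, study_id, measure_id, count=None, durations=(), secondary=None):
    r = h.RawResponse("p", study_id, measure_id, count, tuple(durations), secondary)
    return h.classify_response(
        r, catalog.measure(measure_id), catalog.study(study_id)
    )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

class TestReadResponses:
    def test_wide_direct_mapping(self, catalog):
        df = wide_row(catalog, "PACTO", ed_visits=3)
        responses = {r.measure_id: r for r in h.read_responses(df, catalog)}
        assert responses["ed_visits"].count_value == 3.0
        # every asked measure produces a record; unasked measures none
        assert set(responses) == set(catalog.study("PACTO").recall_days)

    def test_long_layout_compound(self, catalog):
        csv = io.StringIO(
            "participant_id,study_id,measure_id,field,value\n"
            "p1,PACTO,hospitalizations,count,1\n"
            "p1,PACTO,hospitalizations,duration_1,4\n"
        )
        responses = {
            r.measure_id: r
            for r in h.read_responses(csv, catalog, layout="long")
        }
        r = responses["hospitalizations"]
        assert r.count_value == 1.0 and r.event_durations == (4.0,)

    def test_measure_not_in_study(self, catalog):
        df = wide_row(catalog, "BRIGHT2")
        df["money_spent_drugs"] = 50
        with pytest.raises(IngestError, match="not in study"):
            h.read_responses(df, catalog)

    def test_unknown_measure_column(self, catalog):
        df = wide_row(catalog, "PACTO")
        df["bogus_measure"] = 1
        with pytest.raises(IngestError, match="bogus_measure"):
            h.read_responses(df, catalog)

    def test_duplicate_rows_rejected(self, catalog):
        df = pd.concat([wide_row(catalog, "PACTO")] * 2, ignore_index=True)
        with pytest.raises(IngestError, match="duplicate"):
            h.read_responses(df, catalog)

    def test_numeric_sentinel_codes(self, catalog):
        df = wide_row(catalog, "PACTO", ed_visits=-99)
        (r,) = [x for x in h.read_responses(df, catalog, sentinels=("DK", "-99"))
                if x.measure_id == "ed_visits"]
        c = h.classify_response(r, catalog.measure("ed_visits"), catalog.study("PACTO"))
        assert c.category == "absent_code"


# ---------------------------------------------------------------------------
# Classification taxonomy
# ---------------------------------------------------------------------------

class TestClassify:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            # single counts
            (dict(measure_id="days_drug_problems", count=50.0), "out_of_range"),
            (dict(measure_id="days_drug_problems", count=12.0), "none"),
            (dict(measure_id="ed_visits", count="DK"), "absent_code"),
            (dict(measure_id="ed_visits", count=None), "absent_blank"),
            (dict(measure_id="ed_visits", count=0.0), "none"),
            # frequency × duration
            (dict(measure_id="hospitalizations", count=0.0, durations=[2.0]),
             "incompatible_compound"),
            (dict(measure_id="hospitalizations", count=0.0), "none"),
            (dict(measure_id="hospitalizations", count=2.0, durations=[3.0, 5.0]), "none"),
            (dict(measure_id="hospitalizations", count=2.0, durations=[3.0]),
             "absent_blank"),
            (dict(measure_id="hospitalizations", count=2.0, durations=[3.0, "REF"]),
             "absent_code"),
            (dict(measure_id="hospitalizations", count=3.0, durations=[0.0, 0.0, 0.0]),
             "incompatible_compound"),
            (dict(measure_id="hospitalizations", count=1.0), "incompatible_compound"),
            (dict(measure_id="hospitalizations", count=7.0,
                  durations=[1.0, 2.0, 3.0, 4.0, 5.0]), "none"),
            (dict(measure_id="hospitalizations", count=1.0, durations=[400.0]),
             "out_of_range"),
            # provider × visits-per-provider
            (dict(measure_id="physician_visits", count=2.0, secondary=0.0),
             "incompatible_compound"),
            (dict(measure_id="physician_visits", count=0.0, secondary=3.0),
             "incompatible_compound"),
            (dict(measure_id="physician_visits", count=0.0, secondary=None), "none"),
            (dict(measure_id="physician_visits", count=0.0, secondary=0.0), "none"),
            (dict(measure_id="physician_visits", count=1.0, secondary=None),
             "absent_blank"),
            (dict(measure_id="physician_visits", count=1.0, secondary=2.0), "none"),
        ],
    )
    def test_taxonomy(self, catalog, kwargs, expected):
        c = classify(catalog, "PACTO", **kwargs)
        assert c.category == expected
        assert (c.status == "valid") == (expected == "none")

    def test_out_of_range_depends_on_recall(self, catalog):
        # 50 ED visits is out of range in a 30-day window but not over 6 months
        assert classify(catalog, "PACTO", "days_drug_problems", count=50.0).category \
            == "out_of_range"
        assert classify(catalog, "PACTO", "ed_visits", count=50.0).status == "valid"

    def test_precedence_absence_over_range(self, catalog):
        # count out of range AND a duration code: absence wins
        c = classify(
            catalog, "PACTO", "hospitalizations", count=400.0, durations=["DK"]
        )
        assert c.category == "absent_code"
        # count out of range alone (durations fine) stays out_of_range
        c = classify(
            catalog, "PACTO", "hospitalizations", count=400.0, durations=[2.0]
        )
        assert c.category == "out_of_range"

    def test_precedence_range_over_compound(self, catalog):
        # zero count with an out-of-range positive duration: range wins
        c = classify(
            catalog, "PACTO", "hospitalizations", count=0.0, durations=[400.0]
        )
        assert c.category == "out_of_range"

    @given(
        count=st.one_of(
            st.none(),
            st.sampled_from(["DK", "REF", "NA_"]),
            st.floats(min_value=-5, max_value=400, allow_nan=False),
        ),
        durations=st.lists(
            st.one_of(
                st.none(),
                st.sampled_from(["DK"]),
                st.floats(min_value=-2, max_value=500, allow_nan=False),
            ),
            max_size=5,
        ),
    )
    @settings(max_examples=300, derandomize=True)
    def test_partition_and_purity(self, catalog, count, durations):
        """Every response falls in exactly one category; classification is pure."""
        m = catalog.measure("hospitalizations")
        s = catalog.study("PACTO")
        r = h.RawResponse("p", "PACTO", "hospitalizations", count, tuple(durations))
        c1 = h.classify_response(r, m, s)
        c2 = h.classify_response(r, m, s)
        assert c1 == c2
        assert (c1.category in CATEGORIES) or (c1.category == "none")
        assert (c1.status == "valid") == (c1.category == "none")


# ---------------------------------------------------------------------------
# Audit
# ---------------------------------------------------------------------------

class TestAudit:
    def test_hand_counted_fixture(self, catalog):
        """99 participants: 2 non-response codes + 1 incompatible pair = 3.0%."""
        rows = []
        for i in range(99):
            row = {"participant_id": f"b{i}", "study_id": "BRIGHT2",
                   "hospitalizations": 0}
            if i < 2:
                row["hospitalizations"] = "DK"
            elif i == 2:
                row["hospitalizations__dur1"] = 2
            rows.append(row)
        df = pd.DataFrame(rows)
        responses = [
            r for r in h.read_responses(df, catalog)
            if r.measure_id == "hospitalizations"
        ]
        audit = h.audit_missingness(responses, catalog)
        row = audit.iloc[0]
        assert row.n_asked == 99 and row.n_valid == 96
        assert (row.n_absent_code, row.n_out_of_range, row.n_incompatible) == (2, 0, 1)
        assert row.pct_missing == 3.0

    def test_zero_missing_is_zero_pct(self, catalog):
        df = pd.DataFrame(
            [{"participant_id": f"p{i}", "study_id": "PACTO", "ed_visits": 0}
             for i in range(409)]
        )
        responses = [r for r in h.read_responses(df, catalog)
                     if r.measure_id == "ed_visits"]
        audit = h.audit_missingness(responses, catalog)
        assert audit.iloc[0].pct_missing == 0.0

    def test_partition_invariant_on_synthetic_data(self, catalog):
        tables, _ = h.three_study_fixture(seed=7, catalog=catalog)
        responses = []
        for df in tables.values():
            responses += h.read_responses(df, catalog)
        audit = h.audit_missingness(responses, catalog)
        parts = audit[
            ["n_valid", "n_absent_blank", "n_absent_code",
             "n_out_of_range", "n_incompatible"]
        ].sum(axis=1)
        assert (parts == audit["n_asked"]).all()

    def test_injected_blank_rate_recovery(self, catalog):
        """5% injected blanks at n=400 are audited within 3 binomial SEs."""
        p = 0.05
        n = 400
        spec = h.default_synth_spec(catalog, seed=11)
        spec = h.SynthSpec(
            params=spec.params,
            missingness=h.MissingnessRates(p_blank=p),
            seed=11,
        )
        study = h.StudyConfig("PACTO", {"ed_visits": 182}, n_participants=n)
        cat = h.Catalog([catalog.measure("ed_visits")], [study],
                        [catalog.mcf("ed_visits")])
        clean = h.generate_study(spec, study, cat)
        table, truth = h.inject_missingness(clean, spec, cat)
        responses = h.read_responses(table, cat)
        audit = h.audit_missingness(responses, cat)
        rate = audit.iloc[0].n_absent_blank / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(rate - p) <= 3 * se
        assert audit.iloc[0].n_absent_blank == len(truth)


# ---------------------------------------------------------------------------
# Case deletion
# ---------------------------------------------------------------------------

class TestCaseDeletion:
    def test_per_measure_not_listwise(self, catalog):
        df = wide_row(catalog, "PACTO", ed_visits=3, hospitalizations="DK")
        responses = h.read_responses(df, catalog)
        kept, log = h.apply_case_deletion(responses, h.classify_all(responses, catalog))
        kept_measures = {r.measure_id for r in kept}
        assert "ed_visits" in kept_measures  # participant survives on other measures
        assert "hospitalizations" not in kept_measures
        assert log.iloc[0].measure_id == "hospitalizations"
        assert log.iloc[0].category == "absent_code"

    def test_all_valid_is_identity(self, catalog):
        tables, _ = h.three_study_fixture(seed=3, catalog=catalog, with_missingness=False)
        responses = []
        for df in tables.values():
            responses += h.read_responses(df, catalog)
        kept, log = h.apply_case_deletion(responses, h.classify_all(responses, catalog))
        assert kept == responses and len(log) == 0

    def test_fully_missing_measure_reports_empty_not_zero(self, catalog):
        df = pd.DataFrame(
            [{"participant_id": f"p{i}", "study_id": "PACTO",
              "ed_visits": "DK", "days_drug_problems": 5} for i in range(4)]
        )
        responses = [r for r in h.read_responses(df, catalog)
                     if r.measure_id in ("ed_visits", "days_drug_problems")]
        kept, _ = h.apply_case_deletion(responses, h.classify_all(responses, catalog))
        summaries = h.summarize_utilization(
            h.harmonize_responses(kept, catalog), catalog
        )
        ed = [s for s in summaries
              if s.measure_id == "ed_visits" and s.component == "combined"][0]
        assert ed.n == 0 and np.isnan(ed.mean)  # empty, not zero
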