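"""Recall normalization, the 30-day event cap, compound construction, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hrucost as h
from hrucost.harmonize import HarmonizeError

from conftest import run_tables, wide_row


class TestNormalize:
    @pytest.mark.parametrize(
        "count, months, expected",
        [(6, 6, 1.0), (0, 12, 0.0), (5, 12, 5 / 12), (3, 1, 3.0)],
    )
    def test_divide_by_months(self, count, months, expected):
        assert h.normalize_to_30day(count, months) == pytest.approx(expected)

    def test_lifetime_cannot_be_normalized(self):
        with pytest.raises(HarmonizeError, match="cannot be normalized"):
            h.normalize_to_30day(3, h.LIFETIME)

    @given(
        a=st.floats(0, 100, allow_nan=False),
        b=st.floats(0, 100, allow_nan=False),
        m=st.sampled_from([1, 6, 12]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_linearity(self, a, b, m):
        assert h.normalize_to_30day(a + b, m) == pytest.approx(
            h.normalize_to_30day(a, m) + h.normalize_to_30day(b, m)
        )


class TestCap:
    @pytest.mark.parametrize(
        "durations, expected",
        [([8, 45, 30], [8, 30, 30]), ([], []), ([31.5], [30])],
    )
    def test_cap_examples(self, durations, expected):
        assert h.cap_event_durations(durations) == expected


class TestCompound:
    @pytest.mark.parametrize(
        "count, durations, months, expected",
        [
            (1, [40], 6, 5.0),        # one 40-day stay over 6 months -> capped
            (0, [], 12, 0.0),
            (2, [3, 5], 6, 4 / 3),
        ],
    )
    def test_frequency_duration(self, count, durations, months, expected):
        value, freq, mean_capped = h.combine_frequency_duration(count, durations, months)
        assert value == pytest.approx(expected)
        assert value == pytest.approx(freq * mean_capped)
        assert mean_capped <= h.DURATION_CAP_DAYS

    def test_contradictory_pair_is_internal_error(self):
        with pytest.raises(HarmonizeError, match="case deletion"):
            h.combine_frequency_duration(2, [], 6)

    @pytest.mark.parametrize(
        "n_providers, per, months, expected",
        [(1, 2, 6, 1 / 3), (0, 0, 12, 0.0), (3, 1.5, 6, 0.75)],
    )
    def test_provider_visits(self, n_providers, per, months, expected):
        value, _, _ = h.combine_provider_visits(n_providers, per, months)
        assert value == pytest.approx(expected)

    @given(
        count=st.integers(0, 20),
        durations=st.lists(st.floats(1, 365, allow_nan=False), min_size=0, max_size=5),
        months=st.sampled_from([1, 6, 12]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_cap_bound_and_monotonicity(self, count, durations, months):
        """Value never exceeds freq × 30 and is nondecreasing in count and
        in any duration below the cap."""
        if count > 0 and not durations:
            return
        value, freq, _ = h.combine_frequency_duration(count, durations, months)
        assert value <= freq * h.DURATION_CAP_DAYS + 1e-12
        if durations:
            v_more, _, _ = h.combine_frequency_duration(count + 1, durations, months)
            assert v_more >= value - 1e-12
            bumped = [min(d + 1, h.DURATION_CAP_DAYS) if d < 30 else d for d in durations]
            v_bumped, _, _ = h.combine_frequency_duration(count, bumped, months)
            assert v_bumped >= value - 1e-12


class TestSummaries:
    def test_closed_form_sample_sd(self, catalog):
        us = [
            h.Utilization30d("p1", "PACTO", "ed_visits", 0.0),
            h.Utilization30d("p2", "PACTO", "ed_visits", 1.0),
        ]
        (s,) = [x for x in h.summarize_utilization(us, catalog)
                if x.measure_id == "ed_visits" and x.component == "combined"]
        assert s.n == 2 and s.mean == pytest.approx(0.5)
        assert s.sd == pytest.approx(1 / math.sqrt(2), abs=1e-4)

    def test_all_zero_study(self, catalog):
        us = [h.Utilization30d(f"p{i}", "PACTO", "ed_visits", 0.0) for i in range(5)]
        (s,) = [x for x in h.summarize_utilization(us, catalog)
                if x.measure_id == "ed_visits" and x.component == "combined"]
        assert s.mean == 0.0 and s.sd == 0.0

    def test_single_participant_sd_flagged(self, catalog):
        us = [h.Utilization30d("p1", "PACTO", "ed_visits", 2.0)]
        (s,) = [x for x in h.summarize_utilization(us, catalog)
                if x.measure_id == "ed_visits" and x.component == "combined"]
        assert s.n == 1 and np.isnan(s.sd)

    def test_mean_of_products_not_product_of_means(self, catalog):
        """Two participants whose per-participant products differ from the
        product of the component means pin the pipeline to mean-of-products."""
        import pandas as pd

        rows = [
            # p1: 6 stays over 6 months, 2 days each -> (6/6) × 2 = 2.0
            dict(participant_id="p1", study_id="PACTO",
                 hospitalizations=6, hospitalizations__dur1=2,
                 hospitalizations__dur2=2, hospitalizations__dur3=2,
                 hospitalizations__dur4=2, hospitalizations__dur5=2),
            # p2: 3 stays over 6 months, 10 days each -> (3/6) × 10 = 5.0
            dict(participant_id="p2", study_id="PACTO",
                 hospitalizations=3, hospitalizations__dur1=10,
                 hospitalizations__dur2=10, hospitalizations__dur3=10),
        ]
        df = pd.DataFrame(rows)
        responses = [r for r in h.read_responses(df, catalog)
                     if r.measure_id == "hospitalizations"]
        utils = h.harmonize_responses(responses, catalog)
        (s,) = [x for x in h.summarize_utilization(utils, catalog)
                if x.measure_id == "hospitalizations" and x.component == "combined"]
        assert s.mean == pytest.approx(3.5)  # mean of per-participant products
        freq_mean = (1.0 + 0.5) / 2
        dur_mean = (2.0 + 10.0) / 2
        assert freq_mean * dur_mean == pytest.approx(4.5)  # product of means differs

    def test_oracle_equivalence_brute_force(self, catalog):
        """Pipeline per-measure means equal an independent brute-force loop
        over raw responses, to 1e-9."""
        tables, _ = h.three_study_fixture(seed=5, catalog=catalog)
        out = run_tables(tables, catalog)
        # brute force: recompute each participant's value from the raw record
        expected: dict[tuple, list[float]] = {}
        for r in out["kept"]:
            m = catalog.measure(r.measure_id)
            s = catalog.study(r.study_id)
            if m.structure == "binary" or s.recall_days[r.measure_id] == h.LIFETIME:
                continue
            months = s.recall_months(r.measure_id)
            if m.structure == "frequency_duration":
                durs = [float(d) for d in r.event_durations if d is not None]
                capped = [min(d, 30.0) for d in durs]
                v = (float(r.count_value) / months) * (
                    sum(capped) / len(capped) if capped else 0.0
                )
            elif m.structure == "provider_visits":
                sec = float(r.secondary_count) if r.secondary_count is not None else 0.0
                v = (float(r.count_value) / months) * sec
            else:
                v = float(r.count_value) / months
            expected.setdefault((r.study_id, r.measure_id), []).append(v)
        got = {
            (s.study_id, s.measure_id): s.mean
            for s in out["summaries"]
            if s.component == "combined" and s.n > 0
        }
        assert set(got) == set(expected)
        for key, vals in expected.items():
            assert got[key] == pytest.approx(sum(vals) / len(vals), abs=1e-9)

    def test_clt_recovery_of_generator_mean(self, catalog):
        """At n=5000 the harmonized ED mean matches the spec-implied mean
        within 3 standard errors."""
        study = h.StudyConfig("PACTO", {"ed_visits": 182}, n_participants=5000)
        cat = h.Catalog([catalog.measure("ed_visits")], [study],
                        [catalog.mcf("ed_visits")])
        spec = h.default_synth_spec(cat, seed=13)
        p = spec.params[("PACTO", "ed_visits")]
        target = h.expected_mean_30d(p, "single_count", 6)
        df = h.generate_study(spec, study, cat)
        responses = h.read_responses(df, cat)
        utils = h.harmonize_responses(responses, cat)
        values = [u.value for u in utils]
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(np.mean(values) - target) <= 3 * se
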