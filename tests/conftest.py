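import pandas as pd
import pytest

import hrucost as h


@pytest.fixture(scope="session")
def catalog():
    return h.default_catalog()


def run_tables(tables, catalog):
    """Run wide response tables through the full pipeline; return a dict of
    intermediate products (used by many tests)."""
    responses = []
    for df in tables.values():
        responses += h.read_responses(df, catalog)
    classifications = h.classify_all(responses, catalog)
    audit = h.audit_missingness(responses, catalog, classifications)
    kept, deletion_log = h.apply_case_deletion(responses, classifications)
    utilizations = h.harmonize_responses(kept, catalog)
    summaries = h.summarize_utilization(utilizations, catalog)
    cost_table = h.build_cost_table(summaries, catalog)
    return {
        "responses": responses,
        "classifications": classifications,
        "audit": audit,
        "kept": kept,
        "deletion_log": deletion_log,
        "utilizations": utilizations,
        "summaries": summaries,
        "cost_table": cost_table,
    }


@pytest.fixture(scope="session")
def constant_run(catalog):
    """Full pipeline over the degenerate (constant-at-published-mean) fixture."""
    return run_tables(h.constant_mean_fixture(catalog), catalog)


def wide_row(catalog, study_id, participant_id="p1", **values):
    """One-participant wide table with explicit cell values (others blank)."""
    study = catalog.study(study_id)
    cols = {"participant_id": participant_id, "study_id": study_id}
    for mid in study.recall_days:
        m = catalog.measure(mid)
        cols.setdefault(mid, "")
        if m.structure == "frequency_duration":
            for i in range(1, study.max_recorded_events + 1):
                cols.setdefault(f"{mid}__dur{i}", "")
        elif m.structure == "provider_visits":
            cols.setdefault(f"{mid}__per", "")
    cols.update(values)
    return pd.DataFrame([cols])
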