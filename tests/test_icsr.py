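"""Parsing, ATC assignment and the exclusion cascade."""

from __future__ import annotations

import pandas as pd
import pytest

from agepnet import (
    AtcMap,
    apply_exclusions,
    assign_atc,
    default_agep_like_config,
    generate_reports,
    parse_icsr_table,
    simulate_report_set,
)
from agepnet.icsr import ConfigurationError, TableDialect, normalize_name

from conftest import (
    CASCADE_ATC,
    CASCADE_EXPECTED_FLOW,
    CASCADE_RETAINED,
    cascade_table,
)


def test_parse_counts_entries_and_reports():
    df = pd.DataFrame(
        {
            "report_id": ["r1", "r1", "r2"],
            "drug_name": [" Amoxicillin ", "Furosemide", "bisoprolol"],
        }
    )
    entries, meta, counters = parse_icsr_table(df)
    assert len(entries) == 3
    assert meta["report_id"].tolist() == ["r1", "r2"]
    assert counters == {"rows": 3, "rejected_rows": 0}
    # whitespace trimmed and lowercased
    assert entries["drug_name"].tolist() == [
        "amoxicillin", "furosemide", "bisoprolol"
    ]


def test_parse_rejects_empty_drug_names():
    df = pd.DataFrame(
        {"report_id": ["r1", "r1"], "drug_name": ["amoxicillin", "   "]}
    )
    entries, _, counters = parse_icsr_table(df)
    assert len(entries) == 1
    assert counters["rejected_rows"] == 1


def test_parse_missing_required_column_names_it():
    df = pd.DataFrame({"report_id": ["r1"]})
    with pytest.raises(ConfigurationError, match="drug_name"):
        parse_icsr_table(df)


def test_parse_custom_dialect_columns():
    df = pd.DataFrame({"UMCReportId": ["a"], "ActiveSubstance": ["x"]})
    dialect = TableDialect(columns={"report_id": "UMCReportId",
                                    "drug_name": "ActiveSubstance"})
    entries, _, _ = parse_icsr_table(df, dialect)
    assert entries["report_id"].tolist() == ["a"]


def test_atc_map_validates_syntax_and_prefixes():
    AtcMap({"bisoprolol": "C07AB07", "beta blockers": "C07"})
    with pytest.raises(ConfigurationError):
        AtcMap({"bad": "7C0AB07"})


def test_atc_multi_code_tie_break_is_lexicographic_min(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        amap = AtcMap.from_pairs(
            [("acetylsalicylic acid", "N02BA01"),
             ("acetylsalicylic acid", "B01AC06")]
        )
    assert amap.get("acetylsalicylic acid") == "B01AC06"
    assert any("multiple ATC codes" in r.message for r in caplog.records)


def test_assign_atc_sets_code_and_main_group():
    entries = pd.DataFrame(
        {"report_id": ["r1", "r1"], "drug_name": ["bisoprolol", "nonesuch"],
         "role": ["suspected", "concomitant"]}
    )
    out = assign_atc(entries, AtcMap({"bisoprolol": "C07AB07"}))
    assert out.loc[0, "atc_code"] == "C07AB07"
    assert out.loc[0, "atc1"] == "C"
    assert pd.isna(out.loc[1, "atc_code"])  # unmapped flagged for exclusion


def test_cascade_flow_counters_match_hand_counts(cascade_report_set):
    flow = cascade_report_set.flow
    assert flow.extracted == CASCADE_EXPECTED_FLOW["extracted"]
    assert flow.after_duplicate_removal == \
        CASCADE_EXPECTED_FLOW["after_duplicate_removal"]
    assert flow.after_drug_exclusions == \
        CASCADE_EXPECTED_FLOW["after_drug_exclusions"]
    assert flow.retained == CASCADE_EXPECTED_FLOW["retained"]
    # per-stage exclusions sum to extracted - retained
    assert (flow.excluded_duplicates + flow.excluded_no_mapped_drug
            + flow.excluded_single_drug) == flow.extracted - flow.retained


def test_cascade_retained_sets_match_exactly(cascade_report_set):
    got = {r.report_id: set(r.drugs) for r in cascade_report_set.reports}
    assert got == CASCADE_RETAINED
    assert all(len(r.drugs) >= 2 for r in cascade_report_set.reports)
    # every retained drug carries an ATC code
    assert all(cascade_report_set.atc[d] for d in cascade_report_set.drug_names())


def test_cascade_is_idempotent(cascade_report_set):
    """Re-applying the filters to the retained cohort changes nothing."""
    rows = []
    for r in cascade_report_set.reports:
        for d in sorted(r.drugs):
            rows.append({"report_id": r.report_id, "drug_name": d,
                         "duplicate": False})
    entries, meta, _ = parse_icsr_table(pd.DataFrame(rows))
    again = apply_exclusions(entries, meta, AtcMap(CASCADE_ATC))
    assert {r.report_id: r.drugs for r in again.reports} == \
        {r.report_id: r.drugs for r in cascade_report_set.reports}
    assert again.flow.extracted == again.flow.retained


def test_repeated_ingredient_collapses_to_single_drug_report():
    df = pd.DataFrame(
        {"report_id": ["r1", "r1"],
         "drug_name": ["amoxicillin", "Amoxicillin "]}
    )
    entries, meta, _ = parse_icsr_table(df)
    rs = apply_exclusions(entries, meta, AtcMap({"amoxicillin": "J01CA04"}))
    assert rs.n_reports == 0  # one distinct drug -> below the >=2 threshold
    assert rs.flow.after_drug_exclusions == 1


def test_generator_output_round_trips_through_files(tmp_path):
    """Write-then-parse yields the identical retained cohort."""
    config = default_agep_like_config(n_reports=400, seed=5)
    direct, _ = simulate_report_set(config)

    entries, meta, _ = generate_reports(config)
    path = tmp_path / "table.tsv"
    entries.merge(meta, on="report_id", how="left").to_csv(
        path, sep="\t", index=False)
    parsed_entries, parsed_meta, _ = parse_icsr_table(str(path))
    from_file = apply_exclusions(parsed_entries, parsed_meta, config.atc_map())

    assert from_file.flow == direct.flow
    assert {r.report_id: r.drugs for r in from_file.reports} == \
        {r.report_id: r.drugs for r in direct.reports}
    assert [(r.sex, r.age_group, r.serious, r.death)
            for r in from_file.reports] == \
        [(r.sex, r.age_group, r.serious, r.death) for r in direct.reports]


def test_normalize_name_collapses_whitespace():
    assert normalize_name("  Valproic   ACID ") == "valproic acid"
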